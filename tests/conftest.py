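import numpy as np
import pytest

from bacfinish import simulate as sim


@pytest.fixture(scope="session")
def small_pool():
    """Three distinct small clones sharing one vector (desk scale)."""
    return sim.make_clone_pool(
        3, vector_len=3000, insert_len_range=(12_000, 15_000), seed=7
    )


@pytest.fixture(scope="session")
def small_reads(small_pool):
    return sim.simulate_nanopore_run(small_pool, 90, p_single_cut=0.3, seed=8)


@pytest.fixture(scope="session")
def small_drafts(small_pool):
    return {
        c.clone_id: [s for _, s in sim.degrade_to_draft(c, seed=9)]
        for c in small_pool
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))
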