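"""Synthetic clone-pool generator: determinism, structure, error models."""

import numpy as np
import pytest

from bacfinish import seq as sq
from bacfinish import simulate as sim
from bacfinish.align import align_pair

from .oracles import global_identity


class TestClonePool:
    def test_single_clone_construction(self):
        pool = sim.make_clone_pool(1, vector_len=3000, insert_len_range=(5000, 5000), seed=3)
        clone = pool[0]
        assert clone.vector_interval == (0, 3000)
        assert len(clone) == 8000
        assert set(clone.sequence) <= set("ACGT")

    def test_same_seed_is_byte_identical(self):
        a = sim.make_clone_pool(3, insert_len_range=(5000, 6000), seed=11)
        b = sim.make_clone_pool(3, insert_len_range=(5000, 6000), seed=11)
        assert [c.sequence for c in a] == [c.sequence for c in b]
        assert a[0].vector == b[0].vector

    def test_clones_share_one_vector(self):
        pool = sim.make_clone_pool(3, insert_len_range=(5000, 6000), seed=12)
        assert len({c.vector for c in pool}) == 1

    def test_repeat_units_identity_in_band(self):
        spec = sim.RepeatSpec(n_units=2, unit_len=1000, unit_identity=0.99)
        pool = sim.make_clone_pool(
            1, insert_len_range=(6000, 6000), repeat_spec=spec, sfv_per_unit=2, seed=5
        )
        clone = pool[0]
        assert len(clone.repeat_units) == 2
        (a1, b1), (a2, b2) = [u.interval for u in clone.repeat_units]
        u1 = clone.sequence[a1:b1]
        u2 = clone.sequence[a2:b2]
        ident = global_identity(u1, u2)
        assert 0.99 <= ident < 1.0

    def test_sfvs_fall_inside_units_with_recorded_allele(self):
        spec = sim.RepeatSpec(n_units=3, unit_len=800, unit_identity=0.99)
        pool = sim.make_clone_pool(
            1, insert_len_range=(6000, 6000), repeat_spec=spec, sfv_per_unit=2, seed=6
        )
        clone = pool[0]
        for site in clone.sfv_sites:
            u = clone.repeat_units[site.unit_index]
            a, b = u.interval
            assert 0 <= site.offset < b - a
            assert clone.sequence[a + site.offset] == site.allele

    def test_palindrome_arms_are_inverted(self):
        spec = sim.RepeatSpec(n_units=2, unit_len=1000, unit_identity=0.995,
                              arrangement="palindrome")
        pool = sim.make_clone_pool(
            1, insert_len_range=(6000, 6000), repeat_spec=spec, sfv_per_unit=1, seed=8
        )
        u0, u1 = pool[0].repeat_units
        assert (u0.orientation, u1.orientation) == ("direct", "inverted")
        arm1 = pool[0].sequence[u0.interval[0] : u0.interval[1]]
        arm2 = pool[0].sequence[u1.interval[0] : u1.interval[1]]
        assert global_identity(arm1, sq.revcomp(arm2)) >= 0.99

    def test_rejections(self):
        with pytest.raises(ValueError):
            sim.make_clone_pool(0, seed=1)
        with pytest.raises(ValueError):
            spec = sim.RepeatSpec(n_units=4, unit_len=2000)
            sim.make_clone_pool(1, insert_len_range=(5000, 5000), repeat_spec=spec, seed=1)
        with pytest.raises(ValueError):
            spec = sim.RepeatSpec(n_units=2, unit_len=1000)
            sim.make_clone_pool(
                1, insert_len_range=(6000, 6000), repeat_spec=spec,
                sfv_per_unit=0, seed=1,
            )
        # explicit override downgrades the rejection to a warning
        with pytest.warns(UserWarning):
            spec = sim.RepeatSpec(n_units=2, unit_len=1000)
            sim.make_clone_pool(
                1, insert_len_range=(6000, 6000), repeat_spec=spec,
                sfv_per_unit=0, seed=1, allow_indistinguishable=True,
            )
        with pytest.raises(ValueError):
            sim.RepeatSpec(n_units=2, unit_len=1000, unit_identity=0.95)


class TestNanoporeRun:
    def test_zero_error_single_cut_reads_are_rotations(self, small_pool):
        reads = sim.simulate_nanopore_run(
            small_pool[:1], 6, p_single_cut=1.0,
            error_model=sim.ErrorModel(0, 0, 0, 1.0), seed=21,
        )
        truth = small_pool[0].sequence
        for r in reads:
            assert len(r.bases) == len(truth)
            oriented = r.bases if r.truth.strand == "+" else sq.revcomp(r.bases)
            assert oriented == sq.rotate(truth, r.truth.cut_position)

    def test_deterministic_for_seed(self, small_pool):
        a = sim.simulate_nanopore_run(small_pool, 20, seed=22)
        b = sim.simulate_nanopore_run(small_pool, 20, seed=22)
        assert [r.bases for r in a] == [r.bases for r in b]

    def test_adding_reads_preserves_earlier_reads(self, small_pool):
        a = sim.simulate_nanopore_run(small_pool, 10, seed=23)
        b = sim.simulate_nanopore_run(small_pool, 20, seed=23)
        assert [r.bases for r in a] == [r.bases for r in b[:10]]

    def test_mean_read_identity_matches_error_budget(self):
        # 20 fragments through the error model, identity measured by the
        # quadratic DP oracle, compared with the rate budget adjusted for
        # the homopolymer indel multiplier; rates low enough that the
        # first-order budget is exact to well within the tolerance (at high
        # rates the minimum-edit alignment re-explains adjacent events)
        em = sim.ErrorModel(sub=0.02, ins=0.01, dele=0.01,
                            homopolymer_indel_multiplier=6.0)
        rng = np.random.default_rng(24)
        idents = []
        hp_fracs = []
        for i in range(20):
            codes = rng.integers(0, 4, size=800, dtype=np.uint8)
            mutated = sim.mutate_codes(codes, em, np.random.default_rng(500 + i))
            idents.append(global_identity(sq.decode(codes), sq.decode(mutated)))
            hp_fracs.append(sq.homopolymer_runs(codes, 3).mean())
        hp_frac = float(np.mean(hp_fracs))
        mult = em.homopolymer_indel_multiplier
        eff_ins = em.ins * (1 + (mult - 1) * hp_frac)
        eff_del = em.dele * (1 + (mult - 1) * hp_frac)
        expected = (1 - eff_del) * (1 - em.sub) / (1 + eff_ins)
        assert abs(float(np.mean(idents)) - expected) <= 0.01

    def test_balanced_pool_read_share(self):
        pool = sim.make_clone_pool(24, insert_len_range=(5000, 5000), seed=30)
        reads = sim.simulate_nanopore_run(
            pool, 24_000, p_single_cut=0.2,
            length_model=sim.LengthModel(2000), seed=31,
        )
        share = sim.read_share(reads, pool)
        assert max(share.values()) <= 1 / 24 + 0.01
        assert min(share.values()) >= 1 / 24 - 0.01

    def test_rejects_bad_inputs(self, small_pool):
        with pytest.raises(ValueError):
            sim.simulate_nanopore_run(small_pool, 0, seed=1)
        with pytest.raises(ValueError):
            sim.simulate_nanopore_run([], 10, seed=1)
        with pytest.raises(ValueError):
            sim.ErrorModel(sub=1.5)


class TestIllumina:
    def test_coverage_arithmetic(self, small_pool):
        clone = small_pool[0]
        pairs = sim.simulate_illumina([clone], coverage=50, read_len=150, seed=41)
        total = sum(len(p.bases1) + len(p.bases2) for p in pairs)
        assert abs(total - 50 * len(clone)) <= 0.05 * 50 * len(clone)

    def test_error_free_pairs_are_circular_substrings(self, small_pool):
        clone = small_pool[0]
        pairs = sim.simulate_illumina([clone], coverage=2, sub_rate=0.0, seed=42)
        doubled = clone.sequence + clone.sequence
        for p in pairs[:40]:
            assert p.bases1 in doubled
            assert sq.revcomp(p.bases2) in doubled

    def test_reproducible(self, small_pool):
        a = sim.simulate_illumina(small_pool, coverage=1, seed=43)
        b = sim.simulate_illumina(small_pool, coverage=1, seed=43)
        assert [(p.bases1, p.bases2) for p in a] == [(p.bases1, p.bases2) for p in b]

    def test_rejects_short_fragments(self, small_pool):
        with pytest.raises(ValueError):
            sim.simulate_illumina(small_pool, coverage=1, read_len=150, frag_len=200, seed=1)


class TestDraft:
    def test_identity_case(self, small_pool):
        clone = small_pool[0]
        contigs = sim.degrade_to_draft(clone, collapse_repeats=False,
                                       error_rate=0.0, n_contig_breaks=0, seed=51)
        assert contigs == [(clone.clone_id, clone.sequence)]

    def test_collapse_shortens_by_about_one_unit(self):
        spec = sim.RepeatSpec(n_units=2, unit_len=1500, unit_identity=0.995)
        pool = sim.make_clone_pool(
            1, insert_len_range=(8000, 8000), repeat_spec=spec, sfv_per_unit=2, seed=52
        )
        clone = pool[0]
        contigs = sim.degrade_to_draft(clone, collapse_repeats=True, seed=53)
        total = sum(len(s) for _, s in contigs)
        assert abs((len(clone) - total) - 1500) <= 10

    def test_contig_breaks(self, small_pool):
        clone = small_pool[0]
        contigs = sim.degrade_to_draft(clone, collapse_repeats=False,
                                       n_contig_breaks=2, seed=54)
        assert len(contigs) == 3
        assert "".join(s for _, s in contigs) == clone.sequence
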