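"""Vector anchoring, full-length classification, rotation, length estimate."""

from collections import Counter

import numpy as np
import pytest

from bacfinish import fullread as flr
from bacfinish import seq as sq
from bacfinish import simulate as sim


@pytest.fixture(scope="module")
def clone_and_vector(small_pool):
    clone = small_pool[0]
    return clone, clone.vector


def _cut_read(clone, cut, strand="+"):
    bases = sq.rotate(clone.sequence, cut)
    if strand == "-":
        bases = sq.revcomp(bases)
    return sim.NanoporeRead(f"cut{cut}{strand}", bases, sim.ReadTruth(clone.clone_id, cut, strand, False))


class TestVectorHits:
    def test_cut_in_vector_hits_both_ends(self, clone_and_vector):
        clone, vector = clone_and_vector
        read = _cut_read(clone, 1500)
        hits = flr.find_vector_hits(read, vector)
        L = len(read.bases)
        assert any(h.interval[0] < 100 for h in hits)
        assert any(h.interval[1] > L - 100 for h in hits)

    def test_cut_in_insert_single_internal_hit(self, clone_and_vector):
        clone, vector = clone_and_vector
        read = _cut_read(clone, 9000)
        hits = flr.find_vector_hits(read, vector)
        assert len(hits) == 1
        assert hits[0].identity == 1.0
        a, b = hits[0].interval
        assert 0 < a and b < len(read.bases)


class TestClassify:
    def test_zero_error_cut_in_vector_is_anchored(self, clone_and_vector):
        clone, vector = clone_and_vector
        for cut in (200, 1500, 2800):
            call = flr.classify_full_length(_cut_read(clone, cut), vector,
                                            clone_length_estimate=len(clone))
            assert call.status == flr.FULL_VECTOR_ANCHORED

    def test_cut_mid_insert_with_estimate_is_putative(self, clone_and_vector):
        clone, vector = clone_and_vector
        call = flr.classify_full_length(_cut_read(clone, 9000), vector,
                                        clone_length_estimate=len(clone))
        assert call.status == flr.PUTATIVE_FULL_BY_LENGTH

    def test_half_length_read_is_partial(self, clone_and_vector):
        clone, vector = clone_and_vector
        half = sim.NanoporeRead("half", clone.sequence[4000 : 4000 + len(clone) // 2])
        call = flr.classify_full_length(half, vector, clone_length_estimate=len(clone))
        assert call.status == flr.PARTIAL

    def test_vector_only_fragment_is_not_anchored(self, clone_and_vector):
        clone, vector = clone_and_vector
        frag = sim.NanoporeRead("vec", clone.sequence[100:2900])
        call = flr.classify_full_length(frag, vector, clone_length_estimate=len(clone))
        assert call.status == flr.PARTIAL

    def test_zero_error_full_recall_and_vector_cuts_anchored(self, small_pool):
        clone = small_pool[1]
        vector = clone.vector
        reads = sim.simulate_nanopore_run(
            [clone], 20, p_single_cut=1.0,
            error_model=sim.ErrorModel(0, 0, 0, 1.0), seed=71,
        )
        est = len(clone)
        statuses = Counter()
        for r in reads:
            call = flr.classify_full_length(r, vector, clone_length_estimate=est)
            statuses[call.status] += 1
            if r.truth.cut_position < len(vector):
                assert call.status == flr.FULL_VECTOR_ANCHORED
        assert statuses[flr.PARTIAL] == 0


class TestRotate:
    def test_worked_toy_rotation(self):
        # clone AAAACCCCGGGGTTTT with vector AAAA, cut at 8
        clone = "AAAACCCCGGGGTTTT"
        read = sim.NanoporeRead("toy", clone[8:] + clone[:8])
        hit = flr.VectorHit((8, 12), "+", 1.0, (0, 4))
        call = flr.FullLengthCall("toy", flr.PUTATIVE_FULL_BY_LENGTH,
                                  [hit], rotation_offset=8)
        assert flr.rotate_to_vector(read, call).bases == clone

    def test_rotation_group_property(self):
        s = "ACGTACGTGGCA" * 4
        assert sq.rotate(sq.rotate(s, 13), len(s) - 13) == s
        assert sq.rotate(s, len(s)) == s

    def test_rotation_preserves_length_and_base_multiset(self, clone_and_vector):
        clone, vector = clone_and_vector
        # plus-strand read: pure rotation, multiset and length invariant
        read = _cut_read(clone, 7000, "+")
        call = flr.classify_full_length(read, vector, clone_length_estimate=len(clone))
        rotated = flr.rotate_to_vector(read, call)
        assert len(rotated.bases) == len(read.bases)
        assert Counter(rotated.bases) == Counter(read.bases)
        # minus-strand read: length still invariant after strand flip
        read_m = _cut_read(clone, 7000, "-")
        call_m = flr.classify_full_length(read_m, vector, clone_length_estimate=len(clone))
        rotated_m = flr.rotate_to_vector(read_m, call_m)
        assert len(rotated_m.bases) == len(read_m.bases)
        assert rotated_m.bases == rotated.bases  # same canonical form

    def test_zero_error_rotation_recovers_truth(self, small_pool):
        clone = small_pool[2]
        vector = clone.vector
        reads = sim.simulate_nanopore_run(
            [clone], 20, p_single_cut=1.0,
            error_model=sim.ErrorModel(0, 0, 0, 1.0), seed=72,
        )
        for r in reads:
            call = flr.classify_full_length(r, vector, clone_length_estimate=len(clone))
            assert call.status != flr.PARTIAL
            assert flr.rotate_to_vector(r, call).bases == clone.sequence

    def test_refuses_vector_chimera(self, clone_and_vector):
        clone, vector = clone_and_vector
        # two well-separated internal vector copies: a vector-vector artifact
        chim = clone.sequence[3000:8000] + vector + clone.sequence[8000:12_000] + vector + clone.sequence[12_000:16_000]
        read = sim.NanoporeRead("chimera", chim)
        hits = flr.find_vector_hits(read, vector)
        call = flr.FullLengthCall("chimera", flr.PUTATIVE_FULL_BY_LENGTH, hits)
        with pytest.raises(ValueError):
            flr.rotate_to_vector(read, call)


class TestLengthEstimate:
    def test_constant_lengths(self):
        est = flr.estimate_clone_length([120_000] * 30)
        assert abs(est - 120_000) <= 1000

    def test_peak_in_exponential_tail(self):
        # sparse exponential tail plus a tight cluster of full-length reads
        rng = np.random.default_rng(73)
        short = rng.exponential(2000, size=40).astype(int) + 500
        full = rng.integers(149_800, 150_200, size=8)
        est = flr.estimate_clone_length(list(short) + list(full))
        assert est is not None
        assert abs(est - 150_000) <= 2000

    def test_uniform_lengths_no_peak(self):
        rng = np.random.default_rng(74)
        lengths = rng.integers(1000, 100_000, size=40)
        assert flr.estimate_clone_length(list(lengths)) is None

    def test_too_few_reads(self):
        with pytest.warns(UserWarning):
            assert flr.estimate_clone_length([5000] * 10) is None
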