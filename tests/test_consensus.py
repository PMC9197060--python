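"""Backbone selection, long-read polishing, short-read correction."""

import numpy as np
import pytest

from bacfinish import consensus as cns
from bacfinish import fullread as flr
from bacfinish import seq as sq
from bacfinish import simulate as sim
from bacfinish.align import align_pair

from .conftest import random_dna


def _plant_errors(seq, n, rng):
    codes = sq.encode(seq)
    pos = rng.choice(len(seq), size=n, replace=False)
    codes[pos] = (codes[pos] + rng.integers(1, 4, size=n)) % 4
    return sq.decode(codes), set(int(p) for p in pos)


class TestSelectBackbone:
    def _call(self, read_id, status=flr.FULL_VECTOR_ANCHORED):
        return flr.FullLengthCall(read_id, status, [], 0, False)

    def test_single_full_length_read_wins(self, rng):
        s = random_dna(rng, 4000)
        reads = [sim.NanoporeRead("a", s)]
        bb = cns.select_backbone([self._call("a")], reads, s)
        assert bb.read_id == "a"
        assert bb.bases == s

    def test_tie_breaks_to_lexicographically_smaller_id(self, rng):
        s = random_dna(rng, 4000)
        reads = [sim.NanoporeRead("b", s), sim.NanoporeRead("a", s)]
        bb = cns.select_backbone([self._call("b"), self._call("a")], reads, s)
        assert bb.read_id == "a"

    def test_highest_identity_vs_draft_wins(self, rng):
        draft = random_dna(rng, 5000)
        reads, calls = [], []
        best_id = None
        for i, n_err in enumerate([120, 40, 200, 80, 10]):
            bases, _ = _plant_errors(draft, n_err, np.random.default_rng(200 + i))
            rid = f"r{i}"
            reads.append(sim.NanoporeRead(rid, bases))
            calls.append(self._call(rid))
            if n_err == 10:
                best_id = rid
        bb = cns.select_backbone(calls, reads, draft)
        assert bb.read_id == best_id

    def test_no_reads_falls_back_to_draft_with_warning(self, rng):
        draft = random_dna(rng, 4000)
        with pytest.warns(UserWarning):
            bb = cns.select_backbone([], [], draft)
        assert bb.bases == draft

    def test_nothing_to_build_from_raises(self):
        with pytest.raises(ValueError):
            cns.select_backbone([], [], None)


class TestPolishLong:
    def test_identical_reads_are_a_fixed_point(self, rng):
        s = random_dna(rng, 6000)
        reads = [sim.NanoporeRead(f"r{i}", s) for i in range(5)]
        out, info = cns.polish_long(s, reads, rounds=1, circular=False)
        assert out == s

    def test_planted_backbone_errors_are_corrected(self, rng):
        truth = random_dna(rng, 6000)
        backbone, _ = _plant_errors(truth, 50, rng)
        reads = [sim.NanoporeRead(f"r{i}", truth) for i in range(10)]
        out, info = cns.polish_long(backbone, reads, rounds=1, circular=False)
        assert out == truth

    def test_noisy_reads_monotonically_improve_backbone(self):
        rng = np.random.default_rng(210)
        truth = random_dna(rng, 6000)
        em = sim.ErrorModel()
        reads = []
        for i in range(12):
            mutated = sim.mutate_codes(sq.encode(truth), em, np.random.default_rng(300 + i))
            reads.append(sim.NanoporeRead(f"r{i}", sq.decode(mutated)))
        backbone = reads[0].bases
        in_ident = align_pair(backbone, truth, band=500).identity
        out, _ = cns.polish_long(backbone, reads, rounds=2, circular=False)
        out_ident = align_pair(out, truth, band=500).identity
        assert out_ident > in_ident

    def test_parameter_validation(self, rng):
        s = random_dna(rng, 1000)
        with pytest.raises(ValueError):
            cns.polish_long(s, [], window=50)
        with pytest.raises(ValueError):
            cns.polish_long(s, [], rounds=0)


class TestPolishShort:
    def test_homopolymer_run_corrected_to_short_consensus(self, rng):
        # consensus has a 6-A run; every short read shows 5 A's
        left = random_dna(rng, 400).rstrip("A")
        right = random_dna(rng, 400).lstrip("A")
        truth = left + "AAAAA" + right
        wrong = left + "AAAAAA" + right
        reads = [(f"r{i}", truth[j : j + 150])
                 for i, j in enumerate(range(0, len(truth) - 150, 10))]
        asm = cns.polish_short(wrong, reads * 2)
        assert asm.sequence == truth
        hp = [d for d in asm.discrepancies if d.klass == cns.HOMOPOLYMER_INDEL]
        assert len(hp) == 1
        assert hp[0].nanopore_allele == "AAAAAA"
        assert hp[0].illumina_allele == "AAAAA"

    def test_even_split_is_unresolved_and_unedited(self, rng):
        truth = random_dna(rng, 600)
        p = 300
        alt = "ACGT"[("ACGT".index(truth[p]) + 1) % 4]
        other = truth[:p] + alt + truth[p + 1 :]
        reads = []
        for i, j in enumerate(range(0, 450, 15)):
            reads.append((f"a{i}", truth[j : j + 150]))
            reads.append((f"b{i}", other[j : j + 150]))
        asm = cns.polish_short(truth, reads)
        assert asm.sequence == truth
        unres = [d for d in asm.discrepancies if d.klass == cns.UNRESOLVED]
        assert any(d.position == p for d in unres)

    def test_substitution_corrected_and_logged(self, rng):
        truth = random_dna(rng, 600)
        wrong, planted = _plant_errors(truth, 1, rng)
        reads = [(f"r{i}", truth[j : j + 150])
                 for i, j in enumerate(range(0, 450, 10))]
        asm = cns.polish_short(wrong, reads * 2)
        assert asm.sequence == truth
        assert len([d for d in asm.discrepancies if d.klass != cns.UNRESOLVED]) == 1

    def test_idempotent_fixed_point(self, rng):
        truth = random_dna(rng, 800)
        wrong, _ = _plant_errors(truth, 3, rng)
        reads = [(f"r{i}", truth[j : j + 150])
                 for i, j in enumerate(range(0, 650, 8))]
        once = cns.polish_short(wrong, reads)
        twice = cns.polish_short(once.sequence, reads)
        assert twice.sequence == once.sequence
        assert not any(d.klass != cns.UNRESOLVED for d in twice.discrepancies)

    def test_no_short_reads_returns_input_with_warning(self, rng):
        s = random_dna(rng, 500)
        with pytest.warns(UserWarning):
            asm = cns.polish_short(s, [])
        assert asm.sequence == s

    def test_threshold_validation(self, rng):
        s = random_dna(rng, 500)
        with pytest.raises(ValueError):
            cns.polish_short(s, [("r", s[:150])], min_depth=5)
        with pytest.raises(ValueError):
            cns.polish_short(s, [("r", s[:150])], min_agree=0.5)

    def test_discrepancy_positions_strictly_increasing(self, rng):
        truth = random_dna(rng, 900)
        wrong, _ = _plant_errors(truth, 6, rng)
        reads = [(f"r{i}", truth[j : j + 150])
                 for i, j in enumerate(range(0, 750, 8))]
        asm = cns.polish_short(wrong, reads)
        positions = [d.position for d in asm.discrepancies]
        assert positions == sorted(positions)
        assert len(positions) == len(set(positions))


def test_vector_prefix_preserved_through_polish(small_pool):
    clone = small_pool[0]
    reads = sim.simulate_nanopore_run([clone], 25, p_single_cut=0.4, seed=220)
    est = flr.estimate_clone_length([len(r) for r in reads])
    calls = [flr.classify_full_length(r, clone.vector, clone_length_estimate=est)
             for r in reads]
    bb = cns.select_backbone(calls, reads, clone.sequence)
    polished, _ = cns.polish_long(bb.bases, reads, rounds=2)
    # the anchored coordinate frame survives polishing: the vector still
    # maps at the very start of the consensus, spanning its full length
    from bacfinish.align import map_read

    hit = map_read(("v", clone.vector), [("cons", polished)], preset="long")[0]
    assert hit.strand == "+"
    assert hit.t_interval[0] <= 50
    assert hit.q_span() >= 0.95 * len(clone.vector)
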