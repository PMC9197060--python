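"""Repeat-unit detection, SFV calling, divide-and-conquer finishing."""

import numpy as np
import pytest

from bacfinish import repeats as rpt
from bacfinish import seq as sq
from bacfinish import simulate as sim

from .conftest import random_dna

MIN_LEN = 1500


def _tandem_clone(seed, n_units=2, unit_len=2000, sfv_per_unit=2, identity=0.99,
                  arrangement="tandem"):
    spec = sim.RepeatSpec(n_units=n_units, unit_len=unit_len,
                          unit_identity=identity, arrangement=arrangement)
    return sim.make_clone_pool(
        1, vector_len=2000,
        insert_len_range=(n_units * unit_len + 4000,) * 2,
        repeat_spec=spec, sfv_per_unit=sfv_per_unit, seed=seed,
    )[0]


class TestDetect:
    def test_two_planted_tandem_units(self):
        clone = _tandem_clone(80)
        units = rpt.detect_self_repeats(clone.sequence, min_len=MIN_LEN)
        assert len(units) == 2
        assert all(u.orientation == "direct" for u in units)
        assert len({u.paralog_group for u in units}) == 1
        for got, exp in zip(units, clone.repeat_units):
            assert abs(got.interval[0] - exp.interval[0]) <= 25
            assert abs(got.interval[1] - exp.interval[1]) <= 25

    def test_planted_palindrome_gives_inverted_arms(self):
        clone = _tandem_clone(81, arrangement="palindrome")
        units = rpt.detect_self_repeats(clone.sequence, min_len=MIN_LEN)
        assert len(units) == 2
        assert {u.orientation for u in units} == {"direct", "inverted"}

    def test_random_sequence_has_no_units(self, rng):
        s = random_dna(rng, 12_000)
        assert rpt.detect_self_repeats(s, min_len=MIN_LEN) == []

    def test_three_unit_array(self):
        clone = _tandem_clone(82, n_units=3)
        units = rpt.detect_self_repeats(clone.sequence, min_len=MIN_LEN)
        assert len(units) == 3

    def test_too_short_consensus_rejected(self, rng):
        with pytest.raises(ValueError):
            rpt.detect_self_repeats(random_dna(rng, 1000), min_len=MIN_LEN)


class TestCallSfvs:
    def test_planted_sites_recovered_with_correct_alleles(self):
        clone = _tandem_clone(83, sfv_per_unit=1)
        units = rpt.detect_self_repeats(clone.sequence, min_len=MIN_LEN)
        pairs = sim.simulate_illumina([clone], coverage=50, seed=84)
        sfvs = rpt.call_sfvs(units, clone.sequence, pairs)
        # the planted SFV of each unit appears with that unit's allele
        by_unit_offset = {}
        for s in sfvs:
            for uid, pos in s.positions.items():
                by_unit_offset[(uid, pos)] = s.alleles[uid]
        for site in clone.sfv_sites:
            u = clone.repeat_units[site.unit_index]
            pos = u.interval[0] + site.offset
            uid = next(
                x.unit_id for x in units
                if x.interval[0] <= pos < x.interval[1]
            )
            assert by_unit_offset.get((uid, pos)) == site.allele

    def test_identical_units_have_no_sfvs(self, rng):
        unit = random_dna(rng, 2000)
        cons = random_dna(rng, 2500) + unit + unit + random_dna(rng, 2500)
        units = rpt.detect_self_repeats(cons, min_len=MIN_LEN)
        assert len(units) == 2
        reads = [(f"r{i}", cons[j : j + 150])
                 for i, j in enumerate(range(0, len(cons) - 150, 6))]
        sfvs = rpt.call_sfvs(units, cons, reads)
        assert sfvs == []

    @pytest.mark.parametrize("seed", range(10))
    def test_recovery_no_spurious_over_seeds(self, seed):
        """All planted inter-unit differences recovered, none invented."""
        clone = _tandem_clone(300 + seed, n_units=3, unit_len=1600,
                              sfv_per_unit=2, identity=0.995)
        units = rpt.detect_self_repeats(clone.sequence, min_len=1500)
        assert len(units) == 3
        pairs = sim.simulate_illumina([clone], coverage=50, seed=400 + seed)
        sfvs = rpt.call_sfvs(units, clone.sequence, pairs)
        called = set()
        for s in sfvs:
            for uid, pos in s.positions.items():
                called.add(pos)
        # truth: columns where the unit sequences genuinely differ
        truth_cols = set()
        iv = [u.interval for u in clone.repeat_units]
        seqs = [clone.sequence[a:b] for a, b in iv]
        for off in range(min(len(s) for s in seqs)):
            col = {s[off] for s in seqs}
            if len(col) > 1:
                for a, b in iv:
                    truth_cols.add(a + off)
        # tandem decomposition is phase-ambiguous around unit boundaries
        # (the caller trims those columns), so only planted sites clear of
        # every detected boundary are required
        bounds = sorted({b for u in units for b in u.interval})
        planted = {
            p
            for p in (iv[s.unit_index][0] + s.offset for s in clone.sfv_sites)
            if all(abs(p - b) >= 8 for b in bounds)
        }
        assert planted  # the construction puts sites in the interior
        assert planted <= called  # every interior planted site recovered
        assert called <= truth_cols  # nothing spurious


class TestFinishRepetitive:
    def test_repeat_free_clone_is_a_noop(self, rng):
        s = random_dna(rng, 8000)
        asm = rpt.finish_repetitive(s, [], [], [], [])
        assert asm.sequence == s

    def test_planted_allele_swap_is_repaired_by_long_reads(self):
        clone = _tandem_clone(85, sfv_per_unit=2)
        truth = clone.sequence
        units = rpt.detect_self_repeats(truth, min_len=MIN_LEN)
        # swap the first planted SFV's alleles between the two units
        site0 = next(s for s in clone.sfv_sites if s.unit_index == 0)
        u0, u1 = clone.repeat_units
        p0 = u0.interval[0] + site0.offset
        p1 = u1.interval[0] + site0.offset
        swapped = list(truth)
        swapped[p0], swapped[p1] = swapped[p1], swapped[p0]
        swapped = "".join(swapped)
        assert swapped != truth
        long_reads = sim.simulate_nanopore_run(
            [clone], 30, p_single_cut=0.6, seed=86,
        )
        pairs = sim.simulate_illumina([clone], coverage=50, seed=87)
        sfvs = rpt.call_sfvs(units, swapped, pairs)
        asm = rpt.finish_repetitive(swapped, units, sfvs, long_reads, pairs)
        assert asm.sequence[p0] == truth[p0]
        assert asm.sequence[p1] == truth[p1]

    def test_unit_order_is_never_reshuffled(self):
        clone = _tandem_clone(88, sfv_per_unit=2)
        truth = clone.sequence
        units = rpt.detect_self_repeats(truth, min_len=MIN_LEN)
        long_reads = sim.simulate_nanopore_run([clone], 25, p_single_cut=0.6, seed=89)
        pairs = sim.simulate_illumina([clone], coverage=50, seed=90)
        sfvs = rpt.call_sfvs(units, truth, pairs)
        asm = rpt.finish_repetitive(truth, units, sfvs, long_reads, pairs)
        # each unit's private planted alleles are still at their own unit
        for site in clone.sfv_sites:
            u = clone.repeat_units[site.unit_index]
            pos = u.interval[0] + site.offset
            assert asm.sequence[pos] == site.allele

    def test_length_conserved_up_to_logged_edits(self):
        clone = _tandem_clone(91)
        truth = clone.sequence
        units = rpt.detect_self_repeats(truth, min_len=MIN_LEN)
        long_reads = sim.simulate_nanopore_run([clone], 25, p_single_cut=0.6, seed=92)
        pairs = sim.simulate_illumina([clone], coverage=50, seed=93)
        sfvs = rpt.call_sfvs(units, truth, pairs)
        asm = rpt.finish_repetitive(truth, units, sfvs, long_reads, pairs)
        net = 0
        for d in asm.discrepancies:
            if d.klass == rpt.UNRESOLVED:
                continue
            net += len(d.illumina_allele.replace("-", "")) - len(
                d.nanopore_allele.replace("-", "")
            )
        assert len(asm.sequence) == len(truth) + net
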