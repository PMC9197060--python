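"""Aligner contracts: minimizers, chaining, banded extension, mapping."""

import numpy as np
import pytest

from bacfinish import seq as sq
from bacfinish.align import (
    LONG,
    ReferenceIndex,
    SeedChain,
    align_pair,
    chain_anchors,
    extend_align,
    map_read,
    minimizers,
)

from .oracles import best_chain_exhaustive, gotoh_score, window_minimizers
from .conftest import random_dna


def _rand(rng, n):
    return random_dna(rng, n)


class TestMinimizers:
    def test_w1_emits_every_kmer_position(self, rng):
        s = _rand(rng, 200)
        mins = minimizers(s, k=15, w=1)
        assert [p for _, p, _ in mins] == list(range(200 - 15 + 1))

    def test_revcomp_symmetry(self, rng):
        s = _rand(rng, 500)
        fwd = {h for h, _, _ in minimizers(s, 15, 10)}
        rev = {h for h, _, _ in minimizers(sq.revcomp(s), 15, 10)}
        assert fwd == rev

    def test_density_bounds(self, rng):
        s = _rand(rng, 10_000)
        mins = minimizers(s, k=15, w=10)
        n = len(s)
        assert 0.5 * n / 10 <= len(mins) <= 2 * n / 10

    def test_positions_match_brute_force_window_minima(self, rng):
        s = _rand(rng, 300)
        k, w = 11, 5
        per_kmer = minimizers(s, k, w=1)  # every k-mer with its hash
        hashes = [h for h, _, _ in per_kmer]
        expected = window_minimizers(hashes, w)
        got = {p for _, p, _ in minimizers(s, k, w)}
        assert got == expected

    def test_short_sequence_yields_empty(self):
        assert minimizers("ACGT", k=15, w=10) == []


class TestChaining:
    def test_exact_substring_gives_single_spanning_chain(self, rng):
        s = _rand(rng, 8000)
        query = s[2000:7000]
        index = ReferenceIndex([("t", s)], LONG)
        chains = index.best_chains(query)
        assert chains[0].t_span >= 0.95 * 5000
        assert chains[0].strand == "+"

    def test_disjoint_references_give_disjoint_chains(self, rng):
        a = _rand(rng, 4000)
        b = _rand(rng, 4000)
        index = ReferenceIndex([("a", a), ("b", b)], LONG)
        ca = index.best_chains(a[500:2500])
        cb = index.best_chains(b[500:2500])
        assert ca[0].target_id == "a"
        assert cb[0].target_id == "b"

    def test_outlier_anchor_excluded_matches_exhaustive_search(self):
        # co-linear anchors plus one wild outlier
        anchors = [(i * 100, i * 100 + 5) for i in range(8)]
        anchors.insert(4, (410, 4000))  # outlier breaks co-linearity
        chains = chain_anchors(anchors, max_gap=5000, min_chain_score=10, k=15)
        got = set(map(tuple, chains[0].anchors))
        assert (410, 4000) not in got
        exp_score, exp_idx = best_chain_exhaustive(sorted(anchors, key=lambda a: a[1]), 15, 5000)
        assert chains[0].chain_score == exp_score


class TestExtendAlign:
    def test_identical_sequences_full_match(self, rng):
        s = _rand(rng, 2000)
        chain = SeedChain("t", "+", [(0, 0)], 0, 1)
        aln = extend_align(s, s, chain, band=2001)
        assert aln.cigar == [("M", 2000)]
        assert aln.identity == 1.0
        assert aln.score == 2000

    def test_single_internal_deletion(self, rng):
        s = _rand(rng, 1200)
        q = s[:600] + s[603:]  # 3 bp deleted from the query
        chain = SeedChain("t", "+", [(0, 0)], 0, 1)
        aln = extend_align(q, s, chain, band=1300)
        dels = [n for op, n in aln.cigar if op == "D"]
        assert dels == [3]
        assert aln.score == gotoh_score(q, s)

    @pytest.mark.parametrize("trial", range(12))
    def test_score_equals_quadratic_dp_when_band_covers(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(1, 300))
        m = int(rng.integers(1, 300))
        a = _rand(rng, n)
        b = _rand(rng, m)
        if trial % 2:  # make half the pairs related
            b = a[: max(1, n // 2)] + b[: max(1, m // 2)]
        chain = SeedChain("t", "+", [(0, 0)], 0, 1)
        aln = extend_align(a, b, chain, band=max(len(a), len(b)) + 1)
        assert aln.score == gotoh_score(a, b)

    def test_corrupted_read_identity_close_to_oracle(self, rng):
        from .oracles import global_identity

        s = _rand(rng, 800)
        codes = sq.encode(s)
        sub = rng.random(800) < 0.1
        codes[sub] = (codes[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
        q = sq.decode(codes)
        chain = SeedChain("t", "+", [(0, 0)], 0, 1)
        aln = extend_align(q, s, chain, band=900)
        assert abs(aln.identity - global_identity(q, s)) <= 0.02


def _cigar_lengths(aln):
    q = sum(n for op, n in aln.cigar if op in "MIS")
    t = sum(n for op, n in aln.cigar if op in "MD")
    return q, t


class TestMapRead:
    def test_zero_error_read_covers_itself(self, small_pool):
        clone = small_pool[1]
        read = clone.sequence[2000:9000]
        alns = map_read(("r", read), [(c.clone_id, c.sequence) for c in small_pool])
        assert alns[0].target_id == clone.clone_id
        assert alns[0].q_span() >= 0.99 * len(read)

    def test_revcomp_read_mirrors_coordinates_same_score(self, small_pool):
        clone = small_pool[0]
        read = clone.sequence[1500:8000]
        refs = [(c.clone_id, c.sequence) for c in small_pool]
        fwd = map_read(("r", read), refs)[0]
        rev = map_read(("r", sq.revcomp(read)), refs)[0]
        assert rev.strand == "-"
        assert rev.t_interval == fwd.t_interval
        assert rev.q_interval == fwd.q_interval
        assert rev.score == fwd.score

    def test_cigar_conserves_query_and_target_lengths(self, small_pool, small_reads):
        index = ReferenceIndex(
            [(c.clone_id, c.sequence) for c in small_pool], LONG
        )
        checked = 0
        for r in small_reads[:25]:
            for aln in map_read((r.read_id, r.bases), index=index):
                q, t = _cigar_lengths(aln)
                assert q == len(r.bases)
                assert t == aln.t_interval[1] - aln.t_interval[0]
                assert all(n > 0 for _, n in aln.cigar)
                assert all(
                    a != b for (a, _), (b, _) in zip(aln.cigar, aln.cigar[1:])
                )
                checked += 1
        assert checked > 20

    def test_noisy_reads_map_to_their_clone(self, small_pool, small_reads):
        index = ReferenceIndex(
            [(c.clone_id, c.sequence) for c in small_pool], LONG
        )
        ok = tot = 0
        for r in small_reads:
            alns = map_read((r.read_id, r.bases), index=index)
            if not alns:
                continue
            # reads tying across targets (e.g. vector-only fragments) are
            # ambiguous by construction, not mapping errors
            second = next((a for a in alns if a.target_id != alns[0].target_id), None)
            if second is not None and second.score == alns[0].score:
                continue
            tot += 1
            ok += alns[0].target_id == r.truth.clone_id
        assert tot >= 75
        assert ok / tot >= 0.99

    def test_unmappable_read_returns_empty(self, small_pool, rng):
        junk = random_dna(rng, 300)
        alns = map_read(("junk", junk), [(c.clone_id, c.sequence) for c in small_pool])
        assert alns == []


def test_align_pair_on_near_identical_units(rng):
    a = random_dna(rng, 2000)
    codes = sq.encode(a)
    pos = rng.choice(2000, size=10, replace=False)
    codes[pos] = (codes[pos] + 1) % 4
    b = sq.decode(codes)
    aln = align_pair(a, b)
    assert aln.n_columns == 2000
    assert aln.n_matches == 1990
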