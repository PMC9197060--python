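"""Minimizer seed -> chain -> banded-extend pairwise alignment.

This is the alignment contract every pipeline stage consumes: noisy long
reads and accurate short reads against clone-scale references, with explicit
CIGAR strings. The design follows standard long-read mapping practice:
canonical (w,k)-minimizers, co-linear anchor chaining with gap costs, and
piecewise banded affine-gap ("Gotoh") extension between anchors.

Coordinates are 0-based half-open. ``q_interval`` is always reported on the
original (forward) query; for minus-strand alignments the CIGAR describes
the reverse complement of the query laid along the target, as in SAM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .. import seq as sq
from . import kernels

# scoring defaults: match +1, mismatch -2, gap open -4, gap extend -2
MATCH = 1
MISMATCH = 2
GAP_OPEN = 4
GAP_EXT = 2

CIGAR_OPS = "MIDS"


@dataclass(frozen=True)
class Preset:
    """Seeding/alignment parameter bundle."""

    k: int = 15
    w: int = 10
    max_gap: int = 5000
    band: int = 500
    min_chain_score: int = 30
    lookback: int = 32
    max_extends: int = 5
    max_occ: int = 512


LONG = Preset()
SHORT = Preset(k=21, w=1, max_gap=100, band=50, min_chain_score=42, lookback=16)

PRESETS = {"long": LONG, "short": SHORT}


@dataclass
class SeedChain:
    """A co-linear chain of exact k-mer anchors on one (target, strand)."""

    target_id: str
    strand: str  # '+' or '-'
    anchors: list  # [(q_pos, t_pos)] in oriented-query coordinates
    chain_score: int
    k: int

    @property
    def q_span(self) -> int:
        return self.anchors[-1][0] + self.k - self.anchors[0][0]

    @property
    def t_span(self) -> int:
        return self.anchors[-1][1] + self.k - self.anchors[0][1]


@dataclass
class Alignment:
    """Strand-aware pairwise alignment with explicit CIGAR.

    Invariants: sum of M+I (+S) counts equals the query length; sum of M+D
    equals the target interval length; CIGAR has no zero-count or adjacent
    same-op elements; identity = matches / alignment columns.
    """

    query_id: str
    target_id: str
    strand: str
    q_interval: tuple[int, int]
    t_interval: tuple[int, int]
    cigar: list[tuple[str, int]]
    score: int
    identity: float
    n_matches: int = 0
    n_columns: int = 0
    query_length: int = 0
    low_confidence: bool = False

    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)

    def q_span(self) -> int:
        return self.q_interval[1] - self.q_interval[0]

    def t_span(self) -> int:
        return self.t_interval[1] - self.t_interval[0]


def minimizers(seq: str, k: int = 15, w: int = 10) -> list[tuple[int, int, int]]:
    """Canonical (w,k)-minimizers of ``seq``.

    Returns (kmer_hash, position, strand) triples; strand 1 means the
    canonical form of the k-mer is its reverse complement. Each window of w
    consecutive k-mers contributes its minimum-hash k-mer; k-mers containing
    N are skipped. A sequence shorter than k yields an empty list.
    """
    if k > 28:
        raise ValueError("k must be <= 28")
    if w < 1:
        raise ValueError("w must be >= 1")
    h, p, s = kernels.minimizer_scan(sq.encode(seq), k, w)
    return list(zip(h.tolist(), p.tolist(), s.tolist()))


def _rle(expanded: np.ndarray) -> list[tuple[str, int]]:
    """Run-length encode an expanded per-column op array to CIGAR pairs."""
    if expanded.size == 0:
        return []
    change = np.flatnonzero(expanded[1:] != expanded[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [expanded.size]))
    return [(CIGAR_OPS[expanded[a]], int(b - a)) for a, b in zip(starts, ends)]


def _score_and_matches(
    expanded: np.ndarray, q: np.ndarray, t: np.ndarray, q0: int, t0: int
) -> tuple[int, int, int]:
    """(score, matches, columns) of an explicit alignment path."""
    is_m = expanded == 0
    is_i = expanded == 1
    is_d = expanded == 2
    qidx = q0 + np.cumsum(is_m | is_i) - 1
    tidx = t0 + np.cumsum(is_m | is_d) - 1
    mq = q[qidx[is_m]]
    mt = t[tidx[is_m]]
    matches = int(np.count_nonzero(mq == mt))
    mismatches = int(np.count_nonzero(mq != mt)) if mq.size else 0
    score = matches * MATCH - mismatches * MISMATCH
    # gap events: runs of I or runs of D
    gap = is_i | is_d
    if gap.any():
        g = gap.astype(np.int8)
        n_open = int(g[0] == 1) + int(np.count_nonzero(np.diff(g) == 1))
        score -= GAP_OPEN * n_open + GAP_EXT * int(gap.sum())
    return score, matches, int(expanded.size)


def _banded_global(q: np.ndarray, t: np.ndarray, band: int) -> tuple[np.ndarray, bool]:
    """Global alignment of two code arrays; widens the band once if exceeded.

    Returns (expanded ops, low_confidence).
    """
    n, m = q.size, t.size
    if n == 0:
        return np.full(m, 2, dtype=np.uint8), False
    if m == 0:
        return np.full(n, 1, dtype=np.uint8), False
    b = min(band, max(n, m))
    dlo = min(0, m - n) - b
    dhi = max(0, m - n) + b
    _, _, _, ops, touched = kernels.gotoh_banded(
        q, t, dlo, dhi, MATCH, MISMATCH, GAP_OPEN, GAP_EXT, False
    )
    if touched and b < max(n, m):
        b = max(n, m)
        dlo, dhi = -n, m
        _, _, _, ops, touched = kernels.gotoh_banded(
            q, t, dlo, dhi, MATCH, MISMATCH, GAP_OPEN, GAP_EXT, False
        )
        return ops, bool(touched)
    return ops, False


def _extension(q: np.ndarray, t: np.ndarray, band: int) -> tuple[np.ndarray, int, int]:
    """Origin-anchored extension: align prefixes of q and t, soft-clip the rest.

    Returns (expanded ops, query consumed, target consumed).
    """
    if q.size == 0 or t.size == 0:
        return np.zeros(0, dtype=np.uint8), 0, 0
    n, m = q.size, t.size
    b = min(band, max(n, m))
    dlo = min(0, m - n) - b
    dhi = max(0, m - n) + b
    _, ei, ej, ops, _ = kernels.gotoh_banded(
        q, t, dlo, dhi, MATCH, MISMATCH, GAP_OPEN, GAP_EXT, True
    )
    return ops, int(ei), int(ej)


def chain_anchors(
    anchors: Sequence[tuple[int, int]],
    max_gap: int = 5000,
    min_chain_score: int = 30,
    k: int = 15,
    lookback: int = 32,
    target_id: str = "",
    strand: str = "+",
) -> list[SeedChain]:
    """Co-linear chaining of (q_pos, t_pos) anchors by dynamic programming.

    Anchors must be sorted by target position. Returns non-overlapping
    primary chains (no shared anchors), best score first.
    """
    if not len(anchors):
        return []
    arr = np.asarray(anchors, dtype=np.int64).reshape(-1, 2)
    order = np.lexsort((arr[:, 0], arr[:, 1]))
    arr = arr[order]
    f, parent = kernels.chain_dp(
        np.ascontiguousarray(arr[:, 0]),
        np.ascontiguousarray(arr[:, 1]),
        k,
        max_gap,
        lookback,
    )
    used = np.zeros(arr.shape[0], dtype=bool)
    chains: list[SeedChain] = []
    for i in np.argsort(f)[::-1]:
        if used[i] or f[i] < min_chain_score:
            continue
        path = []
        j = int(i)
        score = int(f[i])
        while j >= 0 and not used[j]:
            path.append(j)
            j = int(parent[j])
        if j >= 0:
            score -= int(f[j])  # chain merges into a claimed one: keep the tail only
        if not path or score < min_chain_score:
            continue
        for j in path:
            used[j] = True
        path.reverse()
        sub = arr[path]
        chains.append(
            SeedChain(
                target_id=target_id,
                strand=strand,
                anchors=[(int(a), int(b)) for a, b in sub],
                chain_score=score,
                k=k,
            )
        )
    chains.sort(key=lambda c: (-c.chain_score, c.target_id, c.anchors[0][1]))
    return chains


def extend_align(
    query: str,
    target: str,
    chain: SeedChain,
    band: int = 500,
    query_id: str = "query",
) -> Alignment:
    """Banded global alignment between consecutive chain anchors plus end
    extensions; unaligned query ends are soft-clipped.

    When ``band`` covers the full sequences the result is an unconstrained
    optimal global alignment (no anchors imposed, no soft clips), which is
    what the quadratic-DP equivalence property exercises.
    """
    if not chain.anchors:
        raise ValueError("chain must be non-empty")
    qlen = len(query)
    oriented = query if chain.strand == "+" else sq.revcomp(query)
    q = sq.encode(oriented)
    t = sq.encode(target)
    k = chain.k
    low_conf = False

    if band >= max(len(q), len(t)):
        ops, low_conf = _banded_global(q, t, max(len(q), len(t)))
        q0, t0 = 0, 0
        q1, t1 = len(q), len(t)
        expanded = ops
    else:
        pieces: list[np.ndarray] = []
        anchors = chain.anchors
        aq, at = anchors[0]
        # end extensions recover a bounded stretch beyond the outermost
        # anchors; anything further belongs to a different chain arc
        ext_cap = max(200, min(band, 1000))
        ext_band = min(band, 128)
        # left extension (reversed)
        lcap = min(aq, ext_cap)
        tw0 = max(0, at - (lcap + ext_band))
        ops_l, ci, cj = _extension(
            q[aq - lcap : aq][::-1].copy(), t[tw0:at][::-1].copy(), ext_band
        )
        q0 = aq - ci
        t0 = at - cj
        pieces.append(ops_l[::-1])
        aq_arr = np.array([a[0] for a in anchors], dtype=np.int64)
        at_arr = np.array([a[1] for a in anchors], dtype=np.int64)
        mid_ops, q_end, t_end, seg_low_conf = kernels.stitch_segments(
            q, t, aq_arr, at_arr, k, band, MATCH, MISMATCH, GAP_OPEN, GAP_EXT
        )
        low_conf = low_conf or seg_low_conf
        pieces.append(mid_ops)
        # right extension
        qs = int(q_end)
        ts = int(t_end)
        rem_q = q[qs : qs + ext_cap]
        tw1 = min(len(t), ts + rem_q.size + ext_band)
        ops_r, ci, cj = _extension(rem_q, t[ts:tw1], ext_band)
        pieces.append(ops_r)
        q1 = qs + ci
        t1 = ts + cj
        expanded = np.concatenate(pieces) if pieces else np.zeros(0, dtype=np.uint8)

    if expanded.size:
        expanded = kernels.left_align_path(expanded, q, t, q0, t0)
    score, matches, ncols = _score_and_matches(expanded, q, t, q0, t0)
    cigar = _rle(expanded)
    if q0 > 0:
        cigar.insert(0, ("S", q0))
    if q1 < len(q):
        cigar.append(("S", len(q) - q1))
    if chain.strand == "+":
        q_iv = (q0, q1)
    else:
        q_iv = (qlen - q1, qlen - q0)
    identity = matches / ncols if ncols else 0.0
    return Alignment(
        query_id=query_id,
        target_id=chain.target_id,
        strand=chain.strand,
        q_interval=q_iv,
        t_interval=(t0, t1),
        cigar=cigar,
        score=score,
        identity=identity,
        n_matches=matches,
        n_columns=ncols,
        query_length=qlen,
        low_confidence=low_conf,
    )


def align_pair(
    a: str, b: str, band: int | None = None, query_id: str = "a", target_id: str = "b"
) -> Alignment:
    """Global alignment of two comparable sequences (plus strand).

    ``band`` defaults to a margin above the length difference, which is the
    right regime for near-identical sequences such as repeat unit copies;
    the band widens automatically once if exceeded.
    """
    qa = sq.encode(a)
    tb = sq.encode(b)
    if band is None:
        band = abs(len(a) - len(b)) + max(32, min(len(a), len(b)) // 20)
    expanded, low_conf = _banded_global(qa, tb, band)
    if expanded.size:
        expanded = kernels.left_align_path(expanded, qa, tb, 0, 0)
    score, matches, ncols = _score_and_matches(expanded, qa, tb, 0, 0)
    return Alignment(
        query_id=query_id,
        target_id=target_id,
        strand="+",
        q_interval=(0, len(a)),
        t_interval=(0, len(b)),
        cigar=_rle(expanded),
        score=score,
        identity=matches / ncols if ncols else 0.0,
        n_matches=matches,
        n_columns=ncols,
        query_length=len(a),
        low_confidence=low_conf,
    )


class ReferenceIndex:
    """Sorted minimizer index over a set of reference sequences."""

    def __init__(self, references: Iterable[tuple[str, str]], preset: Preset = LONG):
        self.preset = preset
        self.names: list[str] = []
        self.seqs: list[str] = []
        hs, rids, poss, strs = [], [], [], []
        for rid, (name, s) in enumerate(references):
            self.names.append(name)
            self.seqs.append(s)
            h, p, st = kernels.minimizer_scan(sq.encode(s), preset.k, preset.w)
            hs.append(h)
            rids.append(np.full(h.size, rid, dtype=np.int32))
            poss.append(p)
            strs.append(st)
        if not self.names:
            raise ValueError("references must be non-empty")
        h = np.concatenate(hs) if hs else np.zeros(0, dtype=np.uint64)
        order = np.argsort(h, kind="stable")
        self.h = h[order]
        self.rid = np.concatenate(rids)[order]
        self.pos = np.concatenate(poss)[order]
        self.strand = np.concatenate(strs)[order]
        # mask overly repetitive seeds
        if self.h.size:
            uniq, counts = np.unique(self.h, return_counts=True)
            bad = uniq[counts > preset.max_occ]
            if bad.size:
                keep = ~np.isin(self.h, bad)
                self.h = self.h[keep]
                self.rid = self.rid[keep]
                self.pos = self.pos[keep]
                self.strand = self.strand[keep]

    def __len__(self) -> int:
        return len(self.names)

    def seq(self, name: str) -> str:
        return self.seqs[self.names.index(name)]

    def collect_anchors(self, read_seq: str):
        """Anchors of a read against the index, grouped by (ref, rel_strand).

        Minus-strand anchor q positions are in reverse-complemented-read
        coordinates, so every group is co-linear increasing.
        """
        p = self.preset
        qh, qp, qs = kernels.minimizer_scan(sq.encode(read_seq), p.k, p.w)
        if qh.size == 0:
            return {}
        lo = np.searchsorted(self.h, qh, side="left")
        hi = np.searchsorted(self.h, qh, side="right")
        n_hits = hi - lo
        total = int(n_hits.sum())
        if total == 0:
            return {}
        qidx = np.repeat(np.arange(qh.size), n_hits)
        flat = np.concatenate(
            [np.arange(a, b) for a, b in zip(lo, hi) if b > a]
        )
        rids = self.rid[flat]
        tpos = self.pos[flat]
        rel = (self.strand[flat] != qs[qidx]).astype(np.int8)  # 1 => read is revcomp
        qpos = qp[qidx].copy()
        qlen = len(read_seq)
        minus = rel == 1
        qpos[minus] = qlen - p.k - qpos[minus]
        groups = {}
        key = rids.astype(np.int64) * 2 + minus
        for kk in np.unique(key):
            m = key == kk
            groups[(int(kk // 2), "-" if kk % 2 else "+")] = np.stack(
                [qpos[m], tpos[m]], axis=1
            )
        return groups

    def best_chains(self, read_seq: str) -> list[SeedChain]:
        """All chains of a read against all references, best score first."""
        p = self.preset
        out: list[SeedChain] = []
        for (rid, strand), arr in self.collect_anchors(read_seq).items():
            out.extend(
                chain_anchors(
                    arr,
                    max_gap=p.max_gap,
                    min_chain_score=p.min_chain_score,
                    k=p.k,
                    lookback=p.lookback,
                    target_id=self.names[rid],
                    strand=strand,
                )
            )
        out.sort(key=lambda c: (-c.chain_score, c.target_id))
        return out


def _try_exact_diagonal(
    query: str, target: str, chain: SeedChain, query_id: str, max_mismatches: int = 2
) -> Alignment | None:
    """Fast path for accurate short reads: if all chain anchors sit on one
    diagonal and the full query fits on the target with at most a couple of
    mismatches, emit the all-M alignment without DP. Reads that would need
    an indel (or clipping) fall through to the banded extension."""
    qlen = len(query)
    if qlen > 1000:
        return None
    d = chain.anchors[0][1] - chain.anchors[0][0]
    for q, t in chain.anchors[1:]:
        if t - q != d:
            return None
    if d < 0 or d + qlen > len(target):
        return None
    oriented = query if chain.strand == "+" else sq.revcomp(query)
    q = sq.encode(oriented)
    t = sq.encode(target[d : d + qlen])
    mism = int(np.count_nonzero(q != t))
    if mism > max_mismatches:
        return None
    matches = qlen - mism
    return Alignment(
        query_id=query_id,
        target_id=chain.target_id,
        strand=chain.strand,
        q_interval=(0, qlen),
        t_interval=(d, d + qlen),
        cigar=[("M", qlen)],
        score=matches * MATCH - mism * MISMATCH,
        identity=matches / qlen,
        n_matches=matches,
        n_columns=qlen,
        query_length=qlen,
    )


def _as_pair(read) -> tuple[str, str]:
    if isinstance(read, tuple):
        return read
    if hasattr(read, "read_id"):
        return read.read_id, read.bases
    if hasattr(read, "id"):
        return read.id, str(read.seq)
    raise TypeError(f"cannot interpret read of type {type(read)!r}")


def map_read(
    read,
    references=None,
    preset: str | Preset = "long",
    index: ReferenceIndex | None = None,
    max_secondary: int = 4,
) -> list[Alignment]:
    """Map a read against references, best alignment first.

    Both strands are searched; chains above the preset's minimum score are
    extended (up to ``preset.max_extends``) and the resulting alignments
    returned sorted by score. An empty list signals an unmappable read.
    Equal-score alignments to different targets are both retained so the
    consumer can see the ambiguity.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    if index is None:
        refs = [_as_pair(r) for r in references]
        index = ReferenceIndex(refs, preset)
    else:
        preset = index.preset
    rid, rseq = _as_pair(read)
    chains = index.best_chains(rseq)
    alns = []
    for chain in chains[: preset.max_extends]:
        tseq = index.seqs[index.names.index(chain.target_id)]
        aln = _try_exact_diagonal(rseq, tseq, chain, rid)
        if aln is None:
            if len(rseq) <= 600 and len(chain.anchors) > 1:
                # short reads: one DP from a single anchor instead of
                # piecewise seams that can split a compound indel into
                # divergent representations; the leftmost anchor keeps the
                # forward-DP portion maximal so tie-breaking among
                # co-optimal paths is consistent across reads
                first = chain.anchors[0]
                chain = SeedChain(
                    chain.target_id, chain.strand, [first], chain.chain_score, chain.k
                )
            aln = extend_align(rseq, tseq, chain, band=preset.band, query_id=rid)
        alns.append(aln)
    alns.sort(key=lambda a: (-a.score, a.target_id, a.t_interval))
    return alns[: max_secondary + 1]
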