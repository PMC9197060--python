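"""Full-length read identification, vector-anchored rotation, and clone
length estimation.

A read that traverses an entire circular clone linearizes it at the single
transposase cut. If the cut fell inside the cloning vector, the read starts
and ends in vector sequence; if it fell in the insert, the vector appears
once internally. Either way the read can be rotated (circularly shifted,
reverse-complementing first when the vector matched the minus strand) into
the canonical vector-first orientation shared by drafts and finished
sequences. Clones with no vector-anchored read still reveal their length as
a peak in the tail of the read-length distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import seq as sq
from .align import LONG, Preset, ReferenceIndex, extend_align, kernels
from .align.core import _extension
from .simulate import NanoporeRead

FULL_VECTOR_ANCHORED = "FULL_VECTOR_ANCHORED"
PUTATIVE_FULL_BY_LENGTH = "PUTATIVE_FULL_BY_LENGTH"
PARTIAL = "PARTIAL"


@dataclass
class VectorHit:
    """One alignment of the cloning vector within a read."""

    interval: tuple[int, int]  # on the read, 0-based half-open
    strand: str
    identity: float
    vector_interval: tuple[int, int]

    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class FullLengthCall:
    read_id: str
    status: str
    vector_hits: list[VectorHit] = field(default_factory=list)
    rotation_offset: int = 0  # applied after strand canonicalization
    canonical_strand_applied: bool = False  # True if revcomp needed first


def find_vector_hits(
    read,
    vector: str,
    min_identity: float = 0.75,
    min_len: int = 500,
    preset: Preset = LONG,
) -> list[VectorHit]:
    """All alignments of the vector within a read above the identity and
    length thresholds (defaults tuned for raw nanopore error rates)."""
    if len(vector) < 1000:
        raise ValueError("vector must be >= 1 kb")
    rid, bases = _as_read(read)
    index = ReferenceIndex([("vector", vector)], preset)
    hits = []
    for chain in index.best_chains(bases)[:8]:
        aln = extend_align(bases, vector, chain, band=preset.band, query_id=rid)
        if aln.q_span() >= min_len and aln.identity >= min_identity:
            hits.append(
                VectorHit(aln.q_interval, aln.strand, aln.identity, aln.t_interval)
            )
    hits.sort(key=lambda h: h.interval)
    return _dedupe_hits(hits)


def _dedupe_hits(hits: list[VectorHit]) -> list[VectorHit]:
    out: list[VectorHit] = []
    for h in hits:
        if out and h.interval[0] < out[-1].interval[1] - 100:
            if h.length() > out[-1].length():
                out[-1] = h
            continue
        out.append(h)
    return out


def _as_read(read) -> tuple[str, str]:
    if hasattr(read, "read_id"):
        return read.read_id, read.bases
    return read


def _rescue_end(
    bases: str, vector: str, expected: int, at_start: bool, min_identity: float
) -> VectorHit | None:
    """Look for a short complementary vector piece at a read end.

    When one end of a read aligns flush with a vector boundary, circularity
    predicts the remaining piece of the vector (possibly shorter than the
    generic hit threshold) at the other end; this targeted search accepts it
    down to ~25 bp.
    """
    if expected <= 25:
        # too short to verify by alignment; the caller decides on length
        # consistency grounds
        return None
    slack = max(30, expected // 3)
    n = min(len(bases), expected)
    if at_start:
        # the piece read[:expected] is the vector *end*, flush with the main
        # hit on its right: extend leftward (reversed) from that boundary
        qc = sq.encode(bases[:n])[::-1].copy()
        tc = sq.encode(vector[-(expected + slack):])[::-1].copy()
    else:
        # the piece read[-expected:] is the vector *start*, flush with the
        # main hit on its left: extend rightward from that boundary
        qc = sq.encode(bases[-n:])
        tc = sq.encode(vector[: expected + slack])
    ops, ci, cj = _extension(qc, tc, band=50)
    if ci < 0.5 * expected:
        return None
    is_m = ops == 0
    ncols = ops.size
    if ncols == 0:
        return None
    qi = np.cumsum((ops == 0) | (ops == 1)) - 1
    ti = np.cumsum((ops == 0) | (ops == 2)) - 1
    matches = int(np.count_nonzero(qc[qi[is_m]] == tc[ti[is_m]]))
    ident = matches / ncols
    if ident < min_identity:
        return None
    if at_start:
        iv = (max(0, expected - ci), expected)
        viv = (len(vector) - ci, len(vector))
    else:
        iv = (len(bases) - expected, len(bases) - expected + ci)
        viv = (0, ci)
    return VectorHit(iv, "+", ident, viv)


def classify_full_length(
    read,
    vector: str,
    clone_length_estimate: int | None = None,
    end_window: int = 1000,
    min_identity: float = 0.75,
    min_len: int = 500,
    hits: list[VectorHit] | None = None,
) -> FullLengthCall:
    """Classify a read as vector-anchored full-length, putative full-length
    by length, or partial.

    FULL_VECTOR_ANCHORED requires vector sequence within both the first and
    last ``end_window`` bp of the read. A read whose single end hit is flush
    with a vector boundary is rescued by a targeted search for the short
    complementary piece predicted by circularity at the opposite end.
    PUTATIVE_FULL_BY_LENGTH requires a length within 10% of the supplied
    clone length estimate.
    """
    rid, bases = _as_read(read)
    L = len(bases)
    if hits is None:
        hits = find_vector_hits((rid, bases), vector, min_identity, min_len)
    work = list(hits)
    V = len(vector)
    # a genuine full-length read must hold the whole clone: more than just
    # vector sequence (guards against vector-only fragments, which trivially
    # start and end in vector)
    length_sane = L >= V + 2 * end_window
    length_consistent = bool(
        clone_length_estimate
        and abs(L - clone_length_estimate) <= 0.10 * clone_length_estimate
    )
    start_hit = any(h.interval[0] < end_window for h in work)
    end_hit = any(h.interval[1] > L - end_window for h in work)
    if work and length_sane and not (start_hit and end_hit):
        # rescue: a hit flush with both the read end and a vector boundary
        # predicts the complementary vector piece at the other read end
        big = max(work, key=VectorHit.length)
        tol = 60
        if not start_hit and big.interval[1] > L - end_window:
            va, vb = big.vector_interval
            flush = big.interval[1] >= L - tol and (
                va <= tol if big.strand == "+" else V - vb <= tol
            )
            exp = (V - vb) if big.strand == "+" else va
            if flush and exp < V // 2:
                if exp <= 25:
                    start_hit = length_consistent
                else:
                    r = _rescue_end(
                        bases,
                        vector if big.strand == "+" else sq.revcomp(vector),
                        exp,
                        True,
                        min_identity - 0.05,
                    )
                    if r is not None:
                        work.insert(0, r)
                        start_hit = True
        elif not end_hit and big.interval[0] < end_window:
            va, vb = big.vector_interval
            flush = big.interval[0] <= tol and (
                vb >= V - tol if big.strand == "+" else va <= tol
            )
            exp = va if big.strand == "+" else (V - vb)
            if flush and exp < V // 2:
                if exp <= 25:
                    end_hit = length_consistent
                else:
                    r = _rescue_end(
                        bases,
                        vector if big.strand == "+" else sq.revcomp(vector),
                        exp,
                        False,
                        min_identity - 0.05,
                    )
                    if r is not None:
                        work.append(r)
                        end_hit = True
    if start_hit and end_hit and work and length_sane:
        status = FULL_VECTOR_ANCHORED
    elif length_consistent:
        status = PUTATIVE_FULL_BY_LENGTH
    else:
        status = PARTIAL
    offset = 0
    flipped = False
    if work:
        big = max(work, key=VectorHit.length)
        flipped = big.strand == "-"
        if flipped:
            oriented = [_flip_hit(h, L) for h in work]
            big = max(oriented, key=VectorHit.length)
        offset = (big.interval[0] - big.vector_interval[0]) % L if L else 0
    return FullLengthCall(
        read_id=rid,
        status=status,
        vector_hits=work,
        rotation_offset=offset,
        canonical_strand_applied=flipped,
    )


def _flip_hit(h: VectorHit, read_len: int) -> VectorHit:
    a, b = h.interval
    return VectorHit(
        (read_len - b, read_len - a),
        "+" if h.strand == "-" else "-",
        h.identity,
        h.vector_interval,
    )


def rotate_to_vector(read, call: FullLengthCall) -> NanoporeRead:
    """Rotate a full-length read into canonical vector-first orientation.

    Reverse-complements first when the vector matched the minus strand, then
    applies the circular shift recorded in the call; the rotation preserves
    length and base multiset exactly. Multiple well-separated internal
    vector hits indicate a vector-vector chimera or dimer and are refused.
    """
    rid, bases = _as_read(read)
    L = len(bases)
    internal = [
        h
        for h in call.vector_hits
        if h.interval[0] > 500 and h.interval[1] < L - 500 and h.length() > 1000
    ]
    if len(internal) > 1:
        gaps = [
            b.interval[0] - a.interval[1]
            for a, b in zip(internal, internal[1:])
        ]
        if any(g > 2000 for g in gaps):
            raise ValueError(
                f"read {rid}: multiple well-separated vector hits "
                "(vector-vector chimera or dimer); refusing to rotate"
            )
    if call.canonical_strand_applied:
        bases = sq.revcomp(bases)
    return NanoporeRead(
        read_id=rid,
        bases=sq.rotate(bases, call.rotation_offset),
        truth=read.truth if hasattr(read, "truth") else None,
    )


def estimate_clone_length(
    read_lengths, bin_width: int = 1000, min_modal_reads: int = 3
) -> int | None:
    """Clone length from the peak in the tail of the read-length histogram.

    Lengths above the 75th percentile are binned (1 kb default); the center
    of the modal bin is returned, or None when there are fewer than 20 reads
    or the modal bin holds fewer than ``min_modal_reads`` reads (no peak).
    """
    lengths = np.asarray(list(read_lengths), dtype=np.int64)
    if lengths.size < 20:
        warnings.warn("fewer than 20 reads: no clone length estimate")
        return None
    q75 = np.percentile(lengths, 75)
    tail = lengths[lengths >= q75]
    if tail.size == 0:
        return None
    lo = int(tail.min()) // bin_width
    hi = int(tail.max()) // bin_width + 1
    counts = np.bincount(tail // bin_width - lo, minlength=hi - lo)
    modal = int(np.argmax(counts))
    if counts[modal] < min_modal_reads:
        return None
    return (lo + modal) * bin_width + bin_width // 2
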