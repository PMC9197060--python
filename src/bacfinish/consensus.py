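"""Per-clone consensus: backbone selection, long-read polishing, and
short-read error correction.

The consensus strategy mirrors hybrid clone finishing practice: a single
full-length, vector-anchored nanopore read fixes the overall structure of
the clone (order, orientation and copy number of everything inside it);
windowed column-stack polishing with all long reads removes most random
errors; and the residual errors — indels at homopolymer runs above all,
plus rarer substitutions — are corrected to the consensus of the deep,
accurate short reads, with every edit logged as a discrepancy.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import seq as sq
from .align import LONG, SHORT, Preset, ReferenceIndex, map_read
from .align import kernels  # noqa: F401  (re-exported for pileup consumers)
from .fullread import (
    FULL_VECTOR_ANCHORED,
    PUTATIVE_FULL_BY_LENGTH,
    FullLengthCall,
    rotate_to_vector,
)
from .simulate import IlluminaReadPair, NanoporeRead

HOMOPOLYMER_INDEL = "HOMOPOLYMER_INDEL"
SUBSTITUTION = "SUBSTITUTION"
UNRESOLVED = "UNRESOLVED"

_BASES = "ACGT-"


@dataclass
class Discrepancy:
    """One difference between the long-read consensus and the short-read
    consensus (position on the sequence the edit was assessed against)."""

    position: int
    nanopore_allele: str
    illumina_allele: str
    klass: str  # HOMOPOLYMER_INDEL | SUBSTITUTION | UNRESOLVED


@dataclass
class ConsensusAssembly:
    clone_id: str
    sequence: str
    support: dict = field(default_factory=dict)  # long_depth / short_depth / short_agree_frac
    discrepancies: list[Discrepancy] = field(default_factory=list)
    rounds_applied: int = 0
    flags: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)


def flatten_short_reads(reads) -> list[tuple[str, str]]:
    """Accept IlluminaReadPair lists, (id, seq) tuples, or reads with
    .bases; pairs are treated as independent single-end reads."""
    out = []
    for r in reads:
        if isinstance(r, IlluminaReadPair):
            out.append((f"{r.read_id}/1", r.bases1))
            out.append((f"{r.read_id}/2", r.bases2))
        elif isinstance(r, tuple):
            out.append(r)
        else:
            out.append((r.read_id, r.bases))
    return out


def _cigar_arrays(cigar):
    ops = np.array([("MIDS").index(op) for op, _ in cigar], dtype=np.uint8)
    cnts = np.array([n for _, n in cigar], dtype=np.int64)
    return ops, cnts


def map_and_pileup(
    sequence: str,
    reads: list[tuple[str, str]],
    preset: Preset,
    min_identity: float = 0.0,
    weight_by_identity: bool = False,
    index: ReferenceIndex | None = None,
    end_trim: int = 25,
    circular: bool = False,
):
    """Map reads to one sequence and stack them into a column pileup.

    Returns (counts, insertions, alignments, span_depth): counts is a
    (5, L) matrix of weighted votes for A/C/G/T/deletion per column;
    insertions maps a junction position p to a Counter of strings inserted
    before column p; span_depth[p] is the weighted number of alignments
    strictly spanning junction p (the correct denominator for insertion
    votes — an alignment starting exactly at p covers the column but cannot
    express an insertion before it).

    The first and last ``end_trim`` aligned query bases of every alignment
    are excluded from the pileup: an indel within a few bases of a read end
    is soft-clipped rather than aligned, so untrimmed end columns would
    dilute indel votes with reads that cannot express them.

    With ``circular`` the sequence is treated as a circular molecule: reads
    are mapped against a circularly padded reference so that coverage does
    not collapse at the linearization origin, and votes past the origin are
    folded back.
    """
    L = len(sequence)
    pad = min(L // 2, 1000) if circular else 0
    if circular:
        index = ReferenceIndex([("ref", sequence + sequence[:pad])], preset)
    elif index is None:
        index = ReferenceIndex([("ref", sequence)], preset)
    counts = np.zeros((5, L + pad), dtype=np.int64)
    span_acc = np.zeros(L + pad + 2, dtype=np.int64)
    insertions: dict[int, Counter] = {}
    alns = []
    for rid, bases in reads:
        hits = map_read((rid, bases), index=index, max_secondary=3)
        if not hits:
            continue
        # a read cut elsewhere on the circle maps as two query-disjoint arcs
        # against a linear reference: accumulate every compatible arc
        kept: list = []
        for a in hits:
            if a.identity < min_identity:
                continue
            if any(_q_overlap(a, b) > 0.2 * a.q_span() for b in kept):
                continue
            kept.append(a)
        for a in kept:
            w = max(1, int(round(a.identity * 100))) if weight_by_identity else 1
            oriented = bases if a.strand == "+" else sq.revcomp(bases)
            qcodes = sq.encode(oriented)
            cigar, tstart, qstart = _trim_cigar(a.cigar, a.t_interval[0], end_trim)
            if not cigar:
                continue
            ops, cnts = _cigar_arrays(cigar)
            kernels.pileup_accumulate(counts, ops, cnts, tstart, qcodes, qstart, w)
            tend = tstart + sum(n for op, n in cigar if op in "MD")
            if tend - 1 > tstart + 1:
                span_acc[tstart + 1] += w
                span_acc[tend] -= w
            ti = tstart
            qi = qstart
            for op, n in cigar:
                if op == "M":
                    ti += n
                    qi += n
                elif op == "S":
                    qi += n
                elif op == "D":
                    ti += n
                else:  # I
                    insertions.setdefault(ti, Counter())[oriented[qi : qi + n]] += w
                    qi += n
            alns.append(a)
    span = np.cumsum(span_acc[: L + pad])
    if pad:
        counts[:, :pad] += counts[:, L:]
        counts = counts[:, :L]
        span = span.copy()
        span[:pad] += span[L:]
        span = span[:L]
        folded: dict[int, Counter] = {}
        for j, ctr in insertions.items():
            folded.setdefault(j % L, Counter()).update(ctr)
        insertions = folded
    return counts, insertions, alns, span


def _trim_cigar(cigar, tstart: int, n: int):
    """Drop the first and last ``n`` aligned query bases (M/I columns) from
    a CIGAR; returns (trimmed cigar, new tstart, new qstart in oriented
    query coordinates). Soft clips count toward qstart but not the trim."""
    if n <= 0:
        return list(cigar), tstart, 0
    qstart = 0
    work = list(cigar)
    if work and work[0][0] == "S":
        qstart = work[0][1]
        work = work[1:]
    if work and work[-1][0] == "S":
        work = work[:-1]
    # trim from the front
    left = n
    while work and left > 0:
        op, c = work[0]
        if op == "D":
            tstart += c
            work = work[1:]
            continue
        take = min(c, left)
        if op in "MI":
            qstart += take
            if op == "M":
                tstart += take
            left -= take
        if take == c:
            work = work[1:]
        else:
            work[0] = (op, c - take)
    right = n
    while work and right > 0:
        op, c = work[-1]
        if op == "D":
            work = work[:-1]
            continue
        take = min(c, right)
        if op in "MI":
            right -= take
        if take == c:
            work = work[:-1]
        else:
            work[-1] = (op, c - take)
    while work and work[0][0] == "D":
        tstart += work[0][1]
        work = work[1:]
    while work and work[-1][0] == "D":
        work = work[:-1]
    return work, tstart, qstart


def _q_overlap(a, b) -> int:
    a0, a1 = a.q_interval
    b0, b1 = b.q_interval
    return max(0, min(a1, b1) - max(a0, b0))


def arbitrate_with_long_reads(
    sub: str,
    reads_u: list[tuple[str, str]],
    lcounts: np.ndarray,
    lins: dict[int, Counter],
    min_depth: int,
    min_agree: float,
    offset: int = 0,
    circular: bool = False,
) -> tuple[str, list[Discrepancy]]:
    """Resolve two-allele mixed columns of one repeat unit by long reads.

    When the unit's read set cannot be partitioned further, a column (or
    insertion junction) where the slice pileup splits cleanly between two
    alleles marks a family variant that consensus building blurred into
    identical copies. Short reads from the paralogous copies are
    interchangeable there, so only the long reads — placed by the overall
    clone structure — can say which allele this copy carries. ``offset``
    locates the slice on the consensus the long pileup was computed
    against; the edit requires a >= 60% long-read majority.
    """
    scounts, sins, _, sspan = map_and_pileup(
        sub, reads_u, SHORT, min_identity=0.75, circular=circular
    )
    sdepth = scounts.sum(axis=0)
    L = len(sub)
    edits: list[tuple[int, int, str, Discrepancy]] = []
    # contested substitution / deletion columns
    for p in range(L):
        d = int(sdepth[p])
        if d < min_depth:
            continue
        g = offset + p
        if g >= lcounts.shape[1]:
            continue
        cdel = int(scounts[4, p])
        ltot = int(lcounts[:5, g].sum())
        if 0.3 * d <= cdel < min_agree * d and ltot > 0:
            if lcounts[4, g] >= 0.6 * ltot:
                edits.append((p, p + 1, "", Discrepancy(g, sub[p], "-", SUBSTITUTION)))
                continue
        order = np.argsort(scounts[:4, p])[::-1]
        a1, a2 = int(order[0]), int(order[1])
        c1, c2 = int(scounts[a1, p]), int(scounts[a2, p])
        if c1 >= min_agree * d or c2 < 0.25 * d or (c1 + c2) < 0.85 * d:
            continue
        ld = int(lcounts[:4, g].sum())
        if ld <= 0:
            continue
        lmaj = int(lcounts[:4, g].argmax())
        if lmaj not in (a1, a2) or lcounts[lmaj, g] < 0.6 * ld:
            continue
        winner = _BASES[lmaj]
        if winner != sub[p]:
            edits.append(
                (p, p + 1, winner, Discrepancy(g, sub[p], winner, SUBSTITUTION))
            )
    # contested insertion junctions: a substantial minority of reads insert
    # here (the rest come from a copy without the base, or represent it
    # elsewhere); long-read insertion votes, aggregated by first base over a
    # +-1 junction window, decide
    for j, ctr in sins.items():
        if j > L:
            continue
        d = int(sspan[min(j, L - 1)])
        if d < min_depth:
            continue
        mc = ctr.most_common(2)
        if mc[0][1] >= min_agree * d or mc[0][1] < 0.3 * d:
            continue
        lvotes: dict[str, int] = {}
        for jj in (offset + j - 1, offset + j, offset + j + 1):
            lctr = lins.get(jj)
            if not lctr:
                continue
            for s, c in lctr.items():
                lvotes[s[0]] = lvotes.get(s[0], 0) + c
        if not lvotes:
            continue
        ltot = sum(lvotes.values())
        wb, wc = max(lvotes.items(), key=lambda kv: kv[1])
        if wc < 0.55 * ltot or wc < 200:
            continue
        # insert the short-read string matching the long-read winning base
        s_short = next((s for s, _ in ctr.most_common(4) if s[0] == wb), None)
        if s_short is None:
            continue
        rep = s_short + sub[j : j + 1]
        edits.append(
            (j, min(j + 1, L), rep,
             Discrepancy(offset + j, sub[j : j + 1] or "-", rep, SUBSTITUTION))
        )
    out = sub
    disc = []
    for st, en, rep, d in sorted(edits, key=lambda e: -e[0]):
        out = out[:st] + rep + out[en:]
        disc.append(d)
    disc.sort(key=lambda d: d.position)
    return out, disc



def _window_string(aln, oriented: str, wlo: int, whi: int) -> str | None:
    """The literal read substring aligned between target columns wlo and
    whi (both must be M columns of the alignment), or None."""
    ti = aln.t_interval[0]
    qi = 0
    qa = qb = None
    for op, n in aln.cigar:
        if op == "M":
            if ti <= wlo < ti + n:
                qa = qi + (wlo - ti)
            if ti <= whi < ti + n:
                qb = qi + (whi - ti)
            ti += n
            qi += n
        elif op in "SI":
            qi += n
        else:
            if ti <= wlo < ti + n or ti <= whi < ti + n:
                return None  # boundary falls in a deletion: ambiguous
            ti += n
    if qa is None or qb is None or qb <= qa:
        return None
    return oriented[qa:qb]


def window_repair(
    sequence: str,
    short_reads,
    min_depth: int = 15,
    modal_frac: float = 0.6,
    circular: bool = False,
    max_windows: int = 200,
) -> tuple[str, list[Discrepancy]]:
    """Alignment-free repair of locally garbled stretches.

    Column-wise polishing stalls when a compound difference (e.g. a base
    shifted between two nearby homopolymer runs) has several co-optimal
    alignment representations: reads split their votes between an
    indel-based and a mismatch-based encoding and no single column reaches
    the agreement threshold. Here every contested cluster is re-derived
    literally: each read spanning the window contributes its raw substring
    between two clean flanking columns, and if a clear modal string
    (>= ``modal_frac`` of spanning reads) differs from the sequence, the
    window is replaced by it. Genuine mixed-allele columns (e.g. unresolved
    paralogous variants at ~50/50) never reach the modal threshold and are
    left for long-read arbitration.
    """
    reads = flatten_short_reads(short_reads)
    if not reads:
        return sequence, []
    L = len(sequence)
    counts, insertions, alns, span = map_and_pileup(
        sequence, reads, SHORT, min_identity=0.75, circular=circular, end_trim=15
    )
    depth = counts.sum(axis=0)
    codes = sq.encode(sequence)
    cur_cnt = counts[np.minimum(codes, 4), np.arange(L)]
    # nominate columns with substantial disagreement; the depth gate sits
    # well below the edit threshold so that low-coverage pockets (where
    # column-wise editing can never act) are still examined — the window's
    # own modal condition provides the safety
    disagree = (depth >= 5) & ((depth - cur_cnt) >= 0.12 * depth)
    cand = set(np.flatnonzero(disagree).tolist())
    for j, ctr in insertions.items():
        p = min(j, L - 1)
        if span[p] >= 5 and sum(ctr.values()) >= 0.12 * span[p]:
            cand.add(p)
    if not cand:
        return sequence, []
    # cluster candidates within 40 bp; clusters wider than a read's reach
    # cannot be spanned and are skipped
    todo = sorted(cand)
    clusters = []
    lo = hi = todo[0]
    for p in todo[1:]:
        if p - hi <= 40:
            hi = p
        else:
            if hi - lo <= 60:
                clusters.append((lo, hi))
            lo = hi = p
    if hi - lo <= 60:
        clusters.append((lo, hi))
    clusters = clusters[:max_windows]

    pad = min(L // 2, 1000) if circular else 0
    ext = sequence + sequence[:pad]
    run_mask = sq.homopolymer_runs(codes, 3)
    by_id = dict(reads)
    min_span = 8  # a unanimous-modal window is decisive even at thin depth
    edits: list[tuple[int, int, str, Discrepancy]] = []
    for lo, hi in clusters:
        # wide flanks give cleaner boundaries; at a coverage trough fewer
        # reads span them, so narrow the window until enough do
        for flank in (30, 15):
            wlo, whi = lo - flank, hi + flank + 1
            if wlo < 0 and not circular:
                wlo = 0
            if whi >= L + pad - 5 or wlo < 0:
                break
            votes: Counter = Counter()
            n_span = 0
            for a in alns:
                if a.t_interval[0] > wlo - 5 or a.t_interval[1] < whi + 5:
                    continue
                bases = by_id.get(a.query_id)
                if bases is None:
                    continue
                oriented = bases if a.strand == "+" else sq.revcomp(bases)
                s = _window_string(a, oriented, wlo, whi)
                if s is not None:
                    votes[s] += 1
                    n_span += 1
            if n_span < min_span:
                continue
            modal, c = votes.most_common(1)[0]
            current = ext[wlo:whi]
            if modal == current:
                break
            if c < modal_frac * n_span:
                break
            runner = votes.most_common(2)
            if len(runner) > 1 and runner[1][1] > 0.5 * c:
                break
            st, en = wlo % L, wlo % L + (whi - wlo)
            if en > L:
                break  # folded duplicate of a prefix window
            klass = (
                HOMOPOLYMER_INDEL
                if len(modal) != len(current) and run_mask[st:en].any()
                else SUBSTITUTION
            )
            edits.append((st, en, modal, Discrepancy(st, current, modal, klass)))
            break

    out = sequence
    disc = []
    for st, en, rep, d in sorted(edits, key=lambda e: -e[0]):
        out = out[:st] + rep + out[en:]
        disc.append(d)
    disc.sort(key=lambda d: d.position)
    return out, disc


def reanchor_to_vector(assembly: ConsensusAssembly, vector: str) -> ConsensusAssembly:
    """Rotate a finished circular assembly so the vector starts exactly at 0.

    The backbone read's rotation is only as precise as a noisy vector
    alignment; once polished, aligning the known vector to the consensus
    fixes the linearization origin to the base. Support arrays and
    discrepancy positions are rolled into the new frame.
    """
    seq = assembly.sequence
    L = len(seq)
    hits = map_read(("vector", vector), [("cons", seq)], preset="long")
    if not hits:
        return assembly
    a = hits[0]
    if a.strand != "+":  # canonical orientation should already hold
        return assembly
    off = (a.t_interval[0] - a.q_interval[0]) % L
    if off == 0:
        return assembly
    assembly.sequence = seq[off:] + seq[:off]
    assembly.support = {
        k: np.roll(v, -off) if isinstance(v, np.ndarray) and v.size == L else v
        for k, v in assembly.support.items()
    }
    for d in assembly.discrepancies:
        d.position = (d.position - off) % L
    assembly.discrepancies.sort(key=lambda d: d.position)
    return assembly


def select_backbone(
    full_calls: list[FullLengthCall],
    reads: list[NanoporeRead],
    draft,
    internally_repetitive: bool = False,
) -> NanoporeRead:
    """Choose and canonicalize the backbone read for a clone.

    The highest-identity (vs draft) vector-anchored full-length read wins;
    ties break to the lexicographically smaller read id. Putative
    full-length reads (called by length alone) are eligible only for clones
    not flagged internally repetitive — for tandem arrays an unanchored
    rotation cannot be trusted — and only when no anchored read exists.
    Falls back to the draft itself (with a warning) when the clone has no
    full-length reads at all.
    """
    by_id = {r.read_id: r for r in reads}
    contigs = _draft_contigs(draft)
    draft_len = sum(len(s) for _, s in contigs)
    anchored = [
        c
        for c in full_calls
        if c.status == FULL_VECTOR_ANCHORED
        # a full-length read cannot be much shorter than the draft
        and (draft_len == 0 or len(by_id[c.read_id].bases) >= 0.5 * draft_len)
    ]
    pool = anchored
    if not pool and not internally_repetitive:
        pool = [c for c in full_calls if c.status == PUTATIVE_FULL_BY_LENGTH]
    if not pool:
        if contigs:
            warnings.warn("no full-length reads: falling back to the draft backbone")
            return NanoporeRead(read_id="draft", bases="".join(s for _, s in contigs))
        raise ValueError(
            "no full-length reads and no draft: the clone must be sequenced "
            "again (use the partial reads to polish the next attempt)"
        )
    index = ReferenceIndex(contigs, LONG) if contigs else None
    best = None
    for call in pool:
        rotated = rotate_to_vector(by_id[call.read_id], call)
        if index is not None:
            hits = map_read((rotated.read_id, rotated.bases), index=index, max_secondary=0)
            ident = hits[0].identity if hits else 0.0
        else:
            ident = 1.0
        key = (-ident, call.read_id)
        if best is None or key < best[0]:
            best = (key, rotated)
    return best[1]


def _draft_contigs(draft):
    if draft is None:
        return []
    if isinstance(draft, str):
        return [("draft", draft)]
    out = []
    for item in draft:
        if isinstance(item, tuple):
            out.append(item)
        else:
            out.append((item.id, item.seq))
    return out


def _consensus_from_pileup(
    sequence: str,
    counts: np.ndarray,
    insertions: dict[int, Counter],
    min_depth: int,
    min_frac: float,
    window: int = 500,
    span: np.ndarray | None = None,
) -> tuple[str, list[int]]:
    """Column-wise weighted-majority consensus; returns (sequence,
    zero-coverage window starts). Columns below min_depth keep the input
    base; ties keep the input base. Insertion votes are measured against
    the junction-spanning depth when provided."""
    codes = sq.encode(sequence)
    depth = counts.sum(axis=0)
    ins_depth = depth if span is None else span
    best = counts.argmax(axis=0)
    best_cnt = counts.max(axis=0)
    cur_cnt = counts[codes, np.arange(codes.size)]
    out = []
    L = codes.size
    zero_windows = [w for w in range(0, L, window) if depth[w : w + window].max(initial=0) == 0]
    for p in range(L):
        if p in insertions:
            s, c = insertions[p].most_common(1)[0]
            d = ins_depth[p]
            if d >= min_depth and c > min_frac * d:
                out.append(s)
        if depth[p] < min_depth or best_cnt[p] <= cur_cnt[p]:
            out.append(sq.decode(codes[p : p + 1]))
        elif best[p] == 4:
            pass  # deletion wins
        else:
            out.append(_BASES[best[p]])
    return "".join(out), zero_windows


def polish_long(
    backbone: str,
    long_reads: list[NanoporeRead],
    window: int = 500,
    rounds: int = 2,
    preset: Preset = LONG,
    min_depth: int = 3,
    circular: bool = True,
) -> tuple[str, dict]:
    """Windowed weighted-majority polishing of a backbone with long reads.

    Reads are aligned to the backbone; each backbone-guided column stack is
    resolved by identity-weighted majority (insertions included when a
    majority of covering reads agree on the inserted string). Windows with
    zero coverage keep the backbone sequence and are flagged. Repeated
    ``rounds`` times (re-mapping each round). ``circular`` treats the
    backbone as a circular molecule (a rotated full-length clone read).
    """
    if window < 100:
        raise ValueError("window must be >= 100")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    cur = backbone
    info: dict = {}
    pairs = [(r.read_id, r.bases) for r in long_reads]
    for _ in range(rounds):
        counts, ins, alns, span = map_and_pileup(
            cur, pairs, preset, min_identity=0.6, weight_by_identity=True,
            circular=circular,
        )
        cur, zero_windows = _consensus_from_pileup(
            cur, counts, ins, min_depth=min_depth, min_frac=0.5, window=window,
            span=span,
        )
        info = {
            "long_depth": counts.sum(axis=0),
            "zero_coverage_windows": zero_windows,
            "n_reads_used": len(alns),
        }
    return cur, info


def polish_short(
    sequence: str,
    illumina_pairs,
    min_depth: int = 15,
    min_agree: float = 0.9,
    clone_id: str = "",
    long_depth: np.ndarray | None = None,
    preset: Preset = SHORT,
    circular: bool = False,
) -> ConsensusAssembly:
    """Correct a long-read consensus to the short-read column consensus.

    At every position where the short-read consensus differs from the
    sequence and short depth >= min_depth and agreement >= min_agree, the
    base — or the whole homopolymer run length, for runs >= 3, so indels are
    edited as a unit — is replaced by the short-read consensus. Each edit is
    logged as a discrepancy (HOMOPOLYMER_INDEL within/adjacent to a run >= 3,
    SUBSTITUTION otherwise); positions where the short reads disagree with
    the sequence but fail the thresholds are logged UNRESOLVED and left
    unedited. With no short reads the input is returned unchanged.
    """
    if min_depth < 10:
        raise ValueError("min_depth must be >= 10")
    if min_agree < 0.8:
        raise ValueError("min_agree must be >= 0.8")
    reads = flatten_short_reads(illumina_pairs)
    L = len(sequence)
    if not reads:
        warnings.warn("no short reads: returning the long-read-only assembly")
        return ConsensusAssembly(
            clone_id=clone_id,
            sequence=sequence,
            support={"long_depth": long_depth},
            rounds_applied=0,
        )
    counts, insertions, _, span = map_and_pileup(
        sequence, reads, preset, min_identity=0.75, circular=circular
    )
    codes = sq.encode(sequence)
    depth = counts.sum(axis=0)
    cur_cnt = counts[np.minimum(codes, 4), np.arange(L)]
    agree = np.divide(cur_cnt, depth, out=np.zeros(L), where=depth > 0)
    run_mask = sq.homopolymer_runs(codes, 3)

    # edits: (start, end, replacement, Discrepancy)
    edits: list[tuple[int, int, str, Discrepancy | None]] = []
    consumed = np.zeros(L, dtype=bool)

    def _class_at(p: int) -> str:
        lo = max(0, p - 1)
        hi = min(L, p + 2)
        return HOMOPOLYMER_INDEL if run_mask[lo:hi].any() else SUBSTITUTION

    # homopolymer runs edited as units
    p = 0
    while p < L:
        if not run_mask[p]:
            p += 1
            continue
        a = p
        while p < L and codes[p] == codes[a]:
            p += 1
        b = p
        X = sequence[a]
        xcode = codes[a]
        run_depths = depth[a:b]
        if run_depths.size == 0 or run_depths.min() < min_depth:
            continue
        n_del = 0
        subs_in_run = []
        for c in range(a, b):
            if counts[4, c] >= min_agree * depth[c]:
                n_del += 1
            else:
                bb = int(counts[:4, c].argmax())
                if bb != xcode and counts[bb, c] >= min_agree * depth[c]:
                    subs_in_run.append((c, _BASES[bb]))
        n_ins = 0
        for j in range(a, b + 1):
            if j in insertions:
                pure = {
                    s: c for s, c in insertions[j].items() if set(s) == {X}
                }
                cnt = sum(pure.values())
                dj = span[min(j, L - 1)]
                if pure and dj >= min_depth and cnt >= min_agree * dj:
                    n_ins += len(max(pure, key=pure.get))
        new_len = (b - a) - n_del + n_ins
        if new_len != (b - a):
            edits.append(
                (
                    a,
                    b,
                    X * new_len,
                    Discrepancy(a, X * (b - a), X * new_len, HOMOPOLYMER_INDEL),
                )
            )
            consumed[a:b] = True
        for c, yb in subs_in_run:
            if not consumed[c]:
                edits.append((c, c + 1, yb, Discrepancy(c, sequence[c], yb, _class_at(c))))
                consumed[c] = True

    # generic columns
    for p in range(L):
        if consumed[p]:
            continue
        d = depth[p]
        cb = int(codes[p]) if codes[p] < 4 else 0
        masked = counts[:, p].copy()
        masked[cb] = -1
        alt = int(masked.argmax())  # best non-current allele
        alt_cnt = int(counts[alt, p])
        if d == 0 or alt_cnt == 0:
            continue
        if alt_cnt < cur_cnt[p]:
            continue
        if d >= min_depth and alt_cnt >= min_agree * d:
            if alt == 4:
                edits.append((p, p + 1, "", Discrepancy(p, sequence[p], "-", _class_at(p))))
            else:
                edits.append(
                    (p, p + 1, _BASES[alt], Discrepancy(p, sequence[p], _BASES[alt], _class_at(p)))
                )
        elif alt_cnt >= 0.35 * d:
            edits.append((p, p, sequence[p], Discrepancy(p, sequence[p], _BASES[alt], UNRESOLVED)))

    # non-homopolymer insertions: agreement is on the presence of an
    # insertion (total votes); the dominant string supplies the content
    for j, ctr in insertions.items():
        s, cnt = ctr.most_common(1)[0]
        total = sum(ctr.values())
        dj = span[min(j, L - 1)]
        jr = range(max(0, j - 1), min(L, j + 1))
        if any(consumed[c] for c in jr):
            continue
        # a pure-base insertion flanking a run of that same base belongs to
        # the run pass (it adjusts the run length as a unit)
        in_run = len(set(s)) == 1 and any(
            run_mask[c] and sequence[c] == s[0] for c in jr
        )
        if in_run:
            continue
        if dj >= min_depth and total >= min_agree * dj and cnt >= 0.6 * total:
            st, en = j, min(j + 1, L)
            rep = s + sequence[st:en]  # insert before column j
            klass = _class_at(min(j, L - 1))
            edits.append((st, en, rep, Discrepancy(st, sequence[st:en] or "-", rep, klass)))

    edits.sort(key=lambda e: (e[0], e[1]))
    discrepancies = [e[3] for e in edits if e[3] is not None]
    # apply right-to-left
    out = sequence
    new_short_depth = depth.astype(np.int64).copy()
    new_agree = agree.copy()
    n_applied = 0
    for st, en, rep, disc in sorted(edits, key=lambda e: -e[0]):
        if disc is not None and disc.klass == UNRESOLVED:
            continue
        out = out[:st] + rep + out[en:]
        n_applied += 1
        pad = np.full(len(rep), max(new_short_depth[st:en].max(initial=0), depth[min(st, L - 1)]))
        new_short_depth = np.concatenate((new_short_depth[:st], pad, new_short_depth[en:]))
        new_agree = np.concatenate((new_agree[:st], np.ones(len(rep)), new_agree[en:]))
    support = {
        "short_depth": new_short_depth,
        "short_agree_frac": np.clip(new_agree, 0.0, 1.0),
    }
    if long_depth is not None:
        support["long_depth"] = long_depth
    return ConsensusAssembly(
        clone_id=clone_id,
        sequence=out,
        support=support,
        discrepancies=discrepancies,
        rounds_applied=1,
    )
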