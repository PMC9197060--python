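"""Divide-and-conquer finishing of internally repetitive clones.

Near-identical internal repeats (tandem arrays, palindrome arms) defeat
column-wise polishing: short reads from different copies blur every copy
toward a common consensus. The remedy implemented here follows the
clone-finishing playbook: detect the repeat units by self-alignment of the
consensus, identify the sequence family variants (SFVs) that distinguish
the copies, electronically split the consensus into units, polish each unit
separately with the short reads whose SFV alleles place them in that unit,
and merge the units back — with the full-length long reads arbitrating the
assignment of alleles to units, since only they span several copies in a
single molecule.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import seq as sq
from .align import LONG, SHORT, ReferenceIndex, align_pair, extend_align
from .consensus import (
    SUBSTITUTION,
    arbitrate_with_long_reads,
    UNRESOLVED,
    ConsensusAssembly,
    Discrepancy,
    flatten_short_reads,
    map_and_pileup,
    polish_short,
    window_repair,
)
from .simulate import NanoporeRead

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class RepeatUnit:
    """One copy of an internal repeat on the clone consensus."""

    unit_id: str
    interval: tuple[int, int]  # 0-based half-open on the consensus
    paralog_group: int
    orientation: str  # 'direct' | 'inverted'

    def length(self) -> int:
        return self.interval[1] - self.interval[0]


@dataclass
class SFV:
    """A sequence family variant: one alignment column whose allele differs
    between paralogous repeat units.

    ``column`` is the offset in the group's unit alignment (coordinates of
    the leftmost unit, direct orientation). ``alleles`` and support are per
    unit; ``positions`` locates the column on the consensus for each unit.
    """

    group: int
    column: int
    alleles: dict[str, str]  # unit_id -> base ('-' for deletion)
    short_read_support: dict[str, tuple[int, float]] = field(default_factory=dict)
    positions: dict[str, int] = field(default_factory=dict)


def _unit_seq(consensus: str, unit: RepeatUnit) -> str:
    a, b = unit.interval
    s = consensus[a:b]
    return sq.revcomp(s) if unit.orientation == "inverted" else s


def detect_self_repeats(
    consensus: str,
    min_len: int = 2000,
    min_identity: float = 0.99,
    preset=LONG,
) -> list[RepeatUnit]:
    """Detect internal repeat units by self-alignment of the consensus.

    Both strands are searched; the trivial self-diagonal is excluded. A
    plus-strand off-diagonal hit of period P is decomposed into a tandem
    array of direct units of length P; a minus-strand self-hit is a
    palindrome and yields two inverted arms. An empty list means the clone
    is non-repetitive and the divide-and-conquer stage is skipped.
    """
    L = len(consensus)
    if L < 2 * min_len:
        raise ValueError("consensus shorter than twice the minimum unit length")
    index = ReferenceIndex([("self", consensus)], preset)
    chains = index.best_chains(consensus)
    claimed = np.zeros(L, dtype=bool)
    units: list[RepeatUnit] = []
    group = 0
    for chain in chains:
        k = chain.k
        q0 = chain.anchors[0][0]
        q1 = chain.anchors[-1][0] + k
        t0 = chain.anchors[0][1]
        t1 = chain.anchors[-1][1] + k
        if chain.strand == "+":
            diag = [t - q for q, t in chain.anchors]
            period = int(np.median(diag))
            if abs(period) < 50:
                continue  # trivial self-diagonal
            if period < 0:
                continue  # symmetric duplicate of a q<t chain
            # an unpolished consensus can shrink units slightly, so the
            # unit-length (= period) filter gets 10% slack
            if abs(period) < 0.9 * min_len:
                continue
            if min(q1 - q0, t1 - t0) < 0.8 * min_len:
                continue
            aln = extend_align(consensus, consensus, chain, band=preset.band)
            if aln.identity < min_identity or aln.n_columns < 0.9 * min_len:
                continue
            span_a = aln.q_interval[0]
            span_b = aln.t_interval[1]
            if claimed[span_a:span_b].any():
                continue
            n_units = int(round((span_b - span_a) / period))
            if n_units < 2:
                continue
            width = (span_b - span_a) / n_units
            for i in range(n_units):
                a = span_a + int(round(i * width))
                b = span_a + int(round((i + 1) * width))
                units.append(
                    RepeatUnit(f"u{len(units)}", (a, b), group, "direct")
                )
            claimed[span_a:span_b] = True
            group += 1
        else:
            # inverted self-hit: palindrome arms
            if min(q1 - q0, t1 - t0) < 0.8 * min_len:
                continue
            aln = extend_align(consensus, consensus, chain, band=preset.band)
            if aln.identity < min_identity or aln.n_columns < min_len:
                continue
            qa, qb = aln.q_interval
            ta, tb = aln.t_interval
            ov = min(qb, tb) - max(qa, ta)
            if ov > 0.5 * min(qb - qa, tb - ta):
                # the hit covers the whole palindrome mapped onto itself
                a, b = min(qa, ta), max(qb, tb)
                if claimed[a:b].any():
                    continue
                mid = (a + b) // 2
                units.append(RepeatUnit(f"u{len(units)}", (a, mid), group, "direct"))
                units.append(RepeatUnit(f"u{len(units)}", (mid, b), group, "inverted"))
                claimed[a:b] = True
            else:
                first, second = sorted([(qa, qb), (ta, tb)])
                if claimed[first[0] : first[1]].any() or claimed[second[0] : second[1]].any():
                    continue
                units.append(RepeatUnit(f"u{len(units)}", first, group, "direct"))
                units.append(RepeatUnit(f"u{len(units)}", second, group, "inverted"))
                claimed[first[0] : first[1]] = True
                claimed[second[0] : second[1]] = True
            group += 1
    units.sort(key=lambda u: u.interval)
    return units


def _column_maps(consensus: str, group_units: list[RepeatUnit]):
    """Per-unit mapping from reference-unit columns to unit offsets/alleles.

    Returns (ref_len, maps) with maps[unit_id] = (offsets, alleles): offsets
    is an int array over ref columns giving the unit-local offset (-1 where
    the column is deleted in that unit), alleles the unit-frame base there.
    """
    ref_unit = group_units[0]
    ref_seq = _unit_seq(consensus, ref_unit)
    maps = {}
    n = len(ref_seq)
    off0 = np.arange(n, dtype=np.int64)
    maps[ref_unit.unit_id] = (off0, np.array(list(ref_seq)))
    for unit in group_units[1:]:
        useq = _unit_seq(consensus, unit)
        aln = align_pair(useq, ref_seq)
        offsets = np.full(n, -1, dtype=np.int64)
        alleles = np.full(n, "-", dtype="U1")
        qi = ti = 0
        for op, cnt in aln.cigar:
            if op == "M":
                offsets[ti : ti + cnt] = np.arange(qi, qi + cnt)
                alleles[ti : ti + cnt] = list(useq[qi : qi + cnt])
                qi += cnt
                ti += cnt
            elif op == "I":
                qi += cnt
            elif op == "D":
                ti += cnt
        maps[unit.unit_id] = (offsets, alleles)
    return n, maps


def _consensus_pos(unit: RepeatUnit, offset: int) -> int:
    """Consensus coordinate of a unit-local offset (direct frame)."""
    a, b = unit.interval
    if unit.orientation == "inverted":
        return b - 1 - offset
    return a + offset


def _to_consensus_frame(base: str, unit: RepeatUnit) -> str:
    if base == "-" or unit.orientation == "direct":
        return base
    return sq.revcomp(base)


def call_sfvs(
    units: list[RepeatUnit],
    consensus: str,
    illumina_pairs,
    min_depth: int = 15,
    min_agree: float = 0.9,
    pileup_counts: np.ndarray | None = None,
) -> list[SFV]:
    """Identify SFV columns distinguishing the units of each repeat group.

    Unit sequences are aligned pairwise to the leftmost unit (progressively,
    left to right, for larger groups); columns with differing alleles are
    emitted as SFVs when the short-read pileup supports the called allele on
    at least one unit (depth >= min_depth, agreement >= min_agree). Columns
    where the short reads contradict every unit allele are flagged as
    possible collapse artifacts and not emitted.
    """
    groups: dict[int, list[RepeatUnit]] = {}
    for u in units:
        groups.setdefault(u.paralog_group, []).append(u)
    if pileup_counts is None:
        reads = flatten_short_reads(illumina_pairs)
        pileup_counts, _, _, _ = map_and_pileup(consensus, reads, SHORT, min_identity=0.75)
    depth = pileup_counts.sum(axis=0)
    sfvs: list[SFV] = []
    for g, gunits in sorted(groups.items()):
        if len(gunits) < 2:
            continue
        gunits = sorted(gunits, key=lambda u: u.interval)
        ref_len, maps = _column_maps(consensus, gunits)
        # unit boundaries from self-alignment are only a few bp precise, so
        # edge columns would be called on boundary jitter, not content
        edge = 5
        for col in range(edge, ref_len - edge):
            col_alleles = {}
            for u in gunits:
                offsets, alleles = maps[u.unit_id]
                col_alleles[u.unit_id] = str(alleles[col])
            if len(set(col_alleles.values())) < 2:
                continue
            support = {}
            positions = {}
            contradiction = False
            any_supported = False
            for u in gunits:
                offsets, _ = maps[u.unit_id]
                off = int(offsets[col])
                if off < 0:
                    continue
                pos = _consensus_pos(u, off)
                positions[u.unit_id] = pos
                d = int(depth[pos])
                cons_allele = _to_consensus_frame(col_alleles[u.unit_id], u)
                if cons_allele in _BASES and d > 0:
                    cnt = int(pileup_counts[_BASES.index(cons_allele), pos])
                    frac = cnt / d
                else:
                    frac = 0.0
                support[u.unit_id] = (d, frac)
                if d >= min_depth and frac >= min_agree:
                    any_supported = True
                if d >= min_depth:
                    plur = int(pileup_counts[:4, pos].argmax())
                    plur_base = _BASES[plur]
                    unit_frame_plur = _to_consensus_frame(plur_base, u)  # involution
                    if (
                        pileup_counts[plur, pos] >= min_agree * d
                        and unit_frame_plur not in set(col_alleles.values())
                    ):
                        contradiction = True
            if contradiction:
                logger.warning(
                    "group %d column %d: short reads contradict all unit "
                    "alleles (possible collapse artifact); not emitted",
                    g,
                    col,
                )
                continue
            if any_supported:
                sfvs.append(
                    SFV(
                        group=g,
                        column=col,
                        alleles=col_alleles,
                        short_read_support=support,
                        positions=positions,
                    )
                )
    return sfvs


def _read_base_at(aln, oriented: str, pos: int) -> str | None:
    """Base a read places on consensus position ``pos`` (consensus frame),
    or '-' for a deletion, or None if not covered."""
    ti = aln.t_interval[0]
    qi = 0
    for op, n in aln.cigar:
        if op == "M":
            if ti <= pos < ti + n:
                return oriented[qi + (pos - ti)]
            ti += n
            qi += n
        elif op == "S" or op == "I":
            qi += n
        else:  # D
            if ti <= pos < ti + n:
                return "-"
            ti += n
    return None


def finish_repetitive(
    assembly,
    units: list[RepeatUnit],
    sfvs: list[SFV],
    long_reads: list[NanoporeRead],
    illumina_pairs,
    min_depth: int = 15,
    min_agree: float = 0.9,
) -> ConsensusAssembly:
    """Split, per-unit polish, and merge an internally repetitive consensus.

    Long reads arbitrate SFV alleles first: a full-length molecule spans
    several copies, so its pileup majority at an SFV position is structural
    evidence that cannot be blurred by cross-mapped short reads — a planted
    allele swap between units is repaired here. Short reads are then
    partitioned by their alleles at SFV columns (exact match at >= 1 column,
    no mismatching column); reads spanning no SFV column vote in every unit
    of their group, where they can only support columns on which the units
    agree. Each unit is polished independently and re-inserted at its
    interval; unit order and orientation are fixed by construction. Junctions
    are re-validated against long reads spanning the unit boundaries.
    """
    if isinstance(assembly, ConsensusAssembly):
        base = assembly
        seq_in = assembly.sequence
    else:
        base = ConsensusAssembly(clone_id="", sequence=assembly)
        seq_in = assembly
    if not units:
        return base

    seq = seq_in
    discrepancies = list(base.discrepancies)
    flags = list(base.flags)

    # --- long-read arbitration of SFV alleles.
    # Only molecules that extend beyond the repeat array are structurally
    # anchored; a truncated read contained within the array maps to either
    # copy arbitrarily and would pollute the per-copy evidence.
    span_w = 0
    by_group: dict[int, list[RepeatUnit]] = {}
    for u in units:
        by_group.setdefault(u.paralog_group, []).append(u)
    for gunits in by_group.values():
        w = max(u.interval[1] for u in gunits) - min(u.interval[0] for u in gunits)
        span_w = max(span_w, w)
    anchored = [r for r in long_reads if len(r.bases) >= span_w + 600]
    if len(anchored) < 5:
        anchored = long_reads
    long_pairs = [(r.read_id, r.bases) for r in anchored]
    lcounts, lins, lalns, _ = map_and_pileup(
        seq, long_pairs, LONG, min_identity=0.6, weight_by_identity=True
    )
    unit_by_id = {u.unit_id: u for u in units}
    repaired: list[tuple[int, str]] = []
    for sfv in sfvs:
        cons_alleles = {
            _to_consensus_frame(a, unit_by_id[uid])
            for uid, a in sfv.alleles.items()
            if a in _BASES
        }
        for uid, pos in sfv.positions.items():
            d = int(lcounts[:4, pos].sum())
            if d < 5:
                continue
            maj = int(lcounts[:4, pos].argmax())
            maj_base = _BASES[maj]
            if (
                maj_base != seq[pos]
                and lcounts[maj, pos] >= 0.6 * d
                and maj_base in cons_alleles
            ):
                repaired.append((pos, maj_base))
                u = unit_by_id[uid]
                sfv.alleles[uid] = _to_consensus_frame(maj_base, u)
    for pos, b in repaired:
        discrepancies.append(Discrepancy(pos, seq[pos], b, SUBSTITUTION))
        seq = seq[:pos] + b + seq[pos + 1 :]
    if repaired:
        flags.append(("SFV_REPAIRED_BY_LONG_READS", str(len(repaired))))

    # --- partition short reads by SFV content
    short = flatten_short_reads(illumina_pairs)
    _, _, salns, _ = map_and_pileup(seq, short, SHORT, min_identity=0.75)
    by_read = {(a.query_id): a for a in salns}
    seq_by_id = dict(short)
    groups: dict[int, list[RepeatUnit]] = {}
    for u in units:
        groups.setdefault(u.paralog_group, []).append(u)
    # Only columns with supported alleles on >= 2 units drive the read
    # partition: a column where the short reads pile up on one unit alone is
    # a consensus-error artifact, not a family variant, and reads from every
    # copy agree there anyway (ordinary per-unit polishing repairs it).
    def _balanced(sfv: SFV) -> bool:
        ok = sum(
            1
            for d, f in sfv.short_read_support.values()
            if d >= min_depth and f >= min_agree
        )
        return ok >= 2

    trusted = [s for s in sfvs if _balanced(s)]
    sfv_by_unit: dict[str, list[tuple[int, str]]] = {u.unit_id: [] for u in units}
    for sfv in trusted:
        for uid, pos in sfv.positions.items():
            cons_allele = _to_consensus_frame(sfv.alleles[uid], unit_by_id[uid])
            sfv_by_unit[uid].append((pos, cons_allele))
    # per-read evidence: for each group, either a set of units whose SFV
    # profile the read matches, 'any' (in the repeat but covering no trusted
    # column), or nothing (outside the group)
    read_evidence: dict[str, dict[int, frozenset | str]] = {}
    for rid, aln in by_read.items():
        ta, tb = aln.t_interval
        for g, gunits in groups.items():
            span_a = min(u.interval[0] for u in gunits)
            span_b = max(u.interval[1] for u in gunits)
            if tb <= span_a or ta >= span_b:
                continue
            host = next(
                (u for u in gunits if ta < u.interval[1] and tb > u.interval[0]), None
            )
            if host is None:
                continue
            oriented = seq_by_id[rid]
            if aln.strand == "-":
                oriented = sq.revcomp(oriented)
            covered = [
                (pos, allele)
                for pos, allele in sfv_by_unit[host.unit_id]
                if ta <= pos < tb
            ]
            if not covered:
                read_evidence.setdefault(rid, {})[g] = "any"
                continue
            obs = {pos: _read_base_at(aln, oriented, pos) for pos, _ in covered}
            col_of_pos = {}
            for sfv in trusted:
                if host.unit_id in sfv.positions:
                    col_of_pos[sfv.positions[host.unit_id]] = sfv
            matched = []
            for u in gunits:
                ok = False
                bad = False
                for pos, o in obs.items():
                    sfv = col_of_pos.get(pos)
                    if sfv is None or o is None:
                        continue
                    expect = _to_consensus_frame(sfv.alleles.get(u.unit_id, "?"), host)
                    if o == expect:
                        ok = True
                    else:
                        bad = True
                if ok and not bad:
                    matched.append(u.unit_id)
            read_evidence.setdefault(rid, {})[g] = (
                frozenset(matched) if matched else "any"
            )

    # fragment-level phasing: mates share a molecule, so an SFV under either
    # mate assigns the whole pair — this is what lets a ~500 bp fragment
    # reach past locally featureless stretches of a repeat unit
    unit_reads: dict[str, list[tuple[str, str]]] = {u.unit_id: [] for u in units}
    def _base_id(rid: str) -> str:
        return rid[:-2] if rid.endswith(("/1", "/2")) else rid

    pair_ev: dict[str, dict[int, list]] = {}
    for rid, per_group in read_evidence.items():
        for g, ev in per_group.items():
            pair_ev.setdefault(_base_id(rid), {}).setdefault(g, []).append(ev)
    mates: dict[str, list[str]] = {}
    for rid, _ in short:
        mates.setdefault(_base_id(rid), []).append(rid)
    for bid, per_group in pair_ev.items():
        for g, evs in per_group.items():
            sets = [e for e in evs if e != "any"]
            if not sets:
                assigned = {u.unit_id for u in groups[g]}  # uninformative pair
            else:
                inter = frozenset.intersection(*sets)
                if not inter:
                    continue  # conflicting mates: leave the fragment out
                assigned = set(inter)
            for uid in assigned:
                for rid in mates.get(bid, []):
                    unit_reads[uid].append((rid, seq_by_id[rid]))

    # --- per-unit polishing, then splice back (right to left)
    new_units: dict[str, str] = {}
    for u in sorted(units, key=lambda u: -u.interval[0]):
        a, b = u.interval
        sub = seq[a:b]
        reads_u = unit_reads[u.unit_id]
        if not reads_u:
            flags.append((u.unit_id, "UNRESOLVED_NO_SFV_READS"))
            discrepancies.append(Discrepancy(a, "", "", UNRESOLVED))
            continue
        # long-read arbitration of columns the partition cannot split
        cur_sub, arb_disc = arbitrate_with_long_reads(
            sub, reads_u, lcounts, lins, min_depth, min_agree, offset=a
        )
        discrepancies.extend(arb_disc)
        # literal window re-derivation for representation-split stretches
        # inside the unit (global mapping starves the weaker copy, so this
        # is the only place such columns still see their own reads)
        cur_sub, win_disc = window_repair(cur_sub, reads_u, min_depth=min_depth)
        for d in win_disc:
            discrepancies.append(
                Discrepancy(a + d.position, d.nanopore_allele, d.illumina_allele, d.klass)
            )
        for _ in range(2):  # unit polish to convergence
            polished = polish_short(
                cur_sub, reads_u, min_depth=min_depth, min_agree=min_agree,
                clone_id=u.unit_id,
            )
            for d in polished.discrepancies:
                discrepancies.append(
                    Discrepancy(
                        a + d.position, d.nanopore_allele, d.illumina_allele, d.klass
                    )
                )
            n_edits = sum(1 for d in polished.discrepancies if d.klass != UNRESOLVED)
            cur_sub = polished.sequence
            if n_edits == 0:
                break
        new_units[u.unit_id] = cur_sub
        seq = seq[:a] + cur_sub + seq[b:]

    # --- junction re-validation with spanning long reads
    for u in units:
        for pos in u.interval:
            if pos <= 0 or pos >= len(seq_in):
                continue
            spanning = sum(
                1
                for a in lalns
                if a.t_interval[0] <= pos - 200 and a.t_interval[1] >= pos + 200
            )
            if spanning == 0:
                flags.append((u.unit_id, f"JUNCTION_UNSUPPORTED@{pos}"))

    discrepancies.sort(key=lambda d: d.position)
    support = base.support if len(seq) == len(seq_in) else {}
    return ConsensusAssembly(
        clone_id=base.clone_id,
        sequence=seq,
        support=support,
        discrepancies=discrepancies,
        rounds_applied=base.rounds_applied + 1,
        flags=flags,
    )
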