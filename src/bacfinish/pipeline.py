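"""End-to-end orchestration: pooled reads -> finished clone sequences.

Stages per clone: demultiplex the pooled long reads against the drafts,
classify full-length reads by vector anchoring, select and canonicalize a
backbone, polish with all binned long reads, correct residual errors to the
short-read consensus, and — when the polished consensus contains internal
repeats — resolve them unit by unit. Produces finished sequences, the
discrepancy log, run statistics and troubleshooting flags.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from . import consensus as cns
from . import demux as dmx
from . import fullread as flr
from . import qc
from . import repeats as rpt
from .simulate import CloneTruth, IlluminaReadPair, NanoporeRead

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Tunable parameters of the finishing pipeline (defaults are the
    desk-scale operating point; see docs/methods.md)."""

    margin_frac: float = 0.05
    end_window: int = 1000
    vector_min_identity: float = 0.75
    vector_min_len: int = 500
    polish_window: int = 500
    rounds_long: int = 2
    max_short_rounds: int = 3  # short polish iterates to convergence
    short_min_depth: int = 15
    short_min_agree: float = 0.9
    repeat_min_len: int = 2000
    # detection runs on a consensus that still carries residual error inside
    # under-covered repeat copies, so the threshold sits below the >=99%
    # identity that defines the underlying repeat family
    repeat_min_identity: float = 0.90
    resolve_repeats: bool = True


@dataclass
class CloneResult:
    clone_id: str
    assembly: cns.ConsensusAssembly | None
    full_calls: list = field(default_factory=list)
    n_reads: int = 0
    clone_length_estimate: int | None = None
    repeat_units: list = field(default_factory=list)
    sfvs: list = field(default_factory=list)
    error: str | None = None


@dataclass
class PipelineResult:
    clones: dict[str, CloneResult]
    demux: dmx.DemuxResult
    stats: qc.RunStats

    def finished(self) -> dict[str, str]:
        return {
            c: r.assembly.sequence
            for c, r in self.clones.items()
            if r.assembly is not None
        }


def _short_refine(
    sequence: str,
    clone_id: str,
    bin_reads,
    illumina_pairs,
    cfg: "PipelineConfig",
    all_disc: list,
    long_depth=None,
) -> cns.ConsensusAssembly:
    """Short-read refinement to convergence: column polish, then literal
    window re-derivation for representation-split stretches, then long-read
    arbitration of mixed-allele columns, each followed by re-polish."""
    cur = sequence
    assembly = None
    for _ in range(max(1, cfg.max_short_rounds)):
        assembly = cns.polish_short(
            cur,
            illumina_pairs,
            min_depth=cfg.short_min_depth,
            min_agree=cfg.short_min_agree,
            clone_id=clone_id,
            long_depth=long_depth,
            circular=True,
        )
        all_disc.extend(assembly.discrepancies)
        cur = assembly.sequence
        if not any(d.klass != cns.UNRESOLVED for d in assembly.discrepancies):
            break
    repaired, win_disc = cns.window_repair(
        cur,
        illumina_pairs,
        min_depth=cfg.short_min_depth,
        circular=True,
    )
    if win_disc:
        all_disc.extend(win_disc)
        assembly = cns.polish_short(
            repaired,
            illumina_pairs,
            min_depth=cfg.short_min_depth,
            min_agree=cfg.short_min_agree,
            clone_id=clone_id,
            circular=True,
        )
        all_disc.extend(assembly.discrepancies)
        cur = assembly.sequence
    long_pairs = [(r.read_id, r.bases) for r in bin_reads]
    lcounts, lins, _, _ = cns.map_and_pileup(
        cur, long_pairs, cns.LONG, min_identity=0.6,
        weight_by_identity=True, circular=True,
    )
    arbitrated, arb_disc = cns.arbitrate_with_long_reads(
        cur,
        cns.flatten_short_reads(illumina_pairs),
        lcounts,
        lins,
        cfg.short_min_depth,
        cfg.short_min_agree,
        circular=True,
    )
    if arb_disc:
        all_disc.extend(arb_disc)
        assembly = cns.polish_short(
            arbitrated,
            illumina_pairs,
            min_depth=cfg.short_min_depth,
            min_agree=cfg.short_min_agree,
            clone_id=clone_id,
            circular=True,
        )
        all_disc.extend(assembly.discrepancies)
    if assembly is None:
        assembly = cns.ConsensusAssembly(clone_id=clone_id, sequence=cur)
    return assembly


def finish_clone(
    clone_id: str,
    bin_reads: list[NanoporeRead],
    draft,
    vector: str,
    illumina_pairs: list[IlluminaReadPair],
    config: PipelineConfig | None = None,
) -> CloneResult:
    """Run the per-clone finishing stages on one demultiplexed read bin."""
    cfg = config or PipelineConfig()
    result = CloneResult(clone_id=clone_id, assembly=None, n_reads=len(bin_reads))
    if not bin_reads:
        result.error = "no reads"
        return result
    t0 = time.perf_counter()
    est = flr.estimate_clone_length([len(r) for r in bin_reads])
    result.clone_length_estimate = est
    calls = []
    for r in bin_reads:
        calls.append(
            flr.classify_full_length(
                r,
                vector,
                clone_length_estimate=est,
                end_window=cfg.end_window,
                min_identity=cfg.vector_min_identity,
                min_len=cfg.vector_min_len,
            )
        )
    result.full_calls = calls
    try:
        backbone = cns.select_backbone(calls, bin_reads, draft)
    except ValueError as exc:
        result.error = str(exc)
        return result
    polished, info = cns.polish_long(
        backbone.bases,
        bin_reads,
        window=cfg.polish_window,
        rounds=cfg.rounds_long,
    )
    all_disc: list = []
    assembly = _short_refine(
        polished, clone_id, bin_reads, illumina_pairs, cfg, all_disc,
        long_depth=info.get("long_depth"),
    )
    # keep the full edit log across convergence rounds (UNRESOLVED entries
    # deduplicated by position, last round wins)
    seen: dict[int, cns.Discrepancy] = {}
    for d in all_disc:
        seen[d.position] = d
    assembly.discrepancies = sorted(seen.values(), key=lambda d: d.position)
    assembly.rounds_applied = cfg.rounds_long + cfg.max_short_rounds
    if cfg.resolve_repeats and len(assembly.sequence) >= 2 * cfg.repeat_min_len:
        # the resolution round is iterated: the first pass has few trusted
        # SFV columns (the blurred consensus hides most true differences),
        # so its read partition is weak; once the copies are partially
        # resolved, the second pass sees a much richer variant set and can
        # phase reads across stretches the first pass could not split
        for _ in range(2):
            units = rpt.detect_self_repeats(
                assembly.sequence,
                min_len=cfg.repeat_min_len,
                min_identity=cfg.repeat_min_identity,
            )
            if not units:
                break
            sfvs = rpt.call_sfvs(
                units,
                assembly.sequence,
                illumina_pairs,
                min_depth=cfg.short_min_depth,
                min_agree=cfg.short_min_agree,
            )
            before = assembly.sequence
            assembly = rpt.finish_repetitive(
                assembly,
                units,
                sfvs,
                bin_reads,
                illumina_pairs,
                min_depth=cfg.short_min_depth,
                min_agree=cfg.short_min_agree,
            )
            result.repeat_units = units
            result.sfvs = sfvs
            # a full refinement cleans up after the merge: contested
            # columns can only become visible once the units are back in
            # place, and best-hit mapping cannot undo resolved SFVs (reads
            # support the allele now in place). Long-read arbitration only
            # trusts molecules long enough to extend beyond the repeat
            # array (shorter ones sit in either copy arbitrarily).
            span_w = 0
            by_group: dict[int, list] = {}
            for u in units:
                by_group.setdefault(u.paralog_group, []).append(u)
            for gunits in by_group.values():
                w = max(u.interval[1] for u in gunits) - min(
                    u.interval[0] for u in gunits
                )
                span_w = max(span_w, w)
            anchored = [r for r in bin_reads if len(r.bases) >= span_w + 600]
            if len(anchored) < 5:
                anchored = bin_reads
            post_disc = list(assembly.discrepancies)
            final = _short_refine(
                assembly.sequence, clone_id, anchored, illumina_pairs, cfg,
                post_disc,
            )
            final.discrepancies = sorted(post_disc, key=lambda d: d.position)
            final.flags = assembly.flags
            final.rounds_applied = assembly.rounds_applied + 1
            assembly = final
            if assembly.sequence == before:
                break
    assembly = cns.reanchor_to_vector(assembly, vector)
    result.assembly = assembly
    logger.info(
        "clone %s: %d reads, %d full-length, %d discrepancies, %.1fs",
        clone_id,
        len(bin_reads),
        sum(1 for c in calls if c.status == flr.FULL_VECTOR_ANCHORED),
        len(assembly.discrepancies),
        time.perf_counter() - t0,
    )
    return result


def run_all(
    drafts: dict[str, list[tuple[str, str]] | str],
    vector: str,
    nanopore_reads: list[NanoporeRead],
    illumina_by_clone: dict[str, list[IlluminaReadPair]],
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """The full pipeline over a pooled run.

    ``drafts`` maps clone id to a draft sequence (or list of contig
    (name, seq) tuples); ``illumina_by_clone`` maps clone id to that clone's
    indexed short-read library.
    """
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()
    norm = {c: _contig_pairs(d, c) for c, d in drafts.items()}
    panel_drafts = {c: [s for _, s in pairs] for c, pairs in norm.items()}
    demux_result = dmx.demux_pool(
        nanopore_reads, panel_drafts, vector, margin_frac=cfg.margin_frac
    )
    logger.info(
        "demux: %d reads -> %d assigned, %d ambiguous, %d unassigned (%.1fs)",
        len(nanopore_reads),
        sum(len(b) for b in demux_result.bins.values()),
        len(demux_result.ambiguous),
        len(demux_result.unassigned),
        time.perf_counter() - t0,
    )
    clones: dict[str, CloneResult] = {}
    for clone_id, bin_reads in demux_result.bins.items():
        clones[clone_id] = finish_clone(
            clone_id,
            bin_reads,
            norm[clone_id],
            vector,
            illumina_by_clone.get(clone_id, []),
            cfg,
        )
    stats = build_stats(nanopore_reads, demux_result, clones)
    draft_lens = {c: sum(len(s) for s in seqs) for c, seqs in panel_drafts.items()}
    finished_lens = {
        c: len(r.assembly.sequence) for c, r in clones.items() if r.assembly
    }
    qc.flag_anomalies(stats, draft_lens, finished_lens)
    stats.flags.extend(demux_result.flags)
    return PipelineResult(clones=clones, demux=demux_result, stats=stats)


def _contig_pairs(draft, clone_id: str = "draft"):
    """Normalize a draft (str, list of str, list of (name, seq), or records
    with .id/.seq) into a list of (contig name, sequence) pairs."""
    if isinstance(draft, str):
        return [(clone_id, draft)]
    out = []
    for i, d in enumerate(draft):
        if isinstance(d, str):
            out.append((f"{clone_id}.ctg{i}" if len(draft) > 1 else clone_id, d))
        elif isinstance(d, tuple):
            out.append(d)
        else:
            out.append((d.id, d.seq))
    return out


def build_stats(
    reads: list[NanoporeRead],
    demux_result: dmx.DemuxResult,
    clones: dict[str, CloneResult],
) -> qc.RunStats:
    lengths = [len(r) for r in reads]
    stats = qc.RunStats(
        total_reads=len(reads),
        total_bases=int(sum(lengths)),
        read_n50=qc.compute_n50(lengths) if lengths else 0,
        n_ambiguous=len(demux_result.ambiguous),
        n_unassigned=len(demux_result.unassigned),
    )
    total = max(1, len(reads))
    for clone_id, bin_reads in demux_result.bins.items():
        cr = clones.get(clone_id)
        stats.per_clone[clone_id] = qc.PerCloneStats(
            reads=len(bin_reads),
            fraction=len(bin_reads) / total,
            full_length_count=sum(
                1
                for c in (cr.full_calls if cr else [])
                if c.status == flr.FULL_VECTOR_ANCHORED
            ),
            clone_length_estimate=cr.clone_length_estimate if cr else None,
        )
    return stats
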