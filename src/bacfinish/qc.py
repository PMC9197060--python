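"""Run-level statistics, troubleshooting flags, and overlap-based accuracy.

The flags mirror the wet-lab troubleshooting table for a pooled run: a
clone with no reads usually means its culture failed; a clone whose
finished sequence is much shorter than its draft suggests a deletion during
culture; a low fraction of full-length reads points at over-digestion or
shearing during library preparation. Accuracy of finished sequence is
estimated from the aligned overlaps between independently finished
neighboring clones in a tiling path, reported as differences per megabase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import LONG, ReferenceIndex, extend_align

NO_READS = "NO_READS"
SHORT_CLONE = "SHORT_CLONE"
LOW_LONG_FRACTION = "LOW_LONG_FRACTION"

GUIDANCE = {
    NO_READS: (
        "Clone culture failed: regrow and add to the next run, or replace "
        "the clone; also rule out bookkeeping errors (transposed digits, "
        "rotated plate, contamination from an adjacent well)."
    ),
    SHORT_CLONE: (
        "Deletion during culture: regrow the clone from the original "
        "culture or another library copy, and replace with the alternate "
        "clone; sequence toxic to the host may need long-range PCR."
    ),
    LOW_LONG_FRACTION: (
        "Low fraction of long reads: transposase treatment time too long "
        "(heat-inactivate promptly) or shearing during library prep (use "
        "wide-bore tips for all mixing and loading steps)."
    ),
}


@dataclass
class PerCloneStats:
    reads: int = 0
    fraction: float = 0.0
    full_length_count: int = 0
    clone_length_estimate: int | None = None


@dataclass
class RunStats:
    """Per-run and per-clone read statistics with troubleshooting flags."""

    total_reads: int = 0
    total_bases: int = 0
    read_n50: int = 0
    per_clone: dict[str, PerCloneStats] = field(default_factory=dict)
    n_ambiguous: int = 0
    n_unassigned: int = 0
    flags: list[tuple[str, str, str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "total_reads": self.total_reads,
            "total_bases": self.total_bases,
            "read_n50": self.read_n50,
            "n_ambiguous": self.n_ambiguous,
            "n_unassigned": self.n_unassigned,
            "per_clone": {
                c: {
                    "reads": s.reads,
                    "fraction": s.fraction,
                    "full_length_count": s.full_length_count,
                    "clone_length_estimate": s.clone_length_estimate,
                }
                for c, s in self.per_clone.items()
            },
            "flags": [list(f) for f in self.flags],
        }


def compute_n50(lengths) -> int:
    """Largest L such that reads of length >= L contain at least half of
    all bases."""
    arr = np.sort(np.asarray(list(lengths), dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("n50 of an empty length list is undefined")
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def flag_anomalies(
    stats: RunStats,
    drafts: dict[str, int] | None = None,
    finished: dict[str, int] | None = None,
    short_clone_frac: float = 0.9,
    min_full_length_frac: float = 0.001,
) -> list[tuple[str, str, str]]:
    """Troubleshooting flags from run statistics.

    ``drafts``/``finished`` map clone ids to sequence lengths. Flags are
    appended to ``stats.flags`` and returned.
    """
    flags: list[tuple[str, str, str]] = []
    for clone, s in stats.per_clone.items():
        if s.reads == 0:
            flags.append((clone, NO_READS, GUIDANCE[NO_READS]))
    if drafts and finished:
        for clone, flen in finished.items():
            dlen = drafts.get(clone)
            if dlen and flen < short_clone_frac * dlen:
                flags.append((clone, SHORT_CLONE, GUIDANCE[SHORT_CLONE]))
    if stats.total_reads:
        fl = sum(s.full_length_count for s in stats.per_clone.values())
        if fl / stats.total_reads < min_full_length_frac:
            flags.append(("*", LOW_LONG_FRACTION, GUIDANCE[LOW_LONG_FRACTION]))
    stats.flags.extend(flags)
    return flags


@dataclass
class OverlapReport:
    errors: int
    aligned_bases: int
    errors_per_mb: float
    identity: float
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]


def overlap_error_rate(
    finished_a: str,
    finished_b: str,
    min_overlap: int = 10_000,
    preset=LONG,
) -> OverlapReport | None:
    """Differences per megabase in the aligned overlap of two finished
    clones.

    The best overlap alignment between the two sequences is computed; each
    mismatch column and each indel event (a run of I or D of any length)
    counts as one difference. Returns None when no overlap of at least
    ``min_overlap`` aligned columns exists.
    """
    index = ReferenceIndex([("a", finished_a)], preset)
    chains = index.best_chains(finished_b)
    if not chains:
        return None
    aln = extend_align(finished_b, finished_a, chains[0], band=preset.band)
    if aln.n_columns < min_overlap:
        return None
    mismatches = sum(n for op, n in aln.cigar if op == "M") - aln.n_matches
    indel_events = sum(1 for op, _ in aln.cigar if op in "ID")
    errors = mismatches + indel_events
    return OverlapReport(
        errors=errors,
        aligned_bases=aln.n_columns,
        errors_per_mb=errors / aln.n_columns * 1e6,
        identity=aln.identity,
        interval_a=aln.t_interval,
        interval_b=aln.q_interval,
    )
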