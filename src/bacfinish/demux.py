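"""Barcode-free assignment of pooled nanopore reads to clones.

Reads are assigned by mapping against the per-clone draft assemblies: no
indexing or barcoding is needed because a long read carries enough unique
sequence to identify its clone of origin, even when two pooled clones share
a near-identical repeat. The decision rule is a relative score margin over
per-clone chain scores (the same quantity mapq-style confidence is derived
from in standard long-read mappers): the read is assigned to the top clone
iff (best - second) / best >= margin_frac, with a rescue for reads whose
best chain covers essentially the whole draft (full-length candidates with
a unique best clone).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import LONG, Preset, ReferenceIndex
from .simulate import NanoporeRead

UNASSIGNED = "UNASSIGNED"
AMBIGUOUS = "AMBIGUOUS"

# troubleshooting guidance surfaced with zero-read clones
NO_READS_GUIDANCE = (
    "Clone culture failed: regrow and add to the next run, or replace the "
    "clone with another; also check for bookkeeping errors (transposed "
    "digits, rotated plate, contamination from an adjacent well)."
)


@dataclass
class ReadAssignment:
    """Outcome of assigning one pooled read to a clone."""

    read_id: str
    clone_id: str  # clone id, or UNASSIGNED / AMBIGUOUS
    best_score: int = 0
    margin: int = 0  # best - second best clone score, >= 0
    is_full_length_eligible: bool = False

    @property
    def assigned(self) -> bool:
        return self.clone_id not in (UNASSIGNED, AMBIGUOUS)


class DraftPanel:
    """Minimizer index over per-clone draft contigs.

    Contigs named ``{clone}.ctgN`` are grouped under their clone; a clone's
    score for a read is the sum over its contigs of the best chain score.
    The cloning vector, when provided, participates as a decoy target so
    vector-dominant reads are not forced onto a clone.
    """

    VECTOR = "__vector__"

    def __init__(self, drafts, vector: str | None = None, preset: Preset = LONG):
        refs = []
        self.contig_clone: dict[str, str] = {}
        self.clone_ids: list[str] = []
        self.draft_len: dict[str, int] = {}
        for name, seq in (drafts.items() if isinstance(drafts, dict) else drafts):
            if isinstance(seq, list):  # clone -> list of contig sequences
                for i, s in enumerate(seq):
                    cname = f"{name}.ctg{i}" if len(seq) > 1 else name
                    refs.append((cname, s))
                    self.contig_clone[cname] = name
                    self.draft_len[name] = self.draft_len.get(name, 0) + len(s)
            else:
                clone = name.split(".ctg")[0]
                refs.append((name, seq))
                self.contig_clone[name] = clone
                self.draft_len[clone] = self.draft_len.get(clone, 0) + len(seq)
        if not refs:
            raise ValueError("drafts must be non-empty")
        for c in self.contig_clone.values():
            if c not in self.clone_ids:
                self.clone_ids.append(c)
        if vector:
            refs.append((self.VECTOR, vector))
            self.contig_clone[self.VECTOR] = self.VECTOR
        self.index = ReferenceIndex(refs, preset)

    def clone_scores(self, read_seq: str) -> dict[str, int]:
        best_per_contig: dict[str, int] = {}
        for ch in self.index.best_chains(read_seq):
            if ch.chain_score > best_per_contig.get(ch.target_id, 0):
                best_per_contig[ch.target_id] = ch.chain_score
        scores: dict[str, int] = {}
        for contig, s in best_per_contig.items():
            clone = self.contig_clone[contig]
            scores[clone] = scores.get(clone, 0) + s
        return scores


def assign_read(
    read: NanoporeRead,
    drafts=None,
    vector: str | None = None,
    margin_frac: float = 0.05,
    panel: DraftPanel | None = None,
) -> ReadAssignment:
    """Assign one read to a clone by the relative score-margin rule."""
    if not (0.0 <= margin_frac <= 0.5):
        raise ValueError("margin_frac must be in [0, 0.5]")
    if panel is None:
        panel = DraftPanel(drafts, vector)
    rid, bases = (read.read_id, read.bases) if hasattr(read, "read_id") else read
    scores = panel.clone_scores(bases)
    scores.pop(DraftPanel.VECTOR, None) if _vector_dominated(scores) else None
    if not scores or max(scores.values()) <= 0:
        return ReadAssignment(rid, UNASSIGNED)
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    best_clone, s1 = ranked[0]
    s2 = ranked[1][1] if len(ranked) > 1 else 0
    if best_clone == DraftPanel.VECTOR:
        return ReadAssignment(rid, UNASSIGNED, s1, s1 - s2)
    eligible = s1 >= 0.8 * panel.draft_len.get(best_clone, 1 << 62)
    margin = s1 - s2
    if (s1 - s2) / s1 >= margin_frac or (eligible and margin > 0):
        return ReadAssignment(rid, best_clone, s1, margin, eligible)
    return ReadAssignment(rid, AMBIGUOUS, s1, margin, eligible)


def _vector_dominated(scores: dict[str, int]) -> bool:
    v = scores.get(DraftPanel.VECTOR, 0)
    others = [s for c, s in scores.items() if c != DraftPanel.VECTOR]
    return bool(others) and v > 0 and v < max(others)


@dataclass
class DemuxResult:
    bins: dict[str, list[NanoporeRead]]
    assignments: list[ReadAssignment]
    ambiguous: list[NanoporeRead] = field(default_factory=list)
    unassigned: list[NanoporeRead] = field(default_factory=list)
    flags: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def fractions(self) -> dict[str, float]:
        total = max(1, len(self.assignments))
        return {c: len(rs) / total for c, rs in self.bins.items()}

    def counts(self) -> dict[str, int]:
        return {c: len(rs) for c, rs in self.bins.items()}


def demux_pool(
    reads: list[NanoporeRead],
    drafts,
    vector: str | None = None,
    margin_frac: float = 0.05,
    panel: DraftPanel | None = None,
) -> DemuxResult:
    """Demultiplex a pooled run into per-clone read bins.

    Every read lands in exactly one place (a clone bin, the shared ambiguous
    overflow, or unassigned). Clones with zero reads are flagged with the
    troubleshooting guidance for a failed culture; an empty bin is a
    reportable state, not an error.
    """
    if panel is None:
        panel = DraftPanel(drafts, vector)
    bins: dict[str, list[NanoporeRead]] = {c: [] for c in panel.clone_ids}
    result = DemuxResult(bins=bins, assignments=[])
    for read in reads:
        a = assign_read(read, margin_frac=margin_frac, panel=panel)
        result.assignments.append(a)
        if a.clone_id == UNASSIGNED:
            result.unassigned.append(read)
        elif a.clone_id == AMBIGUOUS:
            result.ambiguous.append(read)
        else:
            bins[a.clone_id].append(read)
    for clone, rs in bins.items():
        if not rs:
            result.flags.append((clone, "NO_READS", NO_READS_GUIDANCE))
    return result
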