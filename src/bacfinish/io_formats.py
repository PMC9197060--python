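"""FASTA/FASTQ/SAM text I/O and the CIGAR operation-limit workaround.

Readers are gzip-transparent and accept CRLF input; writers emit LF with a
canonical layout (80-column FASTA wrap), so write(read(x)) is byte-stable
for canonical input. Malformed records raise :class:`FormatError` with the
offending line number.

``split_alignment`` implements the compatibility workaround for downstream
tools bounded by the BAM limit of 65535 CIGAR operations: alignments are cut
into uniquely named, independently valid sub-alignments every 1000 match
operations (expanded M columns), so that ultra-long noisy read alignments
survive SAM -> BAM conversion.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from . import seq as sq
from .align import Alignment

MAX_BAM_OPS = 65535


class FormatError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class FastaRecord:
    id: str
    seq: str
    description: str = ""


@dataclass
class FastqRecord:
    id: str
    seq: str
    qual: str
    description: str = ""


def _open_text(source, mode: str = "rt"):
    """Open a path (gzip-transparent) or pass a file object through."""
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    p = Path(source)
    if "r" in mode:
        with open(p, "rb") as probe:
            magic = probe.read(2)
        if magic == b"\x1f\x8b":
            return gzip.open(p, mode), True
    elif str(p).endswith(".gz"):
        return gzip.open(p, mode), True
    return open(p, mode), True


def read_fasta(source) -> list[FastaRecord]:
    """Parse FASTA (wrapped or unwrapped, CRLF tolerated)."""
    fh, own = _open_text(source)
    records: list[FastaRecord] = []
    name = None
    desc = ""
    chunks: list[str] = []
    start_line = 0
    try:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    if not chunks:
                        raise FormatError(f"record {name!r} has an empty sequence", start_line)
                    records.append(FastaRecord(name, "".join(chunks), desc))
                head = line[1:].split(None, 1)
                if not head:
                    raise FormatError("empty FASTA header", ln)
                name = head[0]
                desc = head[1] if len(head) > 1 else ""
                chunks = []
                start_line = ln
            else:
                if name is None:
                    raise FormatError("sequence data before any FASTA header", ln)
                chunks.append(line)
        if name is not None:
            if not chunks:
                raise FormatError(f"record {name!r} has an empty sequence", start_line)
            records.append(FastaRecord(name, "".join(chunks), desc))
        if not records:
            raise FormatError("no FASTA records found", 0)
    finally:
        if own:
            fh.close()
    return records


def write_fasta(records: Iterable[FastaRecord | tuple], dest, width: int = 80) -> None:
    fh, own = _open_text(dest, "wt")
    try:
        for rec in records:
            if isinstance(rec, tuple):
                rec = FastaRecord(rec[0], rec[1])
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            s = rec.seq
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")
    finally:
        if own:
            fh.close()


def read_fastq(source) -> list[FastqRecord]:
    fh, own = _open_text(source)
    try:
        lines = [l.rstrip("\r\n") for l in fh]
    finally:
        if own:
            fh.close()
    lines = [l for l in lines if l != ""]
    if len(lines) % 4:
        raise FormatError("FASTQ record count is not a multiple of 4", len(lines))
    records: list[FastqRecord] = []
    for i in range(0, len(lines), 4):
        ln = i + 1
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError("expected '@' header", ln)
        if not plus.startswith("+"):
            raise FormatError("expected '+' separator", ln + 2)
        if not seq:
            raise FormatError("empty sequence", ln + 1)
        if len(qual) != len(seq):
            raise FormatError("quality length differs from sequence length", ln + 3)
        fields = head[1:].split(None, 1)
        records.append(
            FastqRecord(fields[0], seq, qual, fields[1] if len(fields) > 1 else "")
        )
    return records


def write_fastq(records: Iterable[FastqRecord], dest) -> None:
    fh, own = _open_text(dest, "wt")
    try:
        for rec in records:
            header = f"@{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(f"{header}\n{rec.seq}\n+\n{rec.qual}\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# SAM

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_REVERSE = 0x10
FLAG_UNMAPPED = 0x4


@dataclass
class SamRecord:
    """A single SAM alignment line (SAM v1; 1-based POS)."""

    qname: str
    flag: int
    rname: str
    pos: int
    mapq: int
    cigar: list[tuple[str, int]]  # [(op, count)]
    seq: str
    qual: str = "*"
    rnext: str = "*"
    pnext: int = 0
    tlen: int = 0
    tags: dict = field(default_factory=dict)

    @property
    def is_mapped(self) -> bool:
        return not (self.flag & FLAG_UNMAPPED) and self.rname != "*" and bool(self.cigar)

    def cigar_string(self) -> str:
        if not self.cigar:
            return "*"
        return "".join(f"{n}{op}" for op, n in self.cigar)

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in "MIS=X")

    def target_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in "MDN=X")

    def n_elements(self) -> int:
        return len(self.cigar)


def parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*":
        return []
    out = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise FormatError(f"malformed CIGAR {text!r}")
        out.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text):
        raise FormatError(f"malformed CIGAR {text!r}")
    return out


def _format_tag(key: str, val) -> str:
    if isinstance(val, int):
        return f"{key}:i:{val}"
    if isinstance(val, float):
        return f"{key}:f:{val}"
    return f"{key}:Z:{val}"


def read_sam(source) -> tuple[list[str], list[SamRecord]]:
    """Returns (header lines, records)."""
    fh, own = _open_text(source)
    header: list[str] = []
    records: list[SamRecord] = []
    try:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line:
                continue
            if line.startswith("@"):
                header.append(line)
                continue
            f = line.split("\t")
            if len(f) < 11:
                raise FormatError("SAM line has fewer than 11 fields", ln)
            tags = {}
            for t in f[11:]:
                parts = t.split(":", 2)
                if len(parts) != 3:
                    raise FormatError(f"malformed tag {t!r}", ln)
                key, typ, val = parts
                tags[key] = int(val) if typ == "i" else float(val) if typ == "f" else val
            records.append(
                SamRecord(
                    qname=f[0],
                    flag=int(f[1]),
                    rname=f[2],
                    pos=int(f[3]),
                    mapq=int(f[4]),
                    cigar=parse_cigar(f[5]),
                    rnext=f[6],
                    pnext=int(f[7]),
                    tlen=int(f[8]),
                    seq=f[9],
                    qual=f[10],
                    tags=tags,
                )
            )
    finally:
        if own:
            fh.close()
    return header, records


def write_sam(header: list[str], records: Iterable[SamRecord], dest) -> None:
    fh, own = _open_text(dest, "wt")
    try:
        for line in header:
            fh.write(line + "\n")
        for r in records:
            fields = [
                r.qname,
                str(r.flag),
                r.rname,
                str(r.pos),
                str(r.mapq),
                r.cigar_string(),
                r.rnext,
                str(r.pnext),
                str(r.tlen),
                r.seq if r.seq else "*",
                r.qual if r.qual else "*",
            ]
            fields.extend(_format_tag(k, v) for k, v in sorted(r.tags.items()))
            fh.write("\t".join(fields) + "\n")
    finally:
        if own:
            fh.close()


def sam_header(references: Iterable[tuple[str, int]]) -> list[str]:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, length in references:
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    return lines


def alignment_to_sam(aln: Alignment, query_seq: str, qual: str | None = None) -> SamRecord:
    """Convert an internal alignment (0-based half-open) to a SAM record.

    Minus-strand alignments set flag 0x10 and store the reverse-complemented
    query, as SAM requires; soft clips are preserved.
    """
    flag = FLAG_REVERSE if aln.strand == "-" else 0
    seq = query_seq if aln.strand == "+" else sq.revcomp(query_seq)
    if qual is not None and aln.strand == "-":
        qual = qual[::-1]
    return SamRecord(
        qname=aln.query_id,
        flag=flag,
        rname=aln.target_id,
        pos=aln.t_interval[0] + 1,
        mapq=3 if aln.low_confidence else 60,
        cigar=list(aln.cigar),
        seq=seq,
        qual=qual or "*",
        tags={"AS": aln.score, "NM": aln.n_columns - aln.n_matches},
    )


def sam_to_alignment(rec: SamRecord) -> Alignment:
    """Inverse of :func:`alignment_to_sam` (identity/score from tags)."""
    if not rec.is_mapped:
        raise ValueError(f"record {rec.qname!r} is unmapped")
    strand = "-" if rec.flag & FLAG_REVERSE else "+"
    qlen = rec.query_consumed()
    lead = rec.cigar[0][1] if rec.cigar and rec.cigar[0][0] == "S" else 0
    tail = rec.cigar[-1][1] if rec.cigar and rec.cigar[-1][0] == "S" else 0
    q0, q1 = lead, qlen - tail
    if strand == "-":
        q0, q1 = qlen - q1, qlen - q0
    ncols = sum(n for op, n in rec.cigar if op in "MID=X")
    nm = rec.tags.get("NM", 0)
    return Alignment(
        query_id=rec.qname,
        target_id=rec.rname,
        strand=strand,
        q_interval=(q0, q1),
        t_interval=(rec.pos - 1, rec.pos - 1 + rec.target_consumed()),
        cigar=list(rec.cigar),
        score=rec.tags.get("AS", 0),
        identity=(ncols - nm) / ncols if ncols else 0.0,
        n_matches=ncols - nm,
        n_columns=ncols,
        query_length=qlen,
    )


def split_alignment(
    record: SamRecord,
    match_ops_per_chunk: int = 1000,
    count_elements: bool = False,
    max_elements: int = 60_000,
) -> list[SamRecord]:
    """Cut a mapped record into sub-records every ``match_ops_per_chunk``
    match operations, each independently valid and below the 65535-operation
    BAM bound.

    Match operations are counted as expanded M columns by default (a 1500M
    element holds 1500 match operations); with ``count_elements`` the count
    is of M CIGAR elements instead. A chunk is also closed when it reaches
    ``max_elements`` CIGAR elements, which keeps pathological indel-dense
    CIGARs below the BAM bound regardless of match content. Boundaries never
    fall inside an I or D element: an element belongs wholly to the chunk
    where it begins. Sub-records are named ``{qname}.p0001`` ... (zero-padded
    for stable lexicographic order) and carry recomputed POS and soft clips
    so that their aligned columns concatenate exactly to the original's.
    Unmapped records pass through unchanged.
    """
    if not record.is_mapped:
        return [record]
    if max_elements >= MAX_BAM_OPS:
        raise ValueError(f"max_elements must stay below {MAX_BAM_OPS}")
    qlen = record.query_consumed()

    # strip existing clips; they are re-derived per chunk
    core = list(record.cigar)
    lead_clip = 0
    if core and core[0][0] == "S":
        lead_clip = core[0][1]
        core = core[1:]
    if core and core[-1][0] == "S":
        core = core[:-1]

    chunks: list[list[tuple[str, int]]] = []
    cur: list[tuple[str, int]] = []
    m_count = 0
    n_el = 0
    for op, n in core:
        while n > 0:
            if op in "M=X" and not count_elements:
                room = match_ops_per_chunk - m_count
                take = min(n, max(room, 0))
                if take > 0:
                    cur.append((op, take))
                    n_el += 1
                    m_count += take
                    n -= take
            else:
                cur.append((op, n))
                n_el += 1
                if op in "M=X":
                    m_count += 1
                n = 0
            if (
                m_count >= match_ops_per_chunk and any(o in "M=X" for o, _ in cur)
            ) or n_el >= max_elements:
                chunks.append(cur)
                cur = []
                m_count = 0
                n_el = 0
    if cur:
        chunks.append(cur)
    if (
        len(chunks) > 1
        and not any(o in "M=X" for o, _ in chunks[-1])
        and len(chunks[-2]) + len(chunks[-1]) <= max_elements
    ):
        # fold a trailing matchless chunk into its predecessor
        chunks[-2].extend(chunks.pop())
    if len(chunks) <= 1:
        return [record]

    out: list[SamRecord] = []
    q_off = lead_clip
    t_off = 0
    for i, chunk in enumerate(chunks):
        merged: list[tuple[str, int]] = []
        for op, n in chunk:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n)
            else:
                merged.append((op, n))
        q_used = sum(n for op, n in merged if op in "MIS=X")
        t_used = sum(n for op, n in merged if op in "MDN=X")
        cig = list(merged)
        if q_off > 0:
            cig.insert(0, ("S", q_off))
        tail = qlen - q_off - q_used
        if tail > 0:
            cig.append(("S", tail))
        out.append(
            replace(
                record,
                qname=f"{record.qname}.p{i + 1:04d}",
                pos=record.pos + t_off,
                cigar=cig,
                tags=dict(record.tags),
            )
        )
        q_off += q_used
        t_off += t_used
    return out


def merge_split(sub_records: list[SamRecord]) -> SamRecord:
    """Reconstruct the original record from ``split_alignment`` output.

    Sub-records may arrive in any order; they must share a base qname and be
    contiguous in both query and target (a gap or overlap is rejected)."""
    if not sub_records:
        raise ValueError("no sub-records to merge")
    if len(sub_records) == 1:
        r = sub_records[0]
        base = re.sub(r"\.p\d{4}$", "", r.qname)
        return replace(r, qname=base) if base != r.qname else r
    keyed = []
    for r in sub_records:
        m = re.search(r"\.p(\d{4})$", r.qname)
        if not m:
            raise ValueError(f"{r.qname!r} lacks a .pNNNN split suffix")
        keyed.append((int(m.group(1)), r))
    keyed.sort(key=lambda kr: kr[0])
    base = re.sub(r"\.p\d{4}$", "", keyed[0][1].qname)
    first = keyed[0][1]
    q_cursor = first.cigar[0][1] if first.cigar[0][0] == "S" else 0
    t_cursor = first.pos - 1
    merged: list[tuple[str, int]] = []
    lead_clip = q_cursor
    for _, r in keyed:
        if re.sub(r"\.p\d{4}$", "", r.qname) != base:
            raise ValueError("sub-records come from different reads")
        cig = list(r.cigar)
        lead = cig[0][1] if cig and cig[0][0] == "S" else 0
        if cig and cig[0][0] == "S":
            cig = cig[1:]
        if cig and cig[-1][0] == "S":
            cig = cig[:-1]
        if lead != q_cursor or (r.pos - 1) != t_cursor:
            raise ValueError("sub-records are not contiguous (gap or overlap)")
        for op, n in cig:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + n)
            else:
                merged.append((op, n))
        q_cursor += sum(n for op, n in cig if op in "MIS=X")
        t_cursor += sum(n for op, n in cig if op in "MDN=X")
    qlen = first.query_consumed()
    cig = merged
    if lead_clip:
        cig = [("S", lead_clip)] + cig
    tail = qlen - q_cursor
    if tail > 0:
        cig = cig + [("S", tail)]
    return replace(first, qname=base, pos=keyed[0][1].pos, cigar=cig)
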