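"""Synthetic clone pools with ground truth.

Emulates the raw materials of a pooled clone-finishing run: circular
large-insert clones (cloning vector + insert), optional internal repeat
structure (tandem arrays or palindrome arms of >=99% identity distinguished
by planted sequence family variants), single-cut full-length nanopore reads
with indel-rich errors concentrated at homopolymer runs, deep accurate
paired short reads, and degraded per-clone draft assemblies with collapsed
repeats. Every downstream stage of the pipeline is testable against the
truth objects produced here.

Randomness: each operation takes a single integer seed and splits it into
per-object child streams (``numpy.random.SeedSequence.spawn``), so e.g.
increasing ``n_reads`` extends the read list without perturbing earlier
reads, and clone generation is independent of read simulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import seq as sq

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class RepeatUnitTruth:
    interval: tuple[int, int]  # 0-based half-open on the clone sequence
    group: int
    orientation: str  # 'direct' | 'inverted'


@dataclass(frozen=True)
class SfvSite:
    unit_index: int
    offset: int  # within the unit, in unit-local (direct) orientation
    allele: str  # the private base of this unit at that column


@dataclass
class CloneTruth:
    """A simulated circular clone: vector first, then insert.

    The stored ``sequence`` is the canonical linearization starting at the
    vector; the molecule itself is circular.
    """

    clone_id: str
    sequence: str
    vector_interval: tuple[int, int]
    repeat_units: list[RepeatUnitTruth] = field(default_factory=list)
    sfv_sites: list[SfvSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def vector(self) -> str:
        a, b = self.vector_interval
        return self.sequence[a:b]

    @property
    def insert(self) -> str:
        return self.sequence[self.vector_interval[1]:]


@dataclass(frozen=True)
class ReadTruth:
    clone_id: str
    cut_position: int
    strand: str
    truncated: bool


@dataclass
class NanoporeRead:
    read_id: str
    bases: str
    truth: ReadTruth | None = None

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PairTruth:
    clone_id: str
    fragment_interval: tuple[int, int]  # may wrap past the origin (mod length)


@dataclass
class IlluminaReadPair:
    read_id: str
    bases1: str
    bases2: str
    truth: PairTruth | None = None


@dataclass(frozen=True)
class RepeatSpec:
    """Internal repeat structure of a clone insert."""

    n_units: int = 0
    unit_len: int = 2000
    unit_identity: float = 0.995
    arrangement: str = "tandem"  # 'tandem' | 'palindrome' | 'none'

    def __post_init__(self):
        if self.n_units >= 2:
            if not (0.99 <= self.unit_identity < 1.0):
                raise ValueError("unit_identity must be in [0.99, 1.0)")
            if self.arrangement not in ("tandem", "palindrome"):
                raise ValueError(f"unknown arrangement {self.arrangement!r}")


@dataclass(frozen=True)
class ErrorModel:
    """Per-base nanopore error rates; indel rates are multiplied inside
    homopolymer runs of length >= 3."""

    sub: float = 0.04
    ins: float = 0.03
    dele: float = 0.03
    homopolymer_indel_multiplier: float = 6.0

    def __post_init__(self):
        for r in (self.sub, self.ins, self.dele):
            if not (0.0 <= r < 1.0):
                raise ValueError("error rates must be in [0, 1)")


@dataclass(frozen=True)
class LengthModel:
    """Truncated (non-full-length) read length model: exponential tail."""

    mean_truncated: float = 6000.0


# ---------------------------------------------------------------------------
# helpers


def _random_codes(n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def make_vector(length: int, seed: int) -> str:
    """The cloning backbone shared by all clones of a library."""
    if length < 2000:
        raise ValueError("vector length must be >= 2 kb")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return sq.decode(_random_codes(length, rng))


def _build_repeat_region(
    spec: RepeatSpec, sfv_per_unit: int, rng: np.random.Generator
):
    """Construct unit sequences from one template.

    Each unit receives ``floor(unit_len*(1-identity)/2) - sfv_per_unit``
    private background substitutions plus ``sfv_per_unit`` SFVs at offsets
    unique across units, guaranteeing pairwise identity >= unit_identity and
    global distinguishability of every unit.
    """
    L = spec.unit_len
    n = spec.n_units
    template = _random_codes(L, rng)
    n_bg = max(0, int(L * (1.0 - spec.unit_identity) / 2.0) - sfv_per_unit)
    need = n * (n_bg + sfv_per_unit)
    if need > L:
        raise ValueError("unit too short for requested divergence")
    all_pos = rng.choice(L, size=need, replace=False)
    units = []
    sfv_sites: list[SfvSite] = []
    idx = 0
    for u in range(n):
        codes = template.copy()
        for _ in range(n_bg):
            p = all_pos[idx]
            idx += 1
            codes[p] = (codes[p] + rng.integers(1, 4)) % 4
        for _ in range(sfv_per_unit):
            p = all_pos[idx]
            idx += 1
            codes[p] = (template[p] + rng.integers(1, 4)) % 4
            sfv_sites.append(SfvSite(u, int(p), _BASES[codes[p]]))
        units.append(codes)
    return units, sfv_sites


def _layout_units(units: list[np.ndarray], arrangement: str):
    """Concatenate unit sequences; palindromes invert the second half
    (mirror order), tandems are direct repeats."""
    n = len(units)
    laid = []
    orientations = []
    if arrangement == "palindrome":
        n_fwd = (n + 1) // 2
        for u in range(n_fwd):
            laid.append(units[u])
            orientations.append("direct")
        for u in range(n - 1, n_fwd - 1, -1):
            laid.append(sq.revcomp_codes(units[u]))
            orientations.append("inverted")
    else:
        for u in range(n):
            laid.append(units[u])
            orientations.append("direct")
    return laid, orientations


def _make_clone(
    clone_id: str,
    vector: str,
    insert_len: int,
    repeat_spec: RepeatSpec | None,
    sfv_per_unit: int,
    rng: np.random.Generator,
) -> CloneTruth:
    vlen = len(vector)
    insert = _random_codes(insert_len, rng)
    repeat_units: list[RepeatUnitTruth] = []
    sfv_sites: list[SfvSite] = []
    if repeat_spec is not None and repeat_spec.n_units >= 2:
        region_len = repeat_spec.n_units * repeat_spec.unit_len
        if region_len > insert_len:
            raise ValueError("unit_len * n_units exceeds the insert length")
        units, sfv_sites = _build_repeat_region(repeat_spec, sfv_per_unit, rng)
        laid, orientations = _layout_units(units, repeat_spec.arrangement)
        margin = min(1000, max(0, (insert_len - region_len) // 4))
        lo = margin
        hi = insert_len - region_len - margin
        start = int(rng.integers(lo, max(lo + 1, hi + 1)))
        pos = start
        for u, (codes, ori) in enumerate(zip(laid, orientations)):
            insert[pos : pos + len(codes)] = codes
            repeat_units.append(
                RepeatUnitTruth(
                    interval=(vlen + pos, vlen + pos + len(codes)),
                    group=0,
                    orientation=ori,
                )
            )
            pos += len(codes)
    return CloneTruth(
        clone_id=clone_id,
        sequence=vector + sq.decode(insert),
        vector_interval=(0, vlen),
        repeat_units=repeat_units,
        sfv_sites=sfv_sites,
    )


# ---------------------------------------------------------------------------
# operations


def make_clone_pool(
    n_clones: int,
    vector_len: int = 3000,
    insert_len_range: tuple[int, int] = (35_000, 45_000),
    repeat_spec: RepeatSpec | None = None,
    sfv_per_unit: int = 2,
    seed: int = 0,
    allow_indistinguishable: bool = False,
) -> list[CloneTruth]:
    """Generate a pool of circular clones sharing one cloning vector.

    ``repeat_spec`` (if given) plants the same repeat structure in every
    clone; pass per-clone structure via :func:`make_tiling_pool` or by
    composing :func:`make_clone_pool` calls with distinct seeds.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if repeat_spec is not None and repeat_spec.n_units >= 2 and sfv_per_unit < 1:
        if not allow_indistinguishable:
            raise ValueError(
                "sfv_per_unit must be >= 1 when n_units >= 2: units would be "
                "indistinguishable by construction (pass "
                "allow_indistinguishable=True to override)"
            )
        warnings.warn("repeat units carry no SFVs and are indistinguishable")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_clones + 1)
    vec_rng = np.random.default_rng(children[0])
    vector = sq.decode(_random_codes(vector_len, vec_rng))
    if vector_len < 2000:
        raise ValueError("vector length must be >= 2 kb")
    pool = []
    for i in range(n_clones):
        rng = np.random.default_rng(children[i + 1])
        ilen = int(rng.integers(insert_len_range[0], insert_len_range[1] + 1))
        pool.append(
            _make_clone(f"clone{i:02d}", vector, ilen, repeat_spec, sfv_per_unit, rng)
        )
    return pool


def make_tiling_pool(
    n_clones: int,
    insert_len: int = 40_000,
    overlap_len: int = 12_000,
    vector_len: int = 3000,
    repeat_spec: RepeatSpec | None = None,
    repeat_overlap_index: int = 0,
    sfv_per_unit: int = 2,
    seed: int = 0,
) -> list[CloneTruth]:
    """Overlapping clones tiling one synthetic genomic region.

    Clone i carries region[i*step : i*step + insert_len] as its insert
    (step = insert_len - overlap_len), so consecutive finished clones share
    ``overlap_len`` of insert sequence — the overlap used for accuracy
    estimation. When ``repeat_spec`` is given, a repeat region is planted
    inside overlap ``repeat_overlap_index`` so that one clone pair shares it.
    """
    if n_clones < 2:
        raise ValueError("a tiling path needs >= 2 clones")
    if not (0 < overlap_len < insert_len):
        raise ValueError("overlap_len must be in (0, insert_len)")
    ss = np.random.SeedSequence(seed)
    ch = ss.spawn(3)
    vector = sq.decode(_random_codes(vector_len, np.random.default_rng(ch[0])))
    step = insert_len - overlap_len
    region_len = step * (n_clones - 1) + insert_len
    region = _random_codes(region_len, np.random.default_rng(ch[1]))

    region_units: list[tuple[int, int, str]] = []
    region_sfvs: list[SfvSite] = []
    if repeat_spec is not None and repeat_spec.n_units >= 2:
        rep_len = repeat_spec.n_units * repeat_spec.unit_len
        if rep_len > overlap_len:
            raise ValueError("repeat region does not fit in the overlap")
        rng = np.random.default_rng(ch[2])
        units, region_sfvs = _build_repeat_region(repeat_spec, sfv_per_unit, rng)
        laid, orientations = _layout_units(units, repeat_spec.arrangement)
        ov_start = step * (repeat_overlap_index + 1)
        start = ov_start + (overlap_len - rep_len) // 2
        pos = start
        for codes, ori in zip(laid, orientations):
            region[pos : pos + len(codes)] = codes
            region_units.append((pos, pos + len(codes), ori))
            pos += len(codes)

    pool = []
    region_s = sq.decode(region)
    for i in range(n_clones):
        a = i * step
        b = a + insert_len
        units = []
        sfvs = []
        for u, (us, ue, ori) in enumerate(region_units):
            if us >= a and ue <= b:
                units.append(
                    RepeatUnitTruth(
                        interval=(vector_len + us - a, vector_len + ue - a),
                        group=0,
                        orientation=ori,
                    )
                )
        if units:
            sfvs = list(region_sfvs)
        pool.append(
            CloneTruth(
                clone_id=f"clone{i:02d}",
                sequence=vector + region_s[a:b],
                vector_interval=(0, vector_len),
                repeat_units=units,
                sfv_sites=sfvs,
            )
        )
    return pool


def mutate_codes(
    codes: np.ndarray, em: ErrorModel, rng: np.random.Generator
) -> np.ndarray:
    """Apply substitution/indel noise; indel rates are boosted by the
    homopolymer multiplier inside runs of length >= 3."""
    n = codes.size
    if n == 0:
        return codes.copy()
    mult = np.ones(n)
    hp = sq.homopolymer_runs(codes, 3)
    mult[hp] = em.homopolymer_indel_multiplier
    del_p = np.minimum(em.dele * mult, 0.95)
    ins_p = np.minimum(em.ins * mult, 0.95)
    out = codes.copy()
    subs = rng.random(n) < em.sub
    if subs.any():
        out[subs] = (out[subs] + rng.integers(1, 4, size=int(subs.sum()))) % 4
    dels = rng.random(n) < del_p
    ins = rng.random(n) < ins_p
    kept = ~dels
    out = out[kept]
    if ins.any():
        ipos_orig = np.flatnonzero(ins)
        # position in the deletion-compacted array
        cum = np.cumsum(kept)
        ipos = cum[ipos_orig]  # insert after the (possibly deleted) base
        dup = rng.random(ipos_orig.size) < 0.5
        ibase = np.where(
            dup, codes[ipos_orig], rng.integers(0, 4, size=ipos_orig.size)
        ).astype(np.uint8)
        out = np.insert(out, ipos, ibase)
    return out


def simulate_nanopore_run(
    pool: list[CloneTruth],
    n_reads: int,
    p_single_cut: float = 0.2,
    error_model: ErrorModel | None = None,
    length_model: LengthModel | None = None,
    seed: int = 0,
) -> list[NanoporeRead]:
    """Nanopore reads from a pooled run over circular clones.

    Each read is drawn from a uniformly chosen clone. With probability
    ``p_single_cut`` the molecule is cut once at a uniform position and read
    full-length (either orientation); otherwise a truncated fragment with
    exponentially distributed length is emitted. Truth metadata (clone, cut
    position, strand, truncation) is recorded on each read and is never
    consumed by pipeline stages.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if not pool:
        raise ValueError("pool must be non-empty")
    em = error_model or ErrorModel()
    lm = length_model or LengthModel()
    ss = np.random.SeedSequence(seed)
    top = np.random.default_rng(ss.spawn(1)[0])
    clone_idx = top.integers(0, len(pool), size=n_reads)
    children = ss.spawn(n_reads + 1)[1:]
    codes_cache = {c.clone_id: sq.encode(c.sequence) for c in pool}
    reads = []
    for i in range(n_reads):
        rng = np.random.default_rng(children[i])
        clone = pool[int(clone_idx[i])]
        codes = codes_cache[clone.clone_id]
        clen = codes.size
        cut = int(rng.integers(0, clen))
        full = rng.random() < p_single_cut
        if full:
            frag = np.concatenate((codes[cut:], codes[:cut]))
            truncated = False
        else:
            ln = int(min(clen, 1 + rng.exponential(lm.mean_truncated)))
            end = cut + ln
            if end <= clen:
                frag = codes[cut:end]
            else:
                frag = np.concatenate((codes[cut:], codes[: end - clen]))
            truncated = True
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            frag = sq.revcomp_codes(frag)
        frag = mutate_codes(frag, em, rng)
        reads.append(
            NanoporeRead(
                read_id=f"np{i:06d}",
                bases=sq.decode(frag),
                truth=ReadTruth(clone.clone_id, cut, strand, truncated),
            )
        )
    return reads


def simulate_illumina(
    pool: list[CloneTruth],
    coverage: float = 50.0,
    read_len: int = 150,
    frag_len: int = 500,
    frag_sd: float = 50.0,
    sub_rate: float = 0.002,
    seed: int = 0,
) -> list[IlluminaReadPair]:
    """Paired short reads at the given fold coverage per clone.

    Fragments are uniform over each circular clone, pairs point inward, and
    errors are substitution-only — the accurate, deep dataset used for
    polishing. Pairs carry truth clone ids (per-clone libraries are
    individually indexed, so clone of origin is known input metadata).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if frag_len < 2 * read_len:
        raise ValueError("fragment length must exceed twice the read length")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(pool))
    pairs = []
    for ci, clone in enumerate(pool):
        rng = np.random.default_rng(children[ci])
        codes = sq.encode(clone.sequence)
        clen = codes.size
        n_pairs = int(round(coverage * clen / (2 * read_len)))
        starts = rng.integers(0, clen, size=n_pairs)
        flens = np.clip(
            rng.normal(frag_len, frag_sd, size=n_pairs).astype(np.int64),
            2 * read_len,
            None,
        )
        doubled = np.concatenate((codes, codes))
        for j in range(n_pairs):
            a = int(starts[j])
            fl = int(min(flens[j], clen))
            frag = doubled[a : a + fl]
            r1 = frag[:read_len].copy()
            r2 = sq.revcomp_codes(frag[-read_len:])
            for r in (r1, r2):
                errs = rng.random(read_len) < sub_rate
                if errs.any():
                    r[errs] = (r[errs] + rng.integers(1, 4, size=int(errs.sum()))) % 4
            pairs.append(
                IlluminaReadPair(
                    read_id=f"il_{clone.clone_id}_{j:06d}",
                    bases1=sq.decode(r1),
                    bases2=sq.decode(r2),
                    truth=PairTruth(clone.clone_id, (a, a + fl)),
                )
            )
    return pairs


def degrade_to_draft(
    clone: CloneTruth,
    collapse_repeats: bool = True,
    error_rate: float = 0.0,
    n_contig_breaks: int = 0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Degrade a truth clone into a draft-assembly stand-in.

    When ``collapse_repeats`` the paralogous units of each repeat group are
    merged into a single unit at their column-wise majority base (ties go to
    the lowest-index unit) — the hallmark failure mode of short-read
    assemblies of multi-copy inserts. Output contigs are linearized starting
    at the vector.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    codes = sq.encode(clone.sequence)
    if collapse_repeats and clone.repeat_units:
        groups: dict[int, list[RepeatUnitTruth]] = {}
        for u in clone.repeat_units:
            groups.setdefault(u.group, []).append(u)
        # process right-to-left so earlier intervals stay valid
        for g in sorted(groups, key=lambda g: -groups[g][0].interval[0]):
            units = sorted(groups[g], key=lambda u: u.interval[0])
            mats = []
            for u in units:
                a, b = u.interval
                c = codes[a:b]
                if u.orientation == "inverted":
                    c = sq.revcomp_codes(c)
                mats.append(c)
            width = min(len(m) for m in mats)
            stack = np.stack([m[:width] for m in mats])
            # column-wise majority, ties to the lowest-index unit
            maj = np.empty(width, dtype=np.uint8)
            for col in range(width):
                vals, counts = np.unique(stack[:, col], return_counts=True)
                best = counts.max()
                cands = set(vals[counts == best].tolist())
                for m in stack[:, col]:
                    if int(m) in cands:
                        maj[col] = m
                        break
            span_a = units[0].interval[0]
            span_b = units[-1].interval[1]
            codes = np.concatenate((codes[:span_a], maj, codes[span_b:]))
    if error_rate > 0:
        errs = rng.random(codes.size) < error_rate
        if errs.any():
            codes[errs] = (codes[errs] + rng.integers(1, 4, size=int(errs.sum()))) % 4
    n = codes.size
    if n_contig_breaks > 0:
        cuts = np.sort(rng.choice(np.arange(1, n), size=n_contig_breaks, replace=False))
        bounds = [0, *cuts.tolist(), n]
        return [
            (f"{clone.clone_id}.ctg{i}", sq.decode(codes[a:b]))
            for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]))
        ]
    return [(clone.clone_id, sq.decode(codes))]


def read_share(reads: list[NanoporeRead], pool: list[CloneTruth]) -> dict[str, float]:
    """Truth-based per-clone read fraction (simulation QC, not pipeline)."""
    counts = {c.clone_id: 0 for c in pool}
    for r in reads:
        if r.truth:
            counts[r.truth.clone_id] += 1
    n = max(1, len(reads))
    return {k: v / n for k, v in counts.items()}
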