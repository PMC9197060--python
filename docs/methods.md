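# Methods

This note documents the models, algorithms, parameters and design choices
behind `bacfinish`, in the order the pipeline applies them, together with
what the synthetic data does and does not emulate.

## The clone model and the synthetic pool

A clone is a circular molecule: cloning vector (default 3 kb, shared by
every clone of a library) followed by a unique insert. The canonical
linearization starts at vector base 0. Internal repeat structure is modeled
as `n_units` copies of a template unit, laid out as a direct tandem or as
palindrome arms (second half reverse-complemented, mirror order). Each copy
receives `floor(L·(1−identity)/2) − sfv_per_unit` private background
substitutions plus `sfv_per_unit` sequence family variants (SFVs) at
offsets unique across copies, which guarantees pairwise unit identity at or
above the requested level and makes every copy globally distinguishable.
With two or more units and `sfv_per_unit = 0` construction is refused
(units would be indistinguishable) unless explicitly overridden.

Nanopore reads: each read picks a clone uniformly. With probability
`p_single_cut` (default 0.2) the circle is cut once at a uniform position
and read full-length on a uniform strand; otherwise an exponential-length
fragment (mean 6 kb by default) is emitted. The truncated-length
distribution is a modeling choice — run-level length aggregates, not a
fragment model, are what pooled runs report. Errors are applied per base:
substitutions at `sub` (default 0.04) and insertions/deletions at
`ins`/`del` (default 0.03 each), with the indel rates multiplied by a
constant (default 6×) inside homopolymer runs of length ≥ 3; half of the
insertions duplicate the current base. Defaults give ~10% total error with
the error budget checked against a quadratic-DP oracle in the tests.

Illumina reads: uniform circular fragments (normal length, default
500 ± 50), inward-pointing 150 bp pairs, substitution-only errors (default
0.2%), at a fold coverage per clone (default 50×). Per-clone libraries are
individually indexed in practice, so the pipeline may group short reads by
clone of origin; nanopore truth metadata, in contrast, is carried only for
evaluation and never consumed by any pipeline stage.

Drafts: the truth sequence linearized vector-first, optionally with
substitution noise, contig breaks, and — the hallmark failure of
short-read assembly of multi-copy inserts — paralogous repeat units
collapsed to their column-wise majority.

Randomness: every generator takes one integer seed and splits it into
per-object child streams (`numpy.random.SeedSequence.spawn`), so extending
a read set never perturbs earlier reads or the clones.

What the simulation does *not* model: pore-current signal and basecalling,
quality-score realism, chimeric reads, host-cell contamination, coverage
biases, and clone-to-clone abundance imbalance beyond what uniform sampling
produces. Passing tests therefore demonstrate the computational pipeline
under idealized read delivery, not robustness to library artifacts.

## Alignment

All stages share one aligner: canonical (w,k)-minimizer seeding (k=15,
w=10 for long reads; k=21, w=1 for short reads), co-linear anchor chaining
by dynamic programming with bounded lookback and a diagonal-difference gap
cost, and banded affine-gap ("Gotoh") extension between anchors with end
extensions capped at ~1 kb (sequence beyond that belongs to another chain
arc — a full-length read maps against a linear reference as two arcs).
Scoring: match +1, mismatch −2, gap open −4, gap extend −2 (a gap of
length L costs 4 + 2L). When the band covers the full sequences the result
is exactly the unconstrained optimal global alignment, which the tests
verify against an independent quadratic DP.

Two details matter more than the asymptotics:

* **Indel left-alignment.** Equivalent-score gap placements (classically
  ambiguous inside homopolymer runs) are normalized to their leftmost
  position, so independent reads agree on where an indel sits — without
  this, insertion votes smear across junctions and no consensus threshold
  is ever reached.
* **Single-anchor extension for short reads.** Reads ≤ 600 bp are extended
  left and right from one anchor instead of stitching many segments;
  piecewise seams can split a compound indel into divergent
  representations across reads.

Equal-score alignments to different targets are both reported, so the
demultiplexer can see ambiguity. The assignment rule is a relative margin
on per-clone chain scores — the same quantity mapq-style confidence
derives from — with a rescue for reads whose best chain covers essentially
a whole draft. Reads failing the margin go to a shared ambiguous bin; a
read whose best target is the vector decoy is unassigned.

## Full-length identification and rotation

A read is FULL_VECTOR_ANCHORED when vector sequence lies within the first
and last 1 kb (`end_window`) of the read *and* the read is at least
`vector + 2·end_window` long — without the length guard, a vector-only
fragment trivially "starts and ends in vector". When one end shows a hit
flush with a vector boundary, the short complementary piece predicted by
circularity at the other end is searched for explicitly (down to ~25 bp;
below that, clone-length consistency decides). Reads without end anchoring
but within ±10% of the clone length estimate are PUTATIVE_FULL_BY_LENGTH;
they may serve as backbones only for clones not flagged internally
repetitive, because an unanchored rotation of a tandem array cannot be
trusted. The clone length estimate is the modal 1 kb bin of read lengths
above the 75th percentile (None below 20 reads or 3 modal reads).
Rotation reverse-complements first if the vector matched the minus strand,
then circularly shifts so vector base 0 leads; multiple well-separated
internal vector hits (vector–vector chimeras) are refused.

## Consensus and polishing

The backbone is the anchored full-length read with the highest identity to
the draft (ties to the smaller read id), falling back to the draft itself
when a clone has no full-length read. Long-read polishing maps all binned
reads to the backbone (both arcs of origin-crossing reads are used),
stacks identity-weighted votes per column plus insertion strings per
junction, and takes the weighted majority; two rounds by default. All
pileups treat the clone as circular (reads map against a circularly padded
reference; votes fold back), which keeps coverage flat across the
linearization origin.

Short-read correction then edits the sequence to the Illumina column
consensus wherever depth ≥ 15 and agreement ≥ 0.9: homopolymer runs ≥ 3
are edited as units (run length set from deletion columns and pure-base
insertion votes), other columns base by base, insertions judged on the
presence of an insertion (total votes against junction-*spanning* depth)
with the dominant string as content. Positions that differ but fail the
thresholds are logged UNRESOLVED and left alone. Three technical choices
proved necessary for convergence: alignments contribute to the pileup only
after trimming 25 aligned bases at each read end (a read cannot express an
indel next to its own end, so untrimmed ends dilute indel votes);
insertion denominators count only junction-spanning alignments; and the
pipeline repeats the short pass until no edits remain (up to 3 rounds) —
some edits only become visible after remapping to the edited sequence.
The converged sequence is a fixed point (tested).

Two residual failure modes of column-wise voting get dedicated repairs:

* **Window repair.** A compound difference (e.g. a base shifted between
  two nearby runs) admits several co-optimal alignment representations;
  reads split their votes and no single column reaches 0.9. Contested
  clusters are re-derived literally: every spanning read contributes its
  raw substring between clean flanking columns, and a clear modal string
  (≥ 60% of spanning reads, runner-up at most half of that) replaces the
  window. Genuine mixed-allele columns (~50/50) never reach the modal
  threshold.
* **Long-read arbitration.** Columns where the short reads split into two
  substantial camps (30–90% support) are decided by the long-read pileup
  majority (≥ 60%) — the long reads are placed by clone structure and
  cannot be confused between repeat copies. Inside a repeat clone only
  molecules long enough to extend beyond the repeat array count as
  structural evidence: a truncated read contained within the array maps to
  either copy arbitrarily and would pollute the per-copy pileup.

This refinement (polish to convergence, window repair, arbitration, each
followed by re-polish) runs once before repeat resolution and again after
unit merging, because some contested columns only become visible once the
units are back in place.

Finally the finished circle is re-anchored: the known vector is aligned to
the polished consensus and the sequence rotated so the vector starts at
base 0 exactly (a backbone rotation is only as precise as a noisy vector
alignment).

## Repeat resolution

Internal repeats are detected by self-alignment of the consensus: off-
diagonal plus-strand chains of period ≥ ~2 kb decompose into tandem units;
minus-strand self-hits yield palindrome arms. The pipeline's detection
identity threshold is 0.90 — deliberately below the ≥ 99% identity that
defines the underlying family — because the pre-resolution consensus
carries residual error concentrated inside under-covered copies, which
drives the *apparent* inter-unit identity down; chain score and span
already make false positives on non-repetitive sequence implausible.

Units are aligned pairwise to the leftmost copy; columns with differing
alleles and short-read support (depth ≥ 15, agreement ≥ 0.9 on at least
one unit) are emitted as SFVs; columns where the reads contradict every
unit allele are flagged as collapse artifacts and withheld; columns within
5 bp of a unit boundary are skipped (tandem decomposition is phase-
ambiguous there). Only SFVs with supported alleles on ≥ 2 units drive the
read partition — a one-sided column is a consensus error, not a variant.
Partition is fragment-level: either mate's alleles assign the whole pair
(a ~500 bp fragment reaches past locally featureless stretches);
uninformative pairs vote in every unit, where they can only support
columns on which the copies agree. Each unit is then polished with its
read set (with long-read arbitration and window repair for columns the
partition cannot split), units are re-inserted at their intervals — order
and orientation are fixed by construction, never reshuffled — junctions
are re-validated against spanning long reads, and the global refinement
runs again. The whole resolution round is iterated twice: the first pass
works with the few variant columns visible in the blurred consensus, and
once the copies are partially resolved the second pass sees a much richer
variant set and can phase reads over stretches the first could not split.
A planted allele swap between units is repaired by the arbitration step:
only the full-length molecules know which allele belongs to which copy.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| demux margin | 0.05 | relative chain-score margin for unique assignment |
| end_window | 1 kb | "starts and ends in vector" tolerance |
| vector hit identity / length | 0.75 / 500 bp | raw nanopore error tolerance |
| polish window | 500 bp | long-read consensus windowing |
| long rounds / short rounds | 2 / ≤3 (to convergence) | see above |
| short depth / agreement | 15 / 0.9 | edit thresholds for Illumina corrections |
| repeat unit min length | 2 kb (desk) | 10 kb at full scale; scale-free invariants |
| repeat detect identity | 0.90 | blurred-consensus regime (see above) |
| pileup end trim | 25 bp | reads cannot express indels at their own ends |
| homopolymer indel multiplier | 6× | qualitative statement made quantitative |

## Problem sizes

The package's own studies run at desk scale: clones of ~43 kb (3 kb vector
+ 40 kb insert), pools of 6 clones for end-to-end finishing (~60 reads per
clone at 10% error, 50× short reads) and 24 clones / 24,000 reads for
demultiplexing, with 2×2 kb tandem repeats at 99% identity standing in for
full-scale ≥ 10 kb amplicons. All identity and structure invariants are
scale-free; full-scale inserts are supported by the same code paths but
take proportionally longer.

## Known limitations

* The unit decomposition assumes a single period per tandem array and two
  arms per palindrome; nested or mixed repeat architectures are not
  decomposed.
* SFVs within ~5 bp of a unit boundary are not called (phase ambiguity);
  they are still corrected by the global polish when context allows.
* Long-read arbitration needs ≥ ~5 long reads spanning a contested
  position; very under-represented clones fall back to UNRESOLVED flags.
* The simulator's idealizations (uniform coverage, no chimeras, no
  abundance imbalance) mean real pools will exercise the troubleshooting
  flags more often than the tests do.
* Reads shorter than ~2 consecutive minimizer windows (a few hundred
  bases at the long preset) are effectively unmappable and land in the
  unassigned bin.
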