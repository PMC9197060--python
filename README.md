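# bacfinish

Finishing of pooled large-insert clones (BACs/fosmids) from full-length
nanopore reads plus accurate short-read data — as a tested, self-contained
Python library with a thin command line.

## The problem

Reference-quality sequence of structurally complex loci — ampliconic
repeats with >99% identity over >10 kb, palindromes, tandem arrays — still
comes from individually finished large-insert clones. A pooled nanopore run
over ~24 clones yields *full-length reads*: single molecules that traverse
an entire circular clone (cloning vector + 100–300 kb insert) after one
transposase cut. A full-length read fixes the complete structure of its
clone (order, orientation, copy number of every internal repeat), while
deep Illumina data fixes the base-level accuracy. `bacfinish` implements
the computational half of that workflow:

1. **simulate** — synthetic clone pools with ground truth: circular
   vector+insert molecules, internal tandem/palindromic repeat units of
   ≥99% identity distinguished by rare sequence family variants (SFVs),
   single-cut nanopore reads with indel-rich errors concentrated at
   homopolymer runs, paired short reads, and drafts with collapsed repeats.
2. **demux** — barcode-free assignment of pooled reads to clones by
   alignment against per-clone drafts, with a relative score-margin rule
   (`(best − second)/best ≥ 0.05`).
3. **fullread** — vector anchoring: a read that starts and ends in vector
   is full-length; rotation (after strand correction) places the vector
   first; clone length is otherwise estimated from the peak in the tail of
   the read-length distribution.
4. **consensus** — a full-length backbone read, windowed identity-weighted
   long-read polishing, then correction of residual errors (homopolymer
   run lengths above all) to the short-read column consensus at
   depth ≥ 15 and agreement ≥ 0.9; every edit is logged as a discrepancy.
5. **repeats** — divide and conquer for internally repetitive clones:
   repeat units detected by self-alignment, SFVs called with per-unit
   short-read support, reads partitioned per unit by their SFV alleles
   (fragment-level), each unit polished separately, long reads arbitrating
   any column the partition cannot separate, units merged back.
6. **io_formats / qc** — FASTA/FASTQ/SAM text I/O including the workaround
   for BAM's 65535-CIGAR-operation limit (split alignments every 1000
   match operations, exact merge), run statistics (read N50, per-clone
   fractions, full-length counts), troubleshooting flags, and
   overlap-based accuracy between neighboring finished clones.

The aligner underneath (minimizer seeding, co-linear chaining, banded
affine-gap extension with indel left-alignment) is part of the package, so
nothing external is shelled out to.

## A worked example

```sh
python examples/04_polish_clone.py
```

```
clone length estimate : 18,500 bp (truth 18,000)
finished length       : 18,000 bp
identical to truth    : True
differences vs truth  : 0

edits applied while polishing: {'HOMOPOLYMER_INDEL': 291, 'SUBSTITUTION': 303, 'UNRESOLVED': 6}
  pos      1: 'G' -> 'AG' (HOMOPOLYMER_INDEL)
  pos     16: 'C' -> 'A' (HOMOPOLYMER_INDEL)
  ...
```

One simulated 18 kb clone is finished from 40 pooled nanopore reads (10%
error) and 50× short reads: the clone length is first estimated from the
read-length tail, a vector-anchored read becomes the backbone, and the
discrepancy log records every correction of the nanopore consensus to the
Illumina consensus — dominated, as on real data, by homopolymer run-length
errors. The finished sequence equals the simulated truth exactly.

The other scripts in `examples/` walk through pool simulation, barcode-free
demultiplexing, full-length read rotation, SFV calling in a 99%-identity
tandem, and the SAM-splitting workaround. The same stages are available as
a CLI (`bacfinish simulate|demux|fullread|consensus|resolve-repeats|
split-sam|qc|run-all`) for file-based use.

## Layout

```
src/bacfinish/          the library (align/, simulate, demux, fullread,
                        consensus, repeats, io_formats, qc, pipeline, cli)
examples/               one short narrative script per capability
tests/                  pytest suite incl. independent quadratic-DP oracles
scripts/acceptance.py   recompute the headline numbers
docs/methods.md         models, parameters, design choices, limitations
```
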