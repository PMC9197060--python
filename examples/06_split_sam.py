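"""Split an ultra-long alignment for BAM-limited downstream tools.

BAM stores at most 65535 CIGAR operations per record — too few for the
alignment of a full-length nanopore read. The workaround cuts the SAM
record into uniquely named sub-alignments every 1000 match operations,
each independently valid; merging reconstructs the original exactly.
"""

import numpy as np

from bacfinish import io_formats as iof

rng = np.random.default_rng(14)

# an indel-rich alignment like a raw 50 kb nanopore read produces
cigar = []
total_m = 0
while total_m < 50_000:
    m = int(rng.integers(5, 40))
    cigar.append(("M", m))
    total_m += m
    cigar.append(("I", 1) if rng.random() < 0.5 else ("D", 1))
qlen = sum(n for op, n in cigar if op in "MIS")
record = iof.SamRecord("longread", 0, "clone00", 1, 60, cigar,
                       "A" * qlen, "I" * qlen)

print(f"original record : {record.n_elements():,} CIGAR elements, "
      f"{total_m:,} match operations")

subs = iof.split_alignment(record, match_ops_per_chunk=1000)
print(f"split into      : {len(subs)} sub-records "
      f"({subs[0].qname} ... {subs[-1].qname})")
print(f"max elements    : {max(s.n_elements() for s in subs):,} "
      f"(BAM limit {iof.MAX_BAM_OPS:,})")
print(f"POS of first 3  : {[s.pos for s in subs[:3]]}")

merged = iof.merge_split(subs)
print(f"merge round-trip: CIGAR identical = {merged.cigar == record.cigar}")
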