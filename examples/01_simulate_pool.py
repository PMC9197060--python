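"""Simulate a small clone pool and look at its ground truth.

Builds three circular clones (shared cloning vector + unique inserts), one
of them carrying a 2-copy ~99%-identity tandem repeat distinguished by
planted sequence family variants (SFVs), then prints the structure the
downstream pipeline is expected to recover.
"""

from bacfinish import simulate as sim

spec = sim.RepeatSpec(n_units=2, unit_len=1500, unit_identity=0.99)
pool = sim.make_clone_pool(
    3,
    vector_len=3000,
    insert_len_range=(12_000, 15_000),
    repeat_spec=spec,
    sfv_per_unit=2,
    seed=1,
)

for clone in pool:
    print(f"{clone.clone_id}: {len(clone):,} bp "
          f"(vector {clone.vector_interval[1]} bp + insert)")
    for u in clone.repeat_units:
        a, b = u.interval
        print(f"  repeat unit {a}-{b} ({u.orientation})")
    for s in clone.sfv_sites:
        print(f"  SFV: unit {s.unit_index}, offset {s.offset}, allele {s.allele}")

reads = sim.simulate_nanopore_run(pool, 60, p_single_cut=0.3, seed=2)
n_full = sum(1 for r in reads if not r.truth.truncated)
print(f"\nnanopore run: {len(reads)} reads, {n_full} full-length "
      f"({sum(len(r) for r in reads)/1e6:.1f} Mb)")
print("a full-length read is a rotation of its circular clone; truncated")
print("reads are exponential fragments — both carry ~10% error by default.")
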