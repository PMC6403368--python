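"""Merged reads -> affiliated OTU table.

Simulates a tiny mock run at the count level, materialises it as merged
reads (primer binding sites + 133 bp insert), then runs the read
pipeline: primer trimming, length filter, dereplication, chimera
flagging, d=1 clustering and taxonomic affiliation at the 99% identity
threshold.  The recovered table matches the simulated counts exactly
because no sequencing errors were injected.
"""

from maplkit import (
    MergedRead, MockDesign, emit_reads, make_reference_db, process_reads,
    simulate_mock_run,
)

db = make_reference_db(n_parasitoids=2, seed=4)
design = MockDesign(parasitoid_masses_ng=(7.0, 0.7), reads_per_sample=300,
                    n_negative_controls=2)
run = simulate_mock_run(db, design, seed=4)
reads = [MergedRead(s, seq) for s, seq in emit_reads(db, run.counts, seed=4)]

counts, affiliations, log = process_reads(reads, db, run.counts.sample_meta)

print("per-stage read accounting:", log)
print("\nOTU affiliations (taxon assigned at >= 99% identity):")
print(affiliations.to_string(index=False))
print("\nfirst columns of the OTU x replicate count table:")
print(counts.counts.iloc[:, :6].to_string())
print(
    "\nEvery input read carried perfect primer sites and an exact "
    "reference insert, so rejections are 0 and identities are 1.0."
)
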