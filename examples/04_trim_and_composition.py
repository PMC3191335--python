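"""Trim terminal poly-A/T tails and report base composition.

EST reads end in poly-A (or start in poly-T) from the mRNA tail; these
are removed before repeat mining so homopolymer tails are never mistaken
for genomic microsatellites.
"""

from estssr import ESTRecord, composition_stats, trim_poly_tracts

reads = [
    ESTRecord("r1", "GATTACAGATTACAGATTACAGATTACA" + "A" * 18),  # 3' poly-A
    ESTRecord("r2", "T" * 25 + "CCGGATCCGGTACCGGATCCGGTA"),      # 5' poly-T
    ESTRecord("r3", "GCGTCGTTGCATGCGTCGTTGCATGCGT"),              # nothing to trim
]
trimmed = [trim_poly_tracts(r) for r in reads]
for before, after in zip(reads, trimmed):
    print(f"{before.seq_id}: {before.length} -> {after.length} bases")

stats = composition_stats(trimmed)
print(f"A+T content: {stats.pct_AT}%   G+C content: {stats.pct_GC}%")
print(f"mean length: {stats.mean_length:.1f} bases over {stats.n_sequences} reads")
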