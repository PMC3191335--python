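"""Simulate an EST-like dataset and run the full mining pipeline on it.

Builds 500 synthetic reads (mean 469 bp, 56% A+T, 3.5% carrying a planted
microsatellite, plus poly-A/T tails and redundant copies), mines them, and
compares the recovered loci with the generator's truth.
"""

from estssr import SimParams, mine_records, simulate_est_set

params = SimParams(n_sequences=500, seed=42)
records, truth = simulate_est_set(params)
print(f"simulated {len(records)} records, {len(truth.planted_loci)} planted SSRs")

result = mine_records(records, design=False)
summary = result.summary

print(f"kept after trimming + redundancy: {len(result.records_kept)} records")
print(f"detected SSR loci:               {summary.n_ssrs}")
print(f"frequency: {summary.frequency_pct}% of sequences carry an SSR locus")
print(f"density:   one SSR per {summary.density_kb} kb of sequence")

detected = {(l.seq_id, l.start, l.end, l.motif, l.repeat_count) for l in result.loci}
planted = {(p.seq_id, p.start, p.end, p.motif, p.repeat_count) for p in truth.planted_loci}
print(f"planted loci recovered exactly: {len(planted & detected)}/{len(planted)}")
# Any surplus loci are incidental repeats that arose by chance in the
# random background; the generator enumerates those too:
incidental = {(l.seq_id, l.start, l.end, l.motif, l.repeat_count)
              for l in truth.incidental_loci}
print(f"incidental background repeats:  {len(detected - planted)} "
      f"(all accounted: {detected == planted | incidental})")
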