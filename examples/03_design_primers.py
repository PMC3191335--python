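"""Design PCR primers flanking a microsatellite locus.

Candidates satisfy length 18-27 bases, Tm 55-60 deg C (classic
nearest-neighbor calculation), GC 30-70%, product 100-300 bp, and
self/pair complementarity limits; no primer may touch any detected
repeat. Pairs are ranked by Tm balance and GC distance from 50%.
"""

import numpy as np

from estssr import ESTRecord, PrimerConstraints, design_primers, find_perfect_ssrs
from estssr.simulate import plant_ssr

rng = np.random.default_rng(7)
background = "".join(rng.choice(list("ACGT"), size=300, p=[0.28, 0.22, 0.22, 0.28]))
template = ESTRecord("demo", plant_ssr(background, "CA", 15, 150, rng))

loci = find_perfect_ssrs(template)
target = max(loci, key=lambda l: l.span_length)
result = design_primers(template, target, PrimerConstraints(), exclusion_loci=loci)

print(f"target locus: {target.notation()} at {target.start}-{target.end}")
print(f"{len(result.candidates)} candidate pairs; best by penalty:")
best = result.best
print(f"  forward  5'-{best.fw_seq}-3'  Tm {best.fw_tm} C  GC {best.fw_gc}%")
print(f"  reverse  5'-{best.rv_seq}-3'  Tm {best.rv_tm} C  GC {best.rv_gc}%")
print(f"  product {best.product_size} bp, penalty {best.penalty:.2f}")
# The reverse primer is the reverse complement of the template's 3' flank,
# so the pair amplifies a product spanning the repeat.
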