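"""Detect perfect microsatellites in a single sequence and classify them.

A repeat qualifies when a primitive motif of 2-6 bases is tandemly
repeated at least 5 times with no interruptions; dinucleotide motifs are
reported as complement pairs (AG with TC, etc.).
"""

from estssr import DetectionConfig, ESTRecord, classify_motif, find_perfect_ssrs

seq = (
    "GCGTCGTTGCAT" + "CA" * 15        # a (CA)15 repeat
    + "TGCATCCGGAT" + "TTC" * 6       # a (TTC)6 repeat
    + "GCGTCGTTGCAT"
)
record = ESTRecord("demo", seq)

for locus in find_perfect_ssrs(record, DetectionConfig(min_repeats=5)):
    mc = classify_motif(locus.motif)
    print(
        f"{locus.notation():>9}  span {locus.start}-{locus.end}  "
        f"period={locus.period} ({mc.period_class})  class={mc.class_label}"
    )
# Each line shows the repeat in "(motif)count" notation, its 1-based
# inclusive coordinates, and the reporting class used in catalogue tables.
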