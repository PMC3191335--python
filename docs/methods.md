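# Methods

## Scope and model

`estssr` treats a collection of EST-like reads as a flat set of
single-stranded DNA sequences and asks three questions: which terminal
homopolymer stretches are sequencing artefacts, which internal stretches
are perfect microsatellites, and which repeats could be turned into PCR
markers. The package deliberately models nothing about transcript
structure, sequencing error or library normalization; it is a repeat
catalogue engine, not an assembler.

## Trimming

A read's terminal poly-A (or poly-T, for reverse-strand deposits) tail is
removed iteratively: whenever an A- or T-homopolymer run of length ≥ *w*
(default *w* = 10) **starts** within the first *w* bases, the prefix up to
and including the run is removed; the mirror rule applies at the 3′ end
(a run **ending** within the last *w* bases removes the suffix from the
run's first base). Iteration handles stacked tails such as
`TTTT…AAAA…<insert>`. Because any qualifying run that *intersects* a
terminal window necessarily starts (ends) inside it, the loop's fixed
point satisfies the stronger postcondition that no A/T homopolymer
≥ *w* touches either terminal window. Consequences of this definition:

* up to *w* − 1 genuine bases 5′ (3′) of a triggering run are removed
  with it — trimming always takes a prefix/suffix, never an internal
  splice;
* internal homopolymers, and G/C homopolymers anywhere, are never
  touched;
* a read consisting only of tail trims to the empty string; the pipeline
  drops and logs such reads.

Trimming is idempotent and its output is a contiguous substring of its
input (property-tested).

## Repeat detection

A locus is a maximal perfect tandem array of a **primitive** motif
(one that is not itself a repetition of a shorter motif) with period
*p* ∈ [2, 6] and at least 5 complete copies, both configurable
(mononucleotide scanning exists behind `min_period=1` but is excluded
from default catalogues because terminal-tail trimming makes homopolymer
counts uninterpretable). The scanner finds, for each period, maximal
stretches with `s[i] == s[i+p]`; a stretch of pair-length *L* covers
*L* + *p* bases and holds ⌊(*L*+*p*)/*p*⌋ complete units anchored at its
leftmost base. Conventions, chosen once and fixed:

* **Complete units only**: a trailing partial unit extends neither the
  span nor the count, so `GGACACACACACATT` reports (AC)₅ at 3–12 and the
  lone trailing A is ignored.
* **Anchor and rotation**: a run is reported once, at its leftmost
  complete unit, with the motif rotation that appears there.
* **Primitivity**: a run whose anchor motif is non-primitive is skipped;
  the true (smaller) period reports it, so (AT)₆ is never also (ATAT)₃.
  If distinct primitive periods ever produce an identical span, the
  smaller period wins.
* **N matches nothing**: runs are split around ambiguous bases and each
  side re-scanned.
* **Single strand**: only the deposited strand is scanned; the reverse
  complement of a dataset yields complement motifs at mirrored runs.

Every reported locus re-verifies against its sequence (perfection,
primitivity, and the impossibility of extending by one full period in
phase on either side); the detector is checked locus-for-locus against a
brute-force greedy-extension oracle on thousands of random sequences.

## Redundancy

Two deterministic criteria produce the non-redundant marker-candidate
set: (i) sequences identical to, or exact substrings of, another are
clustered by transitive closure and only the longest member is retained
(ties: first in input order); (ii) sequences whose detected repeat spans
jointly cover every base are discarded — without a flank their
uniqueness cannot be established and no primer can be placed. Clustering
is exact string containment on the given strand; inexact homologs
(mismatches, reverse-complement containment) are out of scope, which is
the price of determinism without external alignment tools. The pipeline
applies (ii) before (i) by default (`dedup_first` swaps the order for
sensitivity checks); all drop counts reconcile (input = kept + dropped)
by construction.

## Catalogue statistics

All counting is exact integer arithmetic: frequency = 100·SSRs/reads,
density = bases/SSRs (also as kb at one decimal), per-period shares,
per-motif-class shares within each period, repeat-count histogram,
multi-SSR read count, and the fraction of bases inside repeat spans
(overlaps counted once per base). Dinucleotide motifs are reported as
base-wise complement pairs without reversal — AC/TG, AG/TC, AT/TA,
CA/GT, CG/GC, CT/GA are the six possible classes — because the two
strands of one genomic locus present complementary motifs; longer
periods are reported as raw motifs (a raw dinucleotide table is also
emitted). Percentages are reported at one decimal with round-half-up by
default; a "truncate" mode exists because published catalogues sometimes
floor (467/1,499 = 31.15 % appearing as 31.1 %). Which sequence total
feeds the density (raw input vs trimmed non-redundant) is a
configuration choice recorded with every run; the default is the
analyzed (trimmed, non-redundant) total.

## Primer design

For each locus, forward primers are enumerated from the 5′ flank and
reverse primers (reverse-complemented) from the 3′ flank over all allowed
lengths and positions, then filtered on length (18–27 nt), GC (30–70 %),
Tm (55–60 °C), self-complementarity (longest antiparallel complementary
stretch ≤ 8, 3′-anchored ≤ 4), pair complementarity (same limits) and
product size (100–300 bp). No primer may overlap *any* detected repeat
of the template, not just the target locus — standard protection against
repeat-anchored priming. Surviving pairs are scored with
penalty = |Tm_f − Tm_r| + (|GC_f − 50| + |GC_r − 50|)/100 and returned in
ascending order (ties: leftmost forward start, then smallest product).
Because the unconstrained cross product can reach tens of thousands of
pairs, only the best `max_candidates` (default 50) are materialized; the
cap preserves the property that tightening any single constraint never
increases the number of returned candidates. A locus whose flank cannot
physically hold a primer returns empty with reason "insufficient flank".

Complementarity uses the identity that the longest ungapped antiparallel
complementary stretch between two oligos equals the longest common
substring of one and the reverse complement of the other; the threshold
form (is there a stretch > k?) therefore reduces to a (k+1)-mer substring
test, which is what the designer's inner loop uses.

### Melting temperature

Default is the classic nearest-neighbor formula
Tm = ΔH / (ΔS − 10.8 + R ln(C/4)) − 273.15 + 16.6 log₁₀[Na⁺]
with Breslauer (1986) stacking parameters, C = 50 nM oligo and 50 mM
monovalent salt — the historical default of the most widely used
primer-design program, chosen so published marker Tms are directly
comparable: it reproduces the shipped 40-marker sheet's printed Tms to
0.1 °C. The SantaLucia (1998) unified parameters (via Biopython's
`Tm_NN`, which runs ~8–9 °C lower under the same salt model) and the
Wallace 2(A+T)+4(G+C) rule are selectable; the parameter set is an
explicit argument and recorded in run configuration. Tm is undefined
here for sequences shorter than 8 nt or containing N (error).

## Synthetic data

The generator emulates the features of an EST set that this pipeline is
sensitive to: read length ~ Normal(469, 150) truncated at 100 bp; base
probabilities A = T = 0.28, C = G = 0.22 (≈56 % A+T); a fraction
(default 0.035) of reads carrying one planted perfect repeat with period
mix 0.67/0.311/0.015/0.004 over periods 2–5 and 5–16 units; terminal
poly-A/T tails of 10–30 nt on 20 % of reads; exact-duplicate (2 %) and
contained-prefix (2 %) copies; and pure-repeat flankless reads (0.5 %).
Duplicate/containment/flankless rates are generator design choices at
realistic magnitudes; the length, composition, SSR rate and period-mix
defaults are the study conditions of the EST survey the catalogue
arithmetic is checked against.

Exactness guarantees, which make recovery tests sharp rather than
statistical:

* a planted run's neighbours are rewritten if they would extend it in
  phase, so the detected count equals the planted count exactly;
* the base adjacent to an appended tail is rewritten (to C/G) if it
  equals the tail base, so trimming restores the untailed sequence and
  truth coordinates exactly;
* backgrounds whose terminal windows contain an A/T run ≥ 10 are
  re-rolled (they would interact with trimming);
* incidental repeats that arise by chance in background sequence are
  enumerated (with the detector, on the final untailed sequence,
  excluding the planted span) and stored separately in the truth, so
  `detected = planted ∪ incidental` can be asserted as set equality.
  The planted half of that assertion is detector-independent: planted
  loci are verified by direct substring comparison at known coordinates.

What the generator does **not** emulate: sequencing error, chimeras,
imperfect/interrupted repeats, near-identical (mismatched) homologs, and
cDNA library normalization. Passing recovery tests therefore demonstrate
correctness of the pipeline's logic on clean perfect repeats, not
robustness to noisy real reads.

## Problem sizes and determinism

The test suite runs the detector/oracle equivalence on 1,000 random
300-bp sequences at two thresholds, and the end-to-end recovery on a
2,000-read synthetic set (~60–90 planted loci plus corruptions); the
acceptance script uses the same 2,000-read size. All randomness flows
from explicit integer seeds (numpy `default_rng`); identical parameters
and seed give byte-identical FASTA output, and pipeline reruns produce
byte-identical artifacts.

## Known limitations and recorded inconsistencies

* The published survey's own printed numbers are not mutually consistent
  (mean length × read count ≠ printed base totals; printed density
  15.55 kb vs 15.60 kb from the printed totals; printed 44.3 % G+C vs
  43.4 % by arithmetic; 425+271+9 = 705 vs "630 suitable"). The package
  reports exact arithmetic and does not attempt to reproduce
  dataset-level values that would require the original 42,784-read
  download; the density discrepancy is asserted to be ≤ 1 % in tests.
* Exact-containment clustering is a deterministic stand-in for
  alignment-based redundancy screening; counts on real data will differ
  where near-identical homologs exist.
* The designer approximates PRIMER3's behaviour (explicit constraint
  filters plus a simple penalty) rather than reproducing its full
  penalty model, spacing rules or thermodynamic alignments; published
  "suitable for primer design" fractions are therefore not a target.
* Published marker product sizes reach 400 bp although the stated design
  range was 100–300 bp; the bound is configurable and defaults to the
  stated range.
* Published marker Tms reach 62.2 °C although the stated range was
  55–60 °C; the designer treats [tm_min, tm_max] as a hard filter on the
  calculated Tm and reports values, with a ±1 °C reporting tolerance
  accepted when re-validating external candidates.
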