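"""Constraint-based design of PCR primer pairs flanking SSR loci.

Candidate primers are enumerated from the two flanks of a repeat, filtered
on length, GC content, melting temperature, self/pair complementarity and
product size, then ranked by a penalty combining Tm imbalance and GC
distance from the optimum.  Primers never overlap any detected repeat in
the template, the standard precaution against repeat-anchored priming.

Melting temperatures come from nearest-neighbor thermodynamics.  The
default "breslauer" parameter set is the classic oligotm formula
(Breslauer 1986 stacking table, Rychlik -10.8 e.u. initiation entropy,
Schildkraut-Lifson 16.6*log10[Na+] salt term, annealing concentration
C/4): the historical default of widely used primer-design software, which
makes published marker Tms directly comparable.  A SantaLucia 1998
unified set (via Biopython) and the Wallace rule are available as
alternatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._rounding import round_report
from .detect import SSRLocus, parse_ssr_notation
from .sequence_io import ESTRecord

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# Breslauer 1986 nearest-neighbor magnitudes: delta-H in kcal/mol,
# delta-S in cal/(K*mol), indexed by the 5'->3' dinucleotide.
_BRES_DH = {
    "AA": 9.1, "AC": 6.5, "AG": 7.8, "AT": 8.6,
    "CA": 5.8, "CC": 11.0, "CG": 11.9, "CT": 7.8,
    "GA": 5.6, "GC": 11.1, "GG": 11.0, "GT": 6.5,
    "TA": 6.0, "TC": 5.6, "TG": 5.8, "TT": 9.1,
}
_BRES_DS = {
    "AA": 24.0, "AC": 17.3, "AG": 20.8, "AT": 23.9,
    "CA": 12.9, "CC": 26.6, "CG": 27.8, "CT": 20.8,
    "GA": 13.5, "GC": 26.7, "GG": 26.6, "GT": 17.3,
    "TA": 16.9, "TC": 13.5, "TG": 12.9, "TT": 24.0,
}
_R = 1.987  # cal/(K*mol)

TM_METHODS = ("breslauer", "santalucia", "wallace")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_primer_seq(seq: str, min_len: int = 1) -> None:
    if len(seq) < min_len:
        raise ValueError(f"sequence shorter than {min_len} bases")
    if not seq or set(seq) - set("ACGT"):
        raise ValueError("primer sequences must be non-empty and ACGT only")


def gc_percent(seq: str) -> float:
    """GC content as a percentage, one decimal."""
    _check_primer_seq(seq)
    return round_report(100.0 * (seq.count("G") + seq.count("C")) / len(seq), 1)


def melting_temperature(
    seq: str,
    method: str = "breslauer",
    dna_nM: float = 50.0,
    monovalent_mM: float = 50.0,
) -> float:
    """Primer melting temperature in deg C.

    method "breslauer": classic oligotm nearest-neighbor formula
        Tm = dH / (dS_init + dS_stack + R ln(C/4)) - 273.15
             + 16.6 log10([Na+]) with dS_init = -10.8 e.u.
    method "santalucia": SantaLucia 1998 unified parameters through
        Biopython's Tm_NN.
    method "wallace": 2(A+T) + 4(G+C) rule for short oligos.
    """
    _check_primer_seq(seq, min_len=8)
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return float(2 * at + 4 * gc)
    if method == "santalucia":
        from Bio.SeqUtils import MeltingTemp as mt

        return float(
            mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=monovalent_mM,
                     dnac1=dna_nM / 2, dnac2=dna_nM / 2)
        )
    if method != "breslauer":
        raise ValueError(f"unknown Tm method {method!r}")
    dh = -1000.0 * sum(_BRES_DH[seq[i : i + 2]] for i in range(len(seq) - 1))
    ds = -(10.8 + sum(_BRES_DS[seq[i : i + 2]] for i in range(len(seq) - 1)))
    tm_k = dh / (ds + _R * math.log(dna_nM * 1e-9 / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(monovalent_mM / 1000.0)


def complementarity_scores(fw: str, rv: str) -> tuple[int, int]:
    """(any_comp, three_prime_comp) between two primers, in base pairs.

    any_comp: longest ungapped antiparallel complementary stretch at any
    alignment offset.  three_prime_comp: longest such stretch that
    includes the 3' terminal base of either primer.  Self-complementarity
    is the same computation with fw == rv.
    """
    _check_primer_seq(fw)
    _check_primer_seq(rv)
    s2 = rv[::-1]  # antiparallel alignment
    n1, n2 = len(fw), len(s2)
    any_comp = 0
    for offset in range(-(n2 - 1), n1):
        run = 0
        for i2 in range(n2):
            i1 = offset + i2
            if 0 <= i1 < n1 and fw[i1] == s2[i2].translate(_COMPLEMENT):
                run += 1
                any_comp = max(any_comp, run)
            else:
                run = 0
    three = max(_three_prime_anchor(fw, rv), _three_prime_anchor(rv, fw))
    return any_comp, three


def _three_prime_anchor(a: str, b: str) -> int:
    """Longest suffix of `a` complementary (antiparallel) to a stretch of `b`."""
    target = revcomp(b)
    for length in range(min(len(a), len(b)), 0, -1):
        if a[-length:] in target:
            return length
    return 0


def _violates_complementarity(
    fw: str, rv: str, max_any: int, max_three: int
) -> bool:
    """Threshold form of complementarity_scores, in O(len) time.

    A complementary stretch of length >= k exists iff some k-mer of one
    primer occurs in the reverse complement of the other; a 3'-anchored
    stretch >= k exists iff the primer's k-suffix occurs there.
    """
    target_fw = revcomp(rv)  # stretches of fw pairing with rv
    k = max_any + 1
    if len(fw) >= k and any(
        fw[i : i + k] in target_fw for i in range(len(fw) - k + 1)
    ):
        return True
    k3 = max_three + 1
    if len(fw) >= k3 and fw[-k3:] in target_fw:
        return True
    target_rv = revcomp(fw)
    if len(rv) >= k3 and rv[-k3:] in target_rv:
        return True
    return False


@dataclass(frozen=True)
class PrimerConstraints:
    """PCR design constraints (lengths in bases, Tm in deg C, GC in %)."""

    len_min: int = 18
    len_max: int = 27
    tm_min: float = 55.0
    tm_max: float = 60.0
    product_min: int = 100
    product_max: int = 300
    gc_min: float = 30.0
    gc_max: float = 70.0
    gc_opt: float = 50.0
    max_self_comp: int = 8
    max_3prime_comp: int = 4
    min_flank: int | None = None  # defaults to len_min
    tm_method: str = "breslauer"
    max_candidates: int = 50  # pairs returned after ranking

    def __post_init__(self) -> None:
        if not (self.len_min <= self.len_max):
            raise ValueError("len_min must not exceed len_max")
        if not (self.product_min <= self.product_max):
            raise ValueError("product_min must not exceed product_max")
        if not (self.gc_min <= self.gc_opt <= self.gc_max):
            raise ValueError("need gc_min <= gc_opt <= gc_max")
        if self.tm_method not in TM_METHODS:
            raise ValueError(f"unknown Tm method {self.tm_method!r}")

    @property
    def flank_needed(self) -> int:
        return self.len_min if self.min_flank is None else self.min_flank


@dataclass(frozen=True)
class PrimerCandidate:
    """A scored forward/reverse pair on one template, 1-based coordinates."""

    locus: SSRLocus
    fw_seq: str
    rv_seq: str
    fw_start: int
    rv_end: int
    fw_tm: float
    rv_tm: float
    fw_gc: float
    rv_gc: float
    penalty: float

    @property
    def product_size(self) -> int:
        return self.rv_end - self.fw_start + 1


@dataclass(frozen=True)
class DesignResult:
    candidates: list[PrimerCandidate]
    failure_reason: str | None = None

    def __bool__(self) -> bool:
        return bool(self.candidates)

    @property
    def best(self) -> PrimerCandidate | None:
        return self.candidates[0] if self.candidates else None


def _enumerate_side(
    s: str, lo: int, hi: int, constraints: PrimerConstraints, reverse: bool
) -> list[tuple[int, int, str, float, float]]:
    """Valid single primers on template positions [lo, hi) (0-based).

    Returns (start0, end0_exclusive, primer_seq, tm, gc); primer_seq is the
    reverse complement of the template segment when `reverse`.
    """
    out = []
    for length in range(constraints.len_min, constraints.len_max + 1):
        for a in range(lo, hi - length + 1):
            segment = s[a : a + length]
            if set(segment) - set("ACGT"):
                continue
            primer = revcomp(segment) if reverse else segment
            gc = gc_percent(primer)
            if not (constraints.gc_min <= gc <= constraints.gc_max):
                continue
            tm = melting_temperature(primer, method=constraints.tm_method)
            if not (constraints.tm_min <= tm <= constraints.tm_max):
                continue
            if _violates_complementarity(
                primer, primer, constraints.max_self_comp, constraints.max_3prime_comp
            ):
                continue
            out.append((a, a + length, primer, tm, gc))
    return out


def design_primers(
    record: ESTRecord,
    locus: SSRLocus,
    constraints: PrimerConstraints = PrimerConstraints(),
    exclusion_loci: Sequence[SSRLocus] | None = None,
) -> DesignResult:
    """Enumerate, filter and rank primer pairs flanking one SSR locus.

    `exclusion_loci` lists every detected repeat of the template (default:
    just the target locus); no primer may overlap any of their spans.
    Pairs are ranked by penalty |fw_tm - rv_tm| + (|fw_gc - gc_opt| +
    |rv_gc - gc_opt|)/100, ties broken by leftmost forward start, then
    smallest product; the best `constraints.max_candidates` pairs are
    returned.  Returns an empty result with reason "insufficient flank"
    when a flank cannot hold a primer.
    """
    s = record.sequence
    if not (1 <= locus.start <= locus.end <= len(s)):
        raise ValueError(f"locus {locus} outside record {record.seq_id}")
    exclusion = list(exclusion_loci) if exclusion_loci is not None else [locus]

    left_len = locus.start - 1
    right_len = len(s) - locus.end
    if left_len < constraints.flank_needed or right_len < constraints.flank_needed:
        return DesignResult([], failure_reason="insufficient flank")

    blocked = [False] * len(s)
    for other in exclusion:
        for i in range(other.start - 1, other.end):
            blocked[i] = True

    def unblocked(a: int, b: int) -> bool:
        return not any(blocked[a:b])

    fw_all = [
        c
        for c in _enumerate_side(s, 0, locus.start - 1, constraints, reverse=False)
        if unblocked(c[0], c[1])
    ]
    rv_all = [
        c
        for c in _enumerate_side(s, locus.end, len(s), constraints, reverse=True)
        if unblocked(c[0], c[1])
    ]

    rv_by_end: dict[int, list[tuple[int, int, str, float, float]]] = {}
    for c in rv_all:
        rv_by_end.setdefault(c[1], []).append(c)

    scored: list[tuple] = []
    for fa, fb, fseq, ftm, fgc in fw_all:
        fw_start = fa + 1
        for rv_end in range(
            fw_start + constraints.product_min - 1,
            fw_start + constraints.product_max,
        ):
            for ra, rb, rseq, rtm, rgc in rv_by_end.get(rv_end, ()):
                if _violates_complementarity(
                    fseq, rseq, constraints.max_self_comp, constraints.max_3prime_comp
                ):
                    continue
                penalty = abs(ftm - rtm) + (
                    abs(fgc - constraints.gc_opt) + abs(rgc - constraints.gc_opt)
                ) / 100.0
                scored.append(
                    (penalty, fw_start, rv_end - fw_start + 1,
                     rv_end, fseq, rseq, ftm, rtm, fgc, rgc)
                )
    scored.sort(key=lambda t: t[:3])
    candidates = [
        PrimerCandidate(
            locus=locus, fw_seq=fseq, rv_seq=rseq,
            fw_start=fw_start, rv_end=rv_end,
            fw_tm=round_report(ftm, 1), rv_tm=round_report(rtm, 1),
            fw_gc=fgc, rv_gc=rgc, penalty=penalty,
        )
        for penalty, fw_start, _product, rv_end, fseq, rseq, ftm, rtm, fgc, rgc
        in scored[: constraints.max_candidates]
    ]
    return DesignResult(candidates)


def write_marker_sheet(
    rows: Iterable[tuple[str, ESTRecord, SSRLocus, PrimerCandidate]],
    dest,
) -> None:
    """Marker sheet TSV: name, seq_id, SSR notation, product size, primers, Tms."""
    handle = open(dest, "w", encoding="ascii") if isinstance(dest, (str, Path)) else dest
    close = isinstance(dest, (str, Path))
    try:
        handle.write(
            "name\tseq_id\tssr\tproduct_size\tfw_primer\tfw_tm\trv_primer\trv_tm\n"
        )
        for name, rec, locus, cand in rows:
            handle.write(
                f"{name}\t{rec.seq_id}\t{locus.notation()}\t{cand.product_size}\t"
                f"{cand.fw_seq}\t{cand.fw_tm}\t{cand.rv_seq}\t{cand.rv_tm}\n"
            )
    finally:
        if close:
            handle.close()


def read_marker_sheet(path) -> "pandas.DataFrame":
    """Read a marker sheet TSV (as written above, or hand-curated with the
    same SSR-notation column) into a DataFrame with parsed motif/period/
    repeat_count columns."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    parsed = df["ssr"].map(parse_ssr_notation)
    df["motif"] = parsed.map(lambda t: t[0])
    df["repeat_count"] = parsed.map(lambda t: t[1])
    df["period"] = df["motif"].str.len()
    return df
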