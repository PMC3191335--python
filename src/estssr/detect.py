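"""Perfect simple-sequence-repeat (microsatellite) detection.

A locus is a maximal perfect tandem array of a primitive motif of period
``min_period..max_period`` with at least ``min_repeats`` complete copies.
Only complete motif units count: a trailing partial unit extends neither
the reported span nor the repeat count.  N matches nothing, so runs are
broken at ambiguous bases.  Scanning is strand-asymmetric: only the given
strand is searched, as is conventional for EST repeat surveys.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .sequence_io import ESTRecord

_ACGT = frozenset("ACGT")
_PERIOD_CLASS = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class DetectionConfig:
    """Search thresholds.

    Defaults scan periods 2-6 with a minimum of five complete repeat
    units, the standard criterion for EST-SSR surveys.  Mononucleotide
    scanning is available by setting ``min_period=1`` but is excluded from
    default catalogues (homopolymers are confounded with poly-A/T tails).
    """

    min_period: int = 2
    max_period: int = 6
    min_repeats: int = 5

    def __post_init__(self) -> None:
        if not (1 <= self.min_period <= self.max_period <= 6):
            raise ValueError("need 1 <= min_period <= max_period <= 6")
        if self.min_repeats < 2:
            raise ValueError("min_repeats must be >= 2")


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect repeat: motif as it appears at the run's start,
    1-based inclusive coordinates."""

    seq_id: str
    motif: str
    period: int
    repeat_count: int
    start: int
    end: int

    @property
    def span_length(self) -> int:
        return self.period * self.repeat_count

    def notation(self) -> str:
        """Repeat in conventional "(CA)15" notation."""
        return f"({self.motif}){self.repeat_count}"


@dataclass(frozen=True)
class MotifClass:
    """Reporting label for a motif: complement-paired for dinucleotides
    (e.g. AG and TC share the label "AG/TC"), the raw motif otherwise."""

    class_label: str
    period_class: str


def primitive_motif(motif: str) -> str:
    """Shortest string whose tandem repetition equals `motif`.

    "ATAT" -> "AT"; "ACG" -> "ACG"; "AAAAAA" -> "A".  Guarantees that a
    repeat is never double-reported at a multiple of its true period.
    """
    if not motif:
        raise ValueError("empty motif")
    if "N" in motif:
        raise ValueError("N may not seed a repeat motif")
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return motif[:d]
    return motif  # unreachable: d == n always divides


def classify_motif(motif: str) -> MotifClass:
    """Reporting class of a primitive motif of period 1..6."""
    if primitive_motif(motif) != motif:
        raise ValueError(f"motif {motif!r} is not primitive")
    period = len(motif)
    if period > 6:
        raise ValueError("period above 6 is not a simple sequence repeat")
    if period == 2:
        comp = motif.translate(_COMPLEMENT)  # base-wise, no reversal
        label = "/".join(sorted([motif, comp]))
    else:
        label = motif
    return MotifClass(class_label=label, period_class=_PERIOD_CLASS[period])


def find_perfect_ssrs(
    record: ESTRecord, config: DetectionConfig = DetectionConfig()
) -> list[SSRLocus]:
    """All maximal perfect repeats in one sequence, sorted by start.

    For each period p, maximal stretches with s[i] == s[i+p] are located;
    a stretch of matching-pair length L covers L + p bases and holds
    floor((L+p)/p) complete units anchored at its leftmost base.  The
    motif reported is the rotation appearing at that anchor.  Runs whose
    anchor motif is non-primitive are skipped (the true period reports
    them); if distinct primitive periods ever yield an identical span,
    the smallest period wins.
    """
    s = record.sequence
    n = len(s)
    found: dict[tuple[int, int], SSRLocus] = {}
    for period in range(config.min_period, config.max_period + 1):
        min_span = period * config.min_repeats
        i = 0
        limit = n - period
        while i < limit:
            if s[i] == s[i + period] and s[i] in _ACGT:
                j = i
                while j < limit and s[j] == s[j + period] and s[j] in _ACGT:
                    j += 1
                run_len = j - i + period
                count = run_len // period
                if count >= config.min_repeats:
                    motif = s[i : i + period]
                    if len(primitive_motif(motif)) == period:
                        key = (i + 1, i + count * period)
                        prev = found.get(key)
                        if prev is None or prev.period > period:
                            found[key] = SSRLocus(
                                seq_id=record.seq_id,
                                motif=motif,
                                period=period,
                                repeat_count=count,
                                start=key[0],
                                end=key[1],
                            )
                i = j + 1
            else:
                i += 1
    return sorted(found.values(), key=lambda l: (l.start, l.end, l.period))


def verify_locus(record: ESTRecord, locus: SSRLocus) -> bool:
    """Independently re-check perfection, primitivity and maximality of a
    reported locus against its sequence."""
    s = record.sequence
    start0 = locus.start - 1
    end0 = locus.end  # exclusive
    if locus.end - locus.start + 1 != locus.span_length:
        return False
    if primitive_motif(locus.motif) != locus.motif:
        return False
    if s[start0:end0] != locus.motif * locus.repeat_count:
        return False
    p = locus.period
    # extending by one full period in phase must fail on both sides
    if start0 - p >= 0 and s[start0 - p : end0] == locus.motif * (locus.repeat_count + 1):
        return False
    if end0 + p <= len(s) and s[start0 : end0 + p] == locus.motif * (locus.repeat_count + 1):
        return False
    return True


def parse_ssr_notation(text: str) -> tuple[str, int]:
    """Parse "(CA)15" into ("CA", 15)."""
    m = re.fullmatch(r"\(([ACGTacgt]+)\)(\d+)", text.strip())
    if not m:
        raise ValueError(f"not an SSR notation: {text!r}")
    return m.group(1).upper(), int(m.group(2))
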