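"""Catalogue statistics for a mined SSR set.

Computes the headline numbers of an EST-SSR survey: how many repeats per
hundred sequences, how much sequence per repeat (density), how loci
distribute over motif periods and motif classes, the repeat-count
histogram, and how many sequences carry more than one locus.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._rounding import pct, round_report
from .detect import DetectionConfig, SSRLocus, classify_motif
from .sequence_io import ESTRecord

_PERIOD_ORDER = ("mono", "di", "tri", "tetra", "penta", "hexa")


def frequency_percent(n_ssrs: int, n_ests: int, mode: str = "half_up") -> float:
    """SSRs per 100 ESTs, one decimal."""
    if n_ests <= 0:
        raise ValueError("n_ests must be positive")
    return pct(n_ssrs, n_ests, mode=mode)


def density_bp_per_ssr(total_bases: int, n_ssrs: int) -> float:
    """Average bases of sequence per detected SSR (one decimal)."""
    if n_ssrs <= 0:
        raise ValueError("density undefined for zero SSRs")
    return round_report(total_bases / n_ssrs, 1)


def density_kb_per_ssr(total_bases: int, n_ssrs: int) -> float:
    """Density expressed as kilobases per SSR (one decimal)."""
    if n_ssrs <= 0:
        raise ValueError("density undefined for zero SSRs")
    return round_report(total_bases / n_ssrs / 1000.0, 1)


@dataclass(frozen=True)
class CatalogueSummary:
    n_ests: int
    total_bases: int
    n_ssrs: int
    frequency_pct: float
    density_bp: float | None
    density_kb: float | None
    span_fraction_pct: float
    per_period: dict[str, tuple[int, float]]
    per_motif_class: dict[str, dict[str, tuple[int, float]]]
    per_motif_raw: dict[str, dict[str, int]]
    repeat_count_hist: dict[int, int]
    min_repeat_count: int | None
    max_repeat_count: int | None
    n_multi_ssr_ests: int

    def to_dict(self) -> dict:
        return {
            "n_ests": self.n_ests,
            "total_bases": self.total_bases,
            "n_ssrs": self.n_ssrs,
            "frequency_pct": self.frequency_pct,
            "density_bp_per_ssr": self.density_bp,
            "density_kb_per_ssr": self.density_kb,
            "span_fraction_pct": self.span_fraction_pct,
            "per_period": {
                k: {"count": c, "pct": p} for k, (c, p) in self.per_period.items()
            },
            "per_motif_class": {
                period: {
                    label: {"count": c, "pct": p} for label, (c, p) in classes.items()
                }
                for period, classes in self.per_motif_class.items()
            },
            "per_motif_raw": self.per_motif_raw,
            "repeat_count_hist": {str(k): v for k, v in sorted(self.repeat_count_hist.items())},
            "min_repeat_count": self.min_repeat_count,
            "max_repeat_count": self.max_repeat_count,
            "n_multi_ssr_ests": self.n_multi_ssr_ests,
        }


def _union_span_bases(loci: Sequence[SSRLocus]) -> int:
    """Bases covered by at least one locus span, per sequence."""
    by_seq: dict[str, list[tuple[int, int]]] = {}
    for locus in loci:
        by_seq.setdefault(locus.seq_id, []).append((locus.start, locus.end))
    total = 0
    for spans in by_seq.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for start, end in spans[1:]:
            if start <= cur_end + 1:
                cur_end = max(cur_end, end)
            else:
                total += cur_end - cur_start + 1
                cur_start, cur_end = start, end
        total += cur_end - cur_start + 1
    return total


def summarize_catalogue(
    records: Sequence[ESTRecord],
    loci: Sequence[SSRLocus],
    config: DetectionConfig = DetectionConfig(),
    rounding: str = "half_up",
) -> CatalogueSummary:
    """Exact counting of every catalogue statistic.

    Percentages are reported at one decimal under the configured rounding
    mode.  `total_bases` is taken over `records` as given (the caller
    decides whether that is the raw or the trimmed/non-redundant set).
    """
    known_ids = {rec.seq_id for rec in records}
    for locus in loci:
        if locus.seq_id not in known_ids:
            raise ValueError(f"locus references unknown sequence {locus.seq_id!r}")

    n_ests = len(records)
    total_bases = sum(rec.length for rec in records)
    n_ssrs = len(loci)

    period_counts: Counter[str] = Counter()
    class_counts: dict[str, Counter[str]] = {}
    raw_counts: dict[str, Counter[str]] = {}
    hist: Counter[int] = Counter()
    per_seq: Counter[str] = Counter()
    for locus in loci:
        mc = classify_motif(locus.motif)
        period_counts[mc.period_class] += 1
        class_counts.setdefault(mc.period_class, Counter())[mc.class_label] += 1
        raw_counts.setdefault(mc.period_class, Counter())[locus.motif] += 1
        hist[locus.repeat_count] += 1
        per_seq[locus.seq_id] += 1

    per_period = {
        pc: (period_counts[pc], pct(period_counts[pc], n_ssrs, mode=rounding))
        for pc in _PERIOD_ORDER
        if period_counts[pc]
    }
    per_motif_class = {
        pc: {
            label: (cnt, pct(cnt, period_counts[pc], mode=rounding))
            for label, cnt in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
        }
        for pc, counter in class_counts.items()
    }
    per_motif_raw = {
        pc: dict(sorted(counter.items(), key=lambda kv: (-kv[1], kv[0])))
        for pc, counter in raw_counts.items()
    }

    return CatalogueSummary(
        n_ests=n_ests,
        total_bases=total_bases,
        n_ssrs=n_ssrs,
        frequency_pct=frequency_percent(n_ssrs, n_ests, mode=rounding),
        density_bp=density_bp_per_ssr(total_bases, n_ssrs) if n_ssrs else None,
        density_kb=density_kb_per_ssr(total_bases, n_ssrs) if n_ssrs else None,
        span_fraction_pct=(
            round_report(100.0 * _union_span_bases(loci) / total_bases, 3)
            if total_bases
            else 0.0
        ),
        per_period=per_period,
        per_motif_class=per_motif_class,
        per_motif_raw=per_motif_raw,
        repeat_count_hist=dict(hist),
        min_repeat_count=min(hist) if hist else None,
        max_repeat_count=max(hist) if hist else None,
        n_multi_ssr_ests=sum(1 for c in per_seq.values() if c >= 2),
    )


def write_class_tables(summary: CatalogueSummary, dest_prefix) -> None:
    """Emit per-period and per-class count tables as TSV files."""
    import pandas as pd

    rows = [
        {"period_class": pc, "count": c, "pct": p}
        for pc, (c, p) in summary.per_period.items()
    ]
    pd.DataFrame(rows).to_csv(f"{dest_prefix}_per_period.tsv", sep="\t", index=False)
    rows = [
        {"period_class": pc, "class_label": label, "count": c, "pct_within_period": p}
        for pc, classes in summary.per_motif_class.items()
        for label, (c, p) in classes.items()
    ]
    pd.DataFrame(rows).to_csv(f"{dest_prefix}_per_motif.tsv", sep="\t", index=False)
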