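"""Terminal poly-A/poly-T tract removal and dataset composition statistics.

EST reads carry mRNA poly-A tails (or poly-T on the complementary strand)
at their ends.  These homopolymer tails are sequencing artefacts, not
genomic microsatellites, so they are removed before repeat mining: the
trimmed sequence retains no A- or T-homopolymer of length >= `window`
touching either terminal `window`-base region.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

from ._rounding import pct
from .sequence_io import ESTRecord

logger = logging.getLogger("estssr")


def _poly_runs(seq: str, window: int):
    return list(re.finditer("A{%d,}|T{%d,}" % (window, window), seq))


def trim_poly_tracts(record: ESTRecord, window: int = 10) -> ESTRecord:
    """Remove terminal poly-A/poly-T tails from one record.

    Iteratively, at the 5' end: if an A- or T-homopolymer run of length
    >= `window` starts within the first `window` bases, the prefix up to and
    including that run is removed.  The mirror rule applies at the 3' end
    (a qualifying run ending within the last `window` bases removes the
    suffix from the run's first base).  Iteration handles stacked tails.

    A record trimmed to nothing is returned with an empty sequence; the
    pipeline drops and logs such records.  G/C homopolymers are never
    trimmed.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    seq = record.sequence
    while True:
        runs = _poly_runs(seq, window)
        if runs and runs[0].start() < window:
            seq = seq[runs[0].end():]
            continue
        if runs and runs[-1].end() > len(seq) - window:
            seq = seq[: runs[-1].start()]
            continue
        break
    if not seq and record.sequence:
        logger.info("record %s trimmed to empty sequence", record.seq_id)
    return record.with_sequence(seq)


@dataclass(frozen=True)
class CompositionStats:
    """Whole-dataset base composition (exact integer counts)."""

    count_A: int
    count_C: int
    count_G: int
    count_T: int
    count_N: int
    n_sequences: int

    @property
    def total_bases(self) -> int:
        return self.count_A + self.count_C + self.count_G + self.count_T + self.count_N

    @property
    def at_sum(self) -> int:
        return self.count_A + self.count_T

    @property
    def gc_sum(self) -> int:
        return self.count_G + self.count_C

    @property
    def mean_length(self) -> float:
        return self.total_bases / self.n_sequences

    def pct_of(self, count: int) -> float:
        return pct(count, self.total_bases)

    @property
    def pct_AT(self) -> float:
        return self.pct_of(self.at_sum)

    @property
    def pct_GC(self) -> float:
        return self.pct_of(self.gc_sum)

    def to_dict(self) -> dict:
        return {
            "n_sequences": self.n_sequences,
            "total_bases": self.total_bases,
            "count_A": self.count_A,
            "count_C": self.count_C,
            "count_G": self.count_G,
            "count_T": self.count_T,
            "count_N": self.count_N,
            "at_sum": self.at_sum,
            "gc_sum": self.gc_sum,
            "pct_A": self.pct_of(self.count_A),
            "pct_C": self.pct_of(self.count_C),
            "pct_G": self.pct_of(self.count_G),
            "pct_T": self.pct_of(self.count_T),
            "pct_AT": self.pct_AT,
            "pct_GC": self.pct_GC,
            "mean_length": round(self.mean_length, 1),
        }


def composition_stats(records: Sequence[ESTRecord]) -> CompositionStats:
    """Exact base counts and percentage composition over a record set."""
    if not records:
        raise ValueError("no sequences: composition of an empty set is undefined")
    counts = {b: 0 for b in "ACGTN"}
    for rec in records:
        for base in "ACGTN":
            counts[base] += rec.sequence.count(base)
    return CompositionStats(
        count_A=counts["A"], count_C=counts["C"], count_G=counts["G"],
        count_T=counts["T"], count_N=counts["N"], n_sequences=len(records),
    )
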