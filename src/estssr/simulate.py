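"""Synthetic EST sets with exhaustive, exact ground truth.

The generator emulates what a single-pass cDNA (EST) dataset looks like
to a repeat-mining pipeline: reads of a few hundred bases with a slight
A/T bias, a small fraction carrying a perfect microsatellite, terminal
poly-A/poly-T tails, exact duplicate and contained-prefix redundancy, and
the occasional read that is pure repeat with no flanks.  Every corruption
is recorded so each pipeline stage can be checked against known truth.

Planted repeats are verified by construction (substring equality at the
planted coordinates, with the neighbouring bases rewritten to break the
repeat phase), independently of any detector.  Incidental repeats that
arise by chance in background sequence are enumerated with the detector
and recorded separately, so end-to-end recovery checks can be exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .detect import DetectionConfig, SSRLocus, classify_motif, find_perfect_ssrs, primitive_motif
from .sequence_io import ESTRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimParams:
    """Study-condition defaults: mean read length 469 bp, 56% A+T bias,
    3.5% of reads carrying one planted SSR, period mix 67/31.1/1.5/0.4%
    over periods 2-5, repeat counts 5-16."""

    n_sequences: int
    seed: int
    mean_length: float = 469.0
    sd_length: float = 150.0
    min_length: int = 100
    base_probs: tuple[float, float, float, float] = (0.28, 0.22, 0.22, 0.28)  # A,C,G,T
    ssr_rate: float = 0.035
    period_mix: dict[int, float] = field(
        default_factory=lambda: {2: 0.67, 3: 0.311, 4: 0.015, 5: 0.004}
    )
    repeat_count_range: tuple[int, int] = (5, 16)
    dup_rate: float = 0.02
    containment_rate: float = 0.02
    flankless_rate: float = 0.005
    tail_rate: float = 0.2
    tail_len_range: tuple[int, int] = (10, 30)
    min_plant_flank: int = 25

    def __post_init__(self) -> None:
        if abs(sum(self.base_probs) - 1.0) > 1e-9:
            raise ValueError("base_probs must sum to 1")
        if abs(sum(self.period_mix.values()) - 1.0) > 1e-6:
            raise ValueError("period_mix must sum to 1")
        if self.dup_rate + self.containment_rate + self.flankless_rate > 1.0:
            raise ValueError("mutually exclusive corruption rates sum above 1")
        lo, hi = self.repeat_count_range
        if lo < 2 or hi < lo:
            raise ValueError("invalid repeat_count_range")


@dataclass(frozen=True)
class PlantedLocus:
    seq_id: str
    motif: str
    period: int
    repeat_count: int
    start: int  # 1-based, in the untailed sequence

    @property
    def end(self) -> int:
        return self.start + self.period * self.repeat_count - 1

    def as_locus(self) -> SSRLocus:
        return SSRLocus(
            seq_id=self.seq_id, motif=self.motif, period=self.period,
            repeat_count=self.repeat_count, start=self.start, end=self.end,
        )


@dataclass
class SyntheticTruth:
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    incidental_loci: list[SSRLocus] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    flankless_ids: list[str] = field(default_factory=list)
    tailed_ids: list[tuple[str, str, str, int]] = field(default_factory=list)

    @property
    def per_class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for planted in self.planted_loci:
            label = classify_motif(planted.motif).class_label
            counts[label] = counts.get(label, 0) + 1
        return counts

    @property
    def all_expected_loci(self) -> list[SSRLocus]:
        """Planted plus incidental loci on the untailed base sequences."""
        return [p.as_locus() for p in self.planted_loci] + list(self.incidental_loci)


def _random_seq(rng: np.random.Generator, length: int, probs) -> str:
    return "".join(rng.choice(_BASES, size=length, p=list(probs)))


def _random_primitive_motif(rng: np.random.Generator, period: int) -> str:
    while True:
        motif = "".join(rng.choice(_BASES, size=period))
        if len(primitive_motif(motif)) == period:
            return motif


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in "ACGT" if b not in avoid]
    return str(rng.choice(choices))


def plant_ssr(
    background: str,
    motif: str,
    repeat_count: int,
    position: int,
    rng: np.random.Generator | None = None,
) -> str:
    """Insert motif*repeat_count into `background` at 0-based `position`.

    The bases adjacent to the inserted run are rewritten if they would
    extend the repeat in phase, so the planted run is maximal and the
    detected count equals `repeat_count` exactly.  `position` must leave
    at least one base of flank on each side.
    """
    if primitive_motif(motif) != motif:
        raise ValueError("motif must be primitive")
    if not (1 <= position <= len(background) - 1):
        raise ValueError("position must leave >= 1 base flank on each side")
    rng = rng if rng is not None else np.random.default_rng(0)
    run = motif * repeat_count
    left, right = background[:position], background[position:]
    if left[-1] == motif[-1]:  # would extend the run leftward in phase
        left = left[:-1] + _other_base(rng, motif[-1])
    if right[0] == motif[0]:  # would extend rightward
        right = _other_base(rng, motif[0]) + right[1:]
    return left + run + right


def _has_terminal_poly(seq: str, window: int = 10) -> bool:
    import re

    for m in re.finditer("A{%d,}|T{%d,}" % (window, window), seq):
        if m.start() < window or m.end() > len(seq) - window:
            return True
    return False


def simulate_est_set(params: SimParams) -> tuple[list[ESTRecord], SyntheticTruth]:
    """Generate an EST-like record set plus its exact truth.

    Fully reproducible from ``params.seed``: the same parameters always
    yield byte-identical sequences.
    """
    rng = np.random.default_rng(params.seed)
    truth = SyntheticTruth()
    records: list[ESTRecord] = []
    base_records: list[ESTRecord] = []  # untailed, for redundancy corruptions
    detect_cfg = DetectionConfig()

    for i in range(params.n_sequences):
        seq_id = f"SYN{i:05d}"
        while True:
            length = int(rng.normal(params.mean_length, params.sd_length))
            length = max(length, params.min_length)
            seq = _random_seq(rng, length, params.base_probs)
            if _has_terminal_poly(seq):  # would be eaten by tail trimming
                continue
            planted: PlantedLocus | None = None
            if rng.random() < params.ssr_rate:
                period = int(
                    rng.choice(
                        list(params.period_mix), p=list(params.period_mix.values())
                    )
                )
                motif = _random_primitive_motif(rng, period)
                count = int(rng.integers(*params.repeat_count_range, endpoint=True))
                lo = params.min_plant_flank
                hi = len(seq) - params.min_plant_flank
                position = int(rng.integers(lo, hi + 1))
                seq = plant_ssr(seq, motif, count, position, rng)
                if _has_terminal_poly(seq):
                    continue
                planted = PlantedLocus(seq_id, motif, period, count, position + 1)
            break
        # decide tail first; the base next to a tail must differ from the
        # tail base (C/G so no new A/T run forms) so trimming restores the
        # untailed sequence exactly and truth coordinates stay valid
        tail: tuple[str, str, int] | None = None
        if rng.random() < params.tail_rate:
            tail_len = int(rng.integers(*params.tail_len_range, endpoint=True))
            if rng.random() < 0.5:
                tail = ("3'", "A", tail_len)  # mRNA poly-A
                if seq[-1] == "A":
                    seq = seq[:-1] + _other_base(rng, "A", "T")
            else:
                tail = ("5'", "T", tail_len)  # reverse-strand read
                if seq[0] == "T":
                    seq = _other_base(rng, "A", "T") + seq[1:]

        if planted is not None:
            truth.planted_loci.append(planted)
        rec = ESTRecord(seq_id, seq)
        base_records.append(rec)
        planted_key = (
            {(planted.start, planted.end)} if planted is not None else set()
        )
        for locus in find_perfect_ssrs(rec, detect_cfg):
            if (locus.start, locus.end) not in planted_key:
                truth.incidental_loci.append(locus)

        out_seq = seq
        if tail is not None:
            tail_end, tail_base, tail_len = tail
            if tail_end == "3'":
                out_seq = out_seq + tail_base * tail_len
            else:
                out_seq = tail_base * tail_len + out_seq
            truth.tailed_ids.append((seq_id, tail_end, tail_base, tail_len))
        records.append(ESTRecord(seq_id, out_seq))

    # redundancy corruptions refer to the untailed base sequences
    n_extra = 0
    for rec in list(base_records):
        roll = rng.random()
        if roll < params.dup_rate:
            dup_id = f"{rec.seq_id}_DUP{n_extra}"
            records.append(ESTRecord(dup_id, rec.sequence))
            truth.duplicate_pairs.append((rec.seq_id, dup_id, "identical"))
            n_extra += 1
        elif roll < params.dup_rate + params.containment_rate:
            if rec.length < 2 * params.min_length:
                continue
            cut = int(rng.integers(params.min_length, rec.length))
            sub_id = f"{rec.seq_id}_SUB{n_extra}"
            records.append(ESTRecord(sub_id, rec.sequence[:cut]))
            truth.duplicate_pairs.append((rec.seq_id, sub_id, "contained"))
            n_extra += 1

    n_flankless = int(round(params.flankless_rate * params.n_sequences))
    for k in range(n_flankless):
        period = int(
            rng.choice(list(params.period_mix), p=list(params.period_mix.values()))
        )
        motif = _random_primitive_motif(rng, period)
        count = int(rng.integers(*params.repeat_count_range, endpoint=True))
        seq_id = f"SYNFL{k:03d}"
        records.append(ESTRecord(seq_id, motif * count))
        truth.flankless_ids.append(seq_id)

    return records, truth


def write_truth_table(truth: SyntheticTruth, dest) -> None:
    """Planted-locus truth as TSV (seq_id, motif, period, repeat_count, start, end)."""
    from pathlib import Path

    close = isinstance(dest, (str, Path))
    handle = open(dest, "w", encoding="ascii") if close else dest
    try:
        handle.write("seq_id\tmotif\tperiod\trepeat_count\tstart\tend\n")
        for p in truth.planted_loci:
            handle.write(
                f"{p.seq_id}\t{p.motif}\t{p.period}\t{p.repeat_count}\t{p.start}\t{p.end}\n"
            )
    finally:
        if close:
            handle.close()
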