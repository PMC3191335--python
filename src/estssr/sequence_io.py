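"""FASTA input/output and the core EST record type.

All coordinates in emitted tables are 1-based inclusive, the convention in
which a microsatellite written "(CA)15 at 3-12" is read by biologists.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger("estssr")

_VALID = set("ACGTN")
_WRAP = 70


class FastaFormatError(ValueError):
    """Malformed FASTA input (sequence before header, duplicate id, ...)."""


@dataclass(frozen=True)
class ESTRecord:
    """One EST-like DNA sequence.

    The sequence is stored uppercase over the alphabet {A, C, G, T, N};
    any other IUPAC ambiguity code is normalized to N with a warning.
    """

    seq_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.seq_id:
            raise ValueError("seq_id must be non-empty")
        seq = self.sequence.upper()
        if set(seq) - _VALID:
            bad = sorted(set(seq) - _VALID)
            logger.warning(
                "record %s: mapping non-ACGTN characters %s to N", self.seq_id, bad
            )
            seq = "".join(c if c in _VALID else "N" for c in seq)
        object.__setattr__(self, "sequence", seq)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def with_sequence(self, sequence: str) -> "ESTRecord":
        return ESTRecord(self.seq_id, sequence, self.description)


def _as_text_handle(source: Union[str, Path, TextIO]) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="ascii")
    return source


def parse_fasta(source: Union[str, Path, TextIO]) -> list[ESTRecord]:
    """Parse FASTA text into records.

    The record id is the first whitespace-delimited token of the header;
    the rest of the header becomes the description.  Lowercase sequence is
    accepted and uppercased; line wrapping is arbitrary.

    Raises :class:`FastaFormatError` on a duplicate id or on sequence text
    appearing before any ``>`` header (reported with its line number).
    """
    handle = _as_text_handle(source)
    close = isinstance(source, (str, Path))
    try:
        text = handle.read()
    finally:
        if close:
            handle.close()

    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise FastaFormatError(
                f"line {lineno}: sequence data before any '>' header"
            )
        break

    records: list[ESTRecord] = []
    seen: set[str] = set()
    for title, seq in SimpleFastaParser(io.StringIO(text)):
        parts = title.split(None, 1)
        if not parts:
            raise FastaFormatError("FASTA header with empty id")
        seq_id = parts[0]
        desc = parts[1] if len(parts) > 1 else ""
        if seq_id in seen:
            raise FastaFormatError(f"duplicate sequence id: {seq_id!r}")
        seen.add(seq_id)
        records.append(ESTRecord(seq_id, seq, desc))
    if not records:
        logger.warning("no FASTA records found in input")
    return records


def write_fasta(
    records: Iterable[ESTRecord],
    dest: Union[str, Path, TextIO],
    wrap: int = _WRAP,
) -> None:
    """Write records as FASTA, sequences wrapped at `wrap` columns."""
    handle = open(dest, "w", encoding="ascii") if isinstance(dest, (str, Path)) else dest
    close = isinstance(dest, (str, Path))
    try:
        for rec in records:
            header = f">{rec.seq_id}"
            if rec.description:
                header += f" {rec.description}"
            handle.write(header + "\n")
            seq = rec.sequence
            for i in range(0, max(len(seq), 1), wrap):
                handle.write(seq[i : i + wrap] + "\n")
    finally:
        if close:
            handle.close()


def write_loci_table(loci: Sequence, dest: Union[str, Path, TextIO]) -> None:
    """Write detected repeat loci as a TSV table.

    Columns: seq_id, motif, class_label, period, repeat_count, start, end,
    span_length.  Rows ordered by (seq_id, start).
    """
    from .detect import classify_motif  # local import to avoid a cycle

    handle = open(dest, "w", encoding="ascii") if isinstance(dest, (str, Path)) else dest
    close = isinstance(dest, (str, Path))
    header = [
        "seq_id", "motif", "class_label", "period",
        "repeat_count", "start", "end", "span_length",
    ]
    try:
        handle.write("\t".join(header) + "\n")
        for locus in sorted(loci, key=lambda l: (l.seq_id, l.start, l.end)):
            label = classify_motif(locus.motif).class_label
            row = [
                locus.seq_id, locus.motif, label, str(locus.period),
                str(locus.repeat_count), str(locus.start), str(locus.end),
                str(locus.span_length),
            ]
            handle.write("\t".join(row) + "\n")
    finally:
        if close:
            handle.close()
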