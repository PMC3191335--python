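"""End-to-end mining pipeline: trim -> detect -> redundancy -> summarize
-> primer design, with a fixed on-disk output layout.

Stage order: poly-A/T trimming, repeat detection, discarding flankless
repeat-only records, then duplicate/containment clustering (an alternative
order with deduplication first is available for sensitivity checks).
Counts reconcile at every filter: input = kept + dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

from .detect import DetectionConfig, SSRLocus, find_perfect_ssrs
from .preprocess import CompositionStats, composition_stats, trim_poly_tracts
from .primers import DesignResult, PrimerCandidate, PrimerConstraints, design_primers, write_marker_sheet
from .redundancy import RedundancyReport, combine_reports, deduplicate, drop_flankless
from .sequence_io import ESTRecord, parse_fasta, write_loci_table
from .summarize import CatalogueSummary, summarize_catalogue

logger = logging.getLogger("estssr")


@dataclass(frozen=True)
class PipelineConfig:
    input_path: str
    output_dir: str
    detection: DetectionConfig = DetectionConfig()
    primer_constraints: PrimerConstraints = PrimerConstraints()
    trim_window: int = 10
    rounding: str = "half_up"
    density_basis: str = "analyzed"  # or "raw"
    dedup_first: bool = False

    def __post_init__(self) -> None:
        if self.density_basis not in ("analyzed", "raw"):
            raise ValueError("density_basis must be 'analyzed' or 'raw'")


@dataclass
class MiningResult:
    """In-memory artifacts of one pipeline run."""

    records_kept: list[ESTRecord]
    loci: list[SSRLocus]
    summary: CatalogueSummary
    composition: CompositionStats
    redundancy: RedundancyReport
    n_trimmed_empty: int
    primer_designs: list[tuple[SSRLocus, DesignResult]]

    @property
    def markers(self) -> list[tuple[str, ESTRecord, SSRLocus, PrimerCandidate]]:
        by_id = {r.seq_id: r for r in self.records_kept}
        rows = []
        k = 0
        for locus, result in self.primer_designs:
            if result.best is not None:
                k += 1
                rows.append((f"MK{k}", by_id[locus.seq_id], locus, result.best))
        return rows


def mine_records(
    records: Sequence[ESTRecord],
    detection: DetectionConfig = DetectionConfig(),
    primer_constraints: PrimerConstraints = PrimerConstraints(),
    trim_window: int = 10,
    rounding: str = "half_up",
    density_basis: str = "analyzed",
    dedup_first: bool = False,
    design: bool = True,
) -> MiningResult:
    """Run the full mining pipeline on in-memory records."""
    raw_total = sum(r.length for r in records)

    trimmed = [trim_poly_tracts(r, trim_window) for r in records]
    kept = [r for r in trimmed if r.length > 0]
    n_empty = len(trimmed) - len(kept)
    logger.info("trimming: %d records in, %d dropped as empty", len(records), n_empty)
    if not kept:
        raise ValueError("no sequences survived trimming")

    loci_by_seq = {r.seq_id: find_perfect_ssrs(r, detection) for r in kept}
    n_loci = sum(len(v) for v in loci_by_seq.values())
    logger.info("detection: %d loci on %d records", n_loci, len(kept))

    if dedup_first:
        kept, rep_a = deduplicate(kept)
        kept, rep_b = drop_flankless(kept, loci_by_seq)
    else:
        kept, rep_a = drop_flankless(kept, loci_by_seq)
        kept, rep_b = deduplicate(kept)
    redundancy = combine_reports(rep_a, rep_b)
    logger.info(
        "redundancy: %d kept, %d duplicate, %d flankless",
        redundancy.n_kept,
        redundancy.n_dropped_duplicate,
        redundancy.n_dropped_flankless,
    )

    loci = [l for r in kept for l in loci_by_seq[r.seq_id]]
    composition = composition_stats(kept)
    summary = summarize_catalogue(kept, loci, detection, rounding=rounding)
    if density_basis == "raw" and loci:
        from .summarize import density_bp_per_ssr, density_kb_per_ssr

        summary = CatalogueSummary(
            **{
                **summary.__dict__,
                "density_bp": density_bp_per_ssr(raw_total, len(loci)),
                "density_kb": density_kb_per_ssr(raw_total, len(loci)),
            }
        )

    designs: list[tuple[SSRLocus, DesignResult]] = []
    if design:
        by_id = {r.seq_id: r for r in kept}
        for locus in loci:
            rec = by_id[locus.seq_id]
            result = design_primers(
                rec, locus, primer_constraints,
                exclusion_loci=loci_by_seq[locus.seq_id],
            )
            designs.append((locus, result))
        n_ok = sum(1 for _, res in designs if res.best is not None)
        logger.info("primer design: %d of %d loci yielded a pair", n_ok, len(designs))

    return MiningResult(
        records_kept=kept,
        loci=loci,
        summary=summary,
        composition=composition,
        redundancy=redundancy,
        n_trimmed_empty=n_empty,
        primer_designs=designs,
    )


def run_pipeline(config: PipelineConfig) -> MiningResult:
    """Run the pipeline on a FASTA file and write all artifacts.

    Writes loci.tsv, summary.json, markers.tsv, redundancy.tsv and
    resolved_config.json into the output directory.
    """
    records = parse_fasta(config.input_path)
    result = mine_records(
        records,
        detection=config.detection,
        primer_constraints=config.primer_constraints,
        trim_window=config.trim_window,
        rounding=config.rounding,
        density_basis=config.density_basis,
        dedup_first=config.dedup_first,
    )
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_loci_table(result.loci, outdir / "loci.tsv")
    write_marker_sheet(result.markers, outdir / "markers.tsv")

    summary_doc = {
        "composition": result.composition.to_dict(),
        "redundancy": result.redundancy.to_dict(),
        "catalogue": result.summary.to_dict(),
        "n_trimmed_empty": result.n_trimmed_empty,
    }
    (outdir / "summary.json").write_text(json.dumps(summary_doc, indent=2) + "\n")

    with open(outdir / "redundancy.tsv", "w") as fh:
        fh.write("representative\tmembers\n")
        for rep, members in result.redundancy.clusters:
            fh.write(f"{rep}\t{','.join(members)}\n")

    resolved = {
        "input_path": config.input_path,
        "output_dir": config.output_dir,
        "detection": asdict(config.detection),
        "primer_constraints": asdict(config.primer_constraints),
        "trim_window": config.trim_window,
        "rounding": config.rounding,
        "density_basis": config.density_basis,
        "dedup_first": config.dedup_first,
    }
    (outdir / "resolved_config.json").write_text(json.dumps(resolved, indent=2) + "\n")
    return result
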