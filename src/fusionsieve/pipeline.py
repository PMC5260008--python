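"""End-to-end orchestration of the prioritization cascade.

Stage order: sample-centred regrouping -> duplicate collapsing and
recurrence labeling -> unannotated-partner filter -> normal-shared filter
-> split-read filter -> junction-structure analysis -> driver-score
attachment -> priority marking.  Every stage logs the record count entering
and leaving it, per sample; re-running on identical inputs yields
byte-identical reports (the pipeline proper has no randomness).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence, Union

from .aggregate import collapse_duplicates, group_by_sample, label_recurrence
from .filters import filter_normal, filter_split_reads, filter_unannotated
from .ingest import (
    GenomeAccessor,
    read_fusions,
    read_score_table,
    write_report,
)
from .model import (
    FusionRecord,
    PipelineConfig,
    SampleReport,
    validate_record,
)
from .prioritize import attach_scores, mark_priority
from .structure import build_virtual_references, classify_fusion

__all__ = ["run_pipeline", "PipelineResult", "STAGE_NAMES"]

logger = logging.getLogger("fusionsieve")

#: removal_stage values used in reports, in cascade order
STAGE_NAMES = ("unannotated", "shared_with_normal", "no_split_reads")

PathLike = Union[str, Path]


class PipelineResult:
    """Reports plus the per-sample stage accounting behind the run log."""

    def __init__(self) -> None:
        self.reports: dict[str, SampleReport] = {}
        self.stage_counts: dict[str, dict[str, int]] = {}
        self.report_paths: dict[str, Path] = {}

    def totals(self) -> dict[str, int]:
        """Stage counts summed over samples."""
        out: dict[str, int] = {}
        for counts in self.stage_counts.values():
            for k, v in counts.items():
                out[k] = out.get(k, 0) + v
        return out


def _log(sample: str, stage: str, n_in: int, n_out: int) -> None:
    logger.info("[sample %s] stage %s: %d -> %d", sample, stage, n_in, n_out)


def run_pipeline(
    genome: Union[GenomeAccessor, PathLike],
    tumor_tables: Sequence[PathLike],
    outdir: PathLike,
    normal_tables: Sequence[PathLike] = (),
    score_table: Optional[PathLike] = None,
    config: Optional[PipelineConfig] = None,
    dialect: str = "generic",
) -> PipelineResult:
    """Run the full cascade and write one report file per sample.

    ``tumor_tables`` (and ``normal_tables``) are fusion-call TSVs in
    ``dialect``; the union of all tumor tables is analysed sample by
    sample.  With no normal tables the normal-subtraction stage is a no-op
    (and logged as such); with no score table prioritization is
    structure-only.
    """
    config = config or PipelineConfig()
    if not isinstance(genome, GenomeAccessor):
        genome = GenomeAccessor(genome)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    records: list[FusionRecord] = []
    for path in tumor_tables:
        records.extend(read_fusions(path, dialect=dialect))
    for r in records:
        validate_record(r)

    normal_records: list[FusionRecord] = []
    for path in normal_tables:
        normal_records.extend(read_fusions(path, dialect=dialect))
    normal_groups = group_by_sample(normal_records)
    normal_collapsed: list[FusionRecord] = []
    for sample_id in sorted(normal_groups):
        normal_collapsed.extend(collapse_duplicates(normal_groups[sample_id]))

    scores = read_score_table(score_table) if score_table is not None else {}

    # B: sample-centred regrouping; C: collapse + recurrence
    groups = group_by_sample(records)
    collapsed: dict[str, list[FusionRecord]] = {}
    for sample_id in sorted(groups):
        n_in = len(groups[sample_id])
        collapsed[sample_id] = collapse_duplicates(groups[sample_id])
        _log(sample_id, "collapse_duplicates", n_in, len(collapsed[sample_id]))
    label_recurrence(collapsed)

    result = PipelineResult()
    for sample_id in sorted(collapsed):
        current = collapsed[sample_id]
        counts = {
            "input_records": len(groups[sample_id]),
            "after_collapse": len(current),
        }
        report = SampleReport(sample_id=sample_id)

        kept, removed = filter_unannotated(current, config.exclude_prefixes)
        _log(sample_id, "filter_unannotated", len(current), len(kept))
        counts["removed_unannotated"] = len(removed)
        report.removed.extend((r, "unannotated") for r in removed)
        current = kept

        if normal_collapsed:
            kept, removed = filter_normal(current, normal_collapsed)
        else:
            kept, removed = current, []
            logger.info("[sample %s] stage filter_normal: no normal tables, no-op", sample_id)
        _log(sample_id, "filter_normal", len(current) if normal_collapsed else len(kept), len(kept))
        counts["removed_normal"] = len(removed)
        report.removed.extend((r, "shared_with_normal") for r in removed)
        current = kept

        kept, removed = filter_split_reads(current)
        _log(sample_id, "filter_split_reads", len(current), len(kept))
        counts["removed_no_split"] = len(removed)
        report.removed.extend((r, "no_split_reads") for r in removed)
        current = kept
        counts["retained"] = len(current)

        # I: structure analysis on the survivors
        for r in current:
            refs = build_virtual_references(genome, r, config.flank_len)
            r.structure = classify_fusion(
                r, refs, config.min_overlap, config.tie_break_order
            )
        n_reliable = sum(
            1 for r in current if r.structure is not None and r.structure.label in ("PROM_END", "PROM_PROM")
        )
        _log(sample_id, "structure_analysis", len(current), n_reliable)
        counts["reliable"] = n_reliable

        # scores + L: priority marking
        if scores:
            attach_scores(current, scores)
        for r in current:
            mark_priority(r, config.driver_threshold)
        counts["priority"] = sum(1 for r in current if "priority" in r.flags)
        _log(sample_id, "mark_priority", len(current), counts["priority"])

        report.retained = current
        result.reports[sample_id] = report
        result.stage_counts[sample_id] = counts
        path = outdir / f"{sample_id}_report.tsv"
        write_report(report, path)
        result.report_paths[sample_id] = path

    return result
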