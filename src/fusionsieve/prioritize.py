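"""Driver-score handling and the final priority rule.

The two driver-score classifiers (a gradient-boosting model and a Naive
Bayes model) are external trained artifacts: their per-fusion probabilities
are consumed as inputs, never recomputed.  This module formats the
coordinate file one of them expects, attaches externally computed scores to
records, and applies the final union rule: a fusion is *priority* when its
structure is biologically reliable and/or either driver score strictly
exceeds the threshold.
"""

from __future__ import annotations

import csv
from typing import Iterable, Union
from pathlib import Path

from .model import FusionRecord, TISSUES, ValidationError, fusion_key
from .structure import is_reliable

__all__ = ["format_oncofuse_input", "attach_scores", "mark_priority"]


def format_oncofuse_input(
    records: Iterable[FusionRecord], tissue: str, path: Union[str, Path]
) -> None:
    """Write the 5-column coordinate file the driver-score classifier
    expects: chrom5, bp5, chrom3, bp3, tissue label (EPI, HEM, MES or AVG).
    """
    if tissue not in TISSUES:
        raise ValidationError(f"tissue must be one of {sorted(TISSUES)}, got {tissue!r}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for r in records:
            writer.writerow(
                [r.gene5.chrom, r.gene5.breakpoint, r.gene3.chrom, r.gene3.breakpoint, tissue]
            )


def attach_scores(
    records: list[FusionRecord],
    score_table: dict[tuple, dict[str, float]],
) -> list[FusionRecord]:
    """Set score fields on records whose fusion key appears in the table.

    ``score_table`` maps (gene5, gene3, bp5, bp3) to {source: score} with
    source in {pegasus, oncofuse}.  Unmatched records keep their scores
    absent — absent means "unscored", which never counts as "scored low".
    """
    for scores in score_table.values():
        for source, score in scores.items():
            if source not in ("pegasus", "oncofuse"):
                raise ValidationError(f"unknown score source {source!r}")
            if not (0.0 <= score <= 1.0):
                raise ValidationError(f"score must be in [0, 1], got {score}")
    for r in records:
        scores = score_table.get(fusion_key(r))
        if scores:
            if "pegasus" in scores:
                r.score_pegasus = scores["pegasus"]
            if "oncofuse" in scores:
                r.score_oncofuse = scores["oncofuse"]
    return records


def mark_priority(record: FusionRecord, threshold: float) -> FusionRecord:
    """Apply the final union rule and set the ``priority`` flag.

    Priority iff the structure is reliable OR either driver score is
    strictly greater than ``threshold``.  An absent score never exceeds the
    threshold.  The record must already carry a structure call.
    """
    if record.structure is None:
        raise ValidationError("mark_priority requires a structure call on the record")
    high_score = any(
        score is not None and score > threshold
        for score in (record.score_pegasus, record.score_oncofuse)
    )
    if is_reliable(record.structure):
        record.add_flag("reliable_structure")
    if "reliable_structure" in record.flags or high_score:
        record.add_flag("priority")
    return record
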