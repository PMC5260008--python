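"""The three removal filters of the cascade, with full provenance.

Each filter partitions its input into (kept, removed) — nothing is silently
dropped — and flags removed records with the reason:

* unannotated partners: either gene lacks annotation or its name starts
  with one of the configured prefixes (clone-based symbols, LOC numbers,
  HLA loci, ...);  no driver role can be hypothesized for such fusions;
* shared with normals: the same fusion key occurs in any healthy-sample
  call table, so it is unlikely to drive the tumor;
* no split reads: without at least one read crossing the junction the
  fusion sequence cannot be reconstructed or validated by PCR.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import FusionRecord, ValidationError, fusion_key

__all__ = ["filter_unannotated", "filter_normal", "filter_split_reads"]

Partition = tuple[list[FusionRecord], list[FusionRecord]]


def filter_unannotated(
    records: Iterable[FusionRecord], exclude_prefixes: Sequence[str]
) -> Partition:
    """Remove fusions with an unannotated partner gene.

    A record is removed iff either partner is marked unannotated or its
    gene name starts with any of ``exclude_prefixes`` (plain case-sensitive
    prefix test).
    """
    kept: list[FusionRecord] = []
    removed: list[FusionRecord] = []
    for r in records:
        bad = any(
            (not p.annotated) or any(p.gene_name.startswith(pre) for pre in exclude_prefixes)
            for p in (r.gene5, r.gene3)
        )
        if bad:
            r.add_flag("unannotated_partner")
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def filter_normal(
    tumor_records: Iterable[FusionRecord],
    normal_records: Iterable[FusionRecord],
) -> Partition:
    """Remove tumor fusions whose key occurs in any healthy sample (pooled)."""
    normal_keys = {fusion_key(r) for r in normal_records}
    kept: list[FusionRecord] = []
    removed: list[FusionRecord] = []
    for r in tumor_records:
        if fusion_key(r) in normal_keys:
            r.add_flag("shared_with_normal")
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


def filter_split_reads(records: Iterable[FusionRecord]) -> Partition:
    """Keep fusions supported by at least one split read."""
    kept: list[FusionRecord] = []
    removed: list[FusionRecord] = []
    for r in records:
        if r.split_read_count < 0:
            raise ValidationError(
                f"split_read_count must be >= 0, got {r.split_read_count}"
            )
        if r.split_read_count >= 1:
            kept.append(r)
        else:
            r.add_flag("no_split_reads")
            removed.append(r)
    return kept, removed
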