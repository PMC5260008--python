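"""Sample-centred regrouping, duplicate collapsing and recurrence labeling.

A discovery tool can report the same fusion in the same sample several
times, supported by different reads; such duplicates are merged into one
record.  Independently, a fusion found by more than one tool in a sample
(multi-tool) or in more than one sample of the cohort (shared, as opposed to
private) is more likely real, so both kinds of recurrence are recorded on
the records without ever changing their number.
"""

from __future__ import annotations

from typing import Iterable

from .model import FusionRecord, ValidationError, fusion_key

__all__ = ["group_by_sample", "collapse_duplicates", "label_recurrence"]


def group_by_sample(records: Iterable[FusionRecord]) -> dict[str, list[FusionRecord]]:
    """Partition records by sample_id, preserving input order within groups."""
    groups: dict[str, list[FusionRecord]] = {}
    for r in records:
        groups.setdefault(r.sample_id, []).append(r)
    return groups


def collapse_duplicates(records: list[FusionRecord]) -> list[FusionRecord]:
    """Merge same-tool duplicates of one sample's records.

    Records agreeing on (tool, gene pair, both breakpoints) are one fusion
    reported with different supporting reads: their split reads are unioned
    (deduplicated, order of first appearance), the spanning count is the
    max, the consensus is kept from the first record in input order, and the
    merged record is flagged ``duplicate_collapsed``.  The split-read count
    becomes the size of the read union; when none of the merged records
    carries read sequences (consensus-only callers) the max of their counts
    is kept instead, so collapsing never fabricates a zero-support fusion.
    """
    samples = {r.sample_id for r in records}
    if len(samples) > 1:
        raise ValidationError(
            f"collapse_duplicates expects a single sample, got {sorted(samples)}"
        )
    merged: dict[tuple, FusionRecord] = {}
    counts: dict[tuple, int] = {}
    for r in records:
        key = (r.tool_id,) + fusion_key(r)
        if key not in merged:
            merged[key] = r.copy()
            counts[key] = 1
            continue
        counts[key] += 1
        m = merged[key]
        for read in r.split_reads:
            if read not in m.split_reads:
                m.split_reads.append(read)
        if m.split_reads:
            m.split_read_count = len(m.split_reads)
        else:
            m.split_read_count = max(m.split_read_count, r.split_read_count)
        m.spanning_read_count = max(m.spanning_read_count, r.spanning_read_count)
        if m.consensus_sequence is None:
            m.consensus_sequence = r.consensus_sequence
        m.flags |= r.flags
        m.add_flag("duplicate_collapsed")
    # a record whose reads were already deduplicated keeps a consistent count
    for key, m in merged.items():
        if counts[key] > 1 and m.split_reads:
            m.split_read_count = len(m.split_reads)
    return list(merged.values())


def label_recurrence(
    groups: dict[str, list[FusionRecord]]
) -> dict[str, list[FusionRecord]]:
    """Flag cross-tool and cross-sample recurrence in place.

    Within each sample, records whose fusion key is reported by more than
    one tool get ``multi_tool`` and the full tool list; across samples,
    records whose key occurs in more than one sample get ``shared_sample``
    and the sample list (private fusions keep a singleton list).  Record
    counts never change.
    """
    key_samples: dict[tuple, set[str]] = {}
    for sample_id, records in groups.items():
        for r in records:
            key_samples.setdefault(fusion_key(r), set()).add(sample_id)

    for sample_id, records in groups.items():
        key_tools: dict[tuple, set[str]] = {}
        for r in records:
            key_tools.setdefault(fusion_key(r), set()).add(r.tool_id)
        for r in records:
            key = fusion_key(r)
            r.tools = sorted(key_tools[key])
            if len(r.tools) > 1:
                r.add_flag("multi_tool")
            r.samples_sharing = sorted(key_samples[key])
            if len(r.samples_sharing) > 1:
                r.add_flag("shared_sample")
    return groups
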