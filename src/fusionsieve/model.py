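"""Domain types shared by every stage of the fusion-prioritization cascade.

A *fusion* joins a 5' partner gene (contributing its promoter-proximal
portion) to a 3' partner gene (contributing its 3'-end portion) at a pair of
genomic breakpoints.  One :class:`FusionRecord` is one candidate fusion as
reported by one discovery tool in one sample; the cascade annotates it with
flags as it passes (or fails) each stage, so that every removal is auditable.

Coordinates are 1-based inclusive everywhere inside the package; dialect
adapters normalize on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "ValidationError",
    "GenePartner",
    "FusionRecord",
    "StructureCall",
    "PipelineConfig",
    "SampleReport",
    "STRUCTURE_LABELS",
    "ALL_LABELS",
    "NO_MATCH",
    "FLAGS",
    "TISSUES",
    "DEFAULT_EXCLUDE_PREFIXES",
    "validate_record",
    "fusion_key",
]

#: The four junction-structure hypotheses: which portion (promoter side or
#: 3'-end side) of each partner gene is retained in the chimeric transcript.
STRUCTURE_LABELS: tuple[str, ...] = ("PROM_END", "END_PROM", "PROM_PROM", "END_END")
NO_MATCH = "NO_MATCH"
ALL_LABELS: tuple[str, ...] = STRUCTURE_LABELS + (NO_MATCH,)

#: Provenance flags a record can accumulate.  Flags are only ever added,
#: never cleared, so the final record tells the full story of its run.
FLAGS: frozenset[str] = frozenset(
    {
        "duplicate_collapsed",
        "multi_tool",
        "shared_sample",
        "shared_with_normal",
        "no_split_reads",
        "unannotated_partner",
        "reliable_structure",
        "priority",
    }
)

#: Tissue-of-origin labels accepted by the driver-score input formatter:
#: epithelial, hematological, mesenchymal, or average expression (unknown).
TISSUES: frozenset[str] = frozenset({"EPI", "HEM", "MES", "AVG"})

#: Gene-name prefixes marking unannotated / uninteresting partner genes
#: (clone-based and provisional symbols, non-coding RNA catalogues, HLA and
#: RNase loci).  A fusion is dropped when either partner matches.
DEFAULT_EXCLUDE_PREFIXES: tuple[str, ...] = (
    "AC0",
    "AC1",
    "AK",
    "AD0",
    "AL0",
    "AL1",
    "AL5",
    "AL6",
    "AP0",
    "NCRNA",
    "LL22NC",
    "CTC",
    "RNASE",
    "HLA",
    "BC0",
    "BC1",
    "LOC",
)

_DNA = frozenset("ACGTN")


class ValidationError(ValueError):
    """A record or configuration value violates a type invariant."""


@dataclass
class GenePartner:
    """One side of a fusion: gene symbol, locus and breakpoint.

    ``breakpoint`` is the 1-based genomic coordinate of the last retained
    transcribed base (5' partner) or the first retained transcribed base
    (3' partner).  ``annotated`` is False for genes lacking functional
    annotation; such fusions are filtered out.
    """

    gene_name: str
    chrom: str
    strand: str
    breakpoint: int
    annotated: bool = True


@dataclass
class StructureCall:
    """Assigned junction structure with the best overlap per hypothesis.

    ``best_overlap`` maps each reference kind to the longest junction-
    spanning exact match (in bp) achieved by any query sequence of the
    fusion.  ``label`` is NO_MATCH when no hypothesis reached the minimum
    overlap.
    """

    label: str
    best_overlap: dict[str, int]


@dataclass
class FusionRecord:
    """One candidate fusion from one tool in one sample."""

    sample_id: str
    tool_id: str
    gene5: GenePartner
    gene3: GenePartner
    split_read_count: int = 0
    spanning_read_count: int = 0
    split_reads: list[str] = field(default_factory=list)
    consensus_sequence: Optional[str] = None
    score_pegasus: Optional[float] = None
    score_oncofuse: Optional[float] = None
    annotation_passthrough: dict[str, str] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)
    structure: Optional[StructureCall] = None
    #: tools that reported this fusion in this sample (filled by recurrence
    #: labeling; always contains at least tool_id afterwards)
    tools: list[str] = field(default_factory=list)
    #: samples of the cohort in which this fusion key occurs
    samples_sharing: list[str] = field(default_factory=list)

    @property
    def n_samples_sharing(self) -> int:
        return max(1, len(self.samples_sharing))

    def add_flag(self, flag: str) -> None:
        if flag not in FLAGS:
            raise ValidationError(f"unknown flag: {flag!r}")
        self.flags.add(flag)

    def copy(self) -> "FusionRecord":
        return replace(
            self,
            gene5=replace(self.gene5),
            gene3=replace(self.gene3),
            split_reads=list(self.split_reads),
            annotation_passthrough=dict(self.annotation_passthrough),
            flags=set(self.flags),
            tools=list(self.tools),
            samples_sharing=list(self.samples_sharing),
        )


@dataclass
class PipelineConfig:
    """All tunables of the cascade.

    flank_len
        Length in bp of each breakpoint-flanking segment used to build the
        virtual junction references (each reference is ``2 * flank_len``).
    min_overlap
        Minimum junction-spanning exact overlap (bp) between a read or
        consensus sequence and a virtual reference required to label the
        fusion with that structure.
    driver_threshold
        Driver-score probability above which (strictly) a fusion is marked
        priority regardless of structure.
    exclude_prefixes
        Gene-name prefixes identifying unannotated partners to remove.
    tissue
        Tumor tissue of origin for the driver-score input formatter; only
        required when that output is requested.
    tie_break_order
        Deterministic preference among structure labels on equal overlap;
        biologically reliable interpretations first.
    """

    flank_len: int = 30
    min_overlap: int = 15
    driver_threshold: float = 0.7
    exclude_prefixes: tuple[str, ...] = DEFAULT_EXCLUDE_PREFIXES
    tissue: Optional[str] = None
    tie_break_order: tuple[str, ...] = ("PROM_END", "PROM_PROM", "END_PROM", "END_END")

    def __post_init__(self) -> None:
        if self.flank_len < 1:
            raise ValidationError("flank_len must be >= 1")
        if not (0 < self.min_overlap <= 2 * self.flank_len):
            raise ValidationError(
                f"min_overlap must satisfy 0 < min_overlap <= 2*flank_len "
                f"(got {self.min_overlap} with flank_len {self.flank_len})"
            )
        if not (0.0 <= self.driver_threshold <= 1.0):
            raise ValidationError("driver_threshold must be in [0, 1]")
        if self.tissue is not None and self.tissue not in TISSUES:
            raise ValidationError(
                f"tissue must be one of {sorted(TISSUES)}, got {self.tissue!r}"
            )
        if sorted(self.tie_break_order) != sorted(STRUCTURE_LABELS):
            raise ValidationError(
                "tie_break_order must be a permutation of " + ", ".join(STRUCTURE_LABELS)
            )


@dataclass
class SampleReport:
    """Per-sample outcome: retained records plus every removal with its stage."""

    sample_id: str
    retained: list[FusionRecord] = field(default_factory=list)
    removed: list[tuple[FusionRecord, str]] = field(default_factory=list)


def _check_seq(seq: str, what: str) -> None:
    bad = set(seq) - _DNA
    if bad:
        raise ValidationError(f"{what} contains non-ACGTN characters: {sorted(bad)}")


def _check_partner(p: GenePartner, which: str) -> None:
    if not p.gene_name:
        raise ValidationError(f"{which}.gene_name must be non-empty")
    if p.strand not in ("+", "-"):
        raise ValidationError(f"{which}.strand must be '+' or '-', got {p.strand!r}")
    if p.breakpoint < 1:
        raise ValidationError(
            f"{which}.breakpoint must be >= 1 (1-based), got {p.breakpoint}"
        )


def validate_record(r: FusionRecord) -> FusionRecord:
    """Check every type invariant of ``r``; return it unchanged if valid.

    Raises :class:`ValidationError` naming the offending field otherwise.
    """
    if not r.sample_id:
        raise ValidationError("sample_id must be non-empty")
    if not r.tool_id:
        raise ValidationError("tool_id must be non-empty")
    _check_partner(r.gene5, "gene5")
    _check_partner(r.gene3, "gene3")
    if r.split_read_count < 0:
        raise ValidationError(f"split_read_count must be >= 0, got {r.split_read_count}")
    if r.spanning_read_count < 0:
        raise ValidationError(
            f"spanning_read_count must be >= 0, got {r.spanning_read_count}"
        )
    if r.split_read_count == 0 and r.split_reads:
        raise ValidationError("split_read_count is 0 but split_reads is non-empty")
    for read in r.split_reads:
        _check_seq(read, "split_reads entry")
    if r.consensus_sequence is not None:
        _check_seq(r.consensus_sequence, "consensus_sequence")
    for name, score in (("score_pegasus", r.score_pegasus), ("score_oncofuse", r.score_oncofuse)):
        if score is not None and not (0.0 <= score <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {score}")
    unknown = r.flags - FLAGS
    if unknown:
        raise ValidationError(f"unknown flags: {sorted(unknown)}")
    return r


def fusion_key(r: FusionRecord) -> tuple[str, str, int, int]:
    """Identity of a fusion across tools and samples.

    Gene names verbatim (case-sensitive) plus both breakpoints after 1-based
    normalization; reciprocal fusions (A-B vs B-A) are distinct keys.
    """
    return (
        r.gene5.gene_name,
        r.gene3.gene_name,
        r.gene5.breakpoint,
        r.gene3.breakpoint,
    )
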