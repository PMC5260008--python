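"""I/O: fusion-call tables in several caller dialects, and the genome.

Fusion discovery tools disagree on column layout and coordinate convention;
the adapters here normalize everything to :class:`~fusionsieve.model.FusionRecord`
with 1-based inclusive coordinates.  Four dialects are supported:

``generic``
    The package's unified schema serialized as TSV.  Read by header name, so
    any TSV carrying at least the key columns (including the per-sample
    report files this package writes) round-trips.
``defuse_like``
    1-based coordinates, a caller-assembled consensus sequence, no
    individual split-read sequences.
``chimerascan_like``
    0-based breakpoint start coordinates (converted to 1-based on read) and
    a comma-separated list of split-read sequences.
``mapsplice_like``
    A minimal layout: partners, breakpoints, a split-read count and a
    consensus sequence.

The genome is an indexed FASTA accessed through pyfaidx; chromosome names
are matched verbatim (no "chr" aliasing).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from Bio.Seq import reverse_complement as _rc
from pyfaidx import Fasta

from .model import (
    FusionRecord,
    GenePartner,
    SampleReport,
    ValidationError,
    validate_record,
)

__all__ = [
    "GenomeAccessor",
    "reverse_complement",
    "fetch_flank",
    "read_fusions",
    "write_fusions",
    "write_report",
    "read_score_table",
    "DIALECTS",
    "GENERIC_COLUMNS",
    "REPORT_COLUMNS",
]

PathLike = Union[str, Path]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return _rc(seq)


# ---------------------------------------------------------------------------
# Genome access


class GenomeAccessor:
    """Random access to an indexed reference FASTA, 1-based inclusive.

    Queries outside ``[1, chrom_length]`` raise instead of silently
    truncating, so a flank that would run off a chromosome is an error the
    caller sees.
    """

    def __init__(self, fasta_path: PathLike):
        self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        self.chrom_lengths: dict[str, int] = {
            name: len(self._fasta[name]) for name in self._fasta.keys()
        }

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases ``start..end`` (1-based, inclusive) of ``chrom``."""
        if chrom not in self.chrom_lengths:
            raise ValidationError(f"unknown chromosome {chrom!r} (names match verbatim)")
        length = self.chrom_lengths[chrom]
        if not (1 <= start <= end <= length):
            raise ValidationError(
                f"interval {chrom}:{start}-{end} outside [1, {length}]"
            )
        return str(self._fasta[chrom][start - 1 : end])


#: ``side`` semantics for :func:`fetch_flank`, relative to a 1-based
#: position in *transcript orientation*:
#: ending_at includes pos as the last returned base; starting_at includes it
#: as the first; upstream_of/downstream_of exclude it.
_SIDES = ("upstream_of", "downstream_of", "ending_at", "starting_at")


def fetch_flank(
    genome: GenomeAccessor,
    chrom: str,
    pos: int,
    side: str,
    length: int,
    strand: str,
) -> str:
    """Extract ``length`` bases around ``pos`` in transcript orientation.

    For strand "+" the result is in genomic order; for strand "-" it is the
    reverse complement of the genomic interval mirrored about ``pos``, so
    that e.g. ``ending_at`` always means "the transcribed bases immediately
    up to and including pos".
    """
    if length < 1:
        raise ValidationError(f"flank length must be >= 1, got {length}")
    if side not in _SIDES:
        raise ValidationError(f"side must be one of {_SIDES}, got {side!r}")
    if strand not in ("+", "-"):
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")

    if strand == "+":
        offsets = {
            "ending_at": (pos - length + 1, pos),
            "starting_at": (pos, pos + length - 1),
            "upstream_of": (pos - length, pos - 1),
            "downstream_of": (pos + 1, pos + length),
        }
    else:  # mirror the interval about pos, then reverse complement
        offsets = {
            "ending_at": (pos, pos + length - 1),
            "starting_at": (pos - length + 1, pos),
            "upstream_of": (pos + 1, pos + length),
            "downstream_of": (pos - length, pos - 1),
        }
    start, end = offsets[side]
    seq = genome.fetch(chrom, start, end)
    return reverse_complement(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# Fusion table dialects

GENERIC_COLUMNS = [
    "sample_id",
    "tool_id",
    "gene5",
    "chrom5",
    "bp5",
    "strand5",
    "annotated5",
    "gene3",
    "chrom3",
    "bp3",
    "strand3",
    "annotated3",
    "split_read_count",
    "spanning_read_count",
    "split_reads",
    "consensus_sequence",
    "score_pegasus",
    "score_oncofuse",
]

_DEFUSE_COLUMNS = [
    "gene5",
    "chrom5",
    "breakpoint5",
    "strand5",
    "gene3",
    "chrom3",
    "breakpoint3",
    "strand3",
    "split_read_count",
    "spanning_read_count",
    "consensus_sequence",
]

_CHIMERASCAN_COLUMNS = [
    "chrom5",
    "start5",
    "strand5",
    "gene5",
    "chrom3",
    "start3",
    "strand3",
    "gene3",
    "split_read_count",
    "spanning_read_count",
    "split_reads",
]

_MAPSPLICE_COLUMNS = [
    "gene5",
    "chrom5",
    "bp5",
    "strand5",
    "gene3",
    "chrom3",
    "bp3",
    "strand3",
    "split_read_count",
    "consensus_sequence",
]

DIALECTS = ("generic", "defuse_like", "chimerascan_like", "mapsplice_like")


def _opt_float(value: str) -> Optional[float]:
    return float(value) if value not in ("", None) else None


def _opt_seq(value: str) -> Optional[str]:
    return value if value else None


def _split_reads_field(value: str) -> list[str]:
    return [r for r in value.split(",") if r] if value else []


def _parse_bool(value: str) -> bool:
    return value not in ("0", "false", "False", "")


def _row_error(path: PathLike, lineno: int, msg: str) -> ValidationError:
    return ValidationError(f"{path}:{lineno}: {msg}")


def _read_tsv(path: PathLike) -> tuple[list[str], list[tuple[int, list[str]]]]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValidationError(f"{path}: empty file, expected a header line")
        rows = [(lineno, row) for lineno, row in enumerate(reader, start=2) if row]
    return header, rows


def _generic_record(path, lineno, cols: dict[str, str]) -> FusionRecord:
    def need(name: str) -> str:
        if name not in cols or cols[name] == "":
            raise _row_error(path, lineno, f"missing required field {name!r}")
        return cols[name]

    tool_id = cols.get("tool_id", "")
    if not tool_id and cols.get("tools"):
        # report files list all reporting tools; the first is the emitter
        tool_id = cols["tools"].split(",")[0]
    if not tool_id:
        raise _row_error(path, lineno, "missing required field 'tool_id'")
    try:
        rec = FusionRecord(
            sample_id=need("sample_id"),
            tool_id=tool_id,
            gene5=GenePartner(
                need("gene5"),
                need("chrom5"),
                need("strand5"),
                int(need("bp5")),
                _parse_bool(cols.get("annotated5", "1")),
            ),
            gene3=GenePartner(
                need("gene3"),
                need("chrom3"),
                need("strand3"),
                int(need("bp3")),
                _parse_bool(cols.get("annotated3", "1")),
            ),
            split_read_count=int(cols.get("split_read_count") or 0),
            spanning_read_count=int(cols.get("spanning_read_count") or 0),
            split_reads=_split_reads_field(cols.get("split_reads", "")),
            consensus_sequence=_opt_seq(cols.get("consensus_sequence", "")),
            score_pegasus=_opt_float(cols.get("score_pegasus", "")),
            score_oncofuse=_opt_float(cols.get("score_oncofuse", "")),
        )
    except ValueError as exc:
        raise _row_error(path, lineno, str(exc)) from None
    return rec


def _positional_record(
    path, lineno, header: Sequence[str], row: Sequence[str], expected: Sequence[str]
) -> dict[str, str]:
    if list(header) != list(expected):
        raise ValidationError(
            f"{path}: header {header!r} does not match the dialect's columns {list(expected)!r}"
        )
    if len(row) != len(expected):
        raise _row_error(path, lineno, f"expected {len(expected)} fields, got {len(row)}")
    return dict(zip(expected, row))


def read_fusions(
    path: PathLike,
    dialect: str = "generic",
    sample_id: Optional[str] = None,
) -> list[FusionRecord]:
    """Read a fusion-call table, normalizing coordinates to 1-based.

    For the tool dialects (which carry no sample column) ``sample_id``
    defaults to the file stem.  Every returned record passes
    :func:`~fusionsieve.model.validate_record`; a malformed row raises with
    its line number.
    """
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}, expected one of {DIALECTS}")
    header, rows = _read_tsv(path)
    default_sample = sample_id if sample_id is not None else Path(path).stem
    records: list[FusionRecord] = []

    for lineno, row in rows:
        if dialect == "generic":
            if len(row) != len(header):
                raise _row_error(path, lineno, f"expected {len(header)} fields, got {len(row)}")
            cols = dict(zip(header, row))
            rec = _generic_record(path, lineno, cols)
        elif dialect == "defuse_like":
            cols = _positional_record(path, lineno, header, row, _DEFUSE_COLUMNS)
            try:
                rec = FusionRecord(
                    sample_id=default_sample,
                    tool_id="defuse_like",
                    gene5=GenePartner(cols["gene5"], cols["chrom5"], cols["strand5"], int(cols["breakpoint5"])),
                    gene3=GenePartner(cols["gene3"], cols["chrom3"], cols["strand3"], int(cols["breakpoint3"])),
                    split_read_count=int(cols["split_read_count"]),
                    spanning_read_count=int(cols["spanning_read_count"]),
                    consensus_sequence=_opt_seq(cols["consensus_sequence"]),
                )
            except ValueError as exc:
                raise _row_error(path, lineno, str(exc)) from None
        elif dialect == "chimerascan_like":
            cols = _positional_record(path, lineno, header, row, _CHIMERASCAN_COLUMNS)
            try:
                # 0-based start coordinates -> 1-based inclusive
                rec = FusionRecord(
                    sample_id=default_sample,
                    tool_id="chimerascan_like",
                    gene5=GenePartner(cols["gene5"], cols["chrom5"], cols["strand5"], int(cols["start5"]) + 1),
                    gene3=GenePartner(cols["gene3"], cols["chrom3"], cols["strand3"], int(cols["start3"]) + 1),
                    split_read_count=int(cols["split_read_count"]),
                    spanning_read_count=int(cols["spanning_read_count"]),
                    split_reads=_split_reads_field(cols["split_reads"]),
                )
            except ValueError as exc:
                raise _row_error(path, lineno, str(exc)) from None
        else:  # mapsplice_like
            cols = _positional_record(path, lineno, header, row, _MAPSPLICE_COLUMNS)
            try:
                rec = FusionRecord(
                    sample_id=default_sample,
                    tool_id="mapsplice_like",
                    gene5=GenePartner(cols["gene5"], cols["chrom5"], cols["strand5"], int(cols["bp5"])),
                    gene3=GenePartner(cols["gene3"], cols["chrom3"], cols["strand3"], int(cols["bp3"])),
                    split_read_count=int(cols["split_read_count"]),
                    consensus_sequence=_opt_seq(cols["consensus_sequence"]),
                )
            except ValueError as exc:
                raise _row_error(path, lineno, str(exc)) from None
        try:
            records.append(validate_record(rec))
        except ValidationError as exc:
            raise _row_error(path, lineno, str(exc)) from None
    return records


def _fmt_score(score: Optional[float]) -> str:
    # absent scores serialize as empty, never as "0"
    return "" if score is None else repr(score)


def write_fusions(records: Iterable[FusionRecord], path: PathLike, dialect: str = "generic") -> None:
    """Serialize records in a dialect (inverse of :func:`read_fusions`)."""
    if dialect not in DIALECTS:
        raise ValidationError(f"unknown dialect {dialect!r}, expected one of {DIALECTS}")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        if dialect == "generic":
            writer.writerow(GENERIC_COLUMNS)
            for r in records:
                writer.writerow(
                    [
                        r.sample_id,
                        r.tool_id,
                        r.gene5.gene_name,
                        r.gene5.chrom,
                        r.gene5.breakpoint,
                        r.gene5.strand,
                        int(r.gene5.annotated),
                        r.gene3.gene_name,
                        r.gene3.chrom,
                        r.gene3.breakpoint,
                        r.gene3.strand,
                        int(r.gene3.annotated),
                        r.split_read_count,
                        r.spanning_read_count,
                        ",".join(r.split_reads),
                        r.consensus_sequence or "",
                        _fmt_score(r.score_pegasus),
                        _fmt_score(r.score_oncofuse),
                    ]
                )
        elif dialect == "defuse_like":
            writer.writerow(_DEFUSE_COLUMNS)
            for r in records:
                writer.writerow(
                    [
                        r.gene5.gene_name, r.gene5.chrom, r.gene5.breakpoint, r.gene5.strand,
                        r.gene3.gene_name, r.gene3.chrom, r.gene3.breakpoint, r.gene3.strand,
                        r.split_read_count, r.spanning_read_count, r.consensus_sequence or "",
                    ]
                )
        elif dialect == "chimerascan_like":
            writer.writerow(_CHIMERASCAN_COLUMNS)
            for r in records:
                # 1-based inclusive -> the dialect's 0-based starts
                writer.writerow(
                    [
                        r.gene5.chrom, r.gene5.breakpoint - 1, r.gene5.strand, r.gene5.gene_name,
                        r.gene3.chrom, r.gene3.breakpoint - 1, r.gene3.strand, r.gene3.gene_name,
                        r.split_read_count, r.spanning_read_count, ",".join(r.split_reads),
                    ]
                )
        else:
            writer.writerow(_MAPSPLICE_COLUMNS)
            for r in records:
                writer.writerow(
                    [
                        r.gene5.gene_name, r.gene5.chrom, r.gene5.breakpoint, r.gene5.strand,
                        r.gene3.gene_name, r.gene3.chrom, r.gene3.breakpoint, r.gene3.strand,
                        r.split_read_count, r.consensus_sequence or "",
                    ]
                )


# ---------------------------------------------------------------------------
# Per-sample reports

REPORT_COLUMNS = [
    "sample_id",
    "gene5",
    "gene3",
    "chrom5",
    "bp5",
    "strand5",
    "chrom3",
    "bp3",
    "strand3",
    "tools",
    "n_samples_sharing",
    "split_read_count",
    "spanning_read_count",
    "score_pegasus",
    "score_oncofuse",
    "structure_label",
    "reliable",
    "priority",
    "removal_stage",
]


def _report_row(r: FusionRecord, removal_stage: str = "") -> list:
    return [
        r.sample_id,
        r.gene5.gene_name,
        r.gene3.gene_name,
        r.gene5.chrom,
        r.gene5.breakpoint,
        r.gene5.strand,
        r.gene3.chrom,
        r.gene3.breakpoint,
        r.gene3.strand,
        ",".join(r.tools or [r.tool_id]),
        r.n_samples_sharing,
        r.split_read_count,
        r.spanning_read_count,
        _fmt_score(r.score_pegasus),
        _fmt_score(r.score_oncofuse),
        r.structure.label if r.structure is not None else "",
        int("reliable_structure" in r.flags),
        int("priority" in r.flags),
        removal_stage,
    ]


def write_report(report: SampleReport, path: PathLike) -> None:
    """Write one sample's result file: retained fusions first, then every
    removed fusion with the stage that removed it."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(REPORT_COLUMNS)
        for r in report.retained:
            writer.writerow(_report_row(r))
        for r, stage in report.removed:
            writer.writerow(_report_row(r, removal_stage=stage))


# ---------------------------------------------------------------------------
# Driver-score tables

_SCORE_COLUMNS = ["gene5", "gene3", "bp5", "bp3", "source", "score"]


def read_score_table(path: PathLike) -> dict[tuple, dict[str, float]]:
    """Read a TSV of externally computed driver scores.

    Columns: gene5, gene3, bp5, bp3, source (pegasus|oncofuse), score.
    Returns fusion key -> {source: score}.  Scores outside [0, 1] raise.
    """
    header, rows = _read_tsv(path)
    if header != _SCORE_COLUMNS:
        raise ValidationError(f"{path}: score table header must be {_SCORE_COLUMNS}")
    table: dict[tuple, dict[str, float]] = {}
    for lineno, row in rows:
        cols = dict(zip(header, row))
        source = cols["source"]
        if source not in ("pegasus", "oncofuse"):
            raise _row_error(path, lineno, f"unknown score source {source!r}")
        score = float(cols["score"])
        if not (0.0 <= score <= 1.0):
            raise _row_error(path, lineno, f"score must be in [0, 1], got {score}")
        key = (cols["gene5"], cols["gene3"], int(cols["bp5"]), int(cols["bp3"]))
        table.setdefault(key, {})[source] = score
    return table


def write_score_table(table: dict[tuple, dict[str, float]], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_SCORE_COLUMNS)
        for key in sorted(table):
            for source in sorted(table[key]):
                writer.writerow([key[0], key[1], key[2], key[3], source, repr(table[key][source])])
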