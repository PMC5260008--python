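"""Deterministic simulator: toy genomes, planted fusions, ground truth.

The simulator is the test substrate for the whole cascade.  It writes a
random non-repetitive toy genome, plants fusions of each junction-structure
class, samples split reads (or consensus sequences) from the very same
virtual references the structure module would reconstruct, and emits
tumor/normal call tables in the generic dialect together with a
ground-truth table from which the expected outcome of every pipeline stage
can be predicted exactly.

What it emulates: the statistical structure the cascade assumes — reads
harbouring the fusion breakpoint within their sequence, duplicate records
from one tool with different supporting reads, multi-tool and multi-sample
recurrence, unannotated-gene decoys, fusions shared with healthy samples,
and zero-split-read calls.  What it does not emulate: sequencing errors,
realistic coverage profiles, or fastq-level data.

Reads span the junction by a configurable number of true-reference bases
(``junction_span``, default the whole read).  Bases outside the span are
*anti-matched* — drawn from the three bases differing from the aligned
reference base — so the junction-spanning overlap achieved by such a read
equals ``junction_span`` exactly; setting it below the minimum overlap
forces a NO_MATCH call for that fusion.

Identical seed and parameters give byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from .ingest import (
    GenomeAccessor,
    reverse_complement,
    write_fusions,
    write_score_table,
)
from .model import (
    NO_MATCH,
    STRUCTURE_LABELS,
    FusionRecord,
    GenePartner,
    ValidationError,
)
from .structure import RELIABLE_LABELS, build_virtual_references

__all__ = ["GroundTruthEntry", "SimulationResult", "simulate", "predict_stage_counts"]

_BASES = np.array(["A", "C", "G", "T"])

TRUTH_COLUMNS = [
    "sample_id",
    "gene5",
    "gene3",
    "chrom5",
    "bp5",
    "strand5",
    "chrom3",
    "bp3",
    "strand3",
    "true_label",
    "n_tools",
    "n_samples_in",
    "n_records_emitted",
    "planted_in_normal",
    "unannotated_decoy",
    "n_split_reads",
    "has_consensus",
    "score_pegasus",
    "score_oncofuse",
    "expected_priority",
]


@dataclass
class GroundTruthEntry:
    """Everything needed to predict the fate of one planted fusion."""

    sample_id: str
    gene5: str
    gene3: str
    chrom5: str
    bp5: int
    strand5: str
    chrom3: str
    bp3: int
    strand3: str
    true_label: str
    n_tools: int
    n_samples_in: int
    n_records_emitted: int
    planted_in_normal: bool
    unannotated_decoy: bool
    n_split_reads: int
    has_consensus: bool
    score_pegasus: Optional[float]
    score_oncofuse: Optional[float]
    expected_priority: bool

    @property
    def key(self) -> tuple[str, str, int, int]:
        return (self.gene5, self.gene3, self.bp5, self.bp3)

    @property
    def n_collapsed_records(self) -> int:
        """Records remaining for this fusion after duplicate collapsing."""
        return self.n_tools * self.n_samples_in


@dataclass
class SimulationResult:
    outdir: Path
    genome_fasta: Path
    tumor_table: Path
    truth_table: Path
    normal_table: Optional[Path] = None
    score_table: Optional[Path] = None
    truth: list[GroundTruthEntry] = field(default_factory=list)


def _check_frac(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must be in [0, 1], got {value}")


def _random_chrom(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _anti_base(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return choices[int(rng.integers(0, len(choices)))]


def _read_from_reference(
    rng: np.random.Generator,
    ref: str,
    junction_index: int,
    read_len: int,
    min_overlap: int,
    junction_span: Optional[int],
) -> str:
    """Sample one junction-crossing read from a virtual reference."""
    if junction_span is None or junction_span >= read_len:
        # whole read drawn verbatim from the reference, crossing the
        # junction by at least min(min_overlap, read_len//2) on each side
        min_side = max(1, min(min_overlap, read_len // 2))
        candidates = [
            s
            for s in range(0, len(ref) - read_len + 1)
            if junction_index - s >= min_side
            and s + read_len - junction_index >= min_side
        ]
        if not candidates:
            start = max(0, min(junction_index - read_len // 2, len(ref) - read_len))
            read = ref[start : start + read_len]
        else:
            start = candidates[int(rng.integers(0, len(candidates)))]
            read = ref[start : start + read_len]
    else:
        s = junction_span
        left_true = s - s // 2
        right_true = s // 2
        if right_true == 0:  # the block must cover both junction-adjacent bases
            left_true, right_true = s - 1, 1
        block = ref[junction_index - left_true : junction_index + right_true]
        anti_total = read_len - s
        anti_left = int(rng.integers(0, anti_total + 1))
        anti_right = anti_total - anti_left
        left = []
        for k in range(anti_left):
            pos = junction_index - left_true - anti_left + k
            if 0 <= pos < len(ref):
                left.append(_anti_base(rng, ref[pos]))
            else:
                left.append(str(rng.choice(_BASES)))
        right = []
        for k in range(anti_right):
            pos = junction_index + right_true + k
            if 0 <= pos < len(ref):
                right.append(_anti_base(rng, ref[pos]))
            else:
                right.append(str(rng.choice(_BASES)))
        read = "".join(left) + block + "".join(right)
    if rng.random() < 0.5:  # both orientations occur in real data
        read = reverse_complement(read)
    return read


def _pick(rng: np.random.Generator, pool: list[int], n: int) -> set[int]:
    if n <= 0 or not pool:
        return set()
    n = min(n, len(pool))
    chosen = rng.choice(np.array(pool), size=n, replace=False)
    return {int(i) for i in chosen}


def simulate(
    seed: int,
    n_per_class: int = 5,
    read_len: int = 30,
    flank_len: int = 30,
    frac_normal_shared: float = 0.0,
    frac_decoy: float = 0.0,
    outdir: Union[str, Path] = ".",
    *,
    n_nomatch: int = 0,
    n_samples: int = 2,
    chrom_len: int = 10_000,
    min_overlap: int = 15,
    junction_span: Optional[int] = None,
    frac_no_split: float = 0.0,
    frac_consensus: float = 0.0,
    frac_duplicate: float = 0.0,
    frac_multi_tool: float = 0.0,
    frac_shared_sample: float = 0.0,
    frac_scored: float = 0.0,
    driver_threshold: float = 0.7,
    reads_per_fusion: int = 3,
) -> SimulationResult:
    """Generate a complete simulated input set plus ground truth.

    ``n_per_class`` fusions are planted for each of the four labeled
    structure classes, plus ``n_nomatch`` fusions whose reads span the
    junction by ``min_overlap - 1`` bases only, plus decoy fusions with
    excluded-prefix gene names.  Fractions select (disjointly where it
    matters) fusions that are planted in the normal table, emitted with
    zero split reads, reported via consensus sequence instead of reads,
    duplicated within one tool, reported by a second tool, or shared
    between two samples.
    """
    if read_len < 1:
        raise ValidationError(f"read_len must be >= 1, got {read_len}")
    if n_per_class < 0 or n_nomatch < 0:
        raise ValidationError("fusion counts must be >= 0")
    if flank_len < 1:
        raise ValidationError(f"flank_len must be >= 1, got {flank_len}")
    if read_len > 2 * flank_len:
        raise ValidationError(
            f"read_len ({read_len}) cannot exceed the reference length (2*flank_len = {2 * flank_len})"
        )
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    if junction_span is not None and not (2 <= junction_span <= read_len):
        raise ValidationError("junction_span must be in [2, read_len]")
    if n_nomatch > 0 and min_overlap < 3:
        raise ValidationError("n_nomatch requires min_overlap >= 3")
    for name, value in (
        ("frac_normal_shared", frac_normal_shared),
        ("frac_decoy", frac_decoy),
        ("frac_no_split", frac_no_split),
        ("frac_consensus", frac_consensus),
        ("frac_duplicate", frac_duplicate),
        ("frac_multi_tool", frac_multi_tool),
        ("frac_shared_sample", frac_shared_sample),
        ("frac_scored", frac_scored),
    ):
        _check_frac(name, value)

    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    n_core = 4 * n_per_class + n_nomatch
    n_decoy = round(frac_decoy * n_core)
    n_total = n_core + n_decoy

    # --- genome: enough disjoint breakpoint slots for every gene side
    slot = 2 * flank_len + 20
    slots_per_chrom = max(1, chrom_len // slot)
    n_chroms = max(2, math.ceil((2 * max(n_total, 1)) / slots_per_chrom))
    chrom_names = [f"chr{i + 1}" for i in range(n_chroms)]
    sequences = {name: _random_chrom(rng, chrom_len) for name in chrom_names}
    genome_fasta = outdir / "genome.fa"
    with open(genome_fasta, "w") as fh:
        for name in chrom_names:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")

    all_slots = [(c, s) for c in chrom_names for s in range(slots_per_chrom)]
    order = rng.permutation(len(all_slots))

    def side(i: int) -> tuple[str, int, str]:
        chrom, slot_idx = all_slots[int(order[i])]
        jitter = int(rng.integers(-5, 6))
        bp = slot_idx * slot + slot // 2 + jitter + 1
        strand = "+" if rng.random() < 0.5 else "-"
        return chrom, bp, strand

    # --- plan fusions
    labels = [lab for lab in STRUCTURE_LABELS for _ in range(n_per_class)]
    labels += [NO_MATCH] * n_nomatch
    labels += [str(rng.choice(np.array(STRUCTURE_LABELS))) for _ in range(n_decoy)]
    decoy_flags = [False] * n_core + [True] * n_decoy

    core_ids = list(range(n_core))
    in_normal = _pick(rng, core_ids, round(frac_normal_shared * n_core))
    rest = [i for i in core_ids if i not in in_normal]
    no_split = _pick(rng, rest, round(frac_no_split * n_core))
    with_reads = [i for i in core_ids if i not in no_split]
    consensus_only = _pick(rng, with_reads, round(frac_consensus * n_core))
    dup_pool = [i for i in with_reads if i not in consensus_only]
    duplicated = _pick(rng, dup_pool, round(frac_duplicate * n_core))
    multi_tool = _pick(rng, with_reads, round(frac_multi_tool * n_core))
    shared = _pick(rng, core_ids, round(frac_shared_sample * n_core))
    scored = _pick(rng, core_ids, round(frac_scored * n_core))

    samples = [f"S{i + 1}" for i in range(n_samples)]
    genome = GenomeAccessor(genome_fasta)

    truth: list[GroundTruthEntry] = []
    records: list[FusionRecord] = []
    normal_records: list[FusionRecord] = []
    score_table: dict[tuple, dict[str, float]] = {}

    for i in range(n_total):
        decoy = decoy_flags[i]
        label = labels[i]
        chrom5, bp5, strand5 = side(2 * i)
        chrom3, bp3, strand3 = side(2 * i + 1)
        g5_name = f"LOC{900000 + i}" if decoy else f"GEN{i:04d}A"
        g3_name = f"GEN{i:04d}B"
        g5 = GenePartner(g5_name, chrom5, strand5, bp5)
        g3 = GenePartner(g3_name, chrom3, strand3, bp3)
        proto = FusionRecord(sample_id="", tool_id="", gene5=g5, gene3=g3)
        refs = build_virtual_references(genome, proto, flank_len)
        # reads come from the labeled class's reference; NO_MATCH fusions
        # draw from PROM_END but with a sub-threshold junction span
        ref_kind = label if label != NO_MATCH else "PROM_END"
        span = junction_span if label != NO_MATCH else min_overlap - 1
        ref = refs[ref_kind]

        is_core = not decoy
        fusion_samples = [samples[i % n_samples]]
        if is_core and i in shared and n_samples > 1:
            fusion_samples.append(samples[(i + 1) % n_samples])
        tools = ["toolA"] + (["toolB"] if is_core and i in multi_tool else [])

        has_consensus = is_core and i in consensus_only
        zero_split = is_core and i in no_split
        dup = is_core and i in duplicated

        n_split_total = 0
        n_emitted = 0
        for sample_id in fusion_samples:
            for tool_id in tools:
                if zero_split:
                    rec = FusionRecord(
                        sample_id=sample_id,
                        tool_id=tool_id,
                        gene5=GenePartner(g5_name, chrom5, strand5, bp5),
                        gene3=GenePartner(g3_name, chrom3, strand3, bp3),
                        split_read_count=0,
                        spanning_read_count=int(rng.integers(0, 10)),
                    )
                    records.append(rec)
                    n_emitted += 1
                    continue
                if has_consensus:
                    count = int(rng.integers(1, reads_per_fusion + 1))
                    rec = FusionRecord(
                        sample_id=sample_id,
                        tool_id=tool_id,
                        gene5=GenePartner(g5_name, chrom5, strand5, bp5),
                        gene3=GenePartner(g3_name, chrom3, strand3, bp3),
                        split_read_count=count,
                        spanning_read_count=int(rng.integers(0, 10)),
                        consensus_sequence=ref,
                    )
                    records.append(rec)
                    n_emitted += 1
                    if sample_id == fusion_samples[0] and tool_id == "toolA":
                        n_split_total = count
                    continue
                reads = [
                    _read_from_reference(rng, ref, refs.junction_index, read_len, min_overlap, span)
                    for _ in range(reads_per_fusion)
                ]
                reads = list(dict.fromkeys(reads))  # dedup, keep order
                spanning = int(rng.integers(0, 10))
                if dup and sample_id == fusion_samples[0] and tool_id == "toolA" and len(reads) >= 2:
                    cut = max(1, len(reads) // 2)
                    parts = [reads[:cut], reads[cut:]]
                    for part in parts:
                        records.append(
                            FusionRecord(
                                sample_id=sample_id,
                                tool_id=tool_id,
                                gene5=GenePartner(g5_name, chrom5, strand5, bp5),
                                gene3=GenePartner(g3_name, chrom3, strand3, bp3),
                                split_read_count=len(part),
                                spanning_read_count=spanning,
                                split_reads=part,
                            )
                        )
                        n_emitted += 1
                else:
                    records.append(
                        FusionRecord(
                            sample_id=sample_id,
                            tool_id=tool_id,
                            gene5=GenePartner(g5_name, chrom5, strand5, bp5),
                            gene3=GenePartner(g3_name, chrom3, strand3, bp3),
                            split_read_count=len(reads),
                            spanning_read_count=spanning,
                            split_reads=reads,
                        )
                    )
                    n_emitted += 1
                if sample_id == fusion_samples[0] and tool_id == "toolA":
                    n_split_total = len(reads)

        if is_core and i in in_normal:
            normal_records.append(
                FusionRecord(
                    sample_id="NORMAL1",
                    tool_id="toolA",
                    gene5=GenePartner(g5_name, chrom5, strand5, bp5),
                    gene3=GenePartner(g3_name, chrom3, strand3, bp3),
                    split_read_count=1,
                    spanning_read_count=int(rng.integers(0, 10)),
                    split_reads=[
                        _read_from_reference(rng, ref, refs.junction_index, read_len, min_overlap, span)
                    ],
                )
            )

        sp = so = None
        if is_core and i in scored:
            if rng.random() < 0.8:
                sp = round(float(rng.random()), 4)
            if rng.random() < 0.8:
                so = round(float(rng.random()), 4)
            entry_scores = {}
            if sp is not None:
                entry_scores["pegasus"] = sp
            if so is not None:
                entry_scores["oncofuse"] = so
            if entry_scores:
                score_table[(g5_name, g3_name, bp5, bp3)] = entry_scores

        expected_priority = (label in RELIABLE_LABELS) or any(
            s is not None and s > driver_threshold for s in (sp, so)
        )
        truth.append(
            GroundTruthEntry(
                sample_id=fusion_samples[0],
                gene5=g5_name,
                gene3=g3_name,
                chrom5=chrom5,
                bp5=bp5,
                strand5=strand5,
                chrom3=chrom3,
                bp3=bp3,
                strand3=strand3,
                true_label=label,
                n_tools=len(tools),
                n_samples_in=len(fusion_samples),
                n_records_emitted=n_emitted,
                planted_in_normal=is_core and i in in_normal,
                unannotated_decoy=decoy,
                n_split_reads=0 if zero_split else n_split_total,
                has_consensus=has_consensus,
                score_pegasus=sp,
                score_oncofuse=so,
                expected_priority=expected_priority,
            )
        )

    tumor_table = outdir / "tumor_fusions.tsv"
    write_fusions(records, tumor_table)
    truth_table = outdir / "ground_truth.tsv"
    _write_truth(truth, truth_table)

    normal_table = None
    if frac_normal_shared > 0:
        normal_table = outdir / "normal_fusions.tsv"
        write_fusions(normal_records, normal_table)
    score_path = None
    if frac_scored > 0:
        score_path = outdir / "driver_scores.tsv"
        write_score_table(score_table, score_path)

    return SimulationResult(
        outdir=outdir,
        genome_fasta=genome_fasta,
        tumor_table=tumor_table,
        truth_table=truth_table,
        normal_table=normal_table,
        score_table=score_path,
        truth=truth,
    )


def _write_truth(truth: list[GroundTruthEntry], path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for t in truth:
            writer.writerow(
                [
                    t.sample_id, t.gene5, t.gene3, t.chrom5, t.bp5, t.strand5,
                    t.chrom3, t.bp3, t.strand3, t.true_label, t.n_tools,
                    t.n_samples_in, t.n_records_emitted,
                    int(t.planted_in_normal), int(t.unannotated_decoy),
                    t.n_split_reads, int(t.has_consensus),
                    "" if t.score_pegasus is None else repr(t.score_pegasus),
                    "" if t.score_oncofuse is None else repr(t.score_oncofuse),
                    int(t.expected_priority),
                ]
            )


def read_truth(path: Union[str, Path]) -> list[GroundTruthEntry]:
    """Read a ground-truth table back (inverse of the simulate output)."""
    import csv

    truth = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            truth.append(
                GroundTruthEntry(
                    sample_id=row["sample_id"],
                    gene5=row["gene5"],
                    gene3=row["gene3"],
                    chrom5=row["chrom5"],
                    bp5=int(row["bp5"]),
                    strand5=row["strand5"],
                    chrom3=row["chrom3"],
                    bp3=int(row["bp3"]),
                    strand3=row["strand3"],
                    true_label=row["true_label"],
                    n_tools=int(row["n_tools"]),
                    n_samples_in=int(row["n_samples_in"]),
                    n_records_emitted=int(row["n_records_emitted"]),
                    planted_in_normal=bool(int(row["planted_in_normal"])),
                    unannotated_decoy=bool(int(row["unannotated_decoy"])),
                    n_split_reads=int(row["n_split_reads"]),
                    has_consensus=bool(int(row["has_consensus"])),
                    score_pegasus=float(row["score_pegasus"]) if row["score_pegasus"] else None,
                    score_oncofuse=float(row["score_oncofuse"]) if row["score_oncofuse"] else None,
                    expected_priority=bool(int(row["expected_priority"])),
                )
            )
    return truth


def predict_stage_counts(truth: list[GroundTruthEntry]) -> dict[str, int]:
    """Predict, from ground truth alone, the record counts the pipeline
    must report at every stage (summed over samples).

    Removal precedence follows the stage order: unannotated decoys fall at
    the annotation filter, then normal-shared fusions, then zero-split-read
    fusions; each removal takes all of the fusion's collapsed records.
    """
    counts = {
        "input_records": 0,
        "after_collapse": 0,
        "removed_unannotated": 0,
        "removed_normal": 0,
        "removed_no_split": 0,
        "retained": 0,
        "priority": 0,
    }
    for t in truth:
        counts["input_records"] += t.n_records_emitted
        counts["after_collapse"] += t.n_collapsed_records
        if t.unannotated_decoy:
            counts["removed_unannotated"] += t.n_collapsed_records
        elif t.planted_in_normal:
            counts["removed_normal"] += t.n_collapsed_records
        elif t.n_split_reads == 0 and not t.has_consensus:
            counts["removed_no_split"] += t.n_collapsed_records
        else:
            counts["retained"] += t.n_collapsed_records
            if t.expected_priority:
                counts["priority"] += t.n_collapsed_records
    return counts
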