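"""Dialect adapters, coordinate normalization, flank extraction, reports."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from fusionsieve.ingest import (
    GenomeAccessor,
    fetch_flank,
    read_fusions,
    read_score_table,
    reverse_complement,
    write_fusions,
    write_report,
    write_score_table,
)
from fusionsieve.model import SampleReport, StructureCall, ValidationError, validate_record

from conftest import make_record, random_dna, write_fasta


# --- flank extraction --------------------------------------------------------

@pytest.fixture
def toy(make_genome):
    return make_genome({"chr1": "ACGTACGT"})


@pytest.mark.parametrize(
    "pos, side, length, strand, expected",
    [
        # chr1 = A C G T A C G T (positions 1..8)
        (4, "ending_at", 2, "+", "GT"),
        (4, "starting_at", 2, "+", "TA"),
        (4, "upstream_of", 2, "+", "CG"),
        (4, "downstream_of", 2, "+", "AC"),
        # strand "-": mirrored interval about pos, reverse complemented
        (6, "ending_at", 2, "-", "CG"),      # rc(bases 6..7 "CG") = "CG"
        (6, "starting_at", 2, "-", "GT"),    # rc(bases 5..6 "AC") = "GT"
        (6, "upstream_of", 2, "-", "AC"),    # rc(bases 7..8 "GT") = "AC"
        (6, "downstream_of", 2, "-", "TA"),  # rc(bases 4..5 "TA") = "TA"
    ],
)
def test_fetch_flank_hand_cases(toy, pos, side, length, strand, expected):
    assert fetch_flank(toy, "chr1", pos, side, length, strand) == expected


def test_fetch_flank_rejects_bad_requests(toy):
    with pytest.raises(ValidationError):
        fetch_flank(toy, "chr1", 4, "ending_at", 0, "+")
    with pytest.raises(ValidationError):  # would run off the chromosome start
        fetch_flank(toy, "chr1", 1, "ending_at", 2, "+")
    with pytest.raises(ValidationError):  # off the end
        fetch_flank(toy, "chr1", 8, "starting_at", 2, "+")
    with pytest.raises(ValidationError, match="chromosome"):
        fetch_flank(toy, "chrX", 4, "ending_at", 2, "+")
    with pytest.raises(ValidationError, match="side"):
        fetch_flank(toy, "chr1", 4, "sideways", 2, "+")


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000), pos=st.integers(10, 90), length=st.integers(1, 9))
def test_minus_strand_is_rc_of_mirrored_plus_interval(tmp_path_factory, seed, pos, length):
    """fetch_flank on '-' equals rc of the '+' fetch over the mirrored interval."""
    rng = random.Random(seed)
    path = tmp_path_factory.mktemp("g") / "g.fa"
    write_fasta(path, {"c": random_dna(rng, 100)})
    g = GenomeAccessor(path)
    # ending_at on '-' covers genomic [pos, pos+L-1]: mirror of ending_at on '+'
    minus = fetch_flank(g, "c", pos, "ending_at", length, "-")
    plus_mirror = fetch_flank(g, "c", pos + length - 1, "ending_at", length, "+")
    assert minus == reverse_complement(plus_mirror)
    minus = fetch_flank(g, "c", pos, "starting_at", length, "-")
    plus_mirror = fetch_flank(g, "c", pos - length + 1, "starting_at", length, "+")
    assert minus == reverse_complement(plus_mirror)


# --- dialects ----------------------------------------------------------------

def _sample_records():
    return [
        make_record(reads=["ACGT", "NNTT"], spanning=3),
        make_record(g5="TP53", g3="ERG", bp5=17, bp3=4242, strand5="-", consensus="ACGTACGT",
                    split_count=2, spanning=1),
    ]


def test_generic_round_trip_is_identity(tmp_path):
    records = _sample_records()
    records[0].score_pegasus = 0.25
    path = tmp_path / "fusions.tsv"
    write_fusions(records, path)
    back = read_fusions(path)
    assert back == records


def test_empty_file_with_header_gives_empty_list(tmp_path):
    path = tmp_path / "empty.tsv"
    write_fusions([], path)
    assert read_fusions(path) == []


def test_unknown_dialect_rejected(tmp_path):
    path = tmp_path / "x.tsv"
    write_fusions([], path)
    with pytest.raises(ValidationError, match="dialect"):
        read_fusions(path, dialect="starfusion")


def test_malformed_row_error_carries_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    write_fusions(_sample_records(), path)
    lines = path.read_text().splitlines()
    lines[2] = lines[2].replace("17", "seventeen", 1)
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(ValidationError, match=":3:"):
        read_fusions(path)


def test_chimerascan_zero_based_start_converted_to_one_based(tmp_path):
    path = tmp_path / "cs.tsv"
    header = "chrom5\tstart5\tstrand5\tgene5\tchrom3\tstart3\tstrand3\tgene3\tsplit_read_count\tspanning_read_count\tsplit_reads"
    row = "chr1\t99\t+\tA\tchr2\t199\t-\tB\t2\t5\tACGT,GGTT"
    path.write_text(header + "\n" + row + "\n")
    (rec,) = read_fusions(path, dialect="chimerascan_like", sample_id="S9")
    assert rec.gene5.breakpoint == 100
    assert rec.gene3.breakpoint == 200
    assert rec.sample_id == "S9"
    assert rec.split_reads == ["ACGT", "GGTT"]


def test_chimerascan_conversion_is_bijective(tmp_path):
    """1-based -> 0-based dialect -> 1-based restores the coordinate."""
    records = [make_record(bp5=100, bp3=200, reads=["ACGT"])]
    path = tmp_path / "cs.tsv"
    write_fusions(records, path, dialect="chimerascan_like")
    first_row = path.read_text().splitlines()[1].split("\t")
    assert first_row[1] == "99" and first_row[5] == "199"  # 0-based on disk
    back = read_fusions(path, dialect="chimerascan_like", sample_id="S1")
    assert back[0].gene5.breakpoint == 100
    assert back[0].gene3.breakpoint == 200


def test_defuse_like_carries_consensus(tmp_path):
    records = [make_record(consensus="ACGTACGTAA", split_count=4, spanning=7)]
    path = tmp_path / "df.tsv"
    write_fusions(records, path, dialect="defuse_like")
    (rec,) = read_fusions(path, dialect="defuse_like", sample_id="S1")
    assert rec.consensus_sequence == "ACGTACGTAA"
    assert rec.split_reads == [] and rec.split_read_count == 4
    assert rec.tool_id == "defuse_like"


def test_mapsplice_like_minimal_dialect(tmp_path):
    records = [make_record(consensus="ACGT", split_count=1)]
    path = tmp_path / "ms.tsv"
    write_fusions(records, path, dialect="mapsplice_like")
    (rec,) = read_fusions(path, dialect="mapsplice_like")
    assert rec.sample_id == "ms"  # defaults to the file stem
    assert rec.consensus_sequence == "ACGT"


def test_all_dialect_adapters_emit_valid_records(tmp_path):
    records = [make_record(reads=["ACGT"], consensus="ACGTAC", spanning=2)]
    for dialect in ("generic", "defuse_like", "chimerascan_like", "mapsplice_like"):
        path = tmp_path / f"{dialect}.tsv"
        write_fusions(records, path, dialect=dialect)
        for rec in read_fusions(path, dialect=dialect, sample_id="S1"):
            assert validate_record(rec) is rec


# --- reports -----------------------------------------------------------------

def test_report_rows_and_absent_scores(tmp_path):
    retained = make_record()
    retained.structure = StructureCall("PROM_END", {})
    retained.score_oncofuse = 0.93
    removed = make_record(g5="LOC1", bp5=7)
    report = SampleReport("S1", retained=[retained], removed=[(removed, "unannotated")])
    path = tmp_path / "S1.tsv"
    write_report(report, path)
    lines = path.read_text().splitlines()
    assert len(lines) == 3  # header + 1 retained + 1 removed
    header = lines[0].split("\t")
    row_kept = dict(zip(header, lines[1].split("\t")))
    row_gone = dict(zip(header, lines[2].split("\t")))
    assert row_kept["score_pegasus"] == ""  # absent is empty, never "0"
    assert row_kept["score_oncofuse"] == "0.93"
    assert row_kept["structure_label"] == "PROM_END"
    assert row_kept["removal_stage"] == ""
    assert row_gone["removal_stage"] == "unannotated"


def test_report_readable_as_generic_dialect(tmp_path):
    retained = make_record(g5="TP53", g3="ERG", bp5=17, bp3=4242)
    retained.structure = StructureCall("END_END", {})
    retained.tools = ["toolA", "toolB"]
    report = SampleReport("S1", retained=[retained])
    path = tmp_path / "S1.tsv"
    write_report(report, path)
    (back,) = read_fusions(path)  # header-based generic read
    assert (back.sample_id, back.gene5.gene_name, back.gene3.gene_name) == ("S1", "TP53", "ERG")
    assert back.gene5.breakpoint == 17 and back.gene3.breakpoint == 4242
    assert back.tool_id == "toolA"


# --- score tables ------------------------------------------------------------

def test_score_table_round_trip(tmp_path):
    table = {("A", "B", 10, 20): {"pegasus": 0.9, "oncofuse": 0.1}}
    path = tmp_path / "scores.tsv"
    write_score_table(table, path)
    assert read_score_table(path) == table


def test_score_table_rejects_out_of_range(tmp_path):
    path = tmp_path / "scores.tsv"
    path.write_text("gene5\tgene3\tbp5\tbp3\tsource\tscore\nA\tB\t1\t2\tpegasus\t1.5\n")
    with pytest.raises(ValidationError, match=r"\[0, 1\]"):
        read_score_table(path)
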