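"""Virtual-reference construction and junction-structure classification.

The matching primitive is checked against an O(n^4) brute-force oracle
that enumerates every substring of the reference, requires it to straddle
the junction, and looks it up in the query (both orientations).
"""

import random

import pytest
from hypothesis import given, settings, strategies as st

from fusionsieve.ingest import reverse_complement
from fusionsieve.model import NO_MATCH, STRUCTURE_LABELS, StructureCall, ValidationError
from fusionsieve.structure import (
    VirtualReferenceSet,
    build_virtual_references,
    classify_fusion,
    is_reliable,
    match_query,
)

from conftest import make_record, random_dna


# --- independent oracle ------------------------------------------------------

def brute_force_overlap(query, ref, junction_index):
    """Enumerate all junction-straddling substrings of ref; return the
    longest that occurs exactly in query or rc(query).  N never matches."""
    best = 0
    targets = (query, reverse_complement(query))
    for a in range(len(ref)):           # 0-based start
        if a > junction_index - 1:
            break
        for b in range(junction_index + 1, len(ref) + 1):  # exclusive end
            sub = ref[a:b]
            if "N" in sub:
                continue
            if len(sub) > best and any(sub in t.replace("N", "n") for t in targets):
                best = len(sub)
    return best


# --- build_virtual_references ------------------------------------------------

@pytest.fixture
def toy_pair(make_genome):
    return make_genome({"chr1": "AACCGGTTAACC", "chr2": "TTGGCCAATTGG"})


def test_reference_construction_hand_oracle(toy_pair):
    """Hand extraction, chr1=AACCGGTTAACC chr2=TTGGCCAATTGG, both '+':
    p5 = bases 2..4 of chr1 ending at bp 4  = ACC
    t5 = bases 5..7 (immediately after bp4) = GGT
    p3 = bases 5..7 of chr2 ending at bp 7  = CCA
    t3 = bases 7..9 (starting at bp7)       = AAT
    """
    f = make_record(bp5=4, bp3=7)
    refs = build_virtual_references(toy_pair, f, flank_len=3)
    assert refs["PROM_END"] == "ACC" + "AAT"
    assert refs["END_PROM"] == "CCA" + "GGT"
    assert refs["PROM_PROM"] == "ACC" + reverse_complement("CCA")  # ACC+TGG
    assert refs["END_END"] == reverse_complement("GGT") + "AAT"    # ACC+AAT
    assert refs.junction_index == 3
    assert all(len(refs[k]) == 6 for k in STRUCTURE_LABELS)


def test_reference_construction_minus_strand(toy_pair):
    """gene3 on '-' at bp 7 of chr2: promoter-side flank is the reverse
    complement of genomic bases 7..9 (AAT -> ATT); 3'-end-side flank
    starting at bp is rc of bases 5..7 (CCA -> TGG)."""
    f = make_record(bp5=4, bp3=7, strand3="-")
    refs = build_virtual_references(toy_pair, f, flank_len=3)
    assert refs["PROM_END"] == "ACC" + "TGG"
    assert refs["PROM_PROM"] == "ACC" + reverse_complement("ATT")
    assert refs["END_PROM"].startswith("ATT")


def test_flank_errors(toy_pair):
    with pytest.raises(ValidationError):
        build_virtual_references(toy_pair, make_record(bp5=4, bp3=7), flank_len=0)
    with pytest.raises(ValidationError):  # flank runs off chromosome start
        build_virtual_references(toy_pair, make_record(bp5=2, bp3=7), flank_len=3)


def test_references_pairwise_distinct_on_random_genome(make_genome):
    rng = random.Random(42)
    g = make_genome({"chr1": random_dna(rng, 400), "chr2": random_dna(rng, 400)})
    refs = build_virtual_references(g, make_record(bp5=150, bp3=250), flank_len=30)
    seqs = [refs[k] for k in STRUCTURE_LABELS]
    assert len(set(seqs)) == 4


# --- match_query -------------------------------------------------------------

def test_full_reference_query_scores_full_length():
    rng = random.Random(0)
    ref = random_dna(rng, 60)
    assert match_query(ref, ref, 30) == 60


def test_fourteen_base_junction_block():
    rng = random.Random(1)
    ref = random_dna(rng, 60)
    block = ref[23:37]  # 14 bases covering junction positions 30 and 31
    # embed the block in anti-matched context so it cannot extend
    left = "".join(c for c in ["A" if ref[22] != "A" else "C"])
    right = "".join(c for c in ["A" if ref[37] != "A" else "C"])
    q = left * 5 + block + right * 5
    assert match_query(q, ref, 30) == 14


def test_query_not_spanning_junction_scores_zero():
    ref = "AAAAACCCCC"
    # query matches only the left flank, never crossing positions 5|6
    assert match_query("AAAAA", ref, 5) == 0


def test_n_never_matches():
    ref = "ACGTACGTAC"
    q = ref[:4] + "N" + ref[5:]
    # the N sits exactly on the junction base, splitting any spanning match
    assert match_query(q, ref, 4) < len(ref)
    assert match_query("NNNNN", ref, 4) == 0


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    seed=st.integers(0, 10**6),
    ref_len=st.integers(8, 40),
    q_len=st.integers(1, 25),
)
def test_match_query_agrees_with_brute_force(seed, ref_len, q_len):
    rng = random.Random(seed)
    ref = random_dna(rng, ref_len, alphabet="ACGTN" if seed % 3 == 0 else "ACGT")
    # bias queries toward real junction fragments half the time
    ji = rng.randrange(1, ref_len)
    if seed % 2:
        a = rng.randrange(0, ji)
        b = rng.randrange(ji, ref_len) + 1
        q = (ref[a:b] + random_dna(rng, q_len))[: max(1, q_len)]
    else:
        q = random_dna(rng, max(1, q_len), alphabet="ACGTN" if seed % 5 == 0 else "ACGT")
    assert match_query(q, ref, ji) == brute_force_overlap(q, ref, ji)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(seed=st.integers(0, 10**6))
def test_match_query_rc_symmetric(seed):
    rng = random.Random(seed)
    ref = random_dna(rng, 40)
    q = random_dna(rng, 20)
    assert match_query(q, ref, 20) == match_query(reverse_complement(q), ref, 20)


# --- classify_fusion ---------------------------------------------------------

def _classification_fixture(make_genome, seed=5, flank=30):
    rng = random.Random(seed)
    g = make_genome({"chr1": random_dna(rng, 500), "chr2": random_dna(rng, 500)})
    f = make_record(bp5=200, bp3=300)
    refs = build_virtual_references(g, f, flank)
    return g, f, refs


@pytest.mark.parametrize("true_label", STRUCTURE_LABELS)
def test_reads_from_each_reference_recover_their_class(make_genome, true_label):
    g, f, refs = _classification_fixture(make_genome)
    ref = refs[true_label]
    f.split_reads = [ref[10:40], ref[15:45], ref[18:48]]
    f.split_read_count = 3
    call = classify_fusion(f, refs, min_overlap=15)
    assert call.label == true_label
    assert call.best_overlap[true_label] == 30


def test_reverse_complemented_reads_give_identical_label(make_genome):
    g, f, refs = _classification_fixture(make_genome)
    reads = [refs["PROM_PROM"][12:42], refs["PROM_PROM"][16:46]]
    f.split_reads = list(reads)
    f.split_read_count = 2
    call_fwd = classify_fusion(f, refs, min_overlap=15)
    f.split_reads = [reverse_complement(r) for r in reads]
    call_rev = classify_fusion(f, refs, min_overlap=15)
    assert call_fwd.label == call_rev.label == "PROM_PROM"
    assert call_fwd.best_overlap == call_rev.best_overlap


def test_reads_shorter_than_min_overlap_give_no_match(make_genome):
    g, f, refs = _classification_fixture(make_genome)
    f.split_reads = [refs["PROM_END"][25:35]]  # 10 bp < 15
    f.split_read_count = 1
    call = classify_fusion(f, refs, min_overlap=15)
    assert call.label == NO_MATCH
    assert all(v < 15 for v in call.best_overlap.values())


def test_consensus_used_when_no_split_reads(make_genome):
    g, f, refs = _classification_fixture(make_genome)
    f.consensus_sequence = refs["END_PROM"]
    call = classify_fusion(f, refs, min_overlap=15)
    assert call.label == "END_PROM"


def test_no_queries_is_an_error(make_genome):
    g, f, refs = _classification_fixture(make_genome)
    with pytest.raises(ValidationError):
        classify_fusion(f, refs, min_overlap=15)


def test_tie_broken_by_configured_order():
    seq = "ACGTACGTACGTACGTACGT"  # identical references -> all overlaps tie
    refs = VirtualReferenceSet(
        references={k: seq for k in STRUCTURE_LABELS}, junction_index=10, flank_len=10
    )
    f = make_record(reads=[seq])
    call = classify_fusion(f, refs, min_overlap=5)
    assert call.label == "PROM_END"
    call = classify_fusion(
        f, refs, min_overlap=5, tie_break_order=("END_END", "END_PROM", "PROM_PROM", "PROM_END")
    )
    assert call.label == "END_END"


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_raising_min_overlap_never_relabels_a_no_match(make_genome, seed):
    g, f, refs = _classification_fixture(make_genome, seed=seed + 100)
    rng = random.Random(seed)
    f.split_reads = [random_dna(rng, 25), refs["END_END"][20:40]]
    f.split_read_count = 2
    labels = [classify_fusion(f, refs, m).label for m in range(5, 61, 5)]
    seen_no_match = False
    for lab in labels:
        if seen_no_match:
            assert lab == NO_MATCH
        seen_no_match = seen_no_match or lab == NO_MATCH


def test_is_reliable_taxonomy():
    assert is_reliable(StructureCall("PROM_END", {}))
    assert is_reliable(StructureCall("PROM_PROM", {}))
    for label in ("END_PROM", "END_END", NO_MATCH):
        assert not is_reliable(StructureCall(label, {}))
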