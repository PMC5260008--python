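"""Shared fixtures: tiny genomes and record factories."""

from __future__ import annotations

import random

import pytest

from fusionsieve.ingest import GenomeAccessor
from fusionsieve.model import FusionRecord, GenePartner


def write_fasta(path, chroms: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


@pytest.fixture
def make_genome(tmp_path):
    """Factory: write a dict of chromosome sequences and open it."""

    counter = {"n": 0}

    def _make(chroms: dict[str, str]) -> GenomeAccessor:
        counter["n"] += 1
        path = tmp_path / f"genome{counter['n']}.fa"
        write_fasta(path, chroms)
        return GenomeAccessor(path)

    return _make


def make_record(
    sample="S1",
    tool="toolA",
    g5="GENA",
    g3="GENB",
    chrom5="chr1",
    chrom3="chr2",
    bp5=100,
    bp3=200,
    strand5="+",
    strand3="+",
    reads=None,
    split_count=None,
    spanning=0,
    consensus=None,
    annotated5=True,
    annotated3=True,
    **kwargs,
) -> FusionRecord:
    reads = list(reads) if reads else []
    if split_count is None:
        split_count = len(reads)
    return FusionRecord(
        sample_id=sample,
        tool_id=tool,
        gene5=GenePartner(g5, chrom5, strand5, bp5, annotated5),
        gene3=GenePartner(g3, chrom3, strand3, bp3, annotated3),
        split_read_count=split_count,
        spanning_read_count=spanning,
        split_reads=reads,
        consensus_sequence=consensus,
        **kwargs,
    )


def random_dna(rng: random.Random, length: int, alphabet="ACGT") -> str:
    return "".join(rng.choice(alphabet) for _ in range(length))
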