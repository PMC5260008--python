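"""Classify a single fusion's junction structure against the four virtual
references.

Builds a tiny two-chromosome genome, reconstructs the four junction
hypotheses for one fusion (promoter/3'-end retention on each side), and
matches split reads drawn from the prom-end reference against all four.
"""

import random
import tempfile
from pathlib import Path

from fusionsieve import (
    FusionRecord,
    GenePartner,
    GenomeAccessor,
    build_virtual_references,
    classify_fusion,
    is_reliable,
)

rng = random.Random(11)
workdir = Path(tempfile.mkdtemp())
fasta = workdir / "toy.fa"
with open(fasta, "w") as fh:
    for name in ("chr1", "chr2"):
        fh.write(f">{name}\n" + "".join(rng.choice("ACGT") for _ in range(500)) + "\n")
genome = GenomeAccessor(fasta)

fusion = FusionRecord(
    sample_id="S1",
    tool_id="toolA",
    gene5=GenePartner("GENEA", "chr1", "+", 200),
    gene3=GenePartner("GENEB", "chr2", "-", 300),
)

refs = build_virtual_references(genome, fusion, flank_len=30)
for kind in ("PROM_END", "END_PROM", "PROM_PROM", "END_END"):
    print(f"{kind:9s} reference: {refs[kind]}")

# split reads: error-free 30-mers crossing the prom-end junction
prom_end = refs["PROM_END"]
fusion.split_reads = [prom_end[10:40], prom_end[15:45]]
fusion.split_read_count = 2

call = classify_fusion(fusion, refs, min_overlap=15)
print(f"\nassigned structure : {call.label}")
print(f"best overlaps (bp) : {call.best_overlap}")
print(f"reliable structure : {is_reliable(call)}")

# The prom-end reference contains both reads in full (overlap 30 >= 15);
# the other hypotheses only reach short chance overlaps, so the fusion is
# labeled PROM_END — a promoter-retaining, biologically reliable structure.
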