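"""The priority union rule: structure and/or driver scores.

A fusion is marked *priority* when its junction structure is biologically
reliable (prom-end or prom-prom) OR either external driver score is
strictly greater than the threshold (default 0.7).  This prints the full
truth table, including the boundary case at exactly 0.70.
"""

from fusionsieve import FusionRecord, GenePartner, mark_priority
from fusionsieve.model import StructureCall


def fusion(label, pegasus, oncofuse):
    r = FusionRecord(
        sample_id="S1",
        tool_id="toolA",
        gene5=GenePartner("GENEA", "chr1", "+", 100),
        gene3=GenePartner("GENEB", "chr2", "+", 200),
    )
    r.structure = StructureCall(label, {})
    r.score_pegasus = pegasus
    r.score_oncofuse = oncofuse
    return r


print(f"{'structure':10s} {'pegasus':>8s} {'oncofuse':>9s}  priority")
for label in ("PROM_END", "PROM_PROM", "END_PROM", "END_END", "NO_MATCH"):
    for peg, onc in [(None, None), (0.70, 0.70), (0.71, 0.3), (0.2, 0.93)]:
        r = mark_priority(fusion(label, peg, onc), threshold=0.7)
        peg_s = "-" if peg is None else f"{peg:.2f}"
        onc_s = "-" if onc is None else f"{onc:.2f}"
        print(f"{label:10s} {peg_s:>8s} {onc_s:>9s}  {'priority' in r.flags}")

# Note the strict comparison: scores of exactly 0.70 never make a fusion
# priority on their own, and absent scores never count as "scored low".
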