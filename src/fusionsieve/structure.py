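"""Virtual-reference reconstruction and junction-structure classification.

For each fusion, four synthetic junction sequences ("virtual references")
are built from the genomic sequence flanking the two breakpoints, one per
hypothesis about which portion of each partner gene is retained in the
chimeric transcript:

PROM_END   promoter side of the 5' gene  +  3'-end side of the 3' gene
END_PROM   promoter side of the 3' gene  +  3'-end side of the 5' gene
PROM_PROM  promoter sides of both partners
END_END    3'-end sides of both partners

The split reads (or the caller's consensus sequence) supporting the fusion
are then matched against the four references; the hypothesis achieving the
longest exact junction-spanning overlap, provided it reaches a minimum
overlap, is the assigned structure.  PROM_END and PROM_PROM structures keep
an intact promoter driving the 5' portion and are the biologically
*reliable* configurations — the ones compatible with high transcription of
the chimera.

Flank construction: with B5 the last retained transcribed base of the 5'
partner and B3 the first retained transcribed base of the 3' partner (all
in transcript orientation),

  P(x)  = flank_len bases ending at x's breakpoint inclusive,
  T(x)  = flank_len bases starting immediately after x's breakpoint,
  T3(x) = flank_len bases starting at x's breakpoint inclusive,

  PROM_END  = P(g5)  ++ T3(g3)
  END_PROM  = P(g3)  ++ T(g5)
  PROM_PROM = P(g5)  ++ rc(P(g3))
  END_END   = rc(T(g5)) ++ T3(g3)

so every flank abuts its breakpoint at the junction and each reference has
length ``2 * flank_len`` with the junction after base ``flank_len``.
Matching is exact and ungapped (no error model), N never matches any base,
and queries are tried in both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .ingest import GenomeAccessor, fetch_flank, reverse_complement
from .model import (
    NO_MATCH,
    STRUCTURE_LABELS,
    FusionRecord,
    StructureCall,
    ValidationError,
)

__all__ = [
    "VirtualReferenceSet",
    "build_virtual_references",
    "match_query",
    "classify_fusion",
    "is_reliable",
    "RELIABLE_LABELS",
]

#: Structures retaining a promoter on the 5' side (or both sides): the
#: configurations defined as biologically reliable.
RELIABLE_LABELS: frozenset[str] = frozenset({"PROM_END", "PROM_PROM"})


@dataclass(frozen=True)
class VirtualReferenceSet:
    """The four junction references built for one fusion.

    ``junction_index`` is the number of bases contributed by the first
    flank: bases 1..junction_index of each reference come from it, so the
    junction falls between positions junction_index and junction_index + 1.
    """

    references: dict[str, str]
    junction_index: int
    flank_len: int

    def __post_init__(self) -> None:
        if set(self.references) != set(STRUCTURE_LABELS):
            raise ValidationError(
                f"references must cover exactly {STRUCTURE_LABELS}"
            )
        for kind, seq in self.references.items():
            if len(seq) != 2 * self.flank_len:
                raise ValidationError(
                    f"reference {kind} has length {len(seq)}, expected {2 * self.flank_len}"
                )
        if self.junction_index != self.flank_len:
            raise ValidationError("junction_index must equal flank_len")

    def __getitem__(self, kind: str) -> str:
        return self.references[kind]


def build_virtual_references(
    genome: GenomeAccessor, fusion: FusionRecord, flank_len: int
) -> VirtualReferenceSet:
    """Reconstruct the four virtual references for ``fusion``.

    Both breakpoints must leave ``flank_len`` bp of margin inside their
    chromosomes on each side; a flank running off the chromosome raises.
    """
    if flank_len < 1:
        raise ValidationError(f"flank_len must be >= 1, got {flank_len}")
    g5, g3 = fusion.gene5, fusion.gene3

    def flank(p, side):
        return fetch_flank(genome, p.chrom, p.breakpoint, side, flank_len, p.strand)

    p5 = flank(g5, "ending_at")        # promoter-side flank of the 5' gene
    t5 = flank(g5, "downstream_of")    # 3'-end-side flank of the 5' gene
    p3 = flank(g3, "ending_at")        # promoter-side flank of the 3' gene
    t3 = flank(g3, "starting_at")      # 3'-end-side flank of the 3' gene

    references = {
        "PROM_END": p5 + t3,
        "END_PROM": p3 + t5,
        "PROM_PROM": p5 + reverse_complement(p3),
        "END_END": reverse_complement(t5) + t3,
    }
    return VirtualReferenceSet(references=references, junction_index=flank_len, flank_len=flank_len)


def _spanning_overlap(query: str, ref: str, junction_index: int) -> int:
    """Longest common substring of query and ref covering the junction.

    The substring must cover reference positions junction_index and
    junction_index + 1 (1-based), i.e. straddle the junction.  N never
    matches any base, including another N.  Suffix-length dynamic
    programming: a common substring of length L ending at reference
    position i spans the junction iff i > junction_index and
    L >= i - junction_index + 1.
    """
    n, m = len(ref), len(query)
    best = 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        base = ref[i - 1]
        if base != "N":
            for j in range(1, m + 1):
                if query[j - 1] == base:
                    length = prev[j - 1] + 1
                    cur[j] = length
                    if i > junction_index and length >= i - junction_index + 1:
                        if length > best:
                            best = length
        prev = cur
    return best


def match_query(query: str, ref: str, junction_index: int) -> int:
    """Best junction-spanning exact overlap of ``query`` (either
    orientation) with ``ref``; 0 if none exists."""
    if not query:
        raise ValidationError("query must be non-empty")
    return max(
        _spanning_overlap(query, ref, junction_index),
        _spanning_overlap(reverse_complement(query), ref, junction_index),
    )


def classify_fusion(
    fusion: FusionRecord,
    refs: VirtualReferenceSet,
    min_overlap: int,
    tie_break_order: tuple[str, ...] = ("PROM_END", "PROM_PROM", "END_PROM", "END_END"),
) -> StructureCall:
    """Assign a structure label from the fusion's sequence evidence.

    Queries are the split reads when available, else the consensus
    sequence.  Per reference the best overlap over all queries is recorded;
    the label is the reference with the largest overlap at or above
    ``min_overlap`` (ties broken by ``tie_break_order``), or NO_MATCH when
    none qualifies.
    """
    queries = list(fusion.split_reads) if fusion.split_reads else (
        [fusion.consensus_sequence] if fusion.consensus_sequence else []
    )
    if not queries:
        raise ValidationError(
            "classify_fusion needs at least one split read or a consensus sequence"
        )
    best_overlap = {
        kind: max(match_query(q, refs[kind], refs.junction_index) for q in queries)
        for kind in STRUCTURE_LABELS
    }
    label = NO_MATCH
    best = min_overlap - 1
    for kind in tie_break_order:
        if best_overlap[kind] >= min_overlap and best_overlap[kind] > best:
            label = kind
            best = best_overlap[kind]
    return StructureCall(label=label, best_overlap=best_overlap)


def is_reliable(call: StructureCall) -> bool:
    """True iff the structure keeps a promoter driving the fusion
    (PROM_END or PROM_PROM)."""
    return call.label in RELIABLE_LABELS
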