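# Methods

## Scope and model

`fusionsieve` implements a prioritization cascade for candidate gene
fusions called from paired-end RNA-seq by several discovery tools. It
does not call fusions and it does not reimplement the external
driver-score classifiers (a gradient-tree-boosting model and a Naive
Bayes model): their per-fusion probabilities, like the protein-level
annotation fields (reading frame, domains), are pass-through inputs. The
package's own substance is the harmonization of multi-tool calls, the
three removal filters, the junction-structure analysis against
reconstructed virtual references, and the final priority rule.

## Coordinates, keys and identity

All coordinates are 1-based inclusive internally; the ChimeraScan-like
dialect's 0-based breakpoint starts are incremented by one on read (and
decremented on write, making the conversion bijective). A fusion's
identity is the tuple (5' gene name, 3' gene name, 5' breakpoint,
3' breakpoint), case-sensitive and orientation-sensitive: A–B and B–A are
distinct events, and the same gene pair at different breakpoints is a
distinct isoform junction. Duplicate collapsing additionally keys on the
reporting tool. Collapsing by gene pair alone would merge genuinely
distinct isoform junctions, so the breakpoint-inclusive key is the
conservative choice; cross-tool matching likewise requires exact
breakpoint equality after normalization.

One deliberate deviation inside collapsing: merged records' split-read
count is the size of the deduplicated read union *when read sequences are
present*; when the merged records carry only counts and a consensus (the
deFuse/MapSplice reporting style), the maximum count is kept instead.
Taking the union size unconditionally would set the count of every merged
consensus-only record to zero and have the split-read filter remove
fusions that are, in fact, supported.

## Virtual references and matching

With flank length F (default 30 bp), and writing P(x) for the F
transcript-orientation bases ending at gene x's breakpoint inclusive,
T(x) for the F bases starting immediately after it, and T3(x) for the F
bases starting at it inclusive:

    PROM_END  = P(g5)  ++ T3(g3)
    END_PROM  = P(g3)  ++ T(g5)
    PROM_PROM = P(g5)  ++ rc(P(g3))
    END_END   = rc(T(g5)) ++ T3(g3)

Each reference is 2F bp with the junction after base F. The breakpoint
convention is the common caller one — 5' breakpoint = last retained
transcribed base, 3' breakpoint = first retained transcribed base — which
keeps the prom-end reference gap-free and duplication-free. Flanks are
genomic, not transcript-model-aware: intron-containing flanks are a known
limitation (see below). Minus-strand flanks are reverse complements of
the genomic interval mirrored about the breakpoint, so "ending at" always
means "the transcribed bases up to and including the breakpoint".

The published description leaves three choices open, resolved here as
follows and kept configurable where sensible:

* **Reference length.** "30 bp" is read as 30 bp *per flank* (60 bp
  total), so a 15 bp minimum overlap can sit asymmetrically across the
  junction; `flank_len` is a config key, so the 30-bp-total reading is
  one setting away (`flank_len=15`).
* **Orientation of prom-prom / end-end.** The second flank of PROM_PROM
  and the first of END_END are reverse-complemented as in the formulas
  above; the simulator uses the identical construction, so
  classification is self-consistent by design.
* **Overlap counting.** "Overlap" is the total length of the longest
  exact, ungapped common substring between a query (either orientation)
  and the reference that straddles the junction — not per-side counts.
  Matching is exact with no error model; exactness makes a brute-force
  all-substrings oracle trivially correct, and the matcher is verified
  against that oracle. N never matches any base, including another N.

The matcher is the classical common-suffix dynamic program: a common
substring of length L ending at reference position i straddles the
junction iff i > F and L ≥ i − F + 1; the best such L over all (i, j) is
the overlap. Queries are the split reads when present, else the consensus
sequence. The label is the hypothesis with the largest overlap ≥
`min_overlap`; ties break deterministically by `tie_break_order`, default
PROM_END, PROM_PROM, END_PROM, END_END — the biologically reliable
interpretations first. If nothing reaches the minimum the call is
NO_MATCH. PROM_END and PROM_PROM calls are *reliable*: they retain a
promoter driving the 5' portion (or both promoters), the configurations
compatible with high transcription of the chimera.

## Filters and priority

The unannotated-partner filter removes a fusion when either gene is
flagged unannotated or its name begins with one of the configured
prefixes; the default list is AC0, AC1, AK, AD0, AL0, AL1, AL5, AL6,
AP0, NCRNA, LL22NC, CTC, RNASE, HLA, BC0, BC1, LOC (deduplicated), and
the match is a plain case-sensitive prefix test. Normal subtraction pools
all provided healthy-sample tables: a key match in any of them removes
the fusion. The split-read filter keeps records with count ≥ 1. Stage
order is fixed (annotation → normals → split reads → structure → scores →
priority); the two predicate filters commute in membership, but per-stage
counts are reported in this declared order.

Priority is the union rule: reliable structure OR pegasus score >
threshold OR oncofuse score > threshold, with *strict* inequality
(default threshold 0.7, so 0.70 exactly does not qualify) and absent
scores never exceeding any threshold. Flags accumulate monotonically; no
stage ever clears one.

## The simulator

`synthfix.simulate` generates the complete test substrate: a uniform-base
random toy genome (10 kb chromosomes by default, the count auto-grown so
every gene side gets a disjoint breakpoint slot, both strands exercised),
fusions planted per structure class with reads sampled *from the same
virtual-reference construction the classifier uses*, decoys with
excluded-prefix names, fusions co-planted in a normal table, zero-split
calls, consensus-only calls, same-tool duplicates with partitioned read
sets, multi-tool and multi-sample recurrences, and an optional score
table. A ground-truth table records, per fusion, everything needed to
predict the exact record count at every pipeline stage
(`predict_stage_counts`), which is what the cascade-accounting checks
compare against.

Reads overlap the junction by `junction_span` true-reference bases
(default: the whole read, drawn verbatim from the reference with at least
min(min_overlap, read_len/2) bases on each side of the junction). When
`junction_span` is below the read length the flanking read bases are
*anti-matched* — sampled from the three bases differing from the aligned
reference base — so the achieved overlap equals the span exactly and a
span below `min_overlap` forces NO_MATCH deterministically. Identical
seeds give byte-identical output files.

What the simulator does not emulate: sequencing errors, indels, coverage
and insert-size distributions, transcript structure (exon boundaries,
splicing) and homology between loci. Passing the round-trip and
accounting checks therefore demonstrates the internal consistency and
bookkeeping of the cascade under its own assumptions, not robustness to
noisy reads or to paralogous sequence on real genomes.

## Numerical and degenerate-input choices

* Exact matching has no tolerances; all counts are integers and the only
  real-valued inputs (scores) are compared strictly against the
  threshold.
* A flank that would run off its chromosome is an error, never a silent
  truncation; length-0 flanks and empty queries are errors.
* Empty call tables, empty normal lists and absent score tables are
  valid inputs (the corresponding stages become no-ops and are logged).
* Absent scores are represented as absent (empty TSV fields), never 0,
  distinguishing "unscored" from "scored low".
* Problem sizes in the checked properties — 50 fusions per class for the
  classifier round trip, 1000 random pairs for the oracle comparison,
  ~40-fusion mixed fixtures for accounting — were chosen as the package's
  own verification scale; all complete in seconds.

## Known limitations

* Flanks are genomic, so a breakpoint near an exon boundary of a spliced
  transcript yields a virtual reference containing intronic sequence
  that real junction reads will not fully match; transcript-model-aware
  flank extraction is out of scope.
* Exact, ungapped matching means a single sequencing error inside the
  junction-spanning block shortens the measured overlap.
* Cross-tool matching requires exact breakpoint equality; tools that
  round breakpoints to different positions will not be recognized as the
  same event (no fuzzy windows, no gene-symbol synonym resolution).
* Spanning-read counts are carried through and reported but used by no
  filter.
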