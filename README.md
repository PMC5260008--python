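# fusionsieve

Prioritization of candidate gene fusions from RNA-seq data.

Chimeric-transcript discovery tools (deFuse, ChimeraScan, MapSplice and
kin) emit long, poorly overlapping candidate lists dominated by false
positives, far more than a wet lab can validate by PCR. `fusionsieve`
harmonizes the union of calls from several tools into one sample-centred
table and shrinks it to a short list of *priority* fusions through a
filtering cascade plus an analysis of each fusion's junction structure.

## The cascade

For every sample, candidate records flow through:

1. **Regrouping & collapsing** — calls are grouped per sample; records in
   which one tool reports the same fusion (same gene pair and breakpoints)
   with different supporting reads are merged, their split reads unioned.
   Fusions found by more than one tool, or recurring in more than one
   sample of the cohort (shared vs. private), are labelled.
2. **Unannotated-partner filter** — fusions in which either gene name
   starts with a configurable prefix (LOC, AC0, HLA, …) or is flagged
   unannotated are removed: no driver role can be hypothesized for them.
3. **Normal subtraction** — fusions whose key also occurs in any
   healthy-sample call table are removed.
4. **Split-read filter** — fusions without at least one read crossing the
   junction are removed; without such reads the fusion sequence cannot be
   reconstructed or validated.
5. **Structure analysis** — for each survivor, four *virtual references*
   are built from the genomic sequence flanking the two breakpoints, one
   per retention hypothesis: promoter side of the 5' gene + 3'-end side of
   the 3' gene (*prom-end*), the converse (*end-prom*), both promoter
   sides (*prom-prom*), both 3'-end sides (*end-end*). Each reference is
   `2 × flank_len` bp (default 2 × 30) with the junction in the middle.
   The fusion's split reads (or consensus sequence) are matched exactly,
   in both orientations, against each reference; a match counts only if it
   straddles the junction and reaches `min_overlap` bp (default 15). The
   best-scoring hypothesis is the assigned structure, or *NoMatch*.
   Prom-end and prom-prom structures retain an intact promoter driving the
   chimera and are called **reliable**.
6. **Priority rule** — a fusion is **priority** iff its structure is
   reliable **and/or** either external driver-score probability (from the
   Pegasus or Oncofuse classifiers, consumed as inputs) is strictly
   greater than a threshold (default 0.7).

Every removal is recorded with its stage, so the per-sample report
accounts for every input record.

## Worked example

`examples/01_full_cascade.py` simulates a two-sample cohort — five planted
fusions per structure class plus decoys, normal-shared fusions, calls
without split reads and a driver-score table — and runs the cascade:

```
input records            : 24
after duplicate collapse : 24
removed (unannotated)    : 4
removed (normal-shared)  : 4
removed (no split reads) : 4
retained                 : 12
reliable structure       : 6
priority fusions         : 8
```

Four records fall at each filter (the planted decoy / normal-shared /
zero-split fractions), twelve survive to structure analysis, six of those
have a promoter-retaining junction, and eight end up priority (the six
reliable ones plus two with a driver score above 0.7).

`examples/02_structure_classification.py` shows the four reconstructed
references for one fusion and the per-hypothesis overlaps
(`{'PROM_END': 30, 'END_PROM': 2, 'PROM_PROM': 3, 'END_END': 3}` for reads
drawn from the prom-end junction), and `examples/03_priority_rule.py`
prints the priority truth table including the strict-inequality boundary
at a score of exactly 0.70.

## Command line

```
fusionsieve simulate --seed 7 --n-per-class 5 --outdir sim/
fusionsieve run --genome sim/genome.fa --tumor sim/tumor_fusions.tsv \
    [--normal normal.tsv ...] [--scores scores.tsv] [--config cfg] --outdir out/
```

`run` writes one TSV report per sample and logs the record count entering
and leaving every stage to stderr. The configuration file is plain
`key=value` (`flank_len`, `min_overlap`, `driver_threshold`,
`exclude_prefixes`, `tissue`, `tie_break_order`); missing keys take the
defaults above. Input tables may be in the package's generic TSV dialect
or in deFuse-like, ChimeraScan-like (0-based coordinates, converted on
read) or MapSplice-like layouts.

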