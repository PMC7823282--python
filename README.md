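# refnof1

Method-agnostic consensus reference standards for evaluating
**single-subject differential expression** — the "N-of-1" setting where one
subject contributes exactly one transcriptome per condition (treated vs.
control, stimulated vs. unstimulated) and no replicates exist to estimate
variance.

## The problem

Single-subject DEG calls cannot be validated against a biological gold
standard at genome scale, and validating a method against a standard built
with the *same* method (an isomorphic evaluation) merely replicates that
method's systematic artefacts. Different callers also disagree wildly on the
same data: lists of ~3 000 calls from two standard tools may share only
~2 000 genes, leaving thousands of conflicting calls.

`refnof1` builds *heteromorphic* reference standards instead:

1. Run several statistically heterogeneous DEG callers on a replicated
   isogenic dataset (the closest proxy to a single subject).
2. For every cell of a filter grid — low-expression cutoffs
   `{0, 5, 10, 20, 30, 50}` × oriented fold-change windows
   `{[1, 1.1), [1.1, 1.2), [1.2, 1.3), [1.3, 1.5), [1.5, ∞)}` — compute all
   pairwise Jaccard indices `J(M, N) = |M ∩ N| / |M ∪ N|` between the
   methods' significant-gene sets, stratified into the window.
3. Grid-search (cutoffs ascending, windows ascending; early stop) for the
   first cell whose **median pairwise Jaccard** reaches a user target — the
   smallest thresholds that make the methods agree.
4. Build the consensus standard in that region by **intersection** or
   **strict majority vote**, always *excluding the method under
   evaluation*.
5. Score 1-vs-1 single-subject predictions from held-out sample pairs
   against the standard (precision/recall, averaged over pairs).

Fold changes use `FC_k = A_k / B_k` with down-regulated genes mapped to
their reciprocal (`1/FC`), so windows are symmetric about 1. The expression
cutoff applies to a gene's mean raw count across all samples. Significance
is Benjamini–Hochberg-adjusted `p < α` (default α = 0.05), adjusted within
the expression-filtered universe.

Four built-in callers span the usual distributional families — an exact
conditional (hypergeometric) test on pooled counts, a negative-binomial
Wald test, an exact rank-sum test, and a delta-method z-test on the log2
ratio of scaled means. Output from real external tools (edgeR, DESeq2,
NOISeq, ...) plugs in through a TSV adapter and is treated identically. A
seeded negative-binomial simulator with planted fold changes provides
ground truth for calibration and recovery experiments.

## Worked example

```bash
python examples/02_optimize_filters.py
```

```
target attained at cutoff=0,fc=[1.5,inf) (median Jaccard 0.527)
cells evaluated before stopping: 5 of 30

median pairwise Jaccard per grid cell (rows: expression cutoff, columns: FC window):
       1.0 1.1 1.2  1.3    1.5
       1.1 1.2 1.3  1.5    inf
cutoff
0      NaN NaN NaN  0.0  0.527
5      NaN NaN NaN  0.0  0.518
10     NaN NaN NaN  0.0  0.518
20     NaN NaN NaN  0.0  0.518
30     NaN NaN NaN  0.0  0.527
50     NaN NaN NaN  0.0  0.509
```

On a simulated 2 000-gene, 7-vs-7 replicate experiment, three callers agree
on essentially nothing below fold change 1.3 (blank cells: no method made a
prediction there; 0.0: predictions exist but never overlap), while in the
open `[1.5, ∞)` window more than half of their calls coincide
(median Jaccard 0.53). The optimizer stops at the first qualifying cell —
`cutoff 0, FC ≥ 1.5` — i.e. the least destructive filter combination that
meets the 0.5 concordance target. Examples `01`–`05` walk the remaining
capabilities: simulation, consensus standards, hold-out evaluation, and the
external-tool adapter. The same operations are available from the shell via
the `refnof1` CLI (`simulate`, `optimize`, `build-rs`, `evaluate`,
`report`).

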