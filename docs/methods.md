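# Methods

## Setting and model

A single-subject ("N-of-1") transcriptome study measures one subject once
per condition — two samples total, no replicates — and asks which gene
products changed. Because no per-gene variance can be estimated from the
pair, DEG callers for this setting lean heavily on distributional
assumptions, and different callers produce conflicting lists. `refnof1`
does not propose another caller; it constructs the *evaluation* apparatus:
a consensus reference standard derived from several methods run on
replicated isogenic data, with the method under test excluded, against
which single-subject predictions from held-out sample pairs are scored.

The pipeline has five stages.

**Fold change and orientation.** For gene *k*, `FC_k = A_k / B_k`, the
ratio of its mean expression in condition A to condition B. In replicated
data the means are per-condition arithmetic means of (optionally
library-size scaled) counts; in a 1-vs-1 prediction pair they are the two
samples' values. Up- and down-regulation are not distinguished when
filtering: the *oriented* fold change is `max(FC, 1/FC) ≥ 1`, so a window
like `[1.2, 1.3)` covers raw ratios in `[1.2, 1.3) ∪ (1/1.3, 1/1.2]`.
Windows are half-open on the oriented scale, which guarantees the default
windows `[1,1.1), [1.1,1.2), [1.2,1.3), [1.3,1.5), [1.5,∞)` partition
`[1, ∞)`. When either condition mean is zero, a pseudocount (default 0.5)
is added to *both* means; a gene with both means zero and pseudocount 0
has an undefined fold change and belongs to no window.

**Expression filtering.** A gene enters the analysis universe of a grid
cell when its mean *raw* count across all samples (both conditions pooled)
is at least the cell's cutoff (defaults 0, 5, 10, 20, 30, 50). DEG calling
and Benjamini–Hochberg adjustment happen once per cutoff on exactly that
universe — the power gain of prefiltering materialises only if the
correction follows the filter. The fold-change windows then *stratify*
each method's significant set; they do not trigger re-testing (a
`retest_within_window` flag provides the alternative reading, in which
callers are re-run within each window's gene set).

**Concordance.** Within a region, each unordered pair of methods gets a
Jaccard index `|M ∩ N| / |M ∪ N|` on their significant sets. A pair where
both sets are empty made no predictions and is *undefined* (excluded from
medians, rendered white in heatmaps); one empty set against a non-empty
one scores 0. The region summary is the median over defined pair values;
per-method medians are reported as diagnostics only.

**Optimization.** The grid is walked cutoffs-ascending (outer), windows
ascending by lower bound (inner), and the search stops at the first region
whose defined median reaches the target — under this traversal the first
hit is also the least destructive filter combination. Undefined medians
never satisfy the target; ties are resolved by traversal order alone. The
search is fully deterministic. Targets above 1 are accepted and simply
unattainable, yielding the "no threshold achieved target" outcome.

**Consensus and evaluation.** The reference standard's positives are the
genes called by all contributing methods (intersection) or by strictly
more than half of them (majority; 3-of-4 when four contribute — the
conservative reading of "simple majority" for even counts). The universe
is the region's *expression-filtered* gene set; the window restricts the
positives but not the universe, so negatives remain "the rest of the
measured transcriptome at this cutoff". A multi-region union constructor
supports compositions such as "(cutoff 0, FC 1.3–1.5) ∪ (cutoff 30,
FC ≥ 1.5)". The hold-out protocol splits samples into reference replicates
(default 4 per condition) and disjoint 1-vs-1 prediction pairs (default
3); predictions pass through the same region filters as the standard
before scoring (a flag disables this and scores the raw pair calls).
Precision is undefined for empty prediction sets and recall for empty
positive sets; averages are over pairs where the metric is defined, with
the undefined count reported. Scoring a method against a standard it
contributed to is refused outright (isomorphic-evaluation guard).

## Built-in callers

Faithful reimplementation of the standard Bioconductor callers is out of
scope; external tools' tables enter through the adapter and are
thresholded on their own adjusted p-values without re-adjustment. The four
built-ins are transparent statistics chosen to span the same families —
pooled-count exact, negative binomial, non-parametric, and normal-theory —
so the consensus machinery can be exercised self-contained:

- **pooled_exact** — counts are pooled per condition; each gene's 2×2
  table (gene vs. remainder of library, A vs. B) gets the exact
  conditional hypergeometric test, two-sided by summing the probabilities
  of all tables no more likely than the observed one. Tables with gene
  totals ≤ 64 are evaluated in exact integer arithmetic (ties resolved
  exactly); larger tables use log-space summation with a 1e-9 relative
  tie tolerance. Valid down to one sample per condition.
- **nb_wald** — per-gene NB model with total-count size factors.
  Method-of-moments dispersions from the pooled within-condition variance
  are shrunk 1:2 toward a fitted `a + b/μ` trend (the gene-wise estimate
  is noisy at a handful of replicates). Wald test on `ln(q_A/q_B)` with
  the delta-method variance `(1/n²)(Σ_j 1/(q s_j) + n φ)` per condition,
  against the standard normal. With one sample per condition a fixed
  external dispersion must be supplied.
- **rank_sum** — exact two-sided Mann–Whitney test on scaled counts
  (≥ 3 replicates per condition). The exact null pmf of U is computed
  once per (n_A, n_B) by the standard counting recurrence; genes with
  tied scaled counts fall back to the tie-corrected normal approximation
  with continuity correction.
- **zlogfc** — z-test on the log2 ratio of scaled condition means, same
  delta-method variance as nb_wald but with a single common dispersion
  (median of the per-gene moment estimates, or a fixed value for 1-vs-1).

The normal reference for nb_wald/zlogfc was chosen over a t reference
after calibration measurements: under the NB null at 7 replicates per
condition the normal gives mean type-I error 0.052/0.058 at α = 0.05,
while t(n_A+n_B−2) is over-conservative (0.034/0.039). Plug-in variance
makes both tests mildly anticonservative at very small replicate numbers.

Benjamini–Hochberg adjustment is delegated to
`statsmodels.stats.multitest.multipletests`. The exact hypergeometric
p-value is implemented in-package because generic two-sided Fisher
implementations resolve probability ties with a loose (1e-7) relative
tolerance, too coarse for the 1e-10 oracle-agreement contract this
package tests against.

## Synthetic data

The generator emulates the replicated isogenic designs used to validate
single-subject analyses: a cell line or strain measured with several
biological replicates under stimulus and control. Counts are negative
binomial, `Var = μ + φμ²`, sampled as a gamma–Poisson mixture; `φ = 0`
gives exact Poisson counts. Defaults: 20 000 genes; 7 replicates per
condition; log-normal baselines (log-mean 4, log-sd 1.5); constant
dispersion 0.05 (isogenic replicates are far less variable than human
cohorts), with an optional `+ trend/μ` term; library-size factors
log-normal with log-sd 0.1; 10% of genes differential. Planted oriented
fold changes are drawn per window with mixture weights 85:175:700:1100:365
(proportional to the per-window DEG counts of a replicated breast-cancer
benchmark), direction uniform, the open `[1.5, ∞)` window truncated at 4,
and the effect split symmetrically between conditions
(`μ_A = b·√FC, μ_B = b/√FC`). Non-differential genes have fold change
exactly 1. Seeds are mandatory; no global random state is touched.

What the generator does *not* model: batch effects, read-level artefacts,
GC/length biases, correlated genes, outlier samples, or heavy-tailed
dispersion. Passing recovery tests therefore demonstrates internal
correctness of the pipeline under its stated model, not performance on
real data — for real data the external-tool adapter is the intended path.

### Named scenarios and problem sizes

- `null_scenario` — 2 000 genes, 7 replicates, no planted effects,
  log-mean 5 / log-sd 1 baselines (asymptotic tests assume non-negligible
  counts). Dispersion 0 is the Poisson null matching pooled_exact's
  assumptions; 0.05 is the NB null for the replicate-based callers.
  Used to verify each caller's raw type-I error at α = 0.05 stays within
  3 binomial standard errors of 0.05.
- `recovery_scenario` — 5 000 genes, 7 replicates, 10% DEGs across all
  windows. Seven replicates matches the emulated design and is needed for
  feasibility: an exact rank-sum test at 5v5 has minimum two-sided
  p = 2/C(10,5) ≈ 0.0079, so with a tenth of genes differential its
  minimum attainable BH-adjusted p is ≈ 0.079 — at five replicates it can
  never call anything at α = 0.05, making any "every caller recovers
  signal" check unsatisfiable by arithmetic rather than by defect.
- `strong_effect_scenario` — as above with all effects in `[1.5, ∞)`
  planted on above-median-baseline genes; the high-power setting where
  every caller should recover most of the truth.

Test and acceptance runs use 400–5 000-gene simulations; the acceptance
script's main study uses 4 000 genes so the full pipeline (grid search
over four callers, consensus construction, three-pair hold-out
evaluation) completes in well under a minute.

## Numerical and degenerate-input conventions

- Library scaling: `total_count` divides each sample by its library size
  over the mean library size; zero-depth samples are left unscaled.
- An empty universe (extreme cutoff) yields empty DEG sets, an
  all-undefined concordance cell, and an undefined median — never an
  error.
- Counts must be integers; values within 1e-6 of an integer are rounded
  (public preprocessed matrices often carry float noise), anything
  further is a validation error naming the gene and sample.
- Undefined metrics (precision with no predictions, recall with no
  positives, Jaccard with two empty sets) are represented as
  None/NaN and excluded from averages; they are never coerced to 0.

## Known limitations

- The built-in callers are deliberately simple stand-ins; conclusions
  about real tools require importing their actual output.
- The optimizer searches only the user-supplied grid; no extrapolation or
  self-tuning beyond it.
- Majority weighting is unweighted one-method-one-vote; no probabilistic
  or rank-aggregation consensus.
- No ROC/AUC sweeps; evaluation reports precision/recall at a fixed α.
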