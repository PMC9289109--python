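# Methods

## Model and procedure

The pipeline treats each cohort as an independent case/control study on a
shared gene universe of log2-scale expression. Within cohort *k*, gene *i*'s
group contrast is summarized by Hedges' g with its analytic sampling
variance; across cohorts the per-gene effects are assumed exchangeable
around a gene-level mean with between-cohort variance τ² — the standard
random-effects model — and pooled by the DerSimonian-Laird method-of-moments
estimator. The pooled effect is tested with a two-sided normal z-test (no
small-k t-correction; with the cohort counts this pipeline targets, the
normal approximation is the conventional choice). FDR control is
Benjamini-Hochberg across all pooled genes.

Assumptions worth keeping in mind: expression is approximately normal on the
log2 scale within groups; cohorts differ by location (batch) but share the
within-group SD up to what the standardization absorbs; genes are treated
independently (no correlation structure enters the pooling or the FDR).

## The differential-expression filter

Genes pass with q < `fdr_max` (default 0.01) and |pooled g| > `effect_min`
(default 0.8). The effect threshold is applied on the standardized
(Hedges' g) scale. A fold-change reading of the same threshold ("0.8-fold in
non-log space") is arithmetically awkward — a 0.8-fold change is a
*decrease*, and the back-transform depends on the within-group SD the SMD
already absorbs — so the SMD interpretation is the default and the threshold
is a plain parameter for anyone preferring another convention.

## Forward search

Candidates are assigned to the up or down side once, by the sign of their
pooled effect, and never re-estimated per cohort. The objective is the
sample-size-weighted mean of per-cohort AUCs of the provisional score over
the discovery cohorts (configurable to unweighted). The stopping rule —
`min_improvement` default 0.0, i.e. any strict gain — favours parsimonious
signatures because AUC gains saturate quickly once a few strong genes are
in; `max_genes` is an optional hard cap. The first step always commits the
best single gene (with a warning if even that gene's objective is ≤ 0.5), so
a non-empty candidate list always yields a non-empty signature. Ties at any
step are broken by smaller FDR q, then larger |pooled effect|, then
lexicographic gene id; with strict greater-than comparison in the argmax
this makes the search deterministic and invariant to candidate input order.

## Scoring and evaluation

The disease score is the difference of per-side mean expression, in log2
units. Genes missing from a target cohort drop out of their side's mean; a
fully missing side contributes 0 (logged). Because the score is a difference
of means over a fixed gene set, it is invariant to sample-wise constant
shifts when both sides are non-empty, which is what makes it portable across
location-shifted cohorts.

AUC uses the Mann-Whitney convention (ties count ½). The per-cohort 95% CI
is a stratified percentile bootstrap (default 2000 resamples): resampling
within class guarantees both classes survive every resample, so no redraw
logic is needed. The summary AUC pools per-cohort AUCs on the logit scale by
DerSimonian-Laird, with each AUC's variance taken from the Hanley-McNeil
formula and mapped to the logit scale by the delta method; AUCs of exactly
0 or 1 are clipped into [1/(4n), 1 − 1/(4n)] (n = cohort total sample size)
before the logit. Both choices — bootstrap percentile CI and DL-on-logit
pooling — are implementation decisions; they are conventional but not the
only defensible ones, and are isolated behind `auc_ci` and `summary_auc`.

The Wilcoxon rank-sum test uses exact enumeration when n₁·n₂ ≤ 400 and the
data are tie-free, otherwise the normal approximation with tie correction;
fully tied data return p = 1.

## Quantile normalization

Columns are mapped onto the across-sample mean of order statistics. Ties
within a column receive the mean of the reference values over the tied
ranks, making the map symmetric in tied entries and mass-preserving (column
means stay exactly equal). Note a consequence: on data with ties the
transform is not exactly idempotent, because the first pass changes the
reference distribution that a second pass would compute. On tie-free columns
— the generic case for continuous expression — it is idempotent to machine
precision. Normal-exponential background correction is deliberately not
implemented: it operates on probe-level raw intensities this package never
ingests (inputs are gene-level matrices).

## Synthetic data: what it emulates and what it does not

`simulate_cohorts` plants true effects d_ik ~ Normal(mu_effect, τ²) (negated
for the down set) so that case means exceed control means by d_ik·noise_sd —
i.e. the planted SMD is exactly d_ik. Cohorts get gene-constant location
shifts (batch ~ Normal(0, batch_shift_sd)) and i.i.d. Gaussian noise.
Defaults: the nine-cohort study design (three discovery cohorts of
996/177/49 samples, six validation cohorts of 67/26/72/47/142/115, 55%
cases — the published totals; the case/control split within each total is a
package default), mu_effect = 1.5, τ = 0.2, noise_sd = 1.0 (log2 units,
typical microarray within-group SD), batch_shift_sd = 0.5, baseline 8.0.
Tests and the acceptance script run the scaled design of 200 genes and three
to six cohorts of 40/40, which preserves every statistical property being
checked at a fraction of the cost.

Not emulated: gene–gene correlation, platform-specific mean-variance
trends, probe-level artifacts, RNA-seq count noise, and scale (variance)
heterogeneity between cohorts (off by default). Passing tests therefore
demonstrate correctness of the estimators and the selection machinery under
the model's own assumptions — not robustness to correlated genes or heavy
platform effects.

`simulate_mixture_cohort` draws each sample's cell-type abundance around its
group proportion (truncated-normal jitter, SD 0.1, clipped to [0, 1]) and
reads every marker as `baseline + 4·abundance + Normal(0, 0.3)` log2 units —
markers are strongly cell-type-specific genes whose dynamic range (4 log2
units over the abundance range) dominates replicate noise (0.3 log2).
Abundances are drawn independently per cell type rather than on a simplex:
scores are relative per-cell-type abundances (cross-cell-type comparison is
unsupported), and independence avoids compensatory shifts that would
contaminate specificity checks when one cell type is perturbed.

## Deconvolution

Marker-mean scoring (the MCP-counter family of methods): each cell type is
the arithmetic mean of its present markers' log2 expression; absent markers
are dropped, empty cell types excluded. Group shifts per cell type use the
Wilcoxon rank-sum test with BH correction across cell types and stars at
q < 0.05 / q < 0.01. With ten cell types and one true shift, BH at q < 0.05
flags an extra null cell type in roughly 9% of datasets — the expected
family-wise behaviour of the procedure, visible in the specificity rates the
acceptance script reports.

## Numerical and degenerate-input choices

- Zero pooled-SD genes get NaN effects and are excluded from pooling (no
  continuity correction), with a logged count.
- Genes absent from some cohorts are pooled over the cohorts containing
  them, gated by `min_cohorts` (default: all discovery cohorts — a strict
  common universe).
- k = 1 pooling reduces exactly to the single study's (g, √var) with τ² = 0.
- Raw-intensity detection: matrix maximum above 50 triggers log2(x+1);
  negative values alongside such a maximum are rejected as contradictory.
- Duplicate gene ids collapse by arithmetic mean of their rows.
- Missing values are dropped row-wise, never imputed.

## Known limitations

Exact numerical parity with any particular published multi-cohort analysis
is not claimed: CI method, summary-AUC pooling and the forward-search
stopping rule vary between implementations, and real cross-platform cohorts
add identifier harmonization and probe-level preprocessing that this package
intentionally leaves upstream (inputs must arrive as gene-level matrices
with harmonized gene symbols). The deconvolution component is a single
transparent marker-mean method, not a reimplementation of the many published
deconvolution algorithms; its scores are relative, not proportions.
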