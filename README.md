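# metasig

Multi-cohort case/control transcriptomic meta-analysis: pool per-gene effect
sizes across independent expression cohorts with random effects, select a
minimal diagnostic gene signature by greedy forward search, score samples,
validate the signature on held-out cohorts by ROC analysis, and quantify
immune-cell abundance from marker genes.

The package is aimed at analysts combining several case/control expression
datasets (e.g. public microarray series from different platforms and tissues)
into one diagnostic signature — the setting where single-cohort differential
expression is notoriously irreproducible and cross-cohort pooling with
between-study heterogeneity is the standard remedy.

## The statistics

**Effect sizes.** For gene *i* in cohort *k*, the case/control contrast is
Hedges' g — the standardized mean difference with small-sample correction:

```
J = 1 − 3/(4(n₁+n₂) − 9),   g = J·(x̄₁ − x̄₂)/s_pooled,
var(g) = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂))
```

**Pooling.** Per-gene effects are combined across cohorts by
DerSimonian-Laird random effects: Cochran's Q under fixed-effect weights
wᵢ = 1/vᵢ gives the method-of-moments between-cohort variance
τ² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)); the pooled effect is the
inverse-variance mean under weights 1/(vᵢ + τ²), tested with a two-sided
normal z-test and Benjamini-Hochberg corrected across genes.

**Filter and signature.** Genes with FDR q < 0.01 and |pooled g| > 0.8 enter
a greedy forward search that, at each step, adds the candidate maximizing
the sample-size-weighted mean of per-cohort AUCs of the resulting disease
score. The per-sample score is

```
score = mean(expression of up-regulated genes) − mean(expression of down-regulated genes)
```

**Validation.** Per-cohort AUC is the Mann-Whitney probability (ties = ½)
with a stratified percentile-bootstrap 95% CI; the cross-cohort summary AUC
pools logit-AUCs by DerSimonian-Laird with Hanley-McNeil variances.

**Deconvolution.** Cell types are quantified as the mean log2 expression of
their marker genes; case/control shifts are tested per cell type by Wilcoxon
rank-sum with BH correction across cell types.

A seeded synthetic generator produces multi-cohort data with planted up/down
genes under exactly this random-effects structure (plus per-cohort batch
shifts), and cell-mixture cohorts with known abundances, so the whole
pipeline is testable end to end.

## Worked example

Simulate five cohorts (three discovery, two validation; 40 cases / 40
controls each; genes G0001–G0004 planted up-regulated, G0005 down-regulated
at mean effect 1.5 SMD), then run the full workflow:

```
$ metasig simulate --config demo_config.yaml --out demo
wrote 5 cohorts to demo
$ metasig all --manifest demo/manifest.yaml --out demo/run --n-boot 500 --seed 0
validation summary AUC 0.984
done; artifacts in demo/run
```

`demo/run/signature.json` shows the greedy search recovered four of the five
planted genes, with the objective (weighted mean discovery AUC) rising at
every step:

```
{"up": ["G0004", "G0002", "G0001", "G0003"], "down": [],
 "trace": [["G0004", 0.885], ["G0002", 0.951], ["G0001", 0.970], ["G0003", 0.981]]}
```

and `demo/run/validation_roc.tsv` the held-out performance:

```
cohort_id  auc       ci_low  ci_high  wilcoxon_p  n_case  n_control
val1       0.984375  0.957   0.999    9.1e-14     40      40
val2       0.984375  0.965   0.998    9.1e-14     40      40
summary    0.984375  0.946   0.996                80      80
```

The summary AUC of 0.98 means a randomly chosen case outscores a randomly
chosen control 98% of the time in held-out data — the signature generalizes
beyond the cohorts it was derived from. A config with no planted genes exits
with status 3 ("no gene passes q<0.01"), the correct null behaviour.

The same workflow is available as library calls: `simulate_cohorts` →
`run_discovery` → `run_validation` (see `metasig/pipeline.py`).

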