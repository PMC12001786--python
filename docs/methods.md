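# Methods

## The mixture model

A bulk methylation sample is modelled as a convex combination of cell-type
signals.  For CpG *c*, cell type *k* and sample *i*:

```
X_ck(i) ~ N(μ_ck + y_i · 1[c,k planted] · sign_c · s_c ,  σ²_c)
X_c(i)  = Σ_k f_k(i) · X_ck(i)
```

with `y_i ∈ {0, 1}` the binary phenotype (cases = 1), `f(i)` the sample's
cell-fraction vector, and `s_c = SNR · σ_c` the planted shift expressed in
units of the pooled per-CpG noise SD.  The variance is common across cell
types: on purified-cell pools the homogeneity of per-CpG variances across
cell types is checked with Levene's test
(`reference.levene_common_variance_test`), and the panel carries a single
pooled σ²\_c per CpG (sample-size-weighted average of within-group
variances).  The simulator draws profile noise from that pooled variance,
not from the per-cell-type σ²\_ck.

## Reference panels

`synthesize_reference` emulates a purified-cell reference pool without any
external data: per-(CpG, cell type) means are uniform in `mean_hyper`
(default (0.1, 0.9), covering the usual intermediate-methylation range while
avoiding boundary pile-up), a per-CpG generating SD is uniform in
`sd_hyper` (default (0.01, 0.05), the typical within-cell-type beta-value
noise scale on arrays) and shared across cell types — consistent with the
common-variance model above.  `pure_samples_per_type` (default 20) Gaussian
replicates per cell type yield the empirical σ²\_ck and the pooled σ²\_c.
Pooling defaults to *all* cell types: with a synthetic panel every cell type
has an adequate replicate count, so the reason to restrict pooling to the
well-replicated immune pools (as one would with real purified data, where
epithelial/fibroblast pools are tiny) does not apply.  A
`pooling_cell_types` argument restores any restricted subset.

Preprocessing utilities mirror the array QC chain: `clip_beta` maps β values
into [ε, 1−ε] (default ε = 1e−6) so logit/probit transforms stay finite;
`apply_call_rate_filters` masks entries failing the detection p-value
(threshold 1e−16), then removes samples with call rate < 95% *first* and
probes with call rate < 90% *second* — the order matters, since dropping a
failing sample can rescue a probe.  Missing-data imputation is out of scope:
the simulator never produces missingness, and filtered matrices can be
passed to any imputer.

## Simulation designs

Fractions are drawn uniformly within per-cell-type bounds and each row is
divided by its sum.  The bundled bounds have interval means that already sum
to 1 (five-cell design: epithelial U(0.3, 0.4), fibroblast U(0.35, 0.45),
CD4T U(0.1, 0.2), monocyte U(0, 0.1), B cell U(0, 0.1); six-cell blood
design: neutrophil U(0.4, 0.6), CD4T U(0.2, 0.3), CD8T U(0.05, 0.15),
monocyte/B/NK U(0, 0.1)), so renormalisation is a small correction that
preserves the intended relative abundances.

Effect layouts: the five-cell design plants 500 CpGs each (non-overlapping)
in epithelial, CD4T and monocyte cells out of 10,000; the blood designs
plant 1,000 CpGs per affected cell type out of 20,000, settings 1a/1b with
neutrophil+CD4T+CD8T+monocyte (totals 4,000, or 3,500 unique when 500 CpGs
are shared between CD4T and CD8T in 1b) and 2a/2b with CD4T+CD8T+monocyte
(3,000 / 2,500).  Shared CpGs receive the same s\_c and the same sign in
both members — the natural reading of a "shared effect", and the choice that
makes the γ\_CD4T − γ\_CD8T contrast exactly null.  `scale` shrinks p and
the per-cell-type counts proportionally for desk-scale runs; the effect
*density* (planted fraction of CpGs) is preserved.

Defaults follow the study conditions: SNR grid 7–15 in steps of 2 (default
11, the grid midpoint), n ∈ {100, 200} (default 100), 1:1 case-control
ratio, 50 replicates per setting (replicate r reuses `base_seed + r`, so any
single replicate is independently reproducible).  Effects default to
hypermethylation in cases (+s\_c); a random-sign mode supports bidirectional
scenarios.  Mixtures are clipped to [ε, 1−ε] by default so outputs are valid
beta values; an unclipped mode reproduces the literal Gaussian model (used
by the tests that rely on exact distributional identities, since boundary
clipping truncates the tails).

## Detection

The native detector is the linear interaction-model class: per CpG, OLS of
the bulk values on `[f_1..f_K, f_1·y..f_K·y]` plus optional additive
covariates, **without intercept** — with fractions summing to one an
intercept is collinear with the fraction block, and the no-intercept
parameterisation keeps each interaction coefficient γ\_k interpretable as
the case-control shift within cell type k.  Because the design matrix is
shared across CpGs, one Gram inverse serves the whole array; classical OLS
standard errors with a Student-t(n − 2K − q) reference give per-cell-type
two-sided tests, and any linear combination of coefficients can be tested as
a single-contrast F — for unit contrasts F = t², so the two formulations
coincide to machine precision.  Multiple testing defaults to BH within each
cell type (a `global` mode pools all cells).  The model is intentionally
homoskedastic: the mixture's conditional variance σ²\_c·Σ\_k f²\_k does vary
with f, but under the bundled fraction bounds the variation is mild and the
t reference remains well calibrated (type-I error ≈ nominal in the tests).

`perturb_fractions` adds bounded uniform noise to a fraction matrix and
renormalises, emulating deconvolution error in the pre-estimated
proportions.  External tools plug in through `assemble_cube`, which stacks
per-method p-value tables — converting posterior-probability tables to
1 − posterior — into a CpG × cell-type × method cube.

## Ensemble statistics and thresholding

- `avepv = Φ((1/m) Σ_i Φ⁻¹(p_i))`.  Inputs are clipped to
  [1e−15, 1 − 1e−15] before the probit so boundary p-values stay finite.
  Note the 1/m weight: under independent uniform nulls the probit mean is
  N(0, 1/m), so avepv concentrates toward 1/2 — it is a *conservative*
  combination (lower sensitivity, lower empirical FDR), not a Stouffer
  statistic (which would rescale by √m and be exactly uniform).  The unit
  tests check avepv against its exact null law Φ(√m · Φ⁻¹(x)).
- `minpv = F_Beta(1,m)(min_i p_i) = 1 − (1 − min_i p_i)^m`, the order-
  statistic correction for taking the best of m looks; exactly uniform under
  independent nulls, and the identity map for m = 1.  Subsets of methods use
  the subset size as m.
- Both rules assume independence across methods; correlated detectors make
  minpv conservative and avepv's null law wider.  No dependence correction
  is applied.
- `bh_adjust` is standard step-up BH (via statsmodels), validated against a
  brute-force step-up enumeration.
- `bayesian_fdr_threshold` sorts candidates by q = 1 − posterior and rejects
  the largest prefix whose running mean of q is ≤ α; ties (posterior = 1,
  q = 0) are broken stably in original order, so certain calls are always
  rejected first.

## Evaluation

Per replicate, method and cell type: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), empirical FDR FP/(TP+FP) — defined as 0 when nothing is
rejected, the standard convention that keeps replicate summaries well
defined — false omission rate FN/(FN+TN), F1 2TP/(2TP+FP+FN) (0 when the
denominator vanishes), rank-based AUROC with ties counted half (score =
1 − p for p-value methods, the posterior itself for posterior methods), and
type-I error as the fraction of *unadjusted* p-values below α = 0.05 in cell
types with no planted effects.  The empirical FDR across affected cell types
pools TP/FP counts rather than averaging per-cell-type ratios.  Per-setting
summaries report means over replicates, with medians alongside for
robustness.

## Problem sizes

The bundled desk-scale configuration runs the five-cell design at
`scale = 0.2` (2,000 CpGs, 100 planted per affected cell type), n = 100,
SNR ∈ {7, 11, 15}, 10 replicates — enough replication for stable means
while a full grid completes in seconds; full-size runs (10,000–20,000 CpGs,
50 replicates) use the same code paths unchanged.

## What the synthetic benchmark does and does not show

The generator reproduces the mixture structure, fraction heterogeneity,
noise scale and effect layout of array-based cohorts, so it supports claims
about *relative* detector behaviour: calibration under the null, power as a
function of SNR and cell fraction, FDR control, and the algebraic behaviour
of the ensemble rules.  It deliberately omits probe-type chemistry and
normalisation artefacts, batch effects, covariate structure (age/sex/
smoking), spatially correlated CpGs, deconvolution error in the fractions
(available only through explicit perturbation) and non-Gaussian
heavy-tailed inter-individual variation.  Passing tests therefore certify
the machinery and its operating characteristics under the stated model, not
performance on any particular real cohort.

## Known limitations

- Gaussian profiles can exit [0, 1]; clipping restores validity but slightly
  truncates extreme planted effects at boundary-near CpGs.
- The detector's homoskedasticity assumption is an approximation, as noted
  above; no sandwich correction is offered.
- avepv's conservativeness is inherent to its published form and is
  documented rather than "fixed"; use minpv when null uniformity of the
  combined statistic matters.
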