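# Methods

## Synthetic cohort model

`simcohort` draws a cohort with the structure the downstream analysis
assumes. The default design has four groups (CNTRL n=30, SIRS n=42, ABDM
n=59, PLMN n=84) over timepoints D1/D2/D5/DC; controls are sampled at D1
only. Expression for probe *g* in sample *s* is

    x_gs = b_g + delta_g(group_s, tp_s, surv_s) + e_gs,

with a per-probe baseline b_g ~ N(0, baseline_sd²) drawn once
(baseline_sd = 1.5 log2 units, a typical inter-probe spread), independent
Gaussian noise e_gs ~ N(0, probe_noise_sd²) (default 0.5 log2 units), and a
planted shift delta equal to sign(FC)·log2|FC| scaled by a per-timepoint
multiplier (default 1.0/0.9/0.6/0.3, mimicking decay of the inflammatory
response toward discharge) plus an optional extra log2 shift in
non-survivors. The noise is independent across probes and samples: FC
algebra is exact in expectation, and the standard error of a realized log2
fold change is probe_noise_sd·sqrt(1/n_A + 1/n_B), which the recovery tests
use directly. Block correlation between probes, batch effects and
array-level artefacts are deliberately not modelled, so passing recovery
tests demonstrate algorithmic correctness at the stated signal-to-noise
ratios, not robustness to correlated microarray noise.

Attrition is monotone per patient: from D2 onward each sample is missing
with probability dropout_prob (default 0.15), doubled for non-survivors at
D5/DC (samples not collected due to death). Survival is Bernoulli per
patient with published per-group rates (SIRS 0.611, ABDM 0.745, PLMN 0.784).

Two preset effect lists plant the published fold-change scales: 19
inflammation indicators at Day-1 FCs from 2.83 to 110.31 (all disease
groups vs controls) and 20 SIRS/sepsis discriminators at signed FCs from
−7.09 to +7.47 (sepsis groups only). One discriminator (MIA) has no
published fold change; it is planted at +3.5, mid-scale, so the preset
panel containing it remains evaluable.

Clinical covariates are log-normal with parameters solved by quantile
matching: mu = ln(median), sigma = (ln q3 − ln q1)/(2·z_0.75). Count
variables summarised with a zero lower quartile (basophils) would give
sigma = ∞; the lower quartile is floored at median/10. One published CRP
IQR is typographically impossible (lower bound 497 above upper 163) and is
encoded as (49, 163). SOFA is rounded and clipped to [0, 24]; APACHE II
exists at D1 only.

## Normalization

Per-sample 75th-percentile shift then per-probe median baseline transform.
The quantile is the linear-interpolation ("type 7") definition; the source
tooling does not state one, and this is the numpy/R default. The "global
median" baseline is interpreted per probe across all samples (GeneSpring
baseline-transform semantics) rather than one scalar for the whole matrix —
this produces the zero-centred per-gene scale on which the published
negative panel cut-offs are meaningful. The range filter removes a probe if
any value falls strictly outside [−7, 7]; values exactly at the bounds are
kept. Both transforms are idempotent, and filtering never alters retained
values.

## Differential statistics

Welch's t-test is the default (pooled-variance by flag); zero variance in
both groups with equal means returns p = 1 by convention. One-way ANOVA
uses the classical between/within mean-square ratio with conventions F = 0,
p = 1 for all-identical data and F = ∞, p = 0 for zero within-group
variance with differing means. BH-FDR is the step-up adjustment with
running minima, capped at 1 and order-preserving. Mann-Whitney U uses the
exact distribution when the combined n ≤ 12 and there are no ties
(enumeration is cheap and an independent oracle exists), otherwise the
tie-corrected normal approximation with continuity correction. PCA scores
come from the SVD of probe-centred data with a deterministic sign
convention (largest-magnitude loading positive).

## Stepwise ANN selection

The perceptron has two logistic hidden units and a logistic output,
trained by online backpropagation with momentum
(Δθ_t = α·Δθ_{t−1} − η·∂E/∂θ, η = 0.1, α = 0.5) on the squared error
E = ½(y − o)² (cross-entropy by flag). Weights start N(0, 0.1²), biases at
zero. Updates are per-sample in an order reshuffled every epoch. Several
choices the original protocol leaves open are resolved as follows:

- **Epoch budget / early stopping**: the 20% test split monitors training;
  training checkpoints at the best test-split MSE and stops after 20 epochs
  without improvement (max 300). Fixed-epoch training is available by
  setting patience ≥ max_epochs.
- **Stopping the stepwise additions**: stop when the best candidate fails
  to improve the previous step's mean validation error by ≥ 1e-4, or at 10
  genes. Both are configurable.
- **Ranking error**: mean squared error of the logistic output on the
  blind 20% validation split (MAE by flag).
- **Stability**: `stability_runs` re-runs the whole stepwise procedure
  across master seeds and reports per-gene selection frequencies.

Splits are stratified by class so no subset loses a class (each class needs
≥ 3 samples); a degenerate draw is redrawn with a retry cap. All
per-resample randomness derives deterministically from the config seed via
spawn keys, so the full selection trace is reproducible. The training
inner loop is numba-compiled; a stability study of ~10⁵ network fits runs
in minutes on one CPU.

## Random-forest ranking

The learner is a bagging ensemble of CART trees with per-split feature
subsampling (mtry), the standard random-forest construction, delegated to
scikit-learn. Defaults: 2001 trees; mtry = ⌊√p⌋ unless set (31 and 11 are
the published choices for the two panel sizes). The module's own content is
the stratified 75/25 split protocol, the dual importance report — OOB
permutation mean-decrease-accuracy (per tree, accuracy on its out-of-bag
samples before vs after permuting one feature, averaged over trees; the
conventional reading of "decrease in accuracy") and mean Gini impurity
decrease — and the elimination loop, which refits from scratch each round
and drops the least important gene (ties broken lexicographically) until
the target size remains. Recovery and null-calibration tests run with
101-501 trees rather than 2001: importance estimates at these tree counts
are noisier but unbiased, and the reduced count keeps the 100-seed studies
within a desk-scale run time.

## Panel scoring and ROC

A panel score is the signed sum of collapsed per-gene expression values.
Multi-probe genes collapse by the best single-probe AUC on the comparison
being evaluated (matching the practice of listing multiple probes per gene
and selecting performers), by mean, or by a named probe. The AUC is the
pair-counting statistic (ties half-counted), identical to the trapezoidal
area of the midpoint-threshold curve; its standard error is Hanley-McNeil
with Q1 = A/(2−A), Q2 = 2A²/(1+A), and CIs are z-intervals clipped to
[0, 1]. Cut-offs are "score >" thresholds at midpoints between distinct
scores (±∞ at the ends). The accuracy-optimal cut-off breaks ties by
Youden's J and then by the smaller threshold. Rule-in/rule-out cut-offs
target PPV ≥ 95% / NPV ≥ 98%; among qualifying thresholds the one
maximizing the complementary yield wins (sensitivity for PPV,
specificity for NPV), with ties resolved by the other yield and then the
smaller threshold — on perfectly separated data both cut-offs coincide at
the separating midpoint and the indeterminate zone between them is empty.
Proportion CIs are Clopper-Pearson exact at 95%; the CI method for the
published tables' tool is unknown, so those CIs are not comparison
surfaces. A panel with any gene missing from a matrix is reported as
unevaluable — no imputation. Likelihood ratios are computed on the percent
scale with ∞ as a defined return at zero denominators.

## Pipeline

The `run` subcommand executes simulate → preprocess → diffexp →
ann_select/rf_rank → panels from a YAML config with one global seed.
Outputs are plain TSV/JSON; timestamps appear only in the manifest, so
reruns with the same config and seed are byte-identical elsewhere.

## Known limitations

- No probe-probe correlation, batch structure or array-level artefacts in
  the simulator; recovery rates on real arrays will be lower.
- No moderated (empirical-Bayes) test statistics; at very small n the
  per-probe t-tests are noisier than limma-style alternatives.
- Iterative elimination with one gene per round is O(p²) forest fits;
  use the fractional removal schedule for large pools.
- The exact Mann-Whitney branch is limited to combined n ≤ 12 without
  ties; beyond that the normal approximation is used even where an exact
  computation would be feasible.
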