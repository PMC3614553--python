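# Methods

This note documents the models, procedures, parameter choices and known
limitations of `poolsig`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external
results.

## The problem

Pooling several breast-cancer microarray cohorts profiled on the same
array yields enough subjects to rank recurrence-associated genes and
build prognostic classifiers, but introduces two obstacles the pipeline
must solve: cohorts report intensities on different (approximately
affine-related) scales, and subjects differ in nodal status and
follow-up. The pipeline harmonizes expression, filters subjects, ranks
genes by a bootstrap procedure, compares classifier families, and builds
an incremental Cox risk signature whose size is chosen by held-out AUC.

## Synthetic-data generator

The generator is first-class, tested code; it is the source of every
dataset the tests and the acceptance script use.

**Expression.** Gene g has a baseline log2 level μ_g ~ N(7, 1.5).
Per-subject deviations ("cores") are standard normal. Each gene is
covered by a uniform 1–14 probes; a probe adds a fixed offset
N(0, 0.3) and iid noise N(0, `noise_sd` = 0.3) in log2 units. Cohort c
stores the matrix under the inverse affine map x = (2^y − b_c)/a_c, so
applying y = log₂(a_c·x + b_c) recovers the latent scale exactly
(round-trip ≤ 1e-9, asserted). Default transforms mirror a four-cohort
design: identity, (2.2, −8), (2.65, −0.1), identity.

**Survival.** Event times are exponential with hazard
h₀·exp(Σₛ wₛ·cₛ) over the signal-gene cores (optionally plus a grade
term), h₀ = 0.06/yr, giving ≈ 30% five-year relapse. Censoring is
uniform on (0, 25) years: these node-negative cohorts carry follow-up
out to two decades, so short event-free follow-up is the exception
(roughly the proportions the exclusion cascade expects) — a 10-year
window would instead discard nearly half the subjects. The five-year
relapse label derives from the latent event time; the generator exports
it, together with each subject's linear predictor and analytic relapse
probability 1 − exp(−5·h₀·e^η), as ground truth for recovery tests.

**Effect size.** A genes-first exponential model cannot, by itself,
produce a large mean gap between relapse classes: with S equally
weighted unit-variance genes the gap is bounded by ≈ 1.6/√S per gene
(≈ 0.36 at S = 20), regardless of the weights. The generator therefore
treats `effect_size` as the *realized* class gap: after outcomes are
drawn, each signal gene receives a calibrated additive shift
(`effect_size` minus the hazard-induced natural gap) along the centered
relapse indicator, so the empirical gap equals `effect_size` log2 units
in expectation (verified within ±0.15 at the default scale). With
`effect_size = 0` no shift is applied and the pure proportional-hazards
model remains, so Cox coefficient recovery can be tested at the true
values.

**Clinical covariates** (age, tumor size, grade, ER, nodal status) are
independent of expression by default — they act as adjustment variables,
not confounders — with an optional grade→hazard link. Missing values are
injected only into nodal and relapse status, the two fields the
exclusion cascade filters on.

What the generator does *not* emulate: probe-sequence chemistry and
background (inputs are taken as background-corrected), correlated gene
modules, cohort-specific clinical mixes, non-proportional hazards, and
informative censoring. Passing tests therefore demonstrate correctness
of the procedures and recoverability under this generative model, not
performance on real arrays.

## Harmonization

Stage order is fixed: (1) affine-log per cohort, (2) probe→gene collapse
by the per-sample median (even probe counts average the two middle
values; 13 probes ⇒ the 7th order statistic), (3) per-gene
z-standardization within cohort (sample SD, n−1), (4) merge, (5)
quantile normalization across the merged samples. Collapsing after the
log conversion keeps the median rule on the analysis scale;
standardizing per gene within cohort is what makes cross-cohort gene
values commensurable before a joint quantile step.

The affine form is y = log₂(a·x + b) — the offset inside the logarithm
— because a pure post-log shift cannot change dispersion and so could
never match a reference cohort's spread. When parameters are not given,
they are estimated by derivative-free Nelder–Mead from (a, b) = (1, 0),
minimizing the squared distance between the (mean, SD) of the converted
cohort and of the reference; round-trip recovery on synthetic cohorts is
within ±5% relative error. Non-positive arguments a·x + b ≤ 0 raise with
the offending cell named; there is no silent clipping.

Quantile normalization replaces rank r in every sample by the mean r-th
order statistic; ties within a sample share the mean of their reference
values. On tie-free input (the pipeline's own call sites: continuous
z-scores) the sorted per-sample vectors are identical to ≤ 1e-12 and the
map is idempotent; tie-averaging necessarily relaxes both properties on
tied data.

**Exclusion cascade**, in order: missing relapse status; node-positive
or node-missing; event-free follow-up under five years (subjects who
relapse within five years are retained). Counts at every stage are
reported and must be non-increasing.

## Gene ranking

A 200-subject uniform subsample (redrawn if single-class) anchors the
procedure; 200 bootstrap resamples of it (with replacement, single-class
resamples redrawn so B stays fixed) each yield per-gene two-sided
Mann–Whitney p-values; per gene, the top and bottom floor(B·0.05) = 10
p-values are trimmed and the remaining 180 averaged; genes are ranked
ascending with lexicographic tie-breaks and the top 100 selected. The
subsample is unstratified (the selection step's contract only requires
both classes present). p-values are exact by enumeration for group sizes
≤ 8 without ties and otherwise use the normal approximation with
midranks, tie correction and continuity correction; the bootstrap path
is vectorized across genes and matches the scalar test exactly. No
multiple-testing correction is applied — the trimmed mean is a stability
filter, not an error-rate control.

## Classifier suite

All classifiers consume the 100 selected genes; clinical variables serve
the balance checks and the Cox adjustments. The 757-style cohort is
split 370:387 (proportionally for other sizes) 400 times; per split,
every variable is tested train-vs-test (Mann–Whitney continuous,
chi-square categorical) and the 20 splits with the fewest p < 0.05
variables become the cross-validation sets (ties by split index).

- **DT**: CART-style, Gini impurity, minimum leaf 5, cost-complexity
  pruning α chosen by internal 10-fold CV on the training set (ties to
  the larger α). Importance: impurity decrease; unused variables are
  exactly 0.
- **LR**: maximum likelihood on standardized inputs with ridge
  λ = 1e-4 guarding separation; importance |β| on the standardized
  scale.
- **ANN80 / ANN100**: one hidden layer (10 logistic units), adam with
  learning rate 0.01 (the default 0.001 stalls inside the early-stopping
  patience window), cross-entropy. "Over-training prevention" fraction
  f: with f < 1, a 1−f internal validation holdout and accuracy-based
  early stopping with patience 20; with f = 1, a fixed 400-epoch budget.
  Importance: mean training-accuracy drop under within-column
  permutation (10 permutations, seeded).
- **Composites DL / DA80 / DA100**: variables with positive DT
  importance feed the LR or ANN head; if the pruned tree selects
  nothing, the head receives the 10 top-ranked genes (documented
  fallback).

Evaluation: ACC at probability 0.5 and AUC by the rank (Mann–Whitney)
formulation with midranks, reported in percent, with
ΔACC = ACC_train − ACC_test and ΔAUC likewise (identities asserted
exactly; the rank AUC equals trapezoidal ROC integration to ≤ 1e-10).
Importance integration is Borda: per-model ranks averaged, ties broken
by the ranking stage's trimmed-mean p, missing variables assigned the
worst rank and flagged. All four single models contribute (the composite
models reuse their components' information and are excluded to avoid
double counting).

## Risk signature

Genes enter in integrated-importance order. For each k, a Cox
proportional-hazards model (lifelines; Efron ties; ridge 1e-6 against
monotone likelihood) is fitted on the training half of the
best-balanced split, on z-scores computed with *training* means and SDs;
the risk score Σ βⱼzⱼ is applied unchanged to the test half. AUC is
computed against the binary five-year relapse label (the outcome is
defined at five years; no time-dependent ROC). k\* is the argmax of test
AUC, smallest k on ties; failed fits are skipped and flagged. The cutoff
is the highest-specificity threshold among midpoints of adjacent unique
training scores subject to sensitivity ≥ 0.80 (ties to the higher
threshold). Survival separation of the resulting high/low groups is
quantified by Kaplan–Meier curves, the two-group log-rank test, a
univariate Cox HR, and a multivariate HR adjusted for age, tumor
diameter, dichotomized grade (≥ 3) and ER status. The net
reclassification improvement compares the categories induced by the
cutoff rule applied to a clinical-only Cox score versus a
clinical-plus-signature score, evaluated on the test half:
NRI = [P(up|event) − P(down|event)] + [P(down|non-event) − P(up|non-event)].

## Problem sizes and designs used by the checks

- Default study: 4 cohorts of 198/189/249/286 subjects, 2,000 genes, 20
  signal genes, effect size 1.0 — used for planted-gene recovery
  (≥ 80% of signal genes in the top 100).
- Cox recovery: 1 cohort, 400 subjects, 3 signal genes with
  β = (0.5, −0.5, 0.3), no shift, single probes, low noise — estimates
  within ±0.15, and the fit equals a brute-force partial-likelihood
  maximizer on 6-subject toys to 1e-4.
- End-to-end recovery: weights 0.177 on 20 genes (σ(η) ≈ 0.79, i.e. a
  median-split log-hazard gap ≈ 1.26, hazard ratio ≈ 3.5), effect size
  0.5, 20 CV sets, k_max = 60. The test-AUC-versus-k curve rises and
  then falls; the selected k\* lands within ±5 of the planted 20; the
  dichotomized signature separates survival at log-rank p < 0.001.
  k_max is capped at 60 rather than 100 to keep the full-curve fits
  proportionate to the 2,000-gene desk scale.

## Numerical conventions and degenerate inputs

Sample SD uses n−1 throughout. Zero-variance genes raise (the caller
drops or imputes explicitly); identical pooled values give a Mann–Whitney
p of 1, not an error; single-class test sets report AUC as missing with
a flag; constant balance variables record p = 1 and a flag. Every stage
seed derives from the one pipeline seed via a seed sequence, and two
runs with equal configs are bit-identical (checksummed in the run log).

## Limitations

Classifier internals are idiomatic scikit-learn reconstructions of the
model *roles* (tree variable-selector, ridge-guarded LR, early-stopped
perceptron); no attempt is made to match any proprietary tool's output
bit for bit. The signature's AUC-maximizing k is a greedy choice along
one importance ordering, not a subset search. Hazards are proportional
and the baseline exponential by construction; real cohorts need not
satisfy either. NRI categories follow the pipeline's own cutoff rule;
other category schemes give different NRI values.
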