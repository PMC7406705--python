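# Methods

`dsiscreen` implements a Disease State Index (DSI) analysis for detecting
amyloid-PET positivity in non-demented elderly at elevated dementia risk,
from tabular factors only: demographics (sex, age, education), vascular
factors (BMI, hypertension), APOE ε4 carrier status, four standardized
cognitive composites (modified Neuropsychological Test Battery: total,
memory, processing speed, executive function), fifteen ICV-normalized
regional brain volumes, a visual medial temporal atrophy (MTA) rating on
the 0–4 Scheltens scale, and an AD-signature cortical thickness. The study
population this models is small (n = 48; 28 amyloid negative, 20 positive)
and not publicly available, so the package pairs the classifier with a
synthetic cohort generator that reproduces the published class-conditional
summaries.

## The classifier

**Per-feature fitness.** For a feature value x, place a decision threshold
at x along the positive-typical direction and evaluate the two training
error rates: FN(x), the fraction of positive-class training values strictly
on the negative-typical side of x, and FP(x), the fraction of
negative-class training values at or beyond x on the positive-typical side.
The fitness is

    f(x) = FN(x) / (FN(x) + FP(x)) ∈ [0, 1],

0 where x looks like the negative class, 1 where it looks positive. Both
curves are empirical step functions of the training samples — no smoothing,
no parametric fit — represented exactly by the sorted class samples on the
oriented axis. Evaluation points beyond the training range saturate at
0 / 1; inside a perfect-separation gap FN + FP = 0 and f is defined as the
neutral 0.5. With this convention the positive-typical side of a threshold
is closed (ties at x count fully toward FP); this choice follows from
direct evaluation on the binary APOE case — carrier rates 10/19 in
positives, 4/28 in negatives give f(1) = (9/19) / ((9/19) + (4/28)) ≈ 0.768
— and keeps FN non-decreasing and FP non-increasing along the oriented
axis, hence f monotone.

**Relevance.** Each feature is weighted by its relevance, the maximal
Youden index sensitivity + specificity − 1 over candidate thresholds
(midpoints between adjacent distinct pooled training values, plus ±∞).
Because ±∞ yields J = 0, relevance is non-negative by construction;
worse-than-chance features simply drop to weight ≈ 0 rather than
inverting. The positive-typical orientation is itself learned per feature
as the direction whose best threshold attains the larger Youden index
(ties favor higher-in-positive), and is re-learned inside every
cross-validation training fold — reported ↑/↓ directions are outputs.
Binary and ordinal features use exactly the same threshold machinery;
there is no special-casing.

**Hierarchical composition.** Features are grouped by conceptual likeness
(Demographic, Cardiovascular, APOE, Cognition, MRI with Volumes /
VisualMTA / ADSignatureThickness subgroups). A group's score is the
relevance-weighted mean of its children's scores,

    DSI = Σᵢ relevanceᵢ · fitnessᵢ / Σᵢ relevanceᵢ,

applied recursively up to the root. Each internal node receives its own
relevance by computing its training scores for all training subjects and
taking the maximal Youden index of those scores against the labels, with
the orientation fixed (group scores are similarity-to-positive by
construction). This recursion estimator is the one genuinely open design
point — the method's description states that groups get a new fitness and
relevance but not the estimator — so it is isolated in a single audited
function (`dsiscreen.dsi._max_youden` via `fit_dsi`). A node all of whose
children have zero relevance scores a constant 0.5 and gets relevance 0,
with a warning.

**Missing data.** Missing cells are ignored, not imputed: at every node the
weighted mean runs over the observed children only, with the weights
renormalized. A subject with an observed value in one of two equally
relevant leaves scores exactly the observed leaf's fitness. Subjects with
no observed feature at all are flagged and receive no numeric score.

## Evaluation

**Cross-validation.** 100 repetitions of stratified 5-fold CV (defaults).
Fold assignment shuffles each class and deals members cyclically, the deal
continuing across classes, so per-class fold sizes differ by at most one
and total sizes stay balanced; stratification matters because with only 20
positives unstratified 5-folds frequently starve a training fold. The model
is refit from scratch on every training split. AUC is the rank-based
Mann–Whitney statistic with ties counted ½ (equivalent to trapezoidal ROC
integration), computed per test fold; the 95% CI is mean ± 1.96 SD over all
repetition × fold AUCs (normal approximation; a percentile variant is
available via `ci_method="percentile"`). At folds = n the procedure
degenerates to leave-one-out: every subject is still scored exactly once
per repetition, but single-subject test folds have no defined fold AUC.

**Cutoff statistics.** Per repetition, each subject's single out-of-fold
DSI value is classified positive when ≥ the cutoff (closed on the left, so
cutoff 0 classifies everyone positive and PPV equals the 42% prevalence
exactly). Sensitivity, specificity, PPV, NPV and the rate of positive
predictions are reported in percent as mean and 2.5–97.5 percentile range
across repetitions — percentile rather than min–max, a documented choice
since the convention is not pinned down. Undefined 0/0 ratios (NPV at
cutoff 0, PPV at cutoff 1 when no score reaches 1) are blank, not 0.

**Characterization.** Group summaries are mean (SD) for continuous/ordinal
features and count (%) for binary ones; group differences use the
two-sided tie-corrected normal-approximation Wilcoxon rank-sum test
without continuity correction for all feature kinds. On a 2×2 binary
contingency this statistic satisfies z² = (n−1)/n × Pearson χ², which on
the APOE table (4/28 vs 10/19) gives p ≈ 0.005.

**Scenarios.** The added-value analysis evaluates 20 feature-set
configurations: a demographic+cardiovascular base with single-group
additions, the base plus cognition, the all-but-MRI base, APOE-centred
combinations, and two MRI leave-one-out blocks (all-MRI and MRI+APOE,
each minus one subgroup). Excluded groups are pruned from the tree before
fitting. All scenarios in a run share the same fold partitions (one seed),
so AUC differences are attributable to the feature sets.

## The synthetic generator

The generator emulates the published two-class summaries: continuous
features are Gaussian per class with the printed mean/SD; binary features
Bernoulli with the printed proportion (APOE positive-class rate 10/19, with
a 1-in-20 missingness rate reproducing the single ungenotyped positive
subject); the MTA rating is a Gaussian (means 1.0 vs 1.6, SD 0.7) clamped
to [0, 4] and rounded to the 0.5 grid on which hemisphere-averaged
Scheltens ratings live — this reproduces the printed support and moments
without inventing a latent rating model. Default class sizes are 28/20.
Sampling is deterministic given the config seed, with per-feature
substreams keyed by (seed, crc32(name)) so adding a feature never perturbs
the others; missingness is applied independently per cell after sampling.

What the generator does *not* emulate: the publication contains no
covariance information, so features are independent by default. Real
regional brain volumes are strongly collinear; simulating fifteen of them
independently stacks their signals, and the synthetic complete model
therefore cross-validates around AUC 0.85–0.92 (resubstitution ≈ 0.94),
noticeably above the real-data values (0.78 cross-validated, 0.88
resubstitution) that only the restricted dataset could reproduce. An
optional Gaussian copula (`copula_correlation`) adds exchangeable
within-group correlation for sensitivity analyses; it is off by default
because no published value exists. Passing tests on synthetic cohorts
demonstrate the correctness of the machinery and its calibration under the
null, not the real-data effect sizes.

## Numerical choices and edge cases

- Threshold ties are broken toward the smaller threshold (the candidate
  grid is scanned in increasing order).
- Identical constant samples in both classes yield relevance 0 and a
  constant fitness 0.5.
- Fitted models serialize to JSON (sorted sample breakpoints as float
  lists) and reload bit-exactly.
- All percent values are rounded to integers, and AUCs to two decimals,
  only in the text reports; CSV/JSON outputs carry full precision, and the
  text tables are pure views of the JSON numbers.
- Problem sizes: the analysis drivers and acceptance script use the study's
  own 100×5-fold CV at n = 48 throughout; convergence and parameter-
  recovery checks use 5 000–10 000 subjects per class, where Monte-Carlo
  error of an AUC is below 0.01. Null calibration is assessed as the
  average CV AUC over 16 independent no-signal cohorts because a single
  48-subject cohort's mean CV AUC has sampling SD ≈ 0.09 — far wider than
  any useful calibration band — while its expectation is exactly 0.5 by
  label-score independence.

## Known limitations

- Independence of synthetic features (above) inflates composite
  performance relative to the real cohort; between-group comparisons on
  synthetic data are still meaningful because all scenarios share
  partitions and generating laws.
- The group-relevance recursion estimator (max-Youden on training scores)
  is one defensible reading of the method; a fixed 0.5-threshold variant
  would differ mainly for poorly calibrated groups.
- The normal-approximation CI over fold AUCs ignores the correlation
  between folds of the same repetition; it matches the fold-averaged CI
  convention of the original analysis rather than a formally valid
  inference procedure (DeLong/bootstrap inference is out of scope).
- No probabilistic calibration of DSI values is attempted; the index is a
  similarity score, not a posterior probability.
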