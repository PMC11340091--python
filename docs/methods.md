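# Methods

## Survival model and estimands

The endpoint is disease-free survival (DFS): months from surgery to
relapse or death, censored at last contact. Between-group comparisons use
the Kaplan–Meier estimator and the log-rank test; median follow-up is the
median of the reverse Kaplan–Meier curve (censoring indicator inverted).
All Cox models use the Breslow approximation for tied event times — the
convention of the standard penalized solvers — so the penalized and
unpenalized fitters maximize the same partial likelihood.

The three model specifications are: Model 1, elastic-net penalized Cox on
the miRNA expression block; Model 2, the same with the standard prognostic
factors added; Model 3, standard (unpenalized) Cox on the prognostic
factors alone. The clinical design is sex (M vs F), age as a continuous
per-year covariate, and pathological stage as two dummies (II vs I,
IIIA vs I). In Model 2 the clinical columns carry penalty factor 0 — they
are forced into the model and only the miRNAs are selected over. This
choice is deliberate: the prognostic factors are not candidates, they are
the reference the biomarkers must beat; it also makes Model 2's clinical
coefficients directly comparable with Model 3's. A flag penalizes
everything uniformly instead.

## Preprocessing

Unsupervised filters run first, in fixed order: miRNAs with a third
quartile across samples below 5 counts are removed, then samples whose
median or first quartile across the remaining miRNAs equals zero.
Quantiles use linear interpolation of order statistics (the numpy
default) in both filters. TMM normalization follows the canonical
parameters — 30% two-sided trim of the M-values, 5% of the A-values,
inverse-asymptotic-variance weights, reference sample with 75th
count percentile (library-size-scaled) closest to the mean, factors
rescaled to geometric mean 1; the implementation reproduces Bioconductor
edgeR to ~1e-10 (cross-checked by a test). Counts become log2-CPM with a
0.5 pseudocount against effective library sizes, and each miRNA is then
Blom-transformed across samples: `Φ⁻¹((r − 3/8)/(n + 1/4))` with
tie-averaged ranks. Because the Blom step is rank-based, the pseudocount
only matters through ties among zero counts (which all map to the same
score); the pipeline therefore does not depend on whether the transform
is applied to CPM, log-CPM or TMM-scaled counts beyond those ties.

Normalization and transformation are computed once on the full analysis
set, matching the pipeline order of the study design this package
operationalizes (filters → normalization → modelling). Because the Blom
scores of one sample depend on all samples, a leak-averse variant is
provided (`within_fold_normalization`): inside each CV fold, TMM reference
and factors come from the training samples only and held-out samples are
mapped through the training fold's empirical distribution
(`blom_from_reference`). It is off by default; at the cohort sizes
simulated here the two modes give near-identical CV statistics.

## Elastic-net Cox solver

The penalized fitter minimizes
`−ℓ(β)/n + λ(α‖β‖₁ + (1−α)/2‖β‖₂²)` (Breslow partial log-likelihood ℓ,
per-feature penalty factors allowed) by iteratively reweighted least
squares with cyclic coordinate descent, warm-started along a log-spaced
λ path from λ_max (where all penalized coefficients are exactly zero)
down to `0.1·λ_max` over 30 values by default. Columns are centered and
scaled to unit variance internally; coefficients are reported on the
input scale. Working weights are the exact diagonal of the Hessian in the
linear predictor; each IRLS step is safeguarded by a backtracking line
search on the penalized objective, so the outer iteration is monotone.
Convergence uses the weighted-squared-coefficient-change criterion of the
canonical elastic-net software (threshold 1e-7). Two numerical edges are
handled explicitly: standardized coefficients are capped at ±30, and in
CV contexts a fit that exhausts its iteration budget keeps its last
(monotone) iterate — both arise only under quasi-separation, where the
partial likelihood is flat and no finite optimum exists; the capped
iterate is the right point to score and evaluate deviance at. The
unpenalized Newton–Raphson fitter, by contrast, *reports* separation
(coefficients past ±20) as an error rather than clamping, since its Wald
intervals would be meaningless; inside cross-validation a quasi-separated
clinical-only fold falls back to a mildly ridge-penalized fit.

λ is selected by 5-fold cross-validated partial-likelihood deviance in
the Verweij–van Houwelingen form, `−2[ℓ_all(β_{−k}) − ℓ_train(β_{−k})]`,
minimized over the path (the "optimal λ" rule, not 1-SE). All folds
advance down the path together with warm starts, and the descent stops
early once the running minimum has not improved for 5 consecutive λ
values — the deviance curve is near-convex in practice, and this skips
the dense small-λ tail. Inner CV folds, like outer ones, are stratified
on the event indicator so no training portion is event-free.

## Cross-validated evaluation

Out-of-fold prognostic indices follow the pre-validation idea: 5
event-stratified folds; for each fold, the model specification is
re-fitted on the other four (penalized models re-select λ by an inner
5-fold CV on that training portion only, with fold seeds derived from the
fold index, never from the data) and the held-out fifth is scored with
x'β. Risk groups split at the single median of the pooled out-of-fold
scores (a per-fold-median option exists); scores exactly at the median go
to the low-risk group, which makes the degenerate all-constant-scores
case (every inner model empty) deterministic. The CV-KM log-rank
statistic between the two groups is carried forward as a raw statistic —
its chi-square reference is invalid after cross-validation — and a
degenerate single-group split scores statistic 0.

The landmark ROC at 24 months treats patients with an event by the
landmark as cases and event-free-beyond-landmark patients as controls;
patients censored before 24 months drop out, and cases are reweighted by
the inverse of the censoring survival function (reverse-KM) at their
event time, taken as the left limit G(t⁻). The curve accumulates one
vertex per distinct score (ties contribute diagonal segments, so constant
scores give AUC exactly 0.5) and the AUC is its trapezoidal integral.

## Permutation inference

Absolute-accuracy tests permute the (time, event) pairs jointly against
the covariate rows — events always travel with their times — and re-run
the *entire* CV procedure per permutation, including fold re-draw and
nested λ selection. One-sided add-one p-values,
`(1 + #{null ≥ obs})/(B + 1)`, are reported for the CV log-rank statistic
and the CV AUC; both statistics come from the same re-runs. B defaults to
500 (tests and the acceptance script use 49–100 for runtime).

The added-value test compares Model 2 to Model 3 on shared folds
(Δ log-rank, Δ AUC) and permutes only the miRNA block's rows, clinical
data and outcomes fixed; whole rows move, preserving inter-miRNA
correlation. Here the folds stay fixed at the observed assignment: the
clinical-only reference is computed once on those folds, and re-drawing
folds for the permuted combined model would inject fold-draw luck into
the null differences that cancels in the observed difference —
empirically this shifts the null enough to destroy the uniformity of the
p-value under a redundant-information control. A re-draw mode exists for
variance experiments.

## Covariate screen

Each miRNA's transformed expression is compared between the two levels of
a clinical contrast by a pooled-variance Student t-test (Welch by flag);
p-values are Benjamini–Hochberg adjusted across miRNAs within the
contrast. Multi-level covariates are dichotomized by configuration (e.g.
stage II + IIIA vs I).

## Synthetic cohorts

The generator emulates a prospective resected-NSCLC cohort at the level
of its statistical structure. Defaults: 200 patients; 2000 miRNAs of
which 80% are structurally low (lognormal mean count ≈ 0.3) so that
roughly 250–420 survive the Q3 filter; expressed miRNAs have lognormal
mean counts (median ≈ 50) with patient-level biological SD 1.0 on the log
scale; counts are negative binomial (dispersion 0.15) with lognormal
library-size factors (SD 0.35 on the log scale) and a 15% fraction of
degraded libraries (factor ×0.01) for the sample filter to remove. Age ~
N(69, 8) truncated to 44–85, 60% male, stage mix 64/17/19% (I/II/IIIA).

Hazards follow a Weibull-baseline proportional-hazards model (shape 1.2,
scale 190 months — calibrated once so the default cohort shows ≈27%
observed events) with clinical log-HRs 1.012 (stage II), 1.442 (IIIA),
0.293 (male), 0.030/year (age, centered), magnitudes typical of
early-stage NSCLC cohorts. Prognostic miRNAs act on the log-hazard
through their *standardized latent* expression (default |log HR| 0.7,
alternating sign, five miRNAs), so recovered coefficients on the Blom
scale are directly comparable to the simulated effects. Event times come
from inverse-CDF sampling; censoring is the minimum of an administrative
cap (40 months) and an independent Uniform(12, 42) — emulating ~2.5 years
of accrual with a fixed lock date — giving a reverse-KM median follow-up
around 26 months. With `confound_with_stage`, the prognostic miRNAs'
latent scores are replaced by the standardized stage code, making the
expression signal fully redundant with the clinical model. A global seed
feeds one child RNG stream per component (clinical, expression, outcome,
counts, quality), so sub-draws are reproducible under partial config
changes.

What the generator does *not* emulate: batch or center effects, isomiR
and cross-mapping structure, inter-miRNA correlation beyond the planted
signal, informative censoring, and any biological difference between
cell-free and vesicular fractions. Passing tests therefore demonstrate
the statistical machinery's correctness and calibration, not performance
on real sequencing data.

## Problem sizes used in the checks

The calibration study runs 100 null cohorts (n = 80, 50 miRNAs, no
covariate–outcome association, baseline scale 75 giving ≈30% events) with
B = 100 permutations each; the signal-recovery study 20 cohorts
(n = 300, 200 miRNAs, 5 prognostic, B = 49 for the added-value test);
the redundancy control 50 confounded cohorts (n = 100, 40 miRNAs,
B = 49). The acceptance script analyses one default cohort with B = 100.
These sizes are the package's own scaled-down study conditions; the
analysis default remains B = 500.

## Known limitations

Penalized coefficients are reported without standard errors or intervals
(post-selection inference is out of scope). The added-value permutation
null is not exactly exchangeable when the miRNA block is correlated with
the clinical covariates — the redundancy control shows the resulting
p-values remain approximately uniform, but mild conservatism is expected.
Complete-case handling drops patients missing any model covariate or the
outcome. Competing risks and time-varying effects are not modelled.
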