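# Methods

This note documents the models, the synthetic data-generating process, the
numerical conventions and the open design choices behind `brainpad`.

## Synthetic cohort

The generator emulates the clinical archive structure the analysis assumes:
a skewed, bounded age distribution, a multi-modality multi-scanner scan
inventory with repetitions, and predictions carrying a known linear bias.

**Ages.** Drawn from a two-component truncated normal mixture on
[15, 95] years. The five mixture parameters (weight, two means, two sds) are
solved numerically (Nelder–Mead on the squared target error) so the
*population* mean, median and sd equal the targets — defaults 53.5, 56 and
18 y, giving mean < median (left skew). The solver is cached per target
tuple and raises if the residual mismatch exceeds 0.05 y (infeasible
targets, e.g. an sd above half the range). A mixture was chosen over a
single skewed family because it reaches any feasible (mean, median, sd)
triple on a bounded support with transparent parameters.

**Scan inventory.** Defaults encode an archive of 1,540 patients, 6,224
scans across 7 modalities (MPRAGE, T1w, T2w, T2wFLAIR common; T1wFLAIR,
T2wGRE, IR rare) and 8 scanner models. Each participant includes modality
*m* independently with probability `q_m = (scans_m / E[reps_m]) / N_ref`,
reproducing the archive's marginal cell counts in expectation at the
reference size. Rare modalities are confined to a carrier subset (default
fraction 0.145) and every carrier holds at least one rare modality — this
slightly inflates rare-modality counts relative to the cell table but
guarantees the held-out eligibility rule is exercised at any cohort size.
Repetition counts per (participant, modality) follow per-modality
distributions derived from the archive's repetition columns, capped at 4;
the scanner is drawn once per (participant, modality) from the
modality-conditional scanner frequencies (repeats on one scanner).

**Predictions.**
`predicted = α + β·age + modality_offset + scanner_offset + subject_effect
+ scan_noise`, with defaults α = 15.2 y, β = 0.7 (the regression-dilution
bias the correction layer must remove), zero modality/scanner offsets (the
selected correction model in the emulated study carries none; offsets are
exposed for power studies), subject-effect sd 3 y, scan-noise sd 5 y.
A 2% outlier fraction receives an additional N(0, 15 y) shift, emulating
grossly corrupted scans that slip past QC; 15 y makes such scans clear
brain-PAD outliers without dominating OLS fits at desk scale. Per-slice
output (80 slices) adds iid N(0, 2 y) around the scan value and defines the
scan-level prediction as the slice median, matching the median-aggregation
interface.

**What the generator does not emulate:** MR contrast physics,
super-resolution artefacts, age- or pathology-dependent prediction error,
site effects beyond scanner labels, and informative missingness of
modalities. Passing tests therefore demonstrate the *statistical machinery*
(estimators, splits, CIs) under the assumed generating law, not predictor
performance on real clinical data.

**Toy volumes** are smooth ellipsoidal intensity patterns with mild noise;
corruptions are heavy uniform noise, a blanked half-volume, or a spatial
roll of a third of the grid. They exist solely so the QC stage has inputs
with ground-truth labels. The pipeline's QC stage runs them on a reduced
48³ grid — NMI is grid-agnostic — while the 218 × 182 × 218 1-mm template
grid is used wherever slice geometry matters.

## Image QC

NMI uses the Studholme normalization `(H(A)+H(B))/H(A,B)` over a 64 × 64
joint histogram on [0, 255]², bounded in [1, 2]; entropies are summed in
sorted order so `NMI(a,b) == NMI(b,a)` exactly. The review threshold is the
Tukey lower fence (Q1 − 1.5·IQR) of the NMI values — a reproducible
surrogate for the visual "significantly below the main unimodal
distribution" rule — with a verbatim manual override. Prediction slices are
the 80 contiguous axial slices centred on the slice whose world
z-coordinate (from the NIfTI affine) is nearest 0: 40 strictly below, 40
at/above (a fixed convention since 80 is even). The slice median uses the
conventional mid-pair mean for even counts.

## Data subdivisions

Largest-remainder apportionment resolves fractional counts exactly and
deterministically. Balance of scans-per-participant across subdivisions is
achieved by stratifying on quantile bins of the per-participant scan count
and allocating each bin proportionally to the remaining targets. When
rare-modality carriers outnumber the 14.5% test target, the surplus joins
the linear-correction set (never training, whose participants must hold
exclusively common modalities); a shortfall is covered from the common pool
with a warning.

The emulated study's own arithmetic for the training split is internally
inconsistent (77% described as 70% plus "its 10%", yet also as "70% and 7%
of the whole"); the package exposes `final_fit_holdout_fraction` (default
0.10 *of the training subdivision*) instead of hard-coding either reading.

## Bias correction

Candidate designs expand Wilkinson `a*b` to main effects plus interaction;
categoricals use treatment coding with the most frequent level as
reference. Fits are one row per scan on the aggregated (median) scan-level
prediction. Rank deficiency — empty modality × scanner cells are structural
in realistic archives — raises with the offending cells named; inside CV,
an unfit candidate scores infinity and cannot win. Exact ties in
fold-averaged corrected MAE go to the earlier entry of the candidate list
(fewest parameters). On its own fitting set the corrected brain-PAD has
mean 0 and zero age correlation (OLS residual identities, tested to 1e-10).
Because the correction is affine in the prediction, correcting the median
of slice predictions equals the median of per-slice corrections.

## Accuracy bootstrap

The resampling unit is the participant: a repetition draw alone would give
zero sampling variability for single-repetition participants. Each
replicate draws one repetition uniformly per participant (per modality when
pooling) and resamples participants with replacement; resampling is
implemented through multinomial participant weights, which is exactly
equivalent and vectorises the pooled scheme. Default replicate counts are
`factor × N_r` per modality and `factor × N_r × N_m` pooled with
factor = 10,000 (`N_r` = maximum repetitions observed, `N_m` = number of
modalities); the factor is configurable because desk-scale runs need far
fewer. CIs are percentile 2.5/97.5 — the simplest defensible default.
Replicates with undefined correlation/R² (degenerate resamples) are
excluded from those summaries only.

## Reliability

Filters apply once, rows (< 3 items) before columns (> 95% missing), no
iteration. The pairwise-deletion covariance uses each pair's joint sample
with an n−1 denominator; an item pair with fewer than 2 joint observations
is an error. Small samples can pass the stated filters yet leave such
pairs; the pipeline (not the alpha function) then applies
`ensure_pairwise_support`, greedily dropping the sparsest items until every
pair is supported.

The F-based confidence interval is implemented exactly as specified —
`lower = 1 − (1−α̂)·F_isf(a/2, df1, df2)`,
`upper = 1 − (1−α̂)·F_isf(1−a/2, df1, df2)`, with df1 = n_obs − 1,
df2 = df1·k — using the inverse survival function. **Caveat:** this
convention differs from common Feldt-type intervals (which place α̂'s
F-statistic between quantiles of F(df1, df2) with a different df pairing);
it is reproduced verbatim rather than silently corrected.

## Group model

As literally written, subject fixed effects plus a subject random intercept
are jointly unidentifiable. The default path keeps both: subject effects
are sum-to-zero coded, so the global intercept is exactly the average
subject effect ⟨s_i⟩ and the paper-style contrasts remain well defined,
while the redundant random-intercept variance is free to collapse toward
zero under REML (boundary warnings are expected and suppressed). Two
alternative paths drop one term: `fixed_only` (plain OLS; used where exact
closed-form identities are wanted) and `random_only` (the path on which the
random-intercept sd is a meaningful, recoverable parameter). REML uses the
L-BFGS quasi-Newton optimizer; with a single random intercept the general
Cholesky covariance parameterization reduces to one parameter. Wald tests
use residual degrees of freedom. Population MAE estimates are the linear
contrasts `Intercept + β_m` (β_ref = 0) and their unweighted modality mean.

## Training control

Early stopping strictness: any decrease of the validation loss counts as
improvement (no tolerance is specified by the protocol). The overfitting
rule stops immediately when training MAE < validation MAE — coherent when
training-time regularisation (e.g. heavy dropout) keeps training MAE above
validation MAE until the model overfits. Age-frequency weights use 16
equal-width bins over the observed range and are normalised to mean 1 so
weighted and unweighted losses share a scale. The hyper-parameter search of
the original protocol is represented by a generic deterministic grid-search
driver over pluggable predictors; the neural networks themselves are out of
scope.

## Problem sizes

Default desk-scale runs use 1,540 synthetic participants (the archive's
reference size), 48³ QC volumes, and reduced bootstrap factors; the
acceptance computation uses 5,000 participants for the bias refit and
10,000 ages for the distribution moments. These sizes keep every stage
within seconds to minutes on one CPU while leaving Monte-Carlo error well
below the tolerances tested.

## Known limitations

* The synthetic generating law is additive and Gaussian; heavy-tailed or
  age-dependent prediction error would change bootstrap and reliability
  behaviour in ways these tests do not probe.
* `ensure_pairwise_support` is a desk-scale guard with no counterpart in
  the original protocol (whose sample made all item pairs observable).
* The F-based alpha CI is reproduced as printed (see caveat above).
* The toy volume predictor is intentionally trivial; it exists to exercise
  plumbing, not to approximate a CNN.
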