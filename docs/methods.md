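# Methods

This note documents the models, default parameters, numerical choices and
known limitations of `pattlearn`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
example scripts.

## 1. Event-schedule generation (`design.py`)

A run presents every item of every condition exactly twice, with the two
showings separated by 4–8 intervening trials (fillers count as
intervening trials), plus filler catch trials at uniformly random
positions. With the default 3 conditions × 30 items × 2 repetitions + 9
fillers this is 189 trials.

**ISI jitter.** The source design reports only the ISI range (1–5 s) and
mean (2 s), not the shape of the optimizer's output distribution. We use
a truncated geometric-like distribution on a 0.5 s grid: values
1.0, 1.5, …, 5.0 s with weights *q*ᵏ, where *q* is solved numerically
(Brent's method) so the expectation equals the target mean exactly.
With a target below the grid midpoint this yields many short and few
long ISIs — the profile rapid event-related optimizers produce. When the
target equals the midpoint the weights degenerate to uniform.

**Ordering algorithm.** Randomized construction with restarts (default
budget 1000): filler positions are pinned first; word slots are filled
left-to-right. When an item is started it commits to a target gap drawn
uniformly from [4, 8]; at each slot, any item whose spacing window closes
is forced, otherwise an item at/past its target is placed, otherwise a
new item is started. Two items forced at once, or an item with no
feasible slot left, aborts the attempt. This keeps realized spacings
spread over the whole window (empirical mean ≈ 6.3, close to the
design's reported 5.99) instead of piling up at the deadline.
Infeasible parameter sets (e.g. a spacing minimum larger than the run)
exhaust the budget and raise an explicit infeasible-design error.
Only designs with exactly two repetitions per item are supported; the
spacing constraint is defined pairwise and the similarity statistic is
specifically cross-repetition.

An independent validator re-derives every invariant (strictly increasing
onsets, ISI bounds, repetition counts, spacing bounds, filler count) from
the raw trial list; every generated schedule in the tests passes it.

## 2. Synthetic data (`simulate.py`)

**Patterns.** For a planted correlation ρ, repetition 2 is constructed as
ρ·standardize(rep 1) + √(1−ρ²)·standardized independent noise. The
expected Pearson correlation across repetitions equals ρ, while observed
values keep the natural sampling dispersion ≈ (1−ρ²)/√(n_voxels); at
|ρ| = 1 the construction is exact. A per-subject latent ρ (drawn from
the `rho_trained` interval) is shared across the *coupled* ROIs so one
subject-level similarity drives behavior; uncoupled ROIs and the control
condition receive independent draws from the same intervals, which makes
trained and control marginally exchangeable under the null — the
property the within-subject permutation test needs.

**Behavior.** RT(s, d) = a_s·d^(−b_s) + c·z_s·𝟙[d ≥ 5] + ε, with ε ~
N(0, σ). The coupling c·z_s shifts only the post-learning plateau
(days ≥ 5), because the pipeline's outcome measure is the day 5–12 mean;
early days stay pure power-law. RTs falling below a 200 ms floor are
clipped with a warning. Accuracy follows a saturating curve approaching
ceiling and is generated for completeness only — it is never used in
inference, mirroring the ceiling-effect exclusion in the behavioral
protocol the pipeline targets.

**Defaults as study conditions.** n = 24 subjects, 4 ROIs (left pars
opercularis, left pars triangularis, left/right fusiform), 30 items, 12
days, c = −150 ms per Fisher-z unit, σ = 50 ms, ρ ∈ (0.05, 0.8),
a ∈ (1800, 2200) ms, b ∈ (0.25, 0.35). The spreads of ρ, a and b were
chosen once so that the planted between-subject brain-behavior
correlation magnitude at n = 24 is ≈ 0.45–0.55 — the effect size this
class of study reports — and are not varied per analysis. A useful
emergent property: because higher z lowers only the plateau, subjects
with higher similarity also fit *larger* learning rates b, so the
learning-rate correlation comes out positive in coupled ROIs without
being separately planted.

**Item level.** Per-item similarities are drawn from the ρ interval and
couple negatively (−150 ms/z) to a group-level per-item RT table. The
generator also emits per-subject pattern pairs for the planted fast
(high-similarity) and slow halves as extra conditions
(`trained_fast`/`trained_slow`), standing in for the re-modeled GLM of a
real study; the median split recovered from the item RT table aligns
with the planted halves up to item-level noise (20 ms).

**Reproducibility.** One root seed spawns independent child streams for
patterns and behavior (NumPy `SeedSequence`), so either half can be
regenerated alone; identical seeds give byte-identical outputs.

## 3. Similarity (`similarity.py`)

Pearson correlation on condition-mean patterns, exactly two repetitions,
≥ 3 voxels, voxel values used as-is (no within-pattern normalization —
none is part of the modeled procedure). Zero-variance patterns raise an
error naming the (subject, ROI, condition) cell rather than producing
silent NaNs. Fisher transform z = atanh(r); |r| ≥ 1 − 10⁻⁷ is clamped
to that threshold with a logged warning so downstream statistics stay
finite. Percent signal change is contrast / run-mean × peak-height × 100.

## 4. Learning curves (`learning.py`)

Nonlinear least squares for y = a·x^(−b): starting values from OLS on
log y vs log x (deterministic), Levenberg–Marquardt refinement on the
original millisecond scale. R² = 1 − SS_res/SS_tot is computed on the
original scale, not the log scale — a deliberate choice documented here
because a single goodness-of-fit per subject does not disambiguate the
two; the exclusion threshold (default 0.7) then applies to this R².
Constant RT series yield b ≈ 0 and an undefined R² (NaN, excluded by the
filter). Non-convergence sets an honest `converged=False` flag with the
optimizer message; such fits are always excluded.

Median split: stable sort by (RT, item id), lower half fast; for even
counts the groups are equal, for odd counts the fast group gets the
middle item. All-tied inputs split by item order with a logged warning.

## 5. Inference (`inference.py`)

**Permutation p-values.** Monte-Carlo mode uses the add-one rule
p = (1 + #{null as or more extreme}) / (n_perm + 1), which can never
return 0. `p_one` is one-tailed in the direction of the observed sign —
reported because directional displays are conventional for this analysis
— but note it is not a level-α test on its own (under the null it
rejects at ≈ 2α). Significance flags and the calibration guarantees in
the test suite therefore use the two-tailed `p_two`. Exhaustive modes
(between: all n! orderings for n ≤ 9; within: all 2ⁿ swap assignments
for n ≤ 20, the default for n ≤ 12) report exact proportions over the
enumeration, which includes the identity and so keeps p ≥ 1/N.

**Dependent correlations.** Steiger's (1980) pooled-correlation z for
two correlations sharing one variable:
z = (z_jk − z_jh)·√((n−3)/(2−2c̄)), c̄ = ψ/(1−r̄²)²,
ψ = r_kh(1−2r̄²) − ½r̄²(1−2r̄²−r_kh²), r̄ = (r_jk+r_jh)/2. The triple is
checked for positive semidefiniteness first; inconsistent inputs are
errors. Simulation at n = 24 puts the empirical type-I rate at ≈ 0.048
(nominal 0.05). The correlation between the two similarity vectors
(r_kh) is a required input; when run on data the pipeline computes it
directly.

**LOOCV.** Per fold, simple OLS (one predictor + intercept) on n − 1
subjects; relative error (predicted − observed)/observed. Exactly zero
on noiseless linear data.

**Orchestration.** `run_full_analysis` runs the battery per ROI × task
with deterministic child seeds derived from the config seed. A cell is
*significant* when the trained-condition correlation p, the
between-subject permutation p_two and the within-subject permutation
p_two are all below α; an ROI is *flagged* when significant in every
task. No multiple-testing correction is applied across ROIs/tasks — the
report states the number of tests and provides a Bonferroni-adjusted
column for readers who want it.

## 6. What the simulations do and do not show

The generator reproduces the statistical structure the pipeline needs:
planted correlations with realistic sampling noise, power-law learning
with additive plateau coupling, exchangeable trained/control conditions
under the null. It does not emulate spatial autocorrelation between
voxels, hemodynamic model mis-specification, GLM estimation noise shared
across conditions, motion artifacts, or between-ROI dependence beyond
the shared latent. Passing tests therefore certify the *statistical
machinery* (calibration, recovery, exactness), not robustness to fMRI
preprocessing choices. Published subject-level correlation values cannot
be reproduced without the original (undeposited) data; the quantities
checked here are those fully determined by printed design parameters
plus the pipeline's own guarantees.

## 7. Problem sizes used by the test suite

Null calibration uses 1000 simulated null studies (n = 24, one ROI,
1000 permutations each) per scheme and 2000 trivariate-normal replicates
for the Steiger test; oracle equivalence enumerates 40 320 orderings /
256 swap assignments at n = 8; coupling-sign recovery uses 500
replicates; end-to-end flagging uses 100 replicates at 1000
permutations. These sizes give binomial 99% confidence half-widths of
≈ 0.018 (1000 draws) around the nominal 0.05, tight enough to detect
meaningful miscalibration.
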