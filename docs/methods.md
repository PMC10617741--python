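# Methods

## Cohort model

A cohort is a participants × variables matrix with a binary outcome
(faller = 1, non-faller = 0 everywhere in the package) and an explicit
boolean missing mask. Every variable carries a domain tag from the closed
set {balance, gait, clinical, strength, body_composition}; the analysis
strategy operates on the induced partition ("data packages"). CSVs encode
missing cells as empty strings and carry variable metadata (domain, kind,
units) in a sidecar CSV, so a save/load round trip is bit-exact and the data
file stays a plain numeric table. Standardization is always to mean 0 /
sample SD 1 (ddof = 1) over observed entries; constant columns are an error,
never silently dropped.

## Derived features

Formulas operating on trial-level inputs, each with its degenerate cases
pinned down:

- **Symmetry angle** |45° − arctan(L/R)|/90° × 100, in percent: 0 is perfect
  inter-limb symmetry, 50 the one-side-zero boundary. R = 0 is evaluated as
  the arctan limit 90° (giving 50%), for continuity; both sides zero is an
  error. The magnitude is reported, making the measure order-invariant.
- **Romberg ratio** (eyes-closed / eyes-open sway velocity) and
  **somatosensory ratio** (foam / firm): plain quotients with a positive
  denominator precondition.
- **MAD%**: median absolute deviation of the repeated step measurements as a
  percentage of the median, with the raw MAD (no 1.4826 consistency
  constant) because the quantity is defined relative to the original median,
  not as a normal-SD estimate. Even-length medians are midpoints of the two
  central order statistics.
- **Gait speed reserve**: maximal / usual gait speed.
- **RTD**: torque traces are zero-phase filtered (second-order Butterworth,
  150 Hz default cutoff, forward–backward so onset timing is unbiased);
  contraction onset is the first sample reaching 4 Nm above baseline, with
  baseline the mean of the leading 500 ms (configurable — the onset rule
  needs a rest estimate and the source protocol does not pin one down); RTD
  over (0, w) windows is the endpoint slope Δtorque/Δtime, with a
  least-squares-over-the-window variant exposed as an option. On any affine
  trace both give the ramp slope regardless of the onset threshold.
- **Muscle quality**: summed peak torque per kg of regional lean mass;
  callers compose the single-torque and combined flexion+extension indices,
  dominant limb by higher measured torque, composite as the
  dominant/non-dominant mean.

## Synthetic cohort generator

The generator defines the conditions every downstream test runs under. Its
built-in configuration encodes the published per-group means and SDs of all
51 multi-domain variables (11 balance, 11 gait, 5 clinical, 14 strength, 10
body composition) plus the baseline descriptives (13 continuous, 2 binary),
group sizes 21/39, and 2% MCAR missingness.

Dependence is a Gaussian copula on latent standard normals: a block-constant
correlation target with within-domain r = 0.6, strength↔body-composition
cross-correlation 0.7, balance↔anything 0.1, and 0.3 for the remaining
domain pairs. Only the marginals were published; these levels are the
package's one-time reading of the reported dependence pattern (very strong
strength/body-composition coupling, e.g. r = 0.92 between shank muscle
quality and plantar-flexion torque; moderate gait↔strength couplings around
r = 0.58; balance nearly decoupled). A block-constant target with
cross-block correlation exceeding within-block correlation is not positive
semi-definite at these block sizes, so the matrix is repaired by eigenvalue
clipping and unit-diagonal rescaling; on the fixture the largest entry
adjustment is ≈ 0.05 and a repair beyond 0.35 is treated as a configuration
error. Continuous variables are mean + SD × latent; binary variables
threshold the latent at the group probability quantile. Optional "nuisance"
variables with identical group distributions emulate the redundant remainder
of the full measurement battery so the selection stages have chaff to
discard.

Trial-level gait series draw a participant level from the group
distribution and scatter `steps` values around it with Laplace noise of
scale b (absolute, or relative to |level|, default 5% relative); the MAD of
a Laplace(b) is b·ln 2, giving MAD% a known expectation for calibration
tests.

What the generator does **not** emulate: non-Gaussian marginals (many real
variables are skewed or bounded), informative missingness, measurement
error correlated with the outcome, and any nonlinear group structure.
Passing tests therefore demonstrate correctness and calibration of the
machinery under the stated generative model, not clinical performance on
real cohorts.

## Univariate screen

Welch's unequal-variance t-test from group summaries with pooled-SD
Cohen's d reported as a magnitude — this pairing is the one that reproduces
the published descriptive tables from their printed means/SDs. The 2×2
categorical test is the Yates-corrected χ², floored at zero when
|ad − bc| ≤ n/2 (the correction would otherwise overshoot past the
expectation), with V = √(χ²/n); the floor is required to reproduce the
published near-zero effect sizes, and scipy's implementation is used as a
cross-check on non-floored tables. Correlation matrices are
pairwise-complete Pearson with magnitude labels at 0.10/0.30/0.50 and a
collinearity flag at |r| > 0.50; Bartlett's sphericity
χ² = −(n − 1 − (2p+5)/6)·ln det R on p(p−1)/2 df summarizes redundancy. No
multiple-testing correction is applied; flags mirror the p ≤ 0.10 / 0.05 /
0.001 convention of the source tables.

## PLSCA and LOVO importance

`fit_plsca` is the SVD of R = XᵀY/(n−1) of two z-scored blocks. Untruncated
inertia Σλ² equals ‖R‖²_F exactly; the component cap K is exposed but
defaults to all, and with a single group column the two coincide. The group
block is one z-scored indicator column (a two-level dummy block is rank 1
after centering, so nothing is lost). LOVO importance refits the
decomposition without each variable; with untruncated inertia the decrease
equals the dropped column's squared norm in R, which the test suite uses as
the analytic oracle for the brute-force loop. Between-domain shared
information is reported as measured inertia and measured/(p_a + p_b) — the
normalization consistent with all published pairs — with a row-permutation
p-value (1 + #{perm ≥ obs})/(B + 1), B ≥ 99. Latent scores project rows on
the first right salience, sign-canonicalized to correlate positively with
faller coding (SVD signs are otherwise arbitrary and would break
reproducibility). Missing cells must be imputed before PLSCA; there is no
pairwise deletion inside the SVD.

## Random forest

500 trees, Gini impurity, ⌊√p⌋ features per split, bootstrap with
replacement, unlimited depth, unweighted classes — the canonical
classification-forest configuration, all surfaced in config (scikit-learn
provides the estimator). Importance is mean decrease in Gini; validation is
out-of-bag: each participant's vote fraction from trees that did not see
her, with the OOB "p-value" interpreted as a one-sided binomial test of OOB
accuracy against the majority-class (no-information) rate — the published
report prints such a p-value without defining the test, and this is the
documented reading.

## Jenks selection and union refinement

The importance elbow is the exact Fisher–Jenks optimum: dynamic programming
over contiguous partitions of the sorted scores minimizing within-class sum
of squared deviations (verified against exhaustive search). Two classes by
default, matching a single cut-off line on a scree plot; "important" means
strictly above the lower class's maximum, so ties at the break conservatively
stay below. A manual override cutoff is accepted and recorded, standing in
for the analyst's subjective validation of the elbow. The refined set is the
union of the two engines' selections with per-variable provenance
(both / rf-only / lovo-only).

## PPCA imputation

Model x = Wz + μ + ε, z ~ N(0, I_q), ε ~ N(0, σ²I). Columns are
standardized first (the domains mix units from degrees to MET-minutes) and
de-standardized after, which fixes μ and leaves EM over (W, σ²) with missing
coordinates handled exactly in the E-step: each row's latent posterior uses
only its observed coordinates, and missing cells contribute their
conditional moments to the sufficient statistics. The observed-data
log-likelihood is computed each iteration and asserted non-decreasing;
convergence is a relative change below 1e-6 (max 1000 iterations;
non-convergence is reported on the model, not silenced). Defaults: q = 5 —
small against both n = 60 and the package sizes, and consistent with the
strong low-rank block structure; the source work does not report its choice.
Imputation replaces missing cells with conditional expectations; observed
cells are bitwise untouched.

## Classifiers and evaluation

- **Logistic regression**: statsmodels maximum likelihood (Newton, with a
  quasi-Newton fallback when separation makes the Hessian singular — flagged
  on the report), VIF from auxiliary OLS regressions, AIC/BIC from the
  log-likelihood, McFadden R² = 1 − ℓ/ℓ₀. Backward stepwise removes the
  predictor whose removal most decreases the criterion until none does, ties
  broken by the larger p-value (deterministic path), run for both AIC and
  BIC with an agreement flag.
- **ROC layer**: empirical curve over all thresholds; trapezoid AUC (equal
  to Mann–Whitney concordance with ties counted ½, verified against a
  pair-counting oracle); AUC p-value from the asymptotic Mann–Whitney test;
  optimal cutoff maximizes Youden's J, ties resolved to the lowest
  threshold; classification rule is score ≥ cutoff → faller.
- **LOOCV** for logistic models classifies each held-out participant at
  probability 0.5 — not the in-sample Youden cutoff, which would leak the
  held-out label's information into the threshold. Non-convergent or
  separation-flagged folds are counted and reported.
- The PLSCA classifier scores participants by the first latent component;
  the forest classifier by OOB vote fraction.

## Pipeline

Stage 1 runs every domain package through impute → screen → dual importance
→ Jenks union → baseline and refined classifier suites. Stage 2 aggregates
the domains' important sets (each variable traceable to exactly one
domain), re-imputes, repeats the importance/selection sequence, evaluates
the three classifiers plus LOOCV and stepwise refinement, and emits the
pairwise between-domain inertia table. Each stochastic stage derives its
seed from the run seed, so the pipeline is a pure function of (table,
config). Reports are TSV per table plus a YAML summary and a short text
digest; re-running a config overwrites byte-identically.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 150–300 trees and 99 permutations
on the 51-variable fixture plus 15 nuisance variables; the shipped defaults
are 500 trees and 999 permutations. Identity checks (Frobenius, LOVO
column-norm, Jenks vs exhaustive search, AUC vs pair counting) are asserted
at 1e-12; EM monotonicity at −1e-8 to absorb accumulated round-off;
calibration checks (Welch type-I over 10,000 null cohorts, generator
marginal recovery at 5,000 per group) at Monte-Carlo-appropriate bands.

## Known limitations

- LOVO importance with a single group column reduces analytically to squared
  point-biserial correlations; the brute-force refit is kept because the
  same code path serves multi-column X blocks, where no closed form applies.
- The OOB binomial p-value treats per-participant OOB predictions as
  independent Bernoulli trials, which they are only approximately.
- PPCA assumes an isotropic-noise linear-Gaussian model; imputation quality
  degrades off that model, and no imputation uncertainty is propagated into
  the classifiers.
- In-sample AUCs at p close to n are optimistic (the logistic baseline
  routinely separates perfectly on n = 60); LOOCV is the honest estimate and
  is reported alongside.
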