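# Methods

## Model and procedure

The package estimates brain age (BA) from regional multimodal-MRI features
and analyses the brain-age gap (BAG) trajectory over chronological age (CA).
The estimator is deliberately the simplest one that supports interpretable
per-feature weights:

1. **Confound removal.** Each feature is residualized against gender by a
   per-feature linear regression fitted on training subjects only
   (closed form: `b1 = cov(g, x)/var(g)`), so training residuals are exactly
   orthogonal to the gender regressor.
2. **Normalization.** `Z = (x − u)/s` with `u`, `s` the training mean and
   *sample* standard deviation (ddof = 1). Features whose training SD falls
   below 1e−12 are flagged degenerate and dropped by default (configurable
   to pass through as zeros). Test rows are always transformed with the
   training statistics; training-subject ids are recorded in every fitted
   sub-model so leakage can be audited.
3. **Selection.** LASSO on the z-scored features with fixed penalty
   α = 0.3 (scikit-learn's objective, `1/(2n)·‖y − Xw‖² + α‖w‖₁`),
   coordinate-descent tolerance 1e−6, at most 10,000 iterations — all
   deterministic. An α chosen by k-fold cross-validation over a log grid
   (10⁻³…10, 30 points, 5 folds) is available as `alpha="cv"`. An empty
   selection is a warning-level outcome, not an error: the downstream
   regression then predicts the training mean.
4. **Regression.** Ordinary least squares of CA on the selected features.
   Weights are in years per z-scored feature unit and are ranked by
   magnitude with sign preserved; ties break on the canonical feature
   order. A rank-deficient design raises by default; `rank_policy="pinv"`
   returns the minimum-norm solution instead (required, e.g., for exactly
   collinear noiseless features).
5. **Evaluation.** Leave-one-out cross-validation in controls. Accuracy is
   MAE, rMSE, Pearson r and `R² = 1 − SSE/SST` (SSE about the predictions,
   SST about the mean CA, so R² may be negative). Patients are scored by
   the model trained on *all* controls.
6. **Bias correction.** OLS of the raw control gap (BA − CA) on CA gives
   `offset = α·CA + β`; `correctedBA = BA − offset` is applied uniformly to
   controls and patients. By the OLS residual property the mean corrected
   control gap over the fitting set is exactly zero; the correction is
   idempotent. It is fitted on the out-of-fold control predictions, not on
   refit predictions, to avoid optimism.
7. **Trajectory.** Degree-1 and degree-2 polynomial least squares of the
   corrected patient BAG on CA, compared by adjusted R² (primary) with a
   Gaussian AIC (−2·loglik + 2k, error variance counted as a parameter)
   reported alongside. The quadratic's stationary age `−b/(2a)` — reported
   with its curvature sign so an "upward-opening" claim is checkable — is
   the vertex used to label subjects youth (CA < vertex) or middle
   (CA ≥ vertex). `integer_band=True` instead cuts at `floor(vertex)`,
   reproducing integer-year band tables in which a 47-year-old falls in the
   middle band under a vertex of 47.33.
8. **Group statistics.** Welch's t-test by default (pooled optional) for
   BA-vs-CA within each group × band cell and for SZ-vs-NC gap differences
   within bands; Pearson chi-square without continuity correction for
   gender contingency; a summary-statistics t-test for desk-checking
   printed demographic tables. The two-sample BA-vs-CA comparison is kept
   two-sample for fidelity to common practice even though pairing is
   available. No multiple-testing adjustment is applied; p-values are
   labelled unadjusted.
9. **Permutation test.** CA labels of the control table are shuffled
   `n_perm` times; the *full* pipeline (selection included) is re-run per
   shuffle and the LOOCV MAE recorded. The p-value uses add-one smoothing,
   `p = (1 + #{MAE_perm ≤ MAE_obs})/(1 + n_perm)`, which cannot be zero and
   is exact under exchangeability.

## Selection placement inside LOOCV

Two placements are supported and logged. `nested` (default) refits
preprocessing, selection and regression inside every fold — leakage-free
but n LASSO fits per evaluation. `pooled` fits preprocessing and selection
once on the full training set and cross-validates only the OLS stage; this
reproduces the single-selected-set variant common in applied work
(optimistically biased, since the held-out subject influenced selection)
and admits the exact closed-form leave-one-out identity
`ŷ₋ᵢ = yᵢ − eᵢ/(1 − hᵢᵢ)`, verified against explicit refits in the test
suite. Orchestrated runs use `nested` for the headline accuracy and
`pooled` inside permutation replicates, where thousands of pipeline re-runs
are needed; both choices are recorded in the run manifest.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
images: ages uniform on [20, 60] (rounded to integer years by default, as
band tables are integer-valued), gender Bernoulli(½), and features

* linear-informative: `intercept + slope·effAge`,
* quadratic-informative: `+ curvature·effAge²`,
* pure noise: intercept only,

all plus `γⱼ·gender` on informative columns (`γⱼ ~ N(0, gender_effect_sd)`)
and i.i.d. `N(0, noise_sd)` noise. Slope magnitudes are uniform on
[0.5, 1.5] with random sign; curvatures are drawn on the same scale and
divided by the age span so the quadratic term's contribution over the
observed range is comparable to the linear one (the generator config
intentionally has no separate curvature knob). Informative columns are
assigned round-robin across the sMRI/fMRI/DTI blocks so every modality
subset carries signal. Controls have effective brain age equal to CA;
patients deviate by `a·(CA − c)² + d` with defaults a = 0.01 yr⁻¹,
c = 47 yr, d = 1 yr — an elevated gap in youth declining toward the vertex.
Identical config + seed reproduces the table byte-for-byte.

Default cohort sizes (205 NC, 138 SZ) mirror a recruited 209/154 cohort
after 4/16 quality-control exclusions. The default noise level
(`noise_sd = 30`) was set analytically: with 40 informative features the
Cramér–Rao floor on any age estimator is
`noise_sd/√(Σ gⱼ²)` ≈ 4.6 yr (`gⱼ` the per-feature age sensitivity),
i.e. ~85–90% of the variance of a U(20, 60) age distribution is
explainable — a regime comparable to published multimodal brain-age
accuracy. `GroundTruth.noise_floor_mae()` exposes the corresponding
best-case MAE (`√(2/π)` × floor SD) as the oracle bound used in
parameter-recovery tests.

What the generator does **not** emulate: spatial correlation between
regional features, site/scanner effects, non-Gaussian noise, education or
medication confounds, and longitudinal structure. Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
assumed generating model, not robustness of the scientific conclusions on
real clinical data.

## Numerical choices and degenerate inputs

* Preprocessing order is gender-residualization → z-scoring (configurable;
  residualization is scale-equivariant so the order affects only scale).
  Either step may be omitted. Note that confound removal makes exact
  feature–age relationships inexact whenever gender correlates with age in
  the training sample — the noiseless-recovery test therefore runs the
  normalization-only pipeline.
* LOOCV is invariant to subject row order (outputs permute with rows).
* Leverage ≈ 1 in the closed-form leave-one-out identity (a subject
  uniquely determining its fold) raises rather than returning an unstable
  value.
* Zero CA variance makes r/R², the bias slope and the trajectory fit
  undefined — all raise. Vertex of a flat quadratic (a = 0) raises.
* The adjusted-R² comparison keeps the quadratic term only when its
  in-sample F exceeds 1, so under a truly linear gap the linear model is
  preferred in roughly two-thirds of replicates — the test suite asserts
  the majority, not certainty.

## Experiment sizes

The acceptance experiments run at sizes chosen to make their Monte-Carlo
margins comfortable on a single CPU: brain-age parameter recovery on one
n = 200 control cohort with the full 1,430-column layout (nested LOOCV);
vertex recovery over 50 replicates of n = 150 (true within-±3-years rate
≈ 97%); permutation calibration over 200 null replicates × 99 permutations
on n = 40 cohorts with 30 features using the pooled-mode pipeline; the
full-study permutation test with 200 permutations. The study-scale defaults
themselves (205 + 138 subjects, 1,430 features) are used for the end-to-end
run.

## Known limitations

* The estimator is intentionally linear (MLR); nonlinear regressors are out
  of scope.
* No spline/GAM trajectories and no longitudinal modelling; the quadratic
  vertex is a descriptive split point, not a change-point estimate.
* No site harmonization or nonlinear confound models; gender is the only
  confound handled.
* The fixed α = 0.3 is honoured as the primary operating point even though
  a cross-validated penalty is statistically cleaner; both are exposed.
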