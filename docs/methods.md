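# Methods

## Generative model of the synthetic cohort

Every scan carries a latent brain age `b` per tissue. For a subject of
chronological age `a` in group `g`:

```
b = a + δ(g, tissue) + u_subject
```

with `δ(HC) = 0` for both tissues (healthy brains are unbiased by
construction), `δ(acAN, GM) = +1.79` y, `δ(recAN, GM) = −0.43` y,
`δ(acAN, WM) = −0.39` y, `δ(recAN, WM) = 0`. The subject deviation
`u_subject` is bivariate normal across tissues with SD `subject_sd = 1.5` y
and correlation 0.44, shared across a subject's timepoints (it is the random
intercept the longitudinal model estimates).

`subject_sd` was derived from the reported precision of the acute
grey-matter contrast: a 95% CI of width ≈ 0.68 y at n = 129/167 implies a
within-group SD of ≈ 1.5 y. The between-tissue correlation mirrors the
imperfect coupling of GM- and WM-based scores in real data.

**Ages** are drawn uniformly on 12–23 y *in every group*. Real cohorts of
this design are not age-matched (recovered patients tend to be older); the
generator deliberately matches the distributions so that the white-matter
forward model's nonlinearity (below) cannot convert age differences into
spurious group effects — parameter recovery then tests the pipeline, not an
age confound. This is a known difference from real data: passing tests say
nothing about robustness to group age mismatch (the CS2a age × group model
exists for that purpose).

**Clinical covariates** are group-specific normals with plausible values for
an adolescent eating-disorder cohort (documented constants in
`synthetic_cohort.COVARIATE_PARAMS`; e.g. acAN BMI-SDS −2.8 ± 0.8, EDI-2
220 ± 40, BDI-II 20 ± 9, illness duration gamma with mean 1.9 y). They are
not asserted against any external table.

### Follow-up dynamics

Dynamics act on the BrainAGE *gap* `b − a`: over the follow-up interval
(0.25 y, "~3 months") the brain ages in step with chronological age, and the
grey-matter gap of a completer changes by

```
Δgap_GM = slope × ΔBMI-SDS + ε,   ε ~ N(0, 0.5²),   slope = −0.65
```

The BMI-SDS gain is gamma-distributed (always positive — the analogue of a
mandatory ≥10% BMI regain) with mean `1.69 / 0.65 ≈ 2.6` and SD 1.0. The
mean is not free: it is pinned by requiring the two longitudinal effects to
be jointly consistent — a mean gap change of −1.69 y at −0.65 y per unit
gain forces a mean gain of 2.6 units. The units of the weight-gain predictor
are a package convention (BMI-SDS); the residual SD 0.5 reproduces the
reported precision of the slope (CI half-width ≈ 0.10 at n = 95). The
white-matter gap does not change. EDI-2 and BDI-II improve at follow-up
independently of the gain (a simplification; in real patients symptom change
correlates with weight gain, which would widen — not bias — the L3 CI).

### Forward model to images

Voxel values are tissue-probability-like intensities on a 20×24×20 grid of
nominal 8 mm voxels:

```
value_v = μ_v + s_v · f(b) + N(0, voxel_noise_sd²),  clipped to [0, 1]
```

with `μ_v ~ U(0.3, 0.7)` and tissue-specific loadings and link `f`:

- **GM**: `f(b) = b − 17.5` (identity about the mid-age; monotone volume
  decline via negative loadings `−U(0.008, 0.032)`).
- **WM**: `f(b) = 1 − ((b − 22.5)/5)²`, a concave quadratic peaking at the
  upper edge of the age range with positive loadings `U(0.02, 0.075)` —
  white-matter volume is still rising through adolescence, the start of its
  lifespan inverted U. Placing the peak at the very end of the range keeps
  the age → feature map monotone over almost the whole range, so a linear
  kernel can invert it; a mid-range peak would make the injected WM offset
  unidentifiable and parameter recovery a test of model mismatch.

Loading ranges follow one design rule: the per-entry kernel signal power
`E[s²]·E[f(a)²]` must exceed the voxel-noise power `voxel_noise_sd² = 0.02²`
by roughly an order of magnitude per tissue, so evidence maximisation does
not shrink the age readout toward zero. The WM range is wider because its
quadratic `f` has far less variance over 12–23 than the GM identity. Under
these defaults clipping touches ≪1% of voxels (asserted in tests).

Two consequences are worth noting. First, the GM inverse problem is exactly
linear, so training MAE is near zero — the generator is far cleaner than
real MRI, where this framework reports MAEs above a year; accuracy numbers
on synthetic data say nothing about real-data accuracy. Second, the WM
readout is the best linear approximation of a quadratic, which attenuates
the recovered WM group effect by an analytic factor ≈ 0.93 (plus a small
additional shrinkage from the evidence-estimated noise floor); the recovered
magnitude ≈ 0.33–0.38 y for an injected 0.39 y sits well inside the ±0.15 y
recovery band.

All randomness flows from the single cohort seed through named substreams
(`template`, `training`, `cohort`, `followup`, and a child stream for voxel
noise), so a config + seed reproduces byte-identical tables and maps.

## Preprocessing

Smoothing before resampling, in that order. Smoothing is a separable
Gaussian with `σ = FWHM / voxel / (2√(2 ln 2))` per axis and
renormalised-truncation boundaries: the volume is filtered with zero padding
and divided by the filtered indicator, so no values are invented outside the
grid and constants survive to the edge. Resampling is trilinear onto an
isotropic grid whose centres never extrapolate the input field of view; when
target equals source resolution it is the identity. The brain mask keeps
voxels whose mean training intensity exceeds 0.05 and is frozen for test
data. Vectorisation uses x-fastest (Fortran) ordering. The whole chain is
affine in intensity: `preprocess(aX + b) = a·preprocess(X) + b`.

## Relevance vector regression

Model: `t = Φw + ε`, `ε ~ N(0, β⁻¹I)`, `w_i ~ N(0, α_i⁻¹)`; the design is
the linear kernel of centred training features (scale = feature count) plus
a bias column; targets are centred and the mean restored at prediction.
Hyperparameters maximise the log evidence

```
L(α, β) = −½ [n log 2π + log|C| + tᵀC⁻¹t],   C = β⁻¹I + Φ diag(α)⁻¹ Φᵀ
```

evaluated through the weight-space precision `H = diag(α) + βΦᵀΦ` (matrix
inversion/determinant lemmas), with Cholesky factorisation and a 1e−10
jitter on `H`.

The optimiser combines the classic fixed-point updates with the per-basis
analytic machinery of the fast marginal-likelihood method:

- **Constructive start** (default): the model begins with the single
  best-aligned basis at its per-basis evidence optimum, and bases enter one
  per iteration through an *add* move (largest closed-form evidence gain,
  accepted only if the recomputed evidence strictly increases). A flat
  all-bases start (`start_full=True`, `alpha_init = 1e−6`) is available but
  tends to settle in the dense local optimum of the evidence in which every
  chance alignment is retained.
- **Re-estimation**: per-basis `α_i ← s_i²/(q_i² − s_i)` where the
  sparsity/quality factors are decisive, the `γ_i/μ_i²` fixed point
  otherwise, applied as one damped step (backtracked in log-α space until
  the evidence does not decrease).
- **Deletion**: bases with `q_i² ≤ s_i` (evidence maximised at `α = ∞`) are
  removed, as are bases crossing `prune_threshold = 1e9`.
- **Noise update**: `β ← (n − Σγ_i)/‖t − Φμ‖²`, backtracked likewise, on a
  slower clock (every 4th iteration) — eager β updates race to the
  interpolation optimum before pruning can act — and forced whenever the α
  criterion looks met.

Every recorded evidence value corresponds to an accepted move, so the path
is non-decreasing to numerical precision (asserted at 1e−8 slack).
Convergence requires a relative evidence change below `tol = 1e−6` *and*
hyperparameter stability (max |Δlog α| < 1e−3, |Δlog β| < 1e−3); cap 500
iterations. Constant targets short-circuit to the bias-only model.
Predictive variance is `β⁻¹ + φᵀΣφ` per scan.

Sparsity is a property of correlated (kernel) designs: with near-orthogonal
random bases and very low noise, the exact evidence optimum genuinely
retains many chance-aligned bases — the sparsity test therefore uses a
smooth kernel design, matching how the package uses the model.

## BrainAGE scoring and bias correction

`brainage_raw = predicted − chronological` (exact identity in every emitted
row). The correction is OLS of raw score on age over control scans only,
fitted separately per tissue (GM and WM predictions have different age
trends), then subtracted from all scans. Controls entering the fit are all
HC scans of the analysis sample. By the OLS projection property the
corrected control trend and mean are zero and refitting on corrected
controls is a null correction. Training-set accuracy (MAE, SD of absolute
errors, Pearson r) is reported pre-correction.

## Statistical models

- **CS1**: `score ~ group`, dummy-coded, HC reference; Wald t CIs at 95%.
- **CS2a**: adds centred age and age × group (age centring is the default;
  raw age is a flag away).
- **CS2b/CS2c**: add SSRI use / a binge-purge indicator (0 for controls).
- **CS3**: acAN baseline only; BMI-SDS, EDI-2, BDI-II and illness duration
  z-scored (betas per SD; raw units by flag) plus age in years; listwise
  deletion with a logged count.
- **L1/L2**: random-intercept mixed model (REML) of completers' two
  timepoints, plus HC reference scans and a group term in L1; L2 restricts
  to completers (controls have no illness duration) and covaries for
  baseline clinical measures. On a balanced two-timepoint design the
  timepoint coefficient equals the mean within-person change exactly. A
  singular or non-convergent fit falls back to OLS on change scores with a
  logged notice — the balanced-design estimate is identical.
- **L3**: change-score regression `ΔBrainAGE ~ ΔBMI-SDS + ΔEDI-2 + ΔBDI-II
  + baseline illness duration`, ΔBMI-SDS in raw units. The change-score
  formulation was chosen over a time-varying-covariate mixed model because
  the estimand is "change predicts change".
- **Contrasts**: linear combinations of CS coefficients with t-based CIs; a
  self-contrast is returned as 0 with a degenerate-CI note.
- **Multiplicity**: one global `α = 0.05/(outcomes × model families)`
  (0.0083 for 2 × 3), displayed to four decimals; no per-contrast Bonferroni
  on top.

Rank-deficient designs raise a collinearity error naming the offending
columns (QR with pivoting). Estimates are invariant to row order and
participant relabelling.

## Problem sizes used in the test suite

End-to-end recovery uses 20 replicates of the full default cohort (226
training + 430 cohort scans, both tissues). Error calibration uses 200 null
and 200 effect replicates of a reduced design — 30 acAN / 30 HC with a
60-subject training set on the default grid — which keeps the Monte-Carlo
experiments desk-scale while leaving the per-cohort estimator untouched.
Type-I error of the acute contrast is nominal (0.05 ± 0.03) and 95% CI
coverage of the injected offset is 95% ± 5 points under these conditions.

## Known limitations

- No neuroanatomy: templates are random fields, with no registration or
  partial-volume artefacts; masks are near-trivial.
- The generator's SNR makes GM age prediction nearly exact; real-data MAEs
  are an order of magnitude larger.
- Group age distributions are matched by design (see above).
- Clinical covariates are independent of the imaging latent except where an
  effect is injected, so CS3 on default data estimates a true zero for all
  covariates.
- Hydration, re-feeding, menstrual-cycle and scanner effects are out of
  scope.
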