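# anbrainage

Brain-age analysis for adolescent anorexia nervosa cohorts: estimate grey-
and white-matter brain age from volumetric tissue maps with relevance vector
regression, compute age-bias-corrected BrainAGE scores, and fit the
cross-sectional and longitudinal models of a case–control recovery study —
all runnable end to end on a synthetic cohort generator, because clinical
imaging data of this kind cannot be shared.

## The science

Structural brain maturation follows stereotyped trajectories: grey-matter
(GM) volume declines steadily from childhood, while white-matter (WM) volume
follows an inverted U that is still rising through adolescence. A regression
model trained on healthy subjects can therefore predict a person's age from
their tissue maps. The **BrainAGE score** is the gap

```
BrainAGE = predicted brain age − chronological age
```

with positive values indicating an "older"-appearing brain. In acutely
underweight anorexia nervosa (acAN), GM-based brain age is elevated; the
question this pipeline addresses is whether that advancement is a transient
starvation effect that normalises with weight recovery.

The estimation engine is **relevance vector regression** (RVR): sparse
Bayesian regression with a linear kernel `K(x, x') = x·x'/d` over masked,
smoothed (8 mm FWHM), coarsely resampled (8 mm) voxel intensities. Each
kernel basis carries its own prior precision `α_i`; maximising the marginal
likelihood (evidence) drives most `α_i → ∞`, leaving a few training subjects
as *relevance vectors*. Because kernel age models over-predict the young and
under-predict the old, the linear trend of raw BrainAGE on age is estimated
**in healthy controls only** and subtracted from every scan.

Group inference uses OLS on the bias-corrected scores with controls (HC) as
reference (cross-sectional models 1, 2a–c, 3) and random-intercept mixed
models for the two-timepoint follow-up of partially weight-restored patients
(longitudinal models 1–3), at a Bonferroni threshold of
`0.05 / (2 outcomes × 3 model families) = 0.0083`.

The synthetic cohort mirrors the study design: a healthy training set of
226 females aged 12–23, a test cohort of 129 acAN / 167 HC / 39 recovered
(recAN) baseline scans with 95 acAN follow-ups, GM maps whose latent brain
age is shifted by +1.79 y in acAN and −0.43 y in recAN, WM maps shifted by
−0.39 y in acAN, and follow-up GM normalisation of −0.65 y per BMI-SDS unit
of weight regained (mean change −1.69 y over ~3 months).

## Worked example

```bash
python analysis/01_simulate_cohort.py      # phenotypes + cohort summary
python analysis/02_fit_brainage.py         # train RVR, score, bias-correct
python analysis/03_cross_sectional_models.py
python analysis/04_longitudinal_models.py
python analysis/05_parameter_recovery.py --n-seeds 5
```

Step 02 prints the model accuracy and fitted bias trends, e.g.

```
GM: training MAE 0.000 y (SD 0.000), r(age) 1.000, 225 relevance bases
WM: training MAE 0.679 y (SD 0.439), r(age) 0.966, 4 relevance bases
GM bias trend: slope -0.0524 y/y, intercept 0.770 y (n=167 controls)
```

(the GM forward model is linear in the latent, so the healthy training set
is fit almost perfectly; the WM inverse is harder because WM volume is
quadratic in age). Step 03 prints the group contrasts:

```
multiplicity threshold: 0.0083
CS1 GM   acAN_vs_HC: beta +1.94 y [+1.60, +2.29], p 1.2e-24 *
CS1 GM  recAN_vs_HC: beta -0.46 y [-0.98, +0.06], p 0.085
CS1 WM   acAN_vs_HC: beta -0.08 y [-0.54, +0.38], p 0.74
```

— acute patients show markedly "older" grey matter, recovered patients do
not differ reliably from controls, and the white-matter effect is small.
Step 04 shows the longitudinal normalisation and its coupling to weight
gain:

```
L1 GM followup_vs_baseline: beta -1.743 [-1.907, -1.580], p 1.5e-96
L3 GM            d_bmi_sds: beta -0.634 [-0.745, -0.523], p 4.8e-19
```

All tables land in `results/`. A `anbrainage` console script exposes the
same stages as CLI verbs (`simulate`, `preprocess`, `train`, `predict`,
`analyze`, `run`) over NIfTI/CSV files:

```bash
anbrainage run --out-dir out/ --seed 1
```

## Layout

- `src/anbrainage/` — the library: `synthetic_cohort`, `preprocess`, `rvr`,
  `brainage`, `stats`, `pipeline`, `cli_io`, `cli`
- `analysis/` — numbered narrative drivers over the library
- `tests/` — pytest suite (unit, property and end-to-end recovery checks)
- `docs/methods.md` — models, parameter choices and limitations
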