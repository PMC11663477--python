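"""Synthetic cohort generator for the brain-age analysis.

Emulates the study design the pipeline expects: a healthy training sample
(ages uniform on 12-23 with latent brain age equal to chronological age), a
test cohort of acutely underweight patients (acAN), long-term recovered
patients (recAN) and healthy controls (HC), and a follow-up wave for a subset
of acAN completers after ~3 months of nutritional rehabilitation.

The generative model is linear in a latent brain age ``b``:

* group offsets: ``b = age + delta(group, tissue) + u_subject`` with
  ``delta(HC) = 0`` per tissue, so healthy brains are unbiased by
  construction;
* follow-up dynamics: the grey-matter latent change of a completer is
  ``slope * dBMI-SDS + eps`` so that weight gain drives normalisation;
* the forward model to images puts ``value = mu_v + s_v * f(b) + noise`` in
  each voxel, with ``f`` the identity (around the mid-age) for grey matter
  (monotone volume decline) and a concave quadratic for white matter whose
  peak sits at the upper edge of the age range (white-matter volume still
  rising through adolescence, the start of its lifespan inverted U). Values
  are clipped to [0, 1] to mimic tissue-probability maps.

Every random draw flows from ``CohortConfig.seed`` through named substreams,
so one config yields byte-identical phenotype tables and map payloads on
re-run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ShapeError
from .preprocess import GM, WM, TISSUES, VoxelMap

HC = "HC"
ACAN = "acAN"
RECAN = "recAN"
GROUPS = (HC, ACAN, RECAN)
BASELINE = "baseline"
FOLLOWUP = "followup"
TIMEPOINTS = (BASELINE, FOLLOWUP)
SUBTYPES = ("restricting", "binge_purge", "not_applicable")

PHENOTYPE_COLUMNS = [
    "participant_id", "scan_id", "group", "timepoint", "age", "bmi_sds",
    "edi2_total", "bdi2_total", "illness_duration", "ssri", "subtype",
]

# Named RNG substreams hanging off the single config seed.
_STREAMS = {"template": 0, "training": 1, "cohort": 2, "followup": 3}

# Group-specific covariate distributions (mean, sd), chosen as plausible for
# an adolescent eating-disorder cohort; documented constants, not asserted
# against any external table.
COVARIATE_PARAMS = {
    HC: dict(bmi_sds=(0.0, 0.7), edi2=(140.0, 25.0), bdi2=(5.0, 4.0),
             duration=None, p_ssri=0.0, p_binge_purge=0.0),
    ACAN: dict(bmi_sds=(-2.8, 0.8), edi2=(220.0, 40.0), bdi2=(20.0, 9.0),
               duration=(1.9, 1.5), p_ssri=0.3, p_binge_purge=0.2),
    RECAN: dict(bmi_sds=(0.2, 0.6), edi2=(160.0, 30.0), bdi2=(8.0, 6.0),
                duration=(3.0, 1.5), p_ssri=0.1, p_binge_purge=0.2),
}

# Mean follow-up symptom improvement (EDI-2, BDI-II), independent of weight gain.
_EDI_CHANGE = (-30.0, 15.0)
_BDI_CHANGE = (-6.0, 4.0)

# Correlation between the grey- and white-matter subject deviations; keeps the
# two BrainAGE readouts related but clearly distinct.
GM_WM_SUBJECT_CORR = 0.44


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults mirror the study conditions: 129 acAN / 167 HC / 39 recAN
    baseline scans, 95 acAN follow-ups, a 226-subject healthy training set
    aged 12-23, an acute grey-matter offset of +1.79 y, a recovered-group
    offset of -0.43 y, an acute white-matter offset of -0.39 y, and a
    weight-gain coupling of -0.65 y per BMI-SDS unit with a mean gain of
    1.69/0.65 BMI-SDS so the mean follow-up change is -1.69 y.
    """

    n_hc: int = 167
    n_acan: int = 129
    n_recan: int = 39
    n_followup: int = 95
    n_training: int = 226
    age_range: tuple[float, float] = (12.0, 23.0)
    delta_gm_acan: float = 1.79
    delta_gm_recan: float = -0.43
    delta_wm_acan: float = -0.39
    followup_weightgain_slope: float = -0.65
    followup_residual_sd: float = 0.5
    followup_bmi_gain_mean: float = 1.69 / 0.65
    followup_bmi_gain_sd: float = 1.0
    followup_interval_years: float = 0.25
    subject_sd: float = 1.5
    voxel_noise_sd: float = 0.02
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    voxel_size_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("n_hc", "n_acan", "n_recan", "n_followup", "n_training"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_followup > self.n_acan:
            raise ConfigurationError(
                f"n_followup ({self.n_followup}) cannot exceed n_acan ({self.n_acan})"
            )
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"age_range min must be < max, got {self.age_range}")
        if self.subject_sd < 0 or self.voxel_noise_sd < 0 or self.followup_residual_sd < 0:
            raise ConfigurationError("standard deviations must be >= 0")
        if self.followup_bmi_gain_mean <= 0:
            raise ConfigurationError("followup_bmi_gain_mean must be > 0")
        if any(n < 1 for n in self.grid_shape):
            raise ConfigurationError(f"grid_shape entries must be >= 1, got {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be > 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort config keys: {sorted(unknown)}")
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "grid_shape" in d:
            d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)

    def rng(self, stream: str) -> np.random.Generator:
        """Named, seed-derived random substream."""
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), _STREAMS[stream]]))


@dataclass
class MapTemplate:
    """Forward model from latent brain age to a voxel map.

    ``value_v = mu_v + loading_v * f(b)`` with ``f`` linear (GM, centred at
    mid-age) or concave quadratic (WM, peaking at ``peak``).
    """

    tissue: str
    mu: np.ndarray
    loading: np.ndarray
    kind: str  # "linear" | "quadratic"
    center: float = 17.5
    peak: float = 22.5
    halfwidth: float = 5.0

    def f(self, b) -> np.ndarray:
        b = np.asarray(b, dtype=float)
        if self.kind == "linear":
            return b - self.center
        return 1.0 - ((b - self.peak) / self.halfwidth) ** 2


def make_templates(config: CohortConfig) -> dict[str, MapTemplate]:
    """Seed-deterministic GM/WM templates on the config grid.

    Baselines mu_v ~ U(0.3, 0.7); loadings small enough that maps stay inside
    [0, 1] for all but a sub-percent tail of voxels at default noise.
    """
    rng = config.rng("template")
    lo, hi = config.age_range
    mid = 0.5 * (lo + hi)
    shape = tuple(config.grid_shape)
    templates = {}
    # Loading ranges follow a fixed design rule: the per-entry kernel signal
    # power E[s^2] * E[f(age)^2] must exceed the voxel-noise power
    # voxel_noise_sd^2 by roughly an order of magnitude for each tissue, so
    # the age signal - not the noise floor - dominates the kernel and the
    # evidence-maximised regression does not shrink the age readout. The WM
    # range is wider because its quadratic f has much smaller variance over
    # the age range than the GM identity.
    for tissue in TISSUES:
        mu = rng.uniform(0.3, 0.7, size=shape)
        if tissue == GM:
            mag = rng.uniform(0.008, 0.032, size=shape)
            templates[tissue] = MapTemplate(tissue=GM, mu=mu, loading=-mag,
                                            kind="linear", center=mid)
        else:
            mag = rng.uniform(0.02, 0.075, size=shape)
            templates[tissue] = MapTemplate(tissue=WM, mu=mu, loading=mag,
                                            kind="quadratic",
                                            peak=hi - 0.5, halfwidth=5.0)
    return templates


def render_map(b: float, template: MapTemplate, config: CohortConfig,
               rng: np.random.Generator, scan_id: str = "scan") -> VoxelMap:
    """Render one latent brain age into a tissue-probability-like voxel map."""
    if template.mu.shape != tuple(config.grid_shape):
        raise ShapeError(
            f"template grid {template.mu.shape} does not match config grid {tuple(config.grid_shape)}"
        )
    data = _render_values(np.asarray([b], dtype=float), template, config, rng)[0]
    return VoxelMap.create(data, config.voxel_size_mm, template.tissue, scan_id)


def _render_values(bs: np.ndarray, template: MapTemplate, config: CohortConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorised forward model for a batch of latents; returns (n, nx, ny, nz)."""
    fb = template.f(bs)
    vals = template.mu[None, ...] + template.loading[None, ...] * fb[:, None, None, None]
    if config.voxel_noise_sd > 0:
        vals = vals + rng.normal(0.0, config.voxel_noise_sd, size=vals.shape)
    return np.clip(vals, 0.0, 1.0)


def render_maps(scan_ids, bs, template, config, rng) -> dict[str, VoxelMap]:
    vals = _render_values(np.asarray(bs, dtype=float), template, config, rng)
    return {
        sid: VoxelMap.create(vals[i], config.voxel_size_mm, template.tissue, sid)
        for i, sid in enumerate(scan_ids)
    }


def generate_training_set(
    config: CohortConfig,
) -> tuple[np.ndarray, list[tuple[VoxelMap, VoxelMap]]]:
    """Healthy training sample: ages uniform on the age range, latent b = age.

    Returns the age vector and one (GM map, WM map) pair per subject.
    """
    config.validate()
    rng = config.rng("training")
    templates = make_templates(config)
    n = config.n_training
    ages = rng.uniform(*config.age_range, size=n)
    ids = [f"T{i:04d}" for i in range(n)]
    gm = render_maps(ids, ages, templates[GM], config, rng)
    wm = render_maps(ids, ages, templates[WM], config, rng)
    return ages, [(gm[i], wm[i]) for i in ids]


def _draw_duration(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Right-skewed illness duration (gamma), floored at 0.2 years."""
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return np.maximum(rng.gamma(shape, scale, size=size), 0.2)


def generate_phenotypes(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Baseline phenotype rows and latent brain ages (no maps).

    Returns ``(records, latents)``; ``latents`` has one row per scan and
    tissue with the latent brain age ``b``. All groups draw age uniformly on
    the configured range so that group contrasts are free of age-distribution
    confounding by design.
    """
    config.validate()
    rng = config.rng("cohort")
    lo, hi = config.age_range
    rows, lat_rows = [], []
    counts = [(HC, config.n_hc), (ACAN, config.n_acan), (RECAN, config.n_recan)]
    deltas = {
        HC: {GM: 0.0, WM: 0.0},
        ACAN: {GM: config.delta_gm_acan, WM: config.delta_wm_acan},
        RECAN: {GM: config.delta_gm_recan, WM: 0.0},
    }
    cov = np.array([[1.0, GM_WM_SUBJECT_CORR], [GM_WM_SUBJECT_CORR, 1.0]])
    cov = cov * config.subject_sd ** 2
    pid = 0
    for group, n in counts:
        params = COVARIATE_PARAMS[group]
        ages = rng.uniform(lo, hi, size=n)
        u = (rng.multivariate_normal([0.0, 0.0], cov, size=n)
             if config.subject_sd > 0 else np.zeros((n, 2)))
        bmi = rng.normal(*params["bmi_sds"], size=n)
        edi = np.maximum(rng.normal(*params["edi2"], size=n), 64.0)
        bdi = np.maximum(rng.normal(*params["bdi2"], size=n), 0.0)
        dur = (_draw_duration(rng, *params["duration"], n)
               if params["duration"] else np.full(n, np.nan))
        ssri = rng.random(n) < params["p_ssri"]
        bp = rng.random(n) < params["p_binge_purge"]
        for i in range(n):
            part = f"P{pid:04d}"
            scan = f"{part}_bl"
            subtype = ("not_applicable" if group == HC
                       else ("binge_purge" if bp[i] else "restricting"))
            rows.append(dict(
                participant_id=part, scan_id=scan, group=group, timepoint=BASELINE,
                age=ages[i], bmi_sds=bmi[i], edi2_total=edi[i], bdi2_total=bdi[i],
                illness_duration=dur[i], ssri=bool(ssri[i]), subtype=subtype,
            ))
            lat_rows.append(dict(scan_id=scan, tissue=GM,
                                 b=ages[i] + deltas[group][GM] + u[i, 0]))
            lat_rows.append(dict(scan_id=scan, tissue=WM,
                                 b=ages[i] + deltas[group][WM] + u[i, 1]))
            pid += 1
    records = pd.DataFrame(rows, columns=PHENOTYPE_COLUMNS)
    latents = pd.DataFrame(lat_rows, columns=["scan_id", "tissue", "b"])
    return records, latents


def simulate_followup(
    records: pd.DataFrame,
    latents: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Add follow-up rows for ``n_followup`` acAN completers.

    Dynamics act on the BrainAGE gap ``b - age``: over the follow-up
    interval the brain ages in step with chronological age, and the
    grey-matter gap additionally changes by ``slope * dBMI-SDS + eps`` with
    the BMI-SDS gain drawn gamma-positive (every completer gains weight, the
    analogue of the >=10% BMI regain criterion). The white-matter gap is
    unchanged. Eating-disorder and depression scores improve independently
    of the gain. Returns the extended ``(records, latents)``.
    """
    config.validate()
    if rng is None:
        rng = config.rng("followup")
    base_acan = records[(records["group"] == ACAN) & (records["timepoint"] == BASELINE)]
    if config.n_followup > len(base_acan):
        raise ConfigurationError(
            f"n_followup ({config.n_followup}) exceeds available acAN baselines ({len(base_acan)})"
        )
    idx = rng.choice(len(base_acan), size=config.n_followup, replace=False)
    completers = base_acan.iloc[np.sort(idx)]

    n = len(completers)
    if config.followup_bmi_gain_sd > 0:
        shape = (config.followup_bmi_gain_mean / config.followup_bmi_gain_sd) ** 2
        scale = config.followup_bmi_gain_sd ** 2 / config.followup_bmi_gain_mean
        gains = rng.gamma(shape, scale, size=n)
    else:
        gains = np.full(n, config.followup_bmi_gain_mean)
    eps = (rng.normal(0.0, config.followup_residual_sd, size=n)
           if config.followup_residual_sd > 0 else np.zeros(n))
    d_edi = rng.normal(*_EDI_CHANGE, size=n)
    d_bdi = rng.normal(*_BDI_CHANGE, size=n)

    lat = latents.set_index(["scan_id", "tissue"])["b"]
    new_rows, new_lat = [], []
    for i, (_, row) in enumerate(completers.iterrows()):
        scan = f"{row['participant_id']}_fu"
        new_rows.append(dict(
            participant_id=row["participant_id"], scan_id=scan, group=ACAN,
            timepoint=FOLLOWUP, age=row["age"] + config.followup_interval_years,
            bmi_sds=row["bmi_sds"] + gains[i],
            edi2_total=max(row["edi2_total"] + d_edi[i], 64.0),
            bdi2_total=max(row["bdi2_total"] + d_bdi[i], 0.0),
            illness_duration=row["illness_duration"], ssri=row["ssri"],
            subtype=row["subtype"],
        ))
        d_gap_gm = config.followup_weightgain_slope * gains[i] + eps[i]
        dt = config.followup_interval_years
        new_lat.append(dict(scan_id=scan, tissue=GM,
                            b=lat[(row["scan_id"], GM)] + dt + d_gap_gm))
        new_lat.append(dict(scan_id=scan, tissue=WM,
                            b=lat[(row["scan_id"], WM)] + dt))
    records_out = pd.concat(
        [records, pd.DataFrame(new_rows, columns=PHENOTYPE_COLUMNS)], ignore_index=True
    )
    latents_out = pd.concat(
        [latents, pd.DataFrame(new_lat, columns=["scan_id", "tissue", "b"])],
        ignore_index=True,
    )
    return records_out, latents_out


def generate_cohort(
    config: CohortConfig, include_followup: bool = True, render: bool = True
) -> tuple[pd.DataFrame, dict[tuple[str, str], VoxelMap], pd.DataFrame]:
    """Full test cohort: phenotype rows, rendered maps and latent table.

    Returns ``(records, maps, latents)`` with ``maps`` keyed by
    ``(scan_id, tissue)``. ``render=False`` skips map rendering (phenotypes
    and latents only).
    """
    records, latents = generate_phenotypes(config)
    if include_followup and config.n_followup > 0:
        records, latents = simulate_followup(records, latents, config)
    maps: dict[tuple[str, str], VoxelMap] = {}
    if render:
        templates = make_templates(config)
        # voxel noise gets its own child stream so that adding/removing scans
        # upstream does not shift the phenotype draws
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([int(config.seed), _STREAMS["cohort"], 7])
        )
        for tissue in TISSUES:
            sub = latents[latents["tissue"] == tissue]
            rendered = render_maps(sub["scan_id"].tolist(), sub["b"].to_numpy(),
                                   templates[tissue], config, noise_rng)
            for sid, vmap in rendered.items():
                maps[(sid, tissue)] = vmap
    return records, maps, latents
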