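"""End-to-end study orchestration (in memory).

``run_study`` executes the full analysis on a synthetic cohort: generate ->
preprocess -> train -> predict -> bias-correct -> model fitting, and returns
every intermediate table. File-based orchestration wraps this in
:mod:`anbrainage.cli_io`.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields, replace

import pandas as pd

from . import brainage, stats
from .errors import ConfigurationError
from .preprocess import GM, WM, make_mask, preprocess_maps, vectorize
from .rvr import FitSettings, KernelSpec, RVRModel
from .synthetic_cohort import HC, CohortConfig, generate_cohort, generate_training_set

log = logging.getLogger(__name__)

ALL_MODELS = ("CS1", "CS2a", "CS2b", "CS2c", "CS3", "L1", "L2", "L3")
EFFECT_COLUMNS = ["term", "tissue", "model_tag", "beta", "ci_low", "ci_high", "p_value", "note"]


@dataclass
class PreprocessConfig:
    """Smoothing/resampling/masking stage parameters (mm / fraction)."""

    fwhm_mm: float = 8.0
    target_mm: float = 8.0
    mask_threshold: float = 0.05
    fwhm_post_mm: float = 0.0

    def validate(self) -> None:
        if self.fwhm_mm < 0 or self.fwhm_post_mm < 0:
            raise ConfigurationError("smoothing FWHM must be >= 0")
        if self.target_mm <= 0:
            raise ConfigurationError("target resolution must be > 0")
        if not 0 <= self.mask_threshold <= 1:
            raise ConfigurationError("mask_threshold must be in [0, 1]")


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs; serialises to YAML/JSON."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    rvr: FitSettings = field(default_factory=FitSettings)
    kernel: KernelSpec = field(default_factory=KernelSpec)
    models: tuple[str, ...] = ALL_MODELS
    tissues: tuple[str, ...] = (GM, WM)
    seed: int | None = None
    out_dir: str | None = None
    write_maps: bool = False

    def __post_init__(self) -> None:
        self.models = tuple(self.models)
        self.tissues = tuple(self.tissues)
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ConfigurationError(f"unknown model tags: {sorted(unknown)}")
        unknown = set(self.tissues) - {GM, WM}
        if unknown:
            raise ConfigurationError(f"unknown tissues: {sorted(unknown)}")
        self.preprocess.validate()

    @property
    def effective_cohort(self) -> CohortConfig:
        """Cohort config with the pipeline seed applied (when set)."""
        if self.seed is None:
            return self.cohort
        return replace(self.cohort, seed=int(self.seed))

    def to_dict(self) -> dict:
        d = {
            "cohort": self.cohort.to_dict(),
            "preprocess": asdict(self.preprocess),
            "rvr": asdict(self.rvr),
            "kernel": asdict(self.kernel),
            "models": list(self.models),
            "tissues": list(self.tissues),
            "seed": self.seed,
            "out_dir": self.out_dir,
            "write_maps": self.write_maps,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown pipeline config keys: {sorted(unknown)}")
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        for key, klass in (("preprocess", PreprocessConfig), ("rvr", FitSettings),
                           ("kernel", KernelSpec)):
            if key in d and isinstance(d[key], dict):
                sub_known = {f.name for f in fields(klass)}
                sub_unknown = set(d[key]) - sub_known
                if sub_unknown:
                    raise ConfigurationError(
                        f"unknown {key} config keys: {sorted(sub_unknown)}"
                    )
                d[key] = klass(**d[key])
        return cls(**d)


@dataclass
class StudyResult:
    """All artefacts of one end-to-end run."""

    config: PipelineConfig
    records: pd.DataFrame
    results: pd.DataFrame                       # per scan x tissue, corrected
    training_results: pd.DataFrame              # training-set predictions (uncorrected)
    metrics: dict[str, brainage.EvaluationMetrics]
    corrections: dict[str, brainage.BiasCorrection]
    models: dict[str, RVRModel]
    effects: pd.DataFrame
    descriptives: pd.DataFrame


def effects_frame(effects: list[stats.EffectEstimate]) -> pd.DataFrame:
    rows = [dict(term=e.term, tissue=e.tissue, model_tag=e.model_tag, beta=e.beta,
                 ci_low=e.ci_low, ci_high=e.ci_high, p_value=e.p_value, note=e.note)
            for e in effects]
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def run_study(config: PipelineConfig) -> StudyResult:
    """Execute simulate -> preprocess -> train -> predict -> correct -> analyze."""
    cohort_cfg = config.effective_cohort
    pp = config.preprocess
    log.info("generating training set (n=%d) and cohort (seed=%d)",
             cohort_cfg.n_training, cohort_cfg.seed)
    train_ages, train_pairs = generate_training_set(cohort_cfg)
    records, maps, _ = generate_cohort(cohort_cfg)
    hc_ids = records.loc[records["group"] == HC, "scan_id"]

    results_parts, train_parts = [], []
    metrics, corrections, models = {}, {}, {}
    for tissue in config.tissues:
        idx = 0 if tissue == GM else 1
        train_maps = [pair[idx] for pair in train_pairs]
        pp_train = preprocess_maps(train_maps, pp.fwhm_mm, pp.target_mm, pp.fwhm_post_mm)
        mask = make_mask(pp_train, pp.mask_threshold)
        feats_train = vectorize(pp_train, mask)
        model = brainage.train_brain_age_model(
            feats_train, train_ages, tissue=tissue,
            kernel=config.kernel, settings=config.rvr,
        )
        models[tissue] = model
        tr_res = brainage.score_scans(model, feats_train, train_ages)
        metrics[tissue] = brainage.evaluate_model(tr_res)
        train_parts.append(tr_res)

        cohort_maps = [maps[(sid, tissue)] for sid in records["scan_id"]]
        pp_cohort = preprocess_maps(cohort_maps, pp.fwhm_mm, pp.target_mm, pp.fwhm_post_mm)
        feats = vectorize(pp_cohort, mask)
        res = brainage.score_scans(model, feats, records["age"].to_numpy())
        corr = brainage.fit_bias_correction(res, hc_ids)
        corrections[tissue] = corr
        results_parts.append(brainage.apply_bias_correction(res, corr))

    results = pd.concat(results_parts, ignore_index=True)
    training_results = pd.concat(train_parts, ignore_index=True)

    has_followup = (records["timepoint"] == "followup").any()
    all_effects: list[stats.EffectEstimate] = []
    for tissue in config.tissues:
        spec = stats.AnalysisSpec(outcome=f"BrainAGE_{tissue}")
        for tag in config.models:
            if tag in stats.CS_MODELS:
                all_effects += stats.cross_sectional_model(records, results, spec, model=tag)
            elif tag == "CS3":
                all_effects += stats.clinical_association_model(records, results, spec)
            elif tag in ("L1", "L2"):
                if not has_followup:
                    log.info("no follow-up scans; skipping %s (%s)", tag, tissue)
                    continue
                all_effects += stats.longitudinal_model(records, results, spec, model=tag)
            elif tag == "L3":
                if not has_followup:
                    log.info("no follow-up scans; skipping L3 (%s)", tissue)
                    continue
                all_effects += stats.change_predictor_model(records, results, spec)

    return StudyResult(
        config=config,
        records=records,
        results=results,
        training_results=training_results,
        metrics=metrics,
        corrections=corrections,
        models=models,
        effects=effects_frame(all_effects),
        descriptives=stats.descriptives(records, results),
    )
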