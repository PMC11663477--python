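"""Cross-sectional and longitudinal inference on BrainAGE scores.

Cross-sectional models are ordinary least squares on bias-corrected BrainAGE
with dummy-coded group (healthy controls as reference):

* CS1  : score ~ group
* CS2a : + centred age and age x group (differential age trends)
* CS2b : + SSRI use
* CS2c : + anorexia subtype (binge/purge vs restricting)
* CS3  : clinical associations within acute patients (BMI-SDS, EDI-2,
         BDI-II, illness duration z-scored so betas are per SD, plus age)

Longitudinal models use a participant random intercept (REML):

* L1 : score ~ timepoint (+ group when controls are included); the timepoint
       coefficient is the mean within-person BrainAGE change
* L2 : L1 on completers, covarying for baseline clinical measures
* L3 : change-score regression - dBrainAGE on dBMI-SDS, dEDI-2, dBDI-II and
       baseline illness duration

Confidence intervals are Wald t-based at 95%. The multiple-testing threshold
is a single global Bonferroni alpha over outcomes x model families.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import linalg as sla
from scipy import stats as sps

from .errors import CollinearityError, InsufficientDataError
from .preprocess import GM, WM
from .synthetic_cohort import ACAN, BASELINE, FOLLOWUP, HC, RECAN

log = logging.getLogger(__name__)

CS_MODELS = ("CS1", "CS2a", "CS2b", "CS2c")
CLINICAL_COVARIATES = ["bmi_sds", "edi2_total", "bdi2_total", "illness_duration"]


@dataclass
class EffectEstimate:
    """One model coefficient with its 95% CI and p-value."""

    term: str
    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    model_tag: str
    tissue: str
    note: str = ""


@dataclass
class AnalysisSpec:
    """Which outcome/covariates/reference a model family uses."""

    outcome: str = "BrainAGE_GM"
    covariates: list[str] = field(default_factory=list)
    reference_group: str = HC
    alpha: float = 0.05

    @property
    def tissue(self) -> str:
        return WM if self.outcome.endswith("WM") else GM


@dataclass
class CrossSectionalFit:
    """A fitted cross-sectional model plus the metadata contrasts need."""

    fit: object
    reference: str
    levels: list[str]
    tissue: str
    model_tag: str


def merge_scores(records: pd.DataFrame, results: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Join phenotype rows with the corrected scores of one tissue."""
    sub = results[results["tissue"] == tissue][
        ["scan_id", "predicted_age", "brainage_raw", "brainage_corrected"]
    ]
    return records.merge(sub, on="scan_id", how="inner")


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardise to mean 0, SD 1 (population SD)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise CollinearityError(["zero-variance covariate"])
    return (x - x.mean()) / sd


def _check_rank(exog: np.ndarray, names: list[str]) -> None:
    exog = np.asarray(exog, dtype=float)
    rank = np.linalg.matrix_rank(exog)
    if rank >= exog.shape[1]:
        return
    _, R, piv = sla.qr(exog, mode="economic", pivoting=True)
    bad = sorted(names[piv[i]] for i in range(rank, exog.shape[1]))
    raise CollinearityError(bad)


def _pretty_terms(names: list[str], reference: str) -> list[str]:
    import re

    out = []
    for name in names:
        s = name
        s = re.sub(r"C\(group.*?\[T\.([^\]]+)\]", rf"\1_vs_{reference}", s)
        s = re.sub(r"C\(timepoint.*?\[T\.([^\]]+)\]", r"\1_vs_baseline", s)
        s = s.replace("[T.True]", "").replace("Intercept", "intercept")
        out.append(s)
    return out


def _effects_from_fit(fit, model_tag: str, tissue: str, reference: str = HC,
                      skip_intercept: bool = True) -> list[EffectEstimate]:
    names = list(fit.params.index)
    pretty = _pretty_terms(names, reference)
    ci = fit.conf_int(alpha=0.05)
    effects = []
    for raw, term in zip(names, pretty):
        if skip_intercept and term == "intercept":
            continue
        if raw == "Group Var":
            continue
        effects.append(EffectEstimate(
            term=term, beta=float(fit.params[raw]),
            ci_low=float(ci.loc[raw, 0]), ci_high=float(ci.loc[raw, 1]),
            p_value=float(fit.pvalues[raw]), model_tag=model_tag, tissue=tissue,
        ))
    return effects


def cross_sectional_model(
    records: pd.DataFrame,
    results: pd.DataFrame,
    spec: AnalysisSpec | None = None,
    model: str = "CS1",
    return_fit: bool = False,
):
    """OLS group-difference models on the baseline cross-section.

    Uses one scan per participant (baseline rows); HC is the reference group
    unless the spec says otherwise.
    """
    spec = spec or AnalysisSpec()
    if model not in CS_MODELS:
        raise ValueError(f"unknown cross-sectional model {model!r}; choose from {CS_MODELS}")
    df = merge_scores(records, results, spec.tissue)
    df = df[df["timepoint"] == BASELINE].copy()
    if df.empty:
        raise InsufficientDataError("no baseline scans to model")
    df["age_c"] = df["age"] - df["age"].mean()
    df["ssri_flag"] = df["ssri"].astype(int)
    df["binge_purge"] = (df["subtype"] == "binge_purge").astype(int)
    ref = spec.reference_group
    group_term = f"C(group, Treatment('{ref}'))"
    formula = f"brainage_corrected ~ {group_term}"
    if model == "CS2a":
        formula += f" + age_c + age_c:{group_term}"
    elif model == "CS2b":
        formula += " + ssri_flag"
    elif model == "CS2c":
        formula += " + binge_purge"
    ols = smf.ols(formula, data=df)
    _check_rank(ols.exog, list(ols.exog_names))
    fit = ols.fit()
    effects = _effects_from_fit(fit, model, spec.tissue, reference=ref)
    if return_fit:
        levels = sorted(df["group"].unique())
        return effects, CrossSectionalFit(fit=fit, reference=ref, levels=levels,
                                          tissue=spec.tissue, model_tag=model)
    return effects


def clinical_association_model(
    records: pd.DataFrame,
    results: pd.DataFrame,
    spec: AnalysisSpec | None = None,
    standardize: bool = True,
) -> list[EffectEstimate]:
    """CS3: clinical correlates of BrainAGE within acute patients at baseline.

    Clinical covariates are z-scored (betas per SD) unless ``standardize``
    is False; age enters in raw years. Rows with missing covariates are
    dropped listwise (count logged).
    """
    spec = spec or AnalysisSpec()
    covs = spec.covariates or CLINICAL_COVARIATES
    df = merge_scores(records, results, spec.tissue)
    df = df[(df["group"] == ACAN) & (df["timepoint"] == BASELINE)].copy()
    n0 = len(df)
    df = df.dropna(subset=covs + ["age", "brainage_corrected"])
    if n0 - len(df):
        log.info("CS3: dropped %d of %d rows with missing covariates", n0 - len(df), n0)
    if len(df) < len(covs) + 3:
        raise InsufficientDataError(f"CS3 needs more than {len(covs) + 2} rows, got {len(df)}")
    terms = []
    for c in covs:
        if standardize:
            df[f"z_{c}"] = zscore(df[c].to_numpy())
            terms.append(f"z_{c}")
        else:
            terms.append(c)
    formula = "brainage_corrected ~ " + " + ".join(terms + ["age"])
    ols = smf.ols(formula, data=df)
    _check_rank(ols.exog, list(ols.exog_names))
    fit = ols.fit()
    return _effects_from_fit(fit, "CS3", spec.tissue)


def _completer_frame(records: pd.DataFrame, results: pd.DataFrame, tissue: str) -> pd.DataFrame:
    df = merge_scores(records, results, tissue)
    counts = df.groupby("participant_id")["timepoint"].nunique()
    completers = counts[counts == 2].index
    return df[df["participant_id"].isin(completers)].copy()


def change_scores(records: pd.DataFrame, results: pd.DataFrame, tissue: str) -> pd.DataFrame:
    """Per-completer follow-up minus baseline differences plus baseline covariates."""
    df = _completer_frame(records, results, tissue)
    if df.empty:
        raise InsufficientDataError("no completers with both timepoints")
    base = df[df["timepoint"] == BASELINE].set_index("participant_id")
    fu = df[df["timepoint"] == FOLLOWUP].set_index("participant_id")
    idx = base.index.intersection(fu.index)
    out = pd.DataFrame(index=idx)
    for col in ["brainage_corrected", "bmi_sds", "edi2_total", "bdi2_total"]:
        out[f"d_{col}"] = fu.loc[idx, col] - base.loc[idx, col]
    out["illness_duration"] = base.loc[idx, "illness_duration"]
    out["baseline_age"] = base.loc[idx, "age"]
    return out.reset_index()


def longitudinal_model(
    records: pd.DataFrame,
    results: pd.DataFrame,
    spec: AnalysisSpec | None = None,
    model: str = "L1",
    include_hc: bool = True,
) -> list[EffectEstimate]:
    """Random-intercept mixed model of BrainAGE change (REML).

    L1 models completers' two timepoints (plus HC reference scans when
    ``include_hc``); the timepoint coefficient is the mean within-person
    change. L2 restricts to completers and covaries for baseline clinical
    measures. A singular or non-convergent fit falls back to OLS on change
    scores with a logged notice (the balanced-design estimate is identical).
    """
    spec = spec or AnalysisSpec()
    if model not in ("L1", "L2"):
        raise ValueError(f"unknown longitudinal model {model!r}")
    tissue = spec.tissue
    df = _completer_frame(records, results, tissue)
    if df.empty:
        raise InsufficientDataError("no completers with both timepoints")
    terms = [f"C(timepoint, Treatment('{BASELINE}'))"]
    if model == "L1" and include_hc:
        hc = merge_scores(records, results, tissue)
        hc = hc[(hc["group"] == HC) & (hc["timepoint"] == BASELINE)]
        df = pd.concat([df, hc], ignore_index=True)
        if df["group"].nunique() > 1:
            terms.append(f"C(group, Treatment('{HC}'))")
    if model == "L2":
        base_cov = df[df["timepoint"] == BASELINE].set_index("participant_id")
        for c in CLINICAL_COVARIATES:
            df[f"bl_{c}"] = df["participant_id"].map(base_cov[c])
            terms.append(f"bl_{c}")
        df = df.dropna(subset=[f"bl_{c}" for c in CLINICAL_COVARIATES])
    formula = "brainage_corrected ~ " + " + ".join(terms)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mm = smf.mixedlm(formula, data=df, groups=df["participant_id"])
            fit = mm.fit(reml=True)
        if not np.all(np.isfinite(fit.params.to_numpy(dtype=float))):
            raise RuntimeError("non-finite mixed-model estimates")
        return _effects_from_fit(fit, model, tissue)
    except Exception as exc:  # singular variance / convergence failure
        log.warning("mixed model failed (%s); falling back to change-score OLS", exc)
        ch = change_scores(records, results, tissue)
        fit = smf.ols("d_brainage_corrected ~ 1", data=ch).fit()
        ci = fit.conf_int(alpha=0.05)
        return [EffectEstimate(
            term="followup_vs_baseline", beta=float(fit.params["Intercept"]),
            ci_low=float(ci.loc["Intercept", 0]), ci_high=float(ci.loc["Intercept", 1]),
            p_value=float(fit.pvalues["Intercept"]), model_tag=model, tissue=tissue,
            note="change-score OLS fallback",
        )]


def change_predictor_model(
    records: pd.DataFrame,
    results: pd.DataFrame,
    spec: AnalysisSpec | None = None,
) -> list[EffectEstimate]:
    """L3: regression of BrainAGE change on clinical change over recovery.

    dBrainAGE ~ dBMI-SDS + dEDI-2 + dBDI-II + baseline illness duration,
    with dBMI-SDS in raw units (years of BrainAGE per BMI-SDS unit).
    """
    spec = spec or AnalysisSpec()
    ch = change_scores(records, results, spec.tissue)
    formula = "d_brainage_corrected ~ d_bmi_sds + d_edi2_total + d_bdi2_total + illness_duration"
    ch = ch.dropna(subset=["d_bmi_sds", "d_edi2_total", "d_bdi2_total", "illness_duration"])
    if len(ch) < 6:
        raise InsufficientDataError(f"L3 needs at least 6 complete change rows, got {len(ch)}")
    ols = smf.ols(formula, data=ch)
    _check_rank(ols.exog, list(ols.exog_names))
    fit = ols.fit()
    return _effects_from_fit(fit, "L3", spec.tissue)


def pairwise_contrasts(csfit: CrossSectionalFit, pairs) -> list[EffectEstimate]:
    """Group contrasts (e.g. acAN-HC) from a fitted cross-sectional model."""
    fit = csfit.fit
    names = list(fit.params.index)

    def coef_vector(group: str) -> np.ndarray:
        if group not in csfit.levels:
            raise ValueError(f"unknown group label {group!r}; known: {csfit.levels}")
        v = np.zeros(len(names))
        if group == csfit.reference:
            return v
        key = f"[T.{group}]"
        hits = [i for i, n in enumerate(names) if key in n and ":" not in n]
        if not hits:
            raise ValueError(f"no coefficient for group {group!r} in model")
        v[hits[0]] = 1.0
        return v

    effects = []
    for g1, g2 in pairs:
        term = f"{g1}_vs_{g2}"
        if g1 == g2:
            coef_vector(g1)  # still validates the label
            effects.append(EffectEstimate(term=term, beta=0.0, ci_low=0.0, ci_high=0.0,
                                          p_value=np.nan, model_tag=csfit.model_tag,
                                          tissue=csfit.tissue, note="degenerate contrast"))
            continue
        c = coef_vector(g1) - coef_vector(g2)
        tt = fit.t_test(c)
        ci = tt.conf_int(alpha=0.05)
        effects.append(EffectEstimate(
            term=term, beta=float(np.atleast_1d(tt.effect)[0]),
            ci_low=float(ci[0, 0]), ci_high=float(ci[0, 1]),
            p_value=float(np.atleast_1d(tt.pvalue)[0]),
            model_tag=csfit.model_tag, tissue=csfit.tissue,
        ))
    return effects


def adjust_alpha(n_outcomes: int, n_models: int, family_alpha: float = 0.05) -> float:
    """Bonferroni threshold over outcomes x model families (0.05/6 = 0.0083)."""
    if n_outcomes < 1 or n_models < 1:
        raise ValueError("n_outcomes and n_models must be >= 1")
    return family_alpha / (n_outcomes * n_models)


def format_alpha(alpha: float) -> str:
    """Four-decimal display convention used in summaries."""
    return f"{alpha:.4f}"


def descriptives(records: pd.DataFrame, results: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean +/- SD table with group-comparison p-values.

    Cross-sectional p-values come from OLS across baseline groups;
    the longitudinal p-value compares completers' two timepoints via the
    mixed model (falling back to a paired t-test on change scores).
    """
    measures = ["age", "bmi_sds", "edi2_total", "bdi2_total"]
    df = records.copy()
    for tissue, col in ((GM, "brainage_gm"), (WM, "brainage_wm")):
        sub = results[results["tissue"] == tissue][["scan_id", "brainage_corrected"]]
        sub = sub.rename(columns={"brainage_corrected": col})
        df = df.merge(sub, on="scan_id", how="left")
        if df[col].notna().any():
            measures.append(col)

    def cell(group: str, timepoint: str) -> pd.DataFrame | None:
        sub = df[(df["group"] == group) & (df["timepoint"] == timepoint)]
        return sub if len(sub) else None

    cells = {"HC": cell(HC, BASELINE), "acAN_baseline": cell(ACAN, BASELINE),
             "acAN_followup": cell(ACAN, FOLLOWUP), "recAN": cell(RECAN, BASELINE)}
    cells = {k: v for k, v in cells.items() if v is not None}

    rows = []
    baseline = df[df["timepoint"] == BASELINE]
    multi_group = baseline["group"].nunique() > 1
    counts = df.groupby("participant_id")["timepoint"].nunique()
    completers = counts[counts == 2].index
    for m in measures:
        row = {}
        for label, sub in cells.items():
            row[f"{label}_mean"] = float(sub[m].mean())
            row[f"{label}_sd"] = float(sub[m].std(ddof=1)) if len(sub) > 1 else 0.0
        if multi_group:
            sub = baseline.dropna(subset=[m])
            if sub["group"].nunique() > 1 and sub[m].std() > 0:
                fit = smf.ols(f"{m} ~ C(group)", data=sub).fit()
                row["p_cross_sectional"] = float(fit.f_pvalue)
            else:
                row["p_cross_sectional"] = np.nan
        if len(completers):
            comp = df[df["participant_id"].isin(completers)].dropna(subset=[m])
            base = comp[comp["timepoint"] == BASELINE].set_index("participant_id")[m]
            fu = comp[comp["timepoint"] == FOLLOWUP].set_index("participant_id")[m]
            idx = base.index.intersection(fu.index)
            if len(idx) > 2 and (fu.loc[idx] - base.loc[idx]).std() > 0:
                row["p_longitudinal"] = float(sps.ttest_rel(fu.loc[idx], base.loc[idx]).pvalue)
        rows.append(pd.Series(row, name=m))
    return pd.DataFrame(rows)
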