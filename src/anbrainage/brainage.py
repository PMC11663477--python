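"""Brain-age model training, BrainAGE scoring, and age-bias correction.

A tissue-specific relevance vector regression is trained on healthy subjects
only (chronological age as target, masked voxel intensities as features).
For a test scan, BrainAGE = predicted age - chronological age: positive
values indicate an "older"-appearing brain.

Because kernel age models over-predict young and under-predict old subjects,
raw scores carry a linear age trend. The trend is estimated by ordinary
least squares *on control scans only* and subtracted from every scan
(patients and controls alike), which zeroes the control-group trend exactly
while leaving group offsets intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateFitError, InsufficientDataError
from .preprocess import FeatureMatrix
from .rvr import (FitSettings, KernelSpec, RVRModel, design_matrix, fit_rvr,
                  linear_kernel, predict_rvr)

RESULT_COLUMNS = ["scan_id", "tissue", "age", "predicted_age",
                  "brainage_raw", "brainage_corrected"]


@dataclass
class BiasCorrection:
    """Linear age trend of raw BrainAGE fitted on control scans only."""

    slope: float
    intercept: float
    n_controls: int
    tissue: str

    def trend(self, age) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(age, dtype=float)


@dataclass
class EvaluationMetrics:
    """Accuracy of the age model: MAE (with SD of absolute errors) and Pearson r."""

    mae: float
    mae_sd: float
    pearson_r_age: float
    n: int


def train_brain_age_model(
    features: FeatureMatrix,
    ages: np.ndarray,
    tissue: str | None = None,
    kernel: KernelSpec | None = None,
    settings: FitSettings | None = None,
) -> RVRModel:
    """Train a linear-kernel RVR mapping masked voxel features to age.

    Features are centred by their training means (stored on the model and
    re-applied at prediction); the kernel scale defaults to the feature count
    so kernel entries stay O(intensity^2) regardless of grid size.
    """
    X = np.asarray(features.values, dtype=float)
    ages = np.asarray(ages, dtype=float).ravel()
    if X.shape[0] != ages.shape[0]:
        raise ValueError(f"{X.shape[0]} feature rows but {ages.shape[0]} ages")
    kernel = kernel or KernelSpec(scale=X.shape[1])
    means = X.mean(axis=0)
    Xc = X - means
    K = linear_kernel(Xc, Xc, kernel)
    Phi = design_matrix(K, include_bias=kernel.include_bias)
    model = fit_rvr(Phi, ages, settings)
    model.kernel = kernel
    model.training_feature_means = means
    offset = 1 if kernel.include_bias else 0
    sample_idx = np.asarray([a - offset for a in model.active if a >= offset], dtype=int)
    model.relevance_indices = sample_idx
    model.relevance_vectors = Xc[sample_idx]
    model.tissue = tissue or features.tissue
    return model


def test_design(model: RVRModel, features: FeatureMatrix) -> np.ndarray:
    """Design matrix for new scans against the model's retained bases."""
    Xc = np.asarray(features.values, dtype=float) - model.training_feature_means
    cols = []
    if model.has_bias:
        cols.append(np.ones((Xc.shape[0], 1)))
    if model.relevance_vectors is not None and len(model.relevance_vectors):
        cols.append(linear_kernel(Xc, model.relevance_vectors, model.kernel))
    if not cols:
        # fully pruned (constant-target) model: prediction is the target mean
        return np.zeros((Xc.shape[0], 0))
    return np.hstack(cols)


def predict_ages(model: RVRModel, features: FeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance of brain age for each scan."""
    return predict_rvr(model, test_design(model, features))


def compute_brainage(predicted: float | np.ndarray, chronological: float | np.ndarray):
    """BrainAGE = predicted - chronological age (positive = advanced ageing)."""
    predicted = np.asarray(predicted, dtype=float)
    chronological = np.asarray(chronological, dtype=float)
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(chronological))):
        raise ValueError("predicted and chronological ages must be finite")
    out = predicted - chronological
    return float(out) if out.ndim == 0 else out


def score_scans(model: RVRModel, features: FeatureMatrix, ages: np.ndarray) -> pd.DataFrame:
    """Predict each scan and assemble the per-scan results table (raw scores)."""
    pred, _ = predict_ages(model, features)
    ages = np.asarray(ages, dtype=float).ravel()
    return pd.DataFrame({
        "scan_id": features.scan_ids,
        "tissue": model.tissue or features.tissue,
        "age": ages,
        "predicted_age": pred,
        "brainage_raw": compute_brainage(pred, ages),
        "brainage_corrected": np.nan,
    }, columns=RESULT_COLUMNS)


def fit_bias_correction(results: pd.DataFrame, control_ids) -> BiasCorrection:
    """OLS of raw BrainAGE on chronological age over control scans only."""
    control_ids = set(control_ids)
    ctrl = results[results["scan_id"].isin(control_ids)]
    if len(ctrl) < 3:
        raise InsufficientDataError(
            f"bias correction needs >= 3 control scans, got {len(ctrl)}"
        )
    age = ctrl["age"].to_numpy(dtype=float)
    raw = ctrl["brainage_raw"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise DegenerateFitError("control ages have zero variance")
    slope, intercept = np.polyfit(age, raw, 1)
    tissues = ctrl["tissue"].unique()
    tissue = tissues[0] if len(tissues) == 1 else "mixed"
    return BiasCorrection(slope=float(slope), intercept=float(intercept),
                          n_controls=len(ctrl), tissue=tissue)


def apply_bias_correction(results: pd.DataFrame, correction: BiasCorrection) -> pd.DataFrame:
    """Subtract the control age trend from every scan's raw score."""
    out = results.copy()
    out["brainage_corrected"] = (
        out["brainage_raw"].to_numpy(dtype=float) - correction.trend(out["age"])
    )
    return out


def evaluate_model(results: pd.DataFrame, scan_ids=None) -> EvaluationMetrics:
    """MAE (+SD of absolute errors, sample formula) and Pearson r of predictions."""
    sub = results if scan_ids is None else results[results["scan_id"].isin(set(scan_ids))]
    if len(sub) == 0:
        raise InsufficientDataError("cannot evaluate an empty scan subset")
    err = np.abs(sub["predicted_age"].to_numpy(dtype=float) - sub["age"].to_numpy(dtype=float))
    mae_sd = float(np.std(err, ddof=1)) if len(err) > 1 else 0.0
    if len(sub) > 1 and np.ptp(sub["age"].to_numpy()) > 0 and np.ptp(sub["predicted_age"].to_numpy()) > 0:
        r = float(np.corrcoef(sub["predicted_age"], sub["age"])[0, 1])
    else:
        r = np.nan
    return EvaluationMetrics(mae=float(err.mean()), mae_sd=mae_sd,
                             pearson_r_age=r, n=len(sub))
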