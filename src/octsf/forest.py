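"""Random-forest prediction of visual-field sensitivity with LOPO folds.

A forest of 500 trees (squared-error criterion, bootstrap capped at
10,474 samples or the training-fold size, whichever is smaller) predicts
per-locus sensitivity from nine features: EZ-loss fraction, TRT, ORT,
TR/OR mean intensity, TR/OR minimum intensity and the (x, y) locus
coordinates relative to the fovea.  Cross-validation is
leave-one-patient-out: both eyes of the held-out patient are removed
from every training fold, so no within-patient correlation leaks into
the evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import LeaveOneGroupOut

from .scaffold import FEATURE_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelParams:
    """Forest hyperparameters; anything unlisted uses sklearn defaults."""

    n_estimators: int = 500
    max_bootstrap_samples: int = 10474
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_bootstrap_samples < 1:
            raise ValueError("n_estimators and max_bootstrap_samples must be >= 1")


@dataclass
class PredictionResult:
    """LOPO predictions with per-fold impurity importances."""

    predictions: pd.DataFrame  # patient_id, eye_id, locus_id, y_true, y_pred, fold
    importances: np.ndarray  # (n_folds, n_features)
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))


def build_feature_matrix(
    features: pd.DataFrame,
    exclude_groups: tuple[str, ...] = ("4",),
    exclude_eyes: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, pd.DataFrame]:
    """Assemble (X, y, groups, meta) from the pooled locus feature table.

    Group-4 eyes are excluded by default (their poor fixation invalidates
    point-to-point registration), as are invalid loci and rows with any
    missing feature (the dropped count is logged).  ``groups`` carries the
    patient id of every row for LOPO fold construction.
    """
    df = features[features["valid"]].copy()
    df = df[~df["severity_group"].isin(exclude_groups)]
    df = df[~df["eye_id"].isin(exclude_eyes)]
    n_before = len(df)
    df = df.dropna(subset=[*FEATURE_COLUMNS, "sensitivity_db"])
    dropped = n_before - len(df)
    if dropped:
        logger.info("dropped %d rows with missing features", dropped)
    X = df[FEATURE_COLUMNS].reset_index(drop=True)
    y = df["sensitivity_db"].to_numpy(float)
    groups = df["patient_id"].to_numpy()
    meta = df[["patient_id", "eye_id", "locus_id", "severity_group"]].reset_index(
        drop=True
    )
    return X, y, groups, meta


def train_predict_lopo(
    X: pd.DataFrame,
    y: np.ndarray,
    groups: np.ndarray,
    params: ModelParams | None = None,
    meta: pd.DataFrame | None = None,
) -> PredictionResult:
    """Leave-one-patient-out training and prediction.

    One forest per patient, trained on every other patient's rows;
    reproducible from ``params.seed`` (fold-wise sub-seeds are spawned
    deterministically).  Feature order follows ``FEATURE_COLUMNS``; a
    permuted input is re-ordered by name.
    """
    params = params or ModelParams()
    if len(set(np.asarray(groups))) < 2:
        raise ValueError("LOPO cross-validation needs at least two patients")
    feature_names = [c for c in FEATURE_COLUMNS if c in X.columns]
    if len(feature_names) != X.shape[1]:
        feature_names = list(X.columns)  # custom feature sets pass through
    Xv = X[feature_names].to_numpy(float)
    y = np.asarray(y, dtype=float)

    logo = LeaveOneGroupOut()
    n_folds = logo.get_n_splits(groups=groups)
    fold_seeds = np.random.SeedSequence(params.seed).generate_state(n_folds)

    pred_frames = []
    importances = np.empty((n_folds, Xv.shape[1]))
    for fold, (train_idx, test_idx) in enumerate(logo.split(Xv, y, groups)):
        max_samples = min(params.max_bootstrap_samples, len(train_idx))
        model = RandomForestRegressor(
            n_estimators=params.n_estimators,
            criterion="squared_error",
            bootstrap=True,
            max_samples=max_samples,
            random_state=int(fold_seeds[fold] % (2**31)),
            n_jobs=1,
        )
        model.fit(Xv[train_idx], y[train_idx])
        y_pred = model.predict(Xv[test_idx])
        imp = model.feature_importances_
        importances[fold] = imp / imp.sum() if imp.sum() > 0 else imp
        frame = pd.DataFrame(
            {
                "patient_id": np.asarray(groups)[test_idx],
                "y_true": y[test_idx],
                "y_pred": y_pred,
                "fold": fold,
            }
        )
        if meta is not None:
            frame["eye_id"] = meta["eye_id"].to_numpy()[test_idx]
            frame["locus_id"] = meta["locus_id"].to_numpy()[test_idx]
        pred_frames.append(frame)
    return PredictionResult(
        predictions=pd.concat(pred_frames, ignore_index=True),
        importances=importances,
        feature_names=feature_names,
    )


def summarize_errors(result: PredictionResult) -> dict[str, float]:
    """Error summary over all pooled held-out predictions.

    MAE and the SD of absolute errors, RMSE, pooled R-squared, mean
    signed error, the 95% interval for a single-locus prediction error
    (mean +/- 1.96 RMSE), and - when eye ids are available - the MAE of
    per-eye mean sensitivity.
    """
    df = result.predictions
    if df.empty:
        raise ValueError("no predictions to summarize")
    err = df["y_pred"].to_numpy() - df["y_true"].to_numpy()
    abs_err = np.abs(err)
    sst = float(np.sum((df["y_true"] - df["y_true"].mean()) ** 2))
    rmse = float(np.sqrt(np.mean(err**2)))
    out = {
        "mae_db": float(abs_err.mean()),
        "sd_abs_err_db": float(abs_err.std(ddof=1)) if len(err) > 1 else 0.0,
        "rmse_db": rmse,
        "r_squared": 1.0 - float(np.sum(err**2)) / sst if sst > 0 else np.nan,
        "mean_signed_err_db": float(err.mean()),
        "n_predictions": int(len(err)),
    }
    out["ci95_single_locus_db"] = (
        out["mean_signed_err_db"] - 1.96 * rmse,
        out["mean_signed_err_db"] + 1.96 * rmse,
    )
    if "eye_id" in df.columns:
        per_eye = df.groupby("eye_id")[["y_true", "y_pred"]].mean()
        out["per_eye_mean_sensitivity_mae_db"] = float(
            (per_eye["y_pred"] - per_eye["y_true"]).abs().mean()
        )
    return out


def aggregate_importance(result: PredictionResult) -> np.ndarray:
    """Unweighted mean of per-fold importance vectors, renormalised to 1."""
    mean_imp = result.importances.mean(axis=0)
    total = mean_imp.sum()
    return mean_imp / total if total > 0 else mean_imp


def fit_mild_subset(
    features: pd.DataFrame,
    params: ModelParams | None = None,
    keep_groups: tuple[str, ...] = ("unaffected", "1"),
) -> tuple[PredictionResult, np.ndarray]:
    """LOPO restricted to unaffected and mildly affected eyes.

    Returns the prediction result and its aggregated importance vector,
    for side-by-side comparison with the full-cohort importances.
    """
    subset = features[features["severity_group"].isin(keep_groups)]
    if subset.empty:
        raise ValueError("mild subset is empty")
    X, y, groups, meta = build_feature_matrix(subset, exclude_groups=())
    result = train_predict_lopo(X, y, groups, params=params, meta=meta)
    return result, aggregate_importance(result)
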