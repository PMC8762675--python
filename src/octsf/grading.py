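"""Toxicity grading rules, locus-wise z-scores, and univariate regressions.

Implements the screening-derived classification rules (visual-field
abnormality, mfERG evidence, OCT severity groups 1-4), the modified
z-score against the unaffected reference cohort, severity-group mean
z-maps, and ring-grouped ordinary-least-squares structure-function fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .scaffold import HvfGrid
from .simulate import MfergNormative
from .types import MfergRings

#: Metrics that get locus-wise z-scores and group mean maps.  EZ fraction
#: is excluded: unaffected eyes carry no EZ loss, so its reference SD is
#: zero and the z-score is undefined.
ZSCORE_METRICS = [
    "sensitivity_db",
    "trt_um",
    "ort_um",
    "tr_meani",
    "or_meani",
    "tr_mini",
    "or_mini",
]

#: The seven OCT metrics entering the univariate ring analysis.
UNIVARIATE_METRICS = [
    "ez_frac",
    "trt_um",
    "ort_um",
    "tr_meani",
    "or_meani",
    "tr_mini",
    "or_mini",
]


class SeverityClassificationError(ValueError):
    """EZ morphometry contradicts the grading scheme."""


def assign_severity_group(
    foveal_ez_extent_um: float,
    preserved_island_um: float = np.inf,
    foveal_involved: bool = False,
) -> str:
    """Severity group from foveal-B-scan EZ morphometry.

    Group 1: extent <= 100 um; group 2: 100 < extent <= 1000 um; group 3:
    extent > 1000 um with a preserved central island > 500 um; group 4:
    foveal involvement.  An extent of exactly zero maps to "unaffected".
    Extent > 1000 um with island <= 500 um but no foveal involvement
    contradicts the scheme and raises rather than guessing.
    """
    if foveal_ez_extent_um < 0 or preserved_island_um < 0:
        raise ValueError("extents must be >= 0")
    if foveal_involved:
        return "4"
    if foveal_ez_extent_um == 0:
        return "unaffected"
    if foveal_ez_extent_um <= 100:
        return "1"
    if foveal_ez_extent_um <= 1000:
        return "2"
    if preserved_island_um > 500:
        return "3"
    raise SeverityClassificationError(
        f"EZ extent {foveal_ez_extent_um:.0f} um with island "
        f"{preserved_island_um:.0f} um and no foveal involvement does not "
        "fit any severity group"
    )


def classify_vf_abnormal(
    flags: np.ndarray, grid: HvfGrid, connectivity: int = 4
) -> bool:
    """Visual-field abnormality rule.

    True iff at least three contiguous loci are flagged on the pattern-
    deviation map or some ring is abnormal in its entirety (full ring
    scotoma).  Contiguity is 4-connectivity on the 2-degree locus lattice
    by default (8-connectivity available).
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != (grid.n_loci,):
        raise ValueError(f"expected {grid.n_loci} flags, got {flags.shape}")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")

    # raster the 2-degree lattice: odd coordinates -9..9 -> 10x10 grid
    rows = ((9 - grid.y_deg) / 2).astype(int)
    cols = ((grid.x_deg + 9) / 2).astype(int)
    raster = np.zeros((10, 10), dtype=bool)
    raster[rows, cols] = flags
    structure = (
        ndimage.generate_binary_structure(2, 1)
        if connectivity == 4
        else ndimage.generate_binary_structure(2, 2)
    )
    labelled, n = ndimage.label(raster, structure=structure)
    if n and np.max(np.bincount(labelled.ravel())[1:]) >= 3:
        return True
    for ring in np.unique(grid.ring):
        if flags[grid.ring == ring].all():
            return True
    return False


def classify_mferg(rings: MfergRings, normative: MfergNormative | None = None) -> bool:
    """mfERG evidence of toxicity.

    True iff the R1/R2 ring ratio exceeds the normative upper limit or the
    absolute R1 amplitude falls below the normative lower limit.
    """
    if normative is None:
        raise ValueError("normative limits are required")
    r1 = rings.amplitudes[0]
    ratio = rings.ratios[0]
    return bool(ratio > normative.r1_r2_upper_limit or r1 < normative.r1_lower_limit)


def classify_patient_toxicity(
    vf_abnormal: dict[str, bool],
    mferg_positive: dict[str, bool],
    oct_evidence: dict[str, bool],
) -> dict[str, str]:
    """Per-eye toxicity status for one patient.

    An eye is toxic when the visual field is abnormal AND at least one
    objective modality (mfERG or OCT) corroborates it.  The fellow eye of
    a toxic patient that is mfERG-positive without meeting the VF rule is
    labelled mild toxicity; all other eyes are unaffected.  Keys of the
    three mappings are eye ids (two per patient).
    """
    if not (set(vf_abnormal) == set(mferg_positive) == set(oct_evidence)):
        raise ValueError("per-eye mappings must cover the same eyes")
    status = {}
    for eye in vf_abnormal:
        toxic = vf_abnormal[eye] and (mferg_positive[eye] or oct_evidence[eye])
        status[eye] = "toxic" if toxic else "unaffected"
    if any(s == "toxic" for s in status.values()):
        for eye, s in status.items():
            if s == "unaffected" and mferg_positive[eye]:
                status[eye] = "toxic_mild"
    return status


# ---------------------------------------------------------------------------
# modified z-scores


def compute_zscores(
    features: pd.DataFrame,
    reference_eyes: set[str] | list[str],
    metrics: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Locus-wise modified z-scores against the unaffected reference.

    ``z = (x - mu_unaffected) / sigma_unaffected`` per (locus, metric),
    with mu/sigma the mean and sample SD (n-1) over the reference eyes at
    the same locus.  Returns ``(z_table, reference_stats)``; the z table
    mirrors the input with metric columns replaced by z-values (all eyes,
    reference included).  Loci where sigma is zero are flagged NaN with a
    warning.
    """
    metrics = metrics or [m for m in ZSCORE_METRICS if m in features.columns]
    reference_eyes = set(reference_eyes)
    if not reference_eyes:
        raise ValueError("reference eye set is empty")
    valid = features[features["valid"]]
    ref = valid[valid["eye_id"].isin(reference_eyes)]
    if ref.empty:
        raise ValueError("no valid reference rows found")
    stats = (
        ref.groupby("locus_id")[metrics]
        .agg(["mean", "std", "count"])
        .rename(columns={"std": "sd", "count": "n"})
    )
    stats.columns = [f"{m}__{s}" for m, s in stats.columns]
    stats = stats.reset_index()

    z = features.copy()
    merged = z.merge(stats, on="locus_id", how="left")
    n_zero_sd = 0
    for m in metrics:
        mu = merged[f"{m}__mean"].to_numpy()
        sd = merged[f"{m}__sd"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            zvals = (merged[m].to_numpy() - mu) / sd
        zero = sd == 0
        n_zero_sd += int(np.count_nonzero(zero & np.isfinite(merged[m].to_numpy())))
        zvals[zero] = np.nan
        z[m] = zvals
        z.loc[~z["valid"], m] = np.nan
    if n_zero_sd:
        warnings.warn(
            f"{n_zero_sd} (locus, metric) cells had zero reference SD; "
            "their z-scores are NaN",
            stacklevel=2,
        )
    return z, stats


def group_mean_zmaps(
    z_table: pd.DataFrame,
    severity: dict[str, str] | pd.Series,
    metrics: list[str] | None = None,
) -> dict[str, pd.DataFrame]:
    """Locus-wise mean z per severity group (the group-average map view).

    ``severity`` maps eye_id -> group label.  Returns one DataFrame per
    non-empty group, indexed by locus_id with one column per metric.
    Empty groups are omitted with a warning.
    """
    metrics = metrics or [m for m in ZSCORE_METRICS if m in z_table.columns]
    sev = pd.Series(dict(severity)) if not isinstance(severity, pd.Series) else severity
    table = z_table.copy()
    table["_group"] = table["eye_id"].map(sev)
    out: dict[str, pd.DataFrame] = {}
    for group in sev.unique():
        sub = table[table["_group"] == group]
        if sub.empty:
            warnings.warn(f"severity group {group!r} has no eyes; omitted", stacklevel=2)
            continue
        out[group] = sub.groupby("locus_id")[metrics].mean()
    return out


# ---------------------------------------------------------------------------
# univariate ring regressions


@dataclass(frozen=True)
class RegressionFit:
    """One ring-grouped OLS fit of sensitivity on an OCT metric."""

    metric: str
    ring: int
    slope: float
    intercept: float
    r_squared: float
    mae_db: float
    sd_abs_err_db: float
    n_points: int


def ols_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Closed-form simple OLS ``y = a*x + b`` (normal equations)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    if sxx == 0:
        raise ValueError("degenerate predictor: zero variance")
    slope = float(np.sum((x - xm) * (y - ym))) / sxx
    return slope, ym - slope * xm


def univariate_ring_regression(
    features: pd.DataFrame,
    metric: str,
    ring: int,
    use_zscores: bool = False,
    z_table: pd.DataFrame | None = None,
) -> RegressionFit:
    """OLS of visual-field sensitivity (dB) on one OCT metric within a ring.

    Pools every valid (eye, locus) point of the ring across the cohort.
    Reports slope, intercept, R-squared, the mean absolute residual and
    the SD of absolute residuals.  With ``use_zscores`` both variables are
    taken from ``z_table`` instead of raw values.
    """
    table = z_table if use_zscores else features
    if table is None:
        raise ValueError("use_zscores requires a z_table")
    sub = table[(table["ring"] == ring) & table["valid"]]
    sub = sub.dropna(subset=[metric, "sensitivity_db"])
    if len(sub) < 3:
        raise ValueError(f"need >= 3 valid points in ring {ring}, got {len(sub)}")
    x = sub[metric].to_numpy(float)
    y = sub["sensitivity_db"].to_numpy(float)
    slope, intercept = ols_fit(x, y)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        warnings.warn(
            "zero-variance response; R^2 reported as 0 by convention", stacklevel=2
        )
        r2 = 0.0
    else:
        r2 = 1.0 - float(np.sum(resid**2)) / sst
    abs_resid = np.abs(resid)
    return RegressionFit(
        metric=metric,
        ring=int(ring),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mae_db=float(abs_resid.mean()),
        sd_abs_err_db=float(abs_resid.std(ddof=1)),
        n_points=len(sub),
    )


def allpoint_zscore_regression(z_table: pd.DataFrame, metric: str) -> RegressionFit:
    """OLS of sensitivity z on metric z pooled over every locus of every eye.

    The locus-wise z-normalisation removes the eccentricity structure, so
    all 68 loci can be pooled into a single fit; reported with ring 0.
    """
    sub = z_table[z_table["valid"]].dropna(subset=[metric, "sensitivity_db"])
    if len(sub) < 3:
        raise ValueError("need >= 3 valid z-scored points")
    x = sub[metric].to_numpy(float)
    y = sub["sensitivity_db"].to_numpy(float)
    slope, intercept = ols_fit(x, y)
    resid = y - (slope * x + intercept)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 0.0
    abs_resid = np.abs(resid)
    return RegressionFit(
        metric=metric,
        ring=0,
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        mae_db=float(abs_resid.mean()),
        sd_abs_err_db=float(abs_resid.std(ddof=1)),
        n_points=len(sub),
    )


def univariate_suite(
    features: pd.DataFrame,
    metrics: list[str] | None = None,
    use_zscores: bool = False,
    z_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All metric x ring fits as one tidy table (skipping degenerate cells)."""
    metrics = metrics or UNIVARIATE_METRICS
    rows = []
    for metric in metrics:
        for ring in sorted(features["ring"].unique()):
            try:
                fit = univariate_ring_regression(
                    features, metric, int(ring), use_zscores=use_zscores,
                    z_table=z_table,
                )
            except ValueError as exc:
                warnings.warn(
                    f"skipping {metric} ring {ring}: {exc}", stacklevel=2
                )
                continue
            rows.append(vars(fit))
    return pd.DataFrame(rows)
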