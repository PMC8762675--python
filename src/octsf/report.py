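"""Figure rendering: z-score maps, ring regressions, prediction maps.

All visual-field maps are drawn in VF view, right-eye orientation: x
positive temporal-field-right, y positive superior.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .scaffold import HvfGrid


def vf_raster(values: np.ndarray, grid: HvfGrid) -> np.ndarray:
    """Embed 68 locus values into a 10x10 raster (NaN off-grid), VF view."""
    raster = np.full((10, 10), np.nan)
    rows = ((9 - grid.y_deg) / 2).astype(int)
    cols = ((grid.x_deg + 9) / 2).astype(int)
    raster[rows, cols] = values
    return raster


def plot_vf_maps(
    maps: dict[str, np.ndarray],
    grid: HvfGrid,
    path: Path,
    title: str = "",
    cmap: str = "RdBu_r",
    vlim: float | None = None,
) -> None:
    """One panel per named 68-locus map, shared symmetric color scale."""
    n = len(maps)
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.4), squeeze=False)
    if vlim is None:
        finite = np.concatenate([np.asarray(v)[np.isfinite(v)] for v in maps.values()])
        vlim = float(np.max(np.abs(finite))) if finite.size else 1.0
    for ax, (name, vals) in zip(axes[0], maps.items()):
        im = ax.imshow(
            vf_raster(np.asarray(vals, float), grid),
            cmap=cmap,
            vmin=-vlim,
            vmax=vlim,
            extent=(-10, 10, -10, 10),
        )
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("x (deg)")
        ax.set_ylabel("y (deg)")
    fig.colorbar(im, ax=axes[0].tolist(), shrink=0.8)
    fig.suptitle(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ring_regressions(
    features: pd.DataFrame,
    fits: pd.DataFrame,
    metric: str,
    path: Path,
) -> None:
    """Scatter of sensitivity vs one metric, one panel per ring, with fit."""
    rings = sorted(features["ring"].unique())
    fig, axes = plt.subplots(1, len(rings), figsize=(3 * len(rings), 3), sharey=True)
    for ax, ring in zip(np.atleast_1d(axes), rings):
        sub = features[(features["ring"] == ring) & features["valid"]].dropna(
            subset=[metric, "sensitivity_db"]
        )
        ax.scatter(sub[metric], sub["sensitivity_db"], s=6, alpha=0.4)
        row = fits[(fits["metric"] == metric) & (fits["ring"] == ring)]
        if len(row):
            r = row.iloc[0]
            xs = np.linspace(sub[metric].min(), sub[metric].max(), 20)
            ax.plot(xs, r["slope"] * xs + r["intercept"], "r-", lw=1)
            ax.set_title(f"ring {ring}: $R^2$={r['r_squared']:.2f}", fontsize=9)
        ax.set_xlabel(metric)
    np.atleast_1d(axes)[0].set_ylabel("sensitivity (dB)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_measured_vs_predicted(
    predictions: pd.DataFrame,
    grid: HvfGrid,
    eye_ids: list[str],
    path: Path,
) -> None:
    """Measured and predicted VF maps side by side for example eyes."""
    fig, axes = plt.subplots(
        len(eye_ids), 2, figsize=(6.5, 3.1 * len(eye_ids)), squeeze=False
    )
    vmax = float(predictions[["y_true", "y_pred"]].to_numpy().max())
    for row, eye_id in enumerate(eye_ids):
        sub = predictions[predictions["eye_id"] == eye_id]
        for col, what in enumerate(["y_true", "y_pred"]):
            vals = np.full(grid.n_loci, np.nan)
            vals[sub["locus_id"].to_numpy(int)] = sub[what].to_numpy()
            im = axes[row, col].imshow(
                vf_raster(vals, grid),
                cmap="viridis",
                vmin=0,
                vmax=vmax,
                extent=(-10, 10, -10, 10),
            )
            axes[row, col].set_title(
                f"{eye_id} {'measured' if what == 'y_true' else 'predicted'}",
                fontsize=9,
            )
    fig.colorbar(im, ax=axes.ravel().tolist(), shrink=0.7, label="dB")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_importance(
    importance_full: np.ndarray,
    importance_mild: np.ndarray | None,
    feature_names: list[str],
    path: Path,
) -> None:
    """Aggregated feature importances, full cohort vs mild subset."""
    n_panels = 2 if importance_mild is not None else 1
    fig, axes = plt.subplots(1, n_panels, figsize=(5 * n_panels, 3.2), squeeze=False)
    panels = [("full cohort", importance_full)]
    if importance_mild is not None:
        panels.append(("unaffected + mild", importance_mild))
    for ax, (title, imp) in zip(axes[0], panels):
        ax.bar(range(len(feature_names)), imp)
        ax.set_xticks(range(len(feature_names)))
        ax.set_xticklabels(feature_names, rotation=60, ha="right", fontsize=8)
        ax.set_ylabel("mean importance")
        ax.set_title(title, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
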