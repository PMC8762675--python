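"""On-disk formats: TIFF volumes with JSON sidecars, CSV tables.

Layout per eye (under ``<cohort_dir>/<eye_id>/``)::

    volume.tiff     multi-page float32 stack (one page per B-scan; only
                    when volumes were rendered)
    sidecar.json    geometry + identity metadata
    surfaces.csv    b_scan, a_scan, ilm_px, opl_px, rpe_px
    ez.csv          b_scan, a_scan, ez (0/1)
    hvf.csv         locus_id, sensitivity_db, pd_abnormal
    mferg.csv       ring, amplitude_nv_deg2

plus one ``manifest.csv`` per cohort with one row per eye.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import (
    EnfaceEZMap,
    EyeRecord,
    HvfMeasurement,
    LayerSurfaces,
    MfergRings,
    OctVolume,
    PatientRecord,
)


def write_json_atomic(payload: dict, path: Path) -> None:
    """Write JSON via a temp file + rename so readers never see a torn file."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(payload, indent=2, sort_keys=True))
    os.replace(tmp, path)


def _enface_long(arrays: dict[str, np.ndarray]) -> pd.DataFrame:
    first = next(iter(arrays.values()))
    nb, nw = first.shape
    bb, aa = np.meshgrid(np.arange(nb), np.arange(nw), indexing="ij")
    data = {"b_scan": bb.ravel(), "a_scan": aa.ravel()}
    data.update({k: v.ravel() for k, v in arrays.items()})
    return pd.DataFrame(data)


def _enface_wide(df: pd.DataFrame, col: str) -> np.ndarray:
    nb = int(df["b_scan"].max()) + 1
    nw = int(df["a_scan"].max()) + 1
    arr = np.empty((nb, nw))
    arr[df["b_scan"].to_numpy(), df["a_scan"].to_numpy()] = df[col].to_numpy()
    return arr


def save_eye(eye: EyeRecord, cohort_dir: Path, config) -> Path:
    """Write one eye's modalities; returns the eye directory."""
    eye_dir = Path(cohort_dir) / eye.eye_id
    eye_dir.mkdir(parents=True, exist_ok=True)

    sidecar = {
        "eye_id": eye.eye_id,
        "patient_id": eye.patient_id,
        "laterality": eye.laterality,
        "severity_group": eye.severity_group,
        "axial_pitch_um": config.axial_pitch_um,
        "lateral_pitch_um": config.lateral_pitch_um,
        "bscan_spacing_um": config.bscan_spacing_um,
        "fovea": list(config.fovea),
        "seed": config.seed,
        "md_db": eye.hvf.md_db,
        "psd_db": eye.hvf.psd_db,
        "has_volume": eye.volume is not None,
    }
    write_json_atomic(sidecar, eye_dir / "sidecar.json")

    if eye.volume is not None:
        tifffile.imwrite(
            eye_dir / "volume.tiff", eye.volume.intensity.astype(np.float32)
        )
    _enface_long(
        {
            "ilm_px": eye.surfaces.ilm,
            "opl_px": eye.surfaces.opl,
            "rpe_px": eye.surfaces.rpe,
        }
    ).to_csv(eye_dir / "surfaces.csv", index=False)
    _enface_long({"ez": eye.ez_map.loss}).to_csv(eye_dir / "ez.csv", index=False)
    pd.DataFrame(
        {
            "locus_id": np.arange(68),
            "sensitivity_db": eye.hvf.sensitivity_db,
            "pd_abnormal": eye.hvf.pd_abnormal.astype(int),
        }
    ).to_csv(eye_dir / "hvf.csv", index=False)
    pd.DataFrame(
        {"ring": [1, 2, 3, 4, 5], "amplitude_nv_deg2": eye.mferg.amplitudes}
    ).to_csv(eye_dir / "mferg.csv", index=False)
    return eye_dir


def load_eye(eye_dir: Path) -> tuple[EyeRecord, dict]:
    """Read one eye back; returns ``(record, sidecar)``.

    Ground-truth fields are not persisted, so they come back ``None``.
    """
    eye_dir = Path(eye_dir)
    sidecar = json.loads((eye_dir / "sidecar.json").read_text())
    surf_df = pd.read_csv(eye_dir / "surfaces.csv")
    surfaces = LayerSurfaces(
        ilm=_enface_wide(surf_df, "ilm_px"),
        opl=_enface_wide(surf_df, "opl_px"),
        rpe=_enface_wide(surf_df, "rpe_px"),
    )
    ez = EnfaceEZMap(_enface_wide(pd.read_csv(eye_dir / "ez.csv"), "ez").astype(int))
    hvf_df = pd.read_csv(eye_dir / "hvf.csv").sort_values("locus_id")
    hvf = HvfMeasurement(
        sensitivity_db=hvf_df["sensitivity_db"].to_numpy(),
        pd_abnormal=hvf_df["pd_abnormal"].to_numpy().astype(bool),
        md_db=sidecar["md_db"],
        psd_db=sidecar["psd_db"],
    )
    mferg_df = pd.read_csv(eye_dir / "mferg.csv").sort_values("ring")
    mferg = MfergRings(mferg_df["amplitude_nv_deg2"].to_numpy())

    volume = None
    if sidecar.get("has_volume") and (eye_dir / "volume.tiff").exists():
        volume = OctVolume(
            intensity=tifffile.imread(eye_dir / "volume.tiff").astype(np.float64),
            axial_pitch_um=sidecar["axial_pitch_um"],
            lateral_pitch_um=sidecar["lateral_pitch_um"],
            bscan_spacing_um=sidecar["bscan_spacing_um"],
            laterality=sidecar["laterality"],
            fovea=tuple(sidecar["fovea"]),
        )
    record = EyeRecord(
        eye_id=sidecar["eye_id"],
        patient_id=sidecar["patient_id"],
        laterality=sidecar["laterality"],
        severity_group=sidecar["severity_group"],
        volume=volume,
        surfaces=surfaces,
        ez_map=ez,
        hvf=hvf,
        mferg=mferg,
    )
    return record, sidecar


def save_cohort(patients: list[PatientRecord], cohort_dir: Path, config) -> pd.DataFrame:
    """Write every eye plus a cohort manifest; returns the manifest frame."""
    cohort_dir = Path(cohort_dir)
    rows = []
    for p in patients:
        for eye in p.eyes:
            save_eye(eye, cohort_dir, config)
            rows.append(
                {
                    "eye_id": eye.eye_id,
                    "patient_id": eye.patient_id,
                    "laterality": eye.laterality,
                    "severity_group": eye.severity_group,
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(cohort_dir / "manifest.csv", index=False)
    return manifest


def load_cohort(cohort_dir: Path) -> tuple[list[EyeRecord], list[str]]:
    """Read every listed eye; returns ``(eyes, failed_eye_ids)``."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    eyes, failed = [], []
    for eye_id in manifest["eye_id"]:
        try:
            record, _ = load_eye(cohort_dir / eye_id)
            eyes.append(record)
        except (OSError, KeyError, ValueError):
            failed.append(eye_id)
    return eyes, failed
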