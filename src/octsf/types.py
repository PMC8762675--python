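"""Core in-memory containers shared across the pipeline.

The canonical spatial frame is the OCT en-face lattice: axis 0 indexes
B-scans (superior -> inferior), axis 1 indexes A-scans within a B-scan
(temporal/nasal depending on laterality), and depth runs anterior ->
posterior in pixels.  Physical pitches are carried on every volume so all
geometry downstream can work in micrometres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Conversion between visual angle and retinal distance used throughout;
#: 2 degrees of visual field correspond to 576 um on the retina.
UM_PER_DEGREE = 288.0

SEVERITY_GROUPS = ("unaffected", "1", "2", "3", "4")


@dataclass
class OctVolume:
    """An SD-OCT macular cube with its acquisition geometry.

    ``intensity`` has shape ``(n_bscans, depth_px, width_px)``.  ``fovea``
    is an ``(b_scan, a_scan)`` coordinate (floats allowed) on the en-face
    lattice.
    """

    intensity: np.ndarray
    axial_pitch_um: float
    lateral_pitch_um: float
    bscan_spacing_um: float
    laterality: str  # "OD" | "OS"
    fovea: tuple[float, float]

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (n_bscans, depth, width)")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")
        for p in (self.axial_pitch_um, self.lateral_pitch_um, self.bscan_spacing_um):
            if p <= 0:
                raise ValueError("pixel pitches must be positive")
        if self.laterality not in ("OD", "OS"):
            raise ValueError(f"laterality must be OD or OS, got {self.laterality!r}")
        nb, _, nw = self.intensity.shape
        fb, fa = self.fovea
        if not (0 <= fb <= nb - 1 and 0 <= fa <= nw - 1):
            raise ValueError("fovea must lie inside the en-face lattice")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensity.shape

    @property
    def n_bscans(self) -> int:
        return self.intensity.shape[0]

    @property
    def depth_px(self) -> int:
        return self.intensity.shape[1]

    @property
    def width_px(self) -> int:
        return self.intensity.shape[2]

    def with_intensity(self, intensity: np.ndarray) -> "OctVolume":
        """Copy of this volume with new voxel data, same geometry."""
        return OctVolume(
            intensity=intensity,
            axial_pitch_um=self.axial_pitch_um,
            lateral_pitch_um=self.lateral_pitch_um,
            bscan_spacing_um=self.bscan_spacing_um,
            laterality=self.laterality,
            fovea=self.fovea,
        )


@dataclass
class LayerSurfaces:
    """Depths (pixels, sub-pixel allowed) of ILM, OPL and RPE per A-scan.

    Each array has the en-face shape ``(n_bscans, width_px)`` and must
    satisfy ``ilm <= opl <= rpe`` everywhere.
    """

    ilm: np.ndarray
    opl: np.ndarray
    rpe: np.ndarray

    def __post_init__(self) -> None:
        self.ilm = np.asarray(self.ilm, dtype=np.float64)
        self.opl = np.asarray(self.opl, dtype=np.float64)
        self.rpe = np.asarray(self.rpe, dtype=np.float64)
        if not (self.ilm.shape == self.opl.shape == self.rpe.shape):
            raise ValueError("surface maps must share one en-face shape")
        if np.any(self.ilm > self.opl) or np.any(self.opl > self.rpe):
            raise ValueError("surface ordering ILM <= OPL <= RPE violated")
        if np.any(self.ilm < 0):
            raise ValueError("surface depths must be non-negative")

    @property
    def enface_shape(self) -> tuple[int, int]:
        return self.ilm.shape


@dataclass
class EnfaceEZMap:
    """Binary en-face map of ellipsoid-zone loss on the A-scan lattice."""

    loss: np.ndarray  # (n_bscans, width_px), values in {0, 1}

    def __post_init__(self) -> None:
        arr = np.asarray(self.loss)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("EZ-loss map must be binary")
        self.loss = arr.astype(np.uint8)

    @property
    def enface_shape(self) -> tuple[int, int]:
        return self.loss.shape


@dataclass
class HvfMeasurement:
    """Humphrey 10-2 output for one eye: 68 locus sensitivities in dB.

    ``pd_abnormal`` marks loci flagged on the pattern-deviation map at the
    P < 2% level.  ``md_db``/``psd_db`` are the usual summary indices.
    Arrays are ordered by ``HvfGrid`` locus id.
    """

    sensitivity_db: np.ndarray  # (68,)
    pd_abnormal: np.ndarray  # (68,) bool
    md_db: float
    psd_db: float

    def __post_init__(self) -> None:
        self.sensitivity_db = np.asarray(self.sensitivity_db, dtype=np.float64)
        self.pd_abnormal = np.asarray(self.pd_abnormal, dtype=bool)
        if self.sensitivity_db.shape != (68,) or self.pd_abnormal.shape != (68,):
            raise ValueError("an HVF 10-2 measurement carries exactly 68 loci")
        if not np.all(np.isfinite(self.sensitivity_db)):
            raise ValueError("sensitivities must be finite")


@dataclass
class MfergRings:
    """mfERG ring-average response densities R1..R5 in nV/deg^2."""

    amplitudes: np.ndarray  # (5,) : R1..R5

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.amplitudes.shape != (5,):
            raise ValueError("expected five ring amplitudes R1..R5")
        if np.any(self.amplitudes <= 0):
            raise ValueError("ring amplitudes must be positive")

    @property
    def ratios(self) -> np.ndarray:
        """Central-to-peripheral ratios R1/R2 .. R1/R5."""
        return self.amplitudes[0] / self.amplitudes[1:]


@dataclass
class EyeRecord:
    """One synthetic eye with every modality plus its generation ground truth."""

    eye_id: str
    patient_id: str
    laterality: str
    severity_group: str
    volume: OctVolume
    surfaces: LayerSurfaces
    ez_map: EnfaceEZMap
    hvf: HvfMeasurement
    mferg: MfergRings
    # ground truth, for tests/oracles only
    true_sensitivity_db: np.ndarray | None = None
    true_ez_frac: np.ndarray | None = None
    true_ort_deficit_um: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.severity_group not in SEVERITY_GROUPS:
            raise ValueError(f"unknown severity group {self.severity_group!r}")


@dataclass
class PatientRecord:
    """Both eyes of one participant; LOPO folds drop the whole record."""

    patient_id: str
    eyes: list[EyeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.eyes) != 2:
            raise ValueError("a patient record carries exactly two eyes")
        if any(e.patient_id != self.patient_id for e in self.eyes):
            raise ValueError("eye/patient id mismatch")
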