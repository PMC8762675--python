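"""Humphrey 10-2 scaffold: grid construction, registration, locus sampling.

The 10-2 program tests 68 loci on a 2-degree lattice at odd-degree offsets
within the central 10 degrees.  A digital scaffold of circular test spots
(288 um diameter, one retinal degree) is registered to the fovea on the
OCT en-face lattice; thickness and EZ-loss features are averaged over the
288 um spot while intensity features use a spot enlarged to 576 um.

Internally all geometry lives in a right-eye retinal en-face frame:
left-eye visual-field x is negated and visual-field y is inverted
(superior field projects onto inferior retina) before conversion to
micrometres at 288 um/degree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .types import UM_PER_DEGREE, EnfaceEZMap, HvfMeasurement, OctVolume

#: Default test-spot diameters (um): thickness/EZ use the native spot,
#: intensity metrics use the doubled spot for robustness.
SPOT_DIAMETER_UM = 288.0
INTENSITY_SPOT_DIAMETER_UM = 576.0

#: Squared-eccentricity (deg^2) band edges assigning rings 1..5, central
#: outwards.  Band k covers (edges[k-1], edges[k]].
_RING_EDGES_SQ = (0.0, 2.0, 18.0, 34.0, 58.0, 82.0)

FEATURE_COLUMNS = [
    "ez_frac",
    "trt_um",
    "ort_um",
    "tr_meani",
    "or_meani",
    "tr_mini",
    "or_mini",
    "x_deg",
    "y_deg",
]


@dataclass(frozen=True)
class HvfGrid:
    """The 68-locus 10-2 grid in right-eye visual-field coordinates."""

    x_deg: np.ndarray
    y_deg: np.ndarray
    ring: np.ndarray  # 1..5

    @property
    def n_loci(self) -> int:
        return self.x_deg.size

    @property
    def eccentricity_deg(self) -> np.ndarray:
        return np.hypot(self.x_deg, self.y_deg)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus_id": np.arange(self.n_loci),
                "x_deg": self.x_deg,
                "y_deg": self.y_deg,
                "ring": self.ring,
            }
        )


@dataclass(frozen=True)
class EnfaceGeometry:
    """Just enough geometry to register the scaffold without voxel data."""

    n_bscans: int
    width_px: int
    bscan_spacing_um: float
    lateral_pitch_um: float
    fovea: tuple[float, float]
    laterality: str


@dataclass
class LocusMask:
    """Lattice points whose centres fall within one test spot."""

    locus_id: int
    positions: np.ndarray  # (n, 2) int array of (b_scan, a_scan)
    spot_diameter_um: float
    valid: bool


def build_hvf10_2_grid() -> HvfGrid:
    """Construct the 68-locus Humphrey 10-2 layout with ring labels.

    Loci sit at odd-degree coordinates on a 2-degree lattice; the pattern
    keeps every point with squared eccentricity <= 82 deg^2 (max 9.06
    degrees), which reproduces the instrument's 68-point layout.  Rings
    1..5 are concentric eccentricity bands from the 4 central points out
    to the extremities; corner points whose eccentricity ties two bands
    are assigned to the outermost qualifying ring.
    """
    odd = range(-9, 10, 2)
    coords = [(x, y) for y in odd for x in odd if x * x + y * y <= 82]
    # deterministic ordering: VF reading order, superior row first
    coords.sort(key=lambda c: (-c[1], c[0]))
    x = np.array([c[0] for c in coords], dtype=float)
    y = np.array([c[1] for c in coords], dtype=float)
    ecc_sq = x * x + y * y
    ring = np.digitize(ecc_sq, _RING_EDGES_SQ[1:], right=True) + 1
    return HvfGrid(x_deg=x, y_deg=y, ring=ring.astype(int))


def load_packaged_grid() -> HvfGrid:
    """Read the static grid table shipped with the package."""
    with resources.files("octsf.data").joinpath("hvf10_2_grid.csv").open() as fh:
        df = pd.read_csv(fh)
    return HvfGrid(
        x_deg=df["x_deg"].to_numpy(float),
        y_deg=df["y_deg"].to_numpy(float),
        ring=df["ring"].to_numpy(int),
    )


def locus_centers_um(
    grid: HvfGrid, laterality: str, um_per_degree: float = UM_PER_DEGREE
) -> np.ndarray:
    """Locus centres in retinal en-face micrometres relative to the fovea.

    Returns an (n_loci, 2) array of (row_um, col_um): row is along the
    B-scan stacking axis, col along the A-scan axis.  Visual-field y is
    inverted to the retinal view; left-eye x is negated so the en-face
    frame is anatomically consistent across lateralities.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be OD or OS")
    x_ret = grid.x_deg if laterality == "OD" else -grid.x_deg
    y_ret = -grid.y_deg
    return np.column_stack([y_ret * um_per_degree, x_ret * um_per_degree])


def register_grid(
    grid: HvfGrid,
    vol: OctVolume | EnfaceGeometry,
    spot_diameter_um: float = SPOT_DIAMETER_UM,
    um_per_degree: float = UM_PER_DEGREE,
) -> list[LocusMask]:
    """Register the scaffold to the fovea and rasterise each test spot.

    ``vol`` may be a full :class:`~octsf.types.OctVolume` or a bare
    :class:`EnfaceGeometry`.  A locus mask holds every lattice point whose
    physical centre lies within ``spot_diameter_um / 2`` of the locus
    centre.  A locus is flagged invalid (mask retained, ``valid=False``)
    when its spot is not fully contained in the scanned area or when the
    lattice is too coarse to place any point inside the spot.
    """
    centers = locus_centers_um(grid, vol.laterality, um_per_degree)
    radius = spot_diameter_um / 2.0
    nb, nw = vol.n_bscans, vol.width_px
    fb, fa = vol.fovea
    rows_um = (np.arange(nb) - fb) * vol.bscan_spacing_um
    cols_um = (np.arange(nw) - fa) * vol.lateral_pitch_um
    row_lo = rows_um[0] - vol.bscan_spacing_um / 2.0
    row_hi = rows_um[-1] + vol.bscan_spacing_um / 2.0
    col_lo = cols_um[0] - vol.lateral_pitch_um / 2.0
    col_hi = cols_um[-1] + vol.lateral_pitch_um / 2.0

    masks: list[LocusMask] = []
    for lid, (rc, cc) in enumerate(centers):
        d2 = (rows_um[:, None] - rc) ** 2 + (cols_um[None, :] - cc) ** 2
        if radius > 0:
            ii, jj = np.nonzero(d2 <= radius * radius)
        else:
            ii = jj = np.array([], dtype=int)
        positions = np.column_stack([ii, jj]).astype(int)
        in_bounds = (
            rc - radius >= row_lo
            and rc + radius <= row_hi
            and cc - radius >= col_lo
            and cc + radius <= col_hi
        )
        valid = bool(positions.shape[0] > 0 and in_bounds)
        if not valid:
            warnings.warn(
                f"locus {lid} invalid: "
                + ("empty mask" if positions.shape[0] == 0 else "spot outside scan"),
                stacklevel=2,
            )
        masks.append(
            LocusMask(
                locus_id=lid,
                positions=positions,
                spot_diameter_um=spot_diameter_um,
                valid=valid,
            )
        )
    return masks


def _mask_mean(map2d: np.ndarray, mask: LocusMask) -> float:
    if mask.positions.shape[0] == 0:
        return np.nan
    return float(np.mean(map2d[mask.positions[:, 0], mask.positions[:, 1]]))


def ez_fraction(ez: EnfaceEZMap, mask: LocusMask) -> float:
    """Fraction of the test spot's lattice points showing EZ loss."""
    if mask.positions.shape[0] == 0:
        return np.nan
    vals = ez.loss[mask.positions[:, 0], mask.positions[:, 1]]
    return float(np.count_nonzero(vals)) / vals.size


def sample_locus_features(
    maps,
    ez: EnfaceEZMap,
    masks_thickness: list[LocusMask],
    masks_intensity: list[LocusMask],
    hvf: HvfMeasurement | None,
    grid: HvfGrid,
) -> pd.DataFrame:
    """Aggregate metric maps and the EZ map into a per-locus feature table.

    ``maps`` is an :class:`octsf.metrics.AscanMetricMaps` (or None when
    only geometry/EZ features are wanted).  Thickness and EZ fraction are
    averaged over the native spot; the four intensity features over the
    enlarged spot.  Invalid loci keep their row with ``valid = False`` and
    NaN features.
    """
    n = grid.n_loci
    if len(masks_thickness) != n or len(masks_intensity) != n:
        raise ValueError("one mask per locus required")
    rows = []
    for lid in range(n):
        mt, mi = masks_thickness[lid], masks_intensity[lid]
        valid = mt.valid and mi.valid
        rec: dict[str, float | int | bool] = {
            "locus_id": lid,
            "x_deg": grid.x_deg[lid],
            "y_deg": grid.y_deg[lid],
            "ring": int(grid.ring[lid]),
            "valid": valid,
        }
        if valid:
            rec["ez_frac"] = ez_fraction(ez, mt)
            if maps is not None:
                rec["trt_um"] = _mask_mean(maps.trt_um, mt)
                rec["ort_um"] = _mask_mean(maps.ort_um, mt)
                rec["tr_meani"] = _mask_mean(maps.tr_meani, mi)
                rec["or_meani"] = _mask_mean(maps.or_meani, mi)
                rec["tr_mini"] = _mask_mean(maps.tr_mini, mi)
                rec["or_mini"] = _mask_mean(maps.or_mini, mi)
        rows.append(rec)
    df = pd.DataFrame(rows)
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if hvf is not None:
        df["sensitivity_db"] = hvf.sensitivity_db[df["locus_id"].to_numpy()]
    else:
        df["sensitivity_db"] = np.nan
    return df[["locus_id", *FEATURE_COLUMNS, "ring", "sensitivity_db", "valid"]]
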