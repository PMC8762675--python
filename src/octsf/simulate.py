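"""Synthetic hydroxychloroquine-retinopathy cohort generator.

Every downstream stage of the pipeline is exercised against cohorts
produced here, for which the structure-function relationship is known
exactly.  Each synthetic eye carries:

* three smooth layer surfaces (ILM with a foveal pit, OPL, RPE) whose
  outer-retinal thickness is reduced inside and around the EZ lesion,
* a binary en-face EZ-loss map shaped as a parafoveal annulus whose
  extent on the foveal B-scan falls in its severity group's interval
  (<=100 um; 100-1000 um; >1000 um with a preserved foveal island
  >500 um; foveal involvement),
* a rendered OCT volume with layered reflectivity bands, multiplicative
  speckle and per-B-scan gain jitter,
* a 68-locus Humphrey 10-2 measurement generated from the ground-truth
  rule  S = s0 - ecc_slope*ecc - beta_ez*EZfrac - beta_ort*dORT + noise,
* mfERG ring amplitudes attenuated by the EZ-loss area overlapping each
  ring territory.

The generated severity label is always re-derivable from the rasterised
EZ map through :func:`octsf.grading.assign_severity_group`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from . import scaffold
from .types import (
    UM_PER_DEGREE,
    EnfaceEZMap,
    EyeRecord,
    HvfMeasurement,
    LayerSurfaces,
    MfergRings,
    OctVolume,
    PatientRecord,
    SEVERITY_GROUPS,
)


@dataclass(frozen=True)
class GroundTruthSF:
    """Parameters of the synthetic structure-function rule (all dB-scaled).

    ``s0`` is the foveal sensitivity of a healthy eye; ``ecc_slope`` the
    physiologic decline per degree of eccentricity; ``beta_ez`` the full
    penalty when a test spot is completely EZ-deprived; ``beta_ort`` the
    penalty per micrometre of outer-retinal thinning; ``noise_sd`` the
    test-retest noise of a single threshold estimate.
    """

    s0: float = 34.0
    ecc_slope: float = 0.3
    beta_ez: float = 20.0
    beta_ort: float = 0.25
    noise_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.beta_ez < 0 or self.beta_ort < 0:
            raise ValueError("noise_sd, beta_ez and beta_ort must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic study cohort.

    The default desk-scale geometry (61 B-scans x 256 depth x 384 width,
    120 um B-scan spacing, 22.5 um lateral pitch) preserves the 30 x 25
    degree field of the clinical acquisition at a quarter of its voxel
    count; the clinical 121-B-scan / 60-um geometry is available by
    overriding ``volume_shape`` and ``bscan_spacing_um``.
    """

    n_patients_per_group: dict[str, int] = field(
        default_factory=lambda: {"unaffected": 10, "1": 3, "2": 2, "3": 3, "4": 2}
    )
    volume_shape: tuple[int, int, int] = (61, 256, 384)
    axial_pitch_um: float = 3.87
    lateral_pitch_um: float = 22.5
    bscan_spacing_um: float = 120.0
    speckle_shape: float | None = 16.0
    gain_jitter_sd: float = 0.1
    sf_params: GroundTruthSF = field(default_factory=GroundTruthSF)
    um_per_degree: float = UM_PER_DEGREE
    pd_threshold_db: float = 5.0
    asymmetric_fraction: float = 0.0
    render_volumes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.n_patients_per_group.items():
            if g not in SEVERITY_GROUPS:
                raise ValueError(f"unknown severity group {g!r}")
            if n < 0:
                raise ValueError("patient counts must be >= 0")
        if any(
            p <= 0
            for p in (self.axial_pitch_um, self.lateral_pitch_um, self.bscan_spacing_um)
        ):
            raise ValueError("pixel pitches must be positive")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive (or None to disable)")
        if self.gain_jitter_sd < 0:
            raise ValueError("gain_jitter_sd must be >= 0")
        nb, _, nw = self.volume_shape
        min_span_um = 20.0 * self.um_per_degree
        if nb * self.bscan_spacing_um < min_span_um or nw * self.lateral_pitch_um < min_span_um:
            raise ValueError(
                "volume must span at least 20 x 20 degrees so all 68 loci fit"
            )

    @property
    def fovea(self) -> tuple[float, float]:
        """Geometric centre of the en-face lattice."""
        nb, _, nw = self.volume_shape
        return ((nb - 1) / 2.0, (nw - 1) / 2.0)

    @property
    def enface_shape(self) -> tuple[int, int]:
        nb, _, nw = self.volume_shape
        return (nb, self.volume_shape[2])


#: Reduced preset for quick end-to-end runs (same 30 x 25 degree field).
def reduced_config(**overrides) -> SimulationConfig:
    base = dict(
        n_patients_per_group={"unaffected": 4, "1": 1, "2": 1, "3": 1, "4": 1},
        volume_shape=(31, 192, 288),
        axial_pitch_um=5.0,
        lateral_pitch_um=30.0,
        bscan_spacing_um=240.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)


# ---------------------------------------------------------------------------
# lesion geometry


#: Per-group annulus parameter ranges in micrometres.  ``width`` for group 4
#: is the disc radius (inner radius 0, fovea involved).  Group 1 uses a thin
#: fixed-width ring without boundary dithering so its foveal-B-scan extent
#: stays below 100 um at any lattice pitch; its radius range sits in the gap
#: between the ring-1 and ring-2 test-spot edges (551-767 um from the fovea),
#: so mild EZ loss is below the scaffold's detection limit (EZfrac 0 at every
#: locus) and the mild functional deficit is carried by outer-retinal
#: thinning, as in early toxicity.
_LESION_PARAMS: dict[str, dict] = {
    "1": {"r_in": (615.0, 680.0), "width": (45.0, 45.0), "dither": 0.0},
    "2": {"r_in": (500.0, 700.0), "width": (250.0, 400.0), "dither": 20.0},
    "3": {"r_in": (350.0, 500.0), "width": (2100.0, 2500.0), "dither": 20.0},
    "4": {"r_in": (0.0, 0.0), "width": (800.0, 1200.0), "dither": 20.0},
}

#: Peak outer-retinal thinning (um) applied in and around the lesion.
_ORT_DEFICIT_UM: dict[str, float] = {
    "unaffected": 0.0,
    "1": 20.0,
    "2": 28.0,
    "3": 36.0,
    "4": 45.0,
}

#: Spatial extent (um) of the thinning halo around the EZ lesion.
_DEFICIT_HALO_SIGMA_UM = 250.0


def _enface_coords_um(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    nb, _, nw = config.volume_shape
    fb, fa = config.fovea
    rows = (np.arange(nb) - fb) * config.bscan_spacing_um
    cols = (np.arange(nw) - fa) * config.lateral_pitch_um
    return rows, cols


def generate_ez_loss_map(
    config: SimulationConfig, severity: str, rng: np.random.Generator
) -> EnfaceEZMap:
    """Rasterise a severity-dependent annular EZ lesion centred on the fovea.

    Unaffected eyes get an empty map; group 4 a foveal-involving disc.
    Annulus radii are drawn per eye within safe ranges for the group's
    foveal-B-scan extent interval, with a smooth angular dithering of the
    boundaries (except for the thin group-1 ring).
    """
    if severity not in SEVERITY_GROUPS:
        raise ValueError(f"unknown severity group {severity!r}")
    nb, _, nw = config.volume_shape
    if severity == "unaffected":
        return EnfaceEZMap(np.zeros((nb, nw), dtype=np.uint8))

    p = _LESION_PARAMS[severity]
    if severity == "1":
        # lattice-aligned thin ring: exactly k1 pixels per side on the
        # foveal B-scan, so the extent 2*k1*pitch stays <= 100 um at any
        # supported lateral pitch
        pitch = config.lateral_pitch_um
        if 2 * pitch > 100:
            raise ValueError(
                "lateral pitch too coarse to represent a group-1 lesion "
                "(<=100 um foveal extent)"
            )
        k1 = max(1, int(50.0 // pitch))
        _, cols = _enface_coords_um(config)
        posd = np.sort(np.abs(cols[cols > 0]))
        target = rng.uniform(*p["r_in"])
        i0 = int(np.clip(np.searchsorted(posd, target), 1, posd.size - k1 - 1))
        r_in = (posd[i0 - 1] + posd[i0]) / 2.0
        r_out = (posd[i0 + k1 - 1] + posd[i0 + k1]) / 2.0
    else:
        r_in = rng.uniform(*p["r_in"])
        width = rng.uniform(*p["width"])
        r_out = r_in + width if severity != "4" else width

    rows, cols = _enface_coords_um(config)
    yy = rows[:, None]
    xx = cols[None, :]
    r = np.hypot(yy, xx)
    theta = np.arctan2(yy, xx)

    def dither() -> np.ndarray:
        if p["dither"] == 0.0:
            return np.zeros_like(r)
        a1, a2 = rng.uniform(0, p["dither"] / 2.0, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        return a1 * np.sin(3 * theta + ph1) + a2 * np.sin(5 * theta + ph2)

    if severity == "4":
        loss = r <= r_out + dither()
    else:
        loss = (r >= r_in + dither()) & (r <= r_out + dither())
    return EnfaceEZMap(loss.astype(np.uint8))


def measure_ez_morphometry(
    ez: EnfaceEZMap, config: SimulationConfig
) -> tuple[float, float, bool]:
    """Foveal-B-scan EZ-loss extent, preserved central island, foveal involvement.

    Extent is the total EZ-positive length (um) along the horizontal
    B-scan through the fovea; the island is the contiguous EZ-intact run
    containing the foveal A-scan on that B-scan; foveal involvement means
    any loss within 100 um of the foveal centre.
    """
    fb, fa = config.fovea
    row = ez.loss[int(np.floor(fb + 0.5))]
    extent_um = float(np.count_nonzero(row)) * config.lateral_pitch_um

    rows, cols = _enface_coords_um(config)
    r = np.hypot(rows[:, None], cols[None, :])
    foveal_involved = bool(np.any(ez.loss[r <= 100.0] == 1))

    fa_idx = int(np.floor(fa + 0.5))
    if row[fa_idx]:
        island_um = 0.0
    else:
        lo = fa_idx
        while lo > 0 and not row[lo - 1]:
            lo -= 1
        hi = fa_idx
        while hi < row.size - 1 and not row[hi + 1]:
            hi += 1
        island_um = (hi - lo + 1) * config.lateral_pitch_um
    return extent_um, island_um, foveal_involved


def ort_deficit_map(
    config: SimulationConfig, severity: str, ez: EnfaceEZMap
) -> np.ndarray:
    """Outer-retinal thinning field (um) induced by the lesion.

    The binary lesion is blurred with a ~250 um Gaussian halo and scaled
    so its peak equals the group's deficit amplitude: thinning extends
    beyond the EZ-loss boundary, as mild toxicity thins the outer retina
    before frank EZ loss appears.
    """
    amp = _ORT_DEFICIT_UM[severity]
    if amp == 0.0 or not np.any(ez.loss):
        return np.zeros(ez.enface_shape, dtype=np.float64)
    sigma = (
        _DEFICIT_HALO_SIGMA_UM / config.bscan_spacing_um,
        _DEFICIT_HALO_SIGMA_UM / config.lateral_pitch_um,
    )
    halo = gaussian_filter(ez.loss.astype(np.float64), sigma=sigma, mode="constant")
    return amp * halo / halo.max()


def generate_layer_surfaces(
    config: SimulationConfig,
    severity: str,
    rng: np.random.Generator,
    ez: EnfaceEZMap | None = None,
) -> tuple[LayerSurfaces, np.ndarray]:
    """Generate smooth ILM/OPL/RPE depth maps for one eye.

    Returns ``(surfaces, ort_deficit_um)``.  The ILM carries a foveal pit;
    the outer retina is thinned by the lesion's deficit field.  When no EZ
    map is supplied one is drawn internally for the given severity (the
    cohort generator always passes the eye's actual map so the two stay
    consistent).
    """
    nb, depth, nw = config.volume_shape
    if ez is None:
        ez = generate_ez_loss_map(config, severity, rng)
    if ez.enface_shape != (nb, nw):
        raise ValueError("EZ map does not match the configured en-face lattice")

    rows, cols = _enface_coords_um(config)
    yy = rows[:, None]
    xx = cols[None, :]
    r2 = yy * yy + xx * xx

    # gentle anatomical variation fields (low-order cosines, random phase)
    def anat(amp_range: tuple[float, float]) -> np.ndarray:
        amp = rng.uniform(*amp_range)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        return amp * np.cos(2 * np.pi * yy / (rows[-1] - rows[0] + 1e-9) + ph1) * np.cos(
            2 * np.pi * xx / (cols[-1] - cols[0] + 1e-9) + ph2
        )

    rpe_um = 0.70 * depth * config.axial_pitch_um + anat((4.0, 10.0))
    deficit = ort_deficit_map(config, severity, ez)
    ort_um = 160.0 + anat((4.0, 8.0)) - deficit
    inner_um = 170.0 - 140.0 * np.exp(-r2 / (2 * 500.0**2)) + anat((3.0, 6.0))

    rpe = rpe_um / config.axial_pitch_um
    opl = rpe - ort_um / config.axial_pitch_um
    ilm = opl - inner_um / config.axial_pitch_um
    if ilm.min() < 2.0 or rpe.max() > depth - 3:
        raise ValueError(
            "volume depth too small to contain the retinal model; "
            "increase depth_px or reduce axial_pitch_um"
        )
    return LayerSurfaces(ilm=ilm, opl=opl, rpe=rpe), deficit


# ---------------------------------------------------------------------------
# forward image model


_REFLECTIVITY = {
    "vitreous": 12.0,
    "ilm_line": 180.0,
    "inner": 90.0,
    "inl": 40.0,
    "onl": 45.0,
    "ez_band": 210.0,
    "ez_lost": 50.0,
    "rpe": 230.0,
    "below": 25.0,
}

#: EZ band position: top edge this many pixels above the RPE surface.
_EZ_OFFSET_PX = 8.0
_EZ_THICKNESS_PX = 2.0


def render_volume(
    surfaces: LayerSurfaces,
    ez: EnfaceEZMap,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> OctVolume:
    """Render a reflectivity volume from surfaces and the EZ map.

    Hyperreflective ILM/EZ/RPE lines over hyporeflective nuclear layers;
    the EZ band is suppressed where the loss map is set.  Multiplicative
    gamma speckle (unit mean, shape ``speckle_shape``) and an independent
    per-B-scan gain factor with SD ``gain_jitter_sd`` are applied on top.
    """
    nb, depth, nw = config.volume_shape
    if surfaces.enface_shape != (nb, nw) or ez.enface_shape != (nb, nw):
        raise ValueError("surfaces/EZ map do not match the configured lattice")

    d = np.arange(depth, dtype=np.float64)[None, :, None]
    ilm = surfaces.ilm[:, None, :]
    opl = surfaces.opl[:, None, :]
    rpe = surfaces.rpe[:, None, :]
    ez_top = rpe - _EZ_OFFSET_PX
    loss = ez.loss.astype(bool)[:, None, :]

    R = _REFLECTIVITY
    ez_val = np.where(loss, R["ez_lost"], R["ez_band"])
    template = np.select(
        [
            np.abs(d - ilm) <= 1.0,
            d < ilm,
            d < opl - 8.0,
            d < opl - 3.0,  # inner nuclear layer: darkest band, inner retina only
            d < ez_top,
            d < ez_top + _EZ_THICKNESS_PX,
            d < rpe - 2.0,
            d <= rpe + 2.0,
        ],
        [
            np.broadcast_to(R["ilm_line"], (nb, depth, nw)),
            np.broadcast_to(R["vitreous"], (nb, depth, nw)),
            np.broadcast_to(R["inner"], (nb, depth, nw)),
            np.broadcast_to(R["inl"], (nb, depth, nw)),
            np.broadcast_to(R["onl"], (nb, depth, nw)),
            np.broadcast_to(ez_val, (nb, depth, nw)),
            np.broadcast_to(R["onl"], (nb, depth, nw)),
            np.broadcast_to(R["rpe"], (nb, depth, nw)),
        ],
        default=R["below"],
    )

    out = template
    if config.speckle_shape is not None:
        k = config.speckle_shape
        out = out * rng.gamma(shape=k, scale=1.0 / k, size=out.shape)
    if config.gain_jitter_sd > 0:
        gains = 1.0 + config.gain_jitter_sd * rng.standard_normal(nb)
        gains = np.clip(gains, 0.05, None)
        out = out * gains[:, None, None]

    return OctVolume(
        intensity=out,
        axial_pitch_um=config.axial_pitch_um,
        lateral_pitch_um=config.lateral_pitch_um,
        bscan_spacing_um=config.bscan_spacing_um,
        laterality="OD",
        fovea=config.fovea,
    )


# ---------------------------------------------------------------------------
# functional tests


def simulate_visual_field(
    ez: EnfaceEZMap,
    ort_deficit_um_map: np.ndarray,
    sf: GroundTruthSF,
    masks: list[scaffold.LocusMask],
    grid: scaffold.HvfGrid,
    rng: np.random.Generator,
    pd_threshold_db: float = 5.0,
) -> tuple[HvfMeasurement, np.ndarray]:
    """Generate a 10-2 measurement from the ground-truth rule.

    Per locus:  ``S = s0 - ecc_slope*ecc - beta_ez*EZfrac - beta_ort*dORT
    + N(0, noise_sd)`` where EZfrac and dORT are averaged over the same
    288-um scaffold masks the extraction pipeline uses.  The pattern-
    deviation flag is set where the *noise-free* pathological deficit
    (beta_ez*EZfrac + beta_ort*dORT) reaches ``pd_threshold_db``,
    standing in for the instrument's P < 2% normative flag.  MD is the
    mean deviation from the age-normal template ``s0 - ecc_slope*ecc``
    and PSD the sample SD of those deviations.

    Returns the measurement and the noise-free sensitivities.
    """
    ecc = grid.eccentricity_deg
    ez_frac = np.zeros(grid.n_loci)
    dort = np.zeros(grid.n_loci)
    for m in masks:
        if m.valid:
            ez_frac[m.locus_id] = scaffold.ez_fraction(ez, m)
            dort[m.locus_id] = float(
                np.mean(ort_deficit_um_map[m.positions[:, 0], m.positions[:, 1]])
            )
    deficit = sf.beta_ez * ez_frac + sf.beta_ort * dort
    template = sf.s0 - sf.ecc_slope * ecc
    noise_free = template - deficit
    noise = (
        rng.normal(0.0, sf.noise_sd, size=grid.n_loci) if sf.noise_sd > 0 else 0.0
    )
    observed = noise_free + noise
    deviations = observed - template
    hvf = HvfMeasurement(
        sensitivity_db=observed,
        pd_abnormal=deficit >= pd_threshold_db,
        md_db=float(np.mean(deviations)),
        psd_db=float(np.std(deviations, ddof=1)),
    )
    return hvf, noise_free


@dataclass(frozen=True)
class MfergNormative:
    """Normative means and limits for the synthetic mfERG model."""

    ring_means: tuple[float, ...] = (120.0, 60.0, 40.0, 30.0, 25.0)
    noise_sd: float = 0.05  # log-normal sigma on each amplitude
    r1_lower_limit: float = 100.0
    r1_r2_upper_limit: float = 2.4


#: Ring territories (degrees of eccentricity) for R1..R5.
_MFERG_RING_EDGES_DEG = (0.0, 1.5, 4.5, 8.0, 13.0, 20.0)

#: Amplitude reduction per unit loss fraction (capped at 90% reduction);
#: steep on purpose so even thin parafoveal lesions shift R1/R2 past the
#: normative limit, mirroring the disproportionate parafoveal attenuation
#: used as objective evidence of toxicity.
_MFERG_LOSS_COEF = 3.0


def simulate_mferg(
    ez: EnfaceEZMap,
    config: SimulationConfig,
    rng: np.random.Generator,
    normative: MfergNormative | None = None,
) -> MfergRings:
    """Ring amplitudes attenuated by the EZ-loss area in each ring territory."""
    norm = normative or MfergNormative()
    rows, cols = _enface_coords_um(config)
    r_deg = np.hypot(rows[:, None], cols[None, :]) / config.um_per_degree
    amps = []
    for k in range(5):
        band = (r_deg >= _MFERG_RING_EDGES_DEG[k]) & (r_deg < _MFERG_RING_EDGES_DEG[k + 1])
        n_band = np.count_nonzero(band)
        frac = float(np.count_nonzero(ez.loss[band])) / n_band if n_band else 0.0
        atten = max(1.0 - _MFERG_LOSS_COEF * frac, 0.1)
        noise = np.exp(rng.normal(0.0, norm.noise_sd)) if norm.noise_sd > 0 else 1.0
        amps.append(norm.ring_means[k] * atten * noise)
    return MfergRings(np.array(amps))


# ---------------------------------------------------------------------------
# cohort assembly


def generate_eye(
    config: SimulationConfig,
    severity: str,
    patient_id: str,
    laterality: str,
    rng: np.random.Generator,
    grid: scaffold.HvfGrid | None = None,
) -> EyeRecord:
    """Generate one complete synthetic eye."""
    grid = grid or scaffold.build_hvf10_2_grid()
    ez = generate_ez_loss_map(config, severity, rng)
    surfaces, deficit = generate_layer_surfaces(config, severity, rng, ez=ez)

    volume: OctVolume | None = None
    if config.render_volumes:
        volume = render_volume(surfaces, ez, config, rng)
        volume = replace(volume, laterality=laterality)

    geom = scaffold.EnfaceGeometry(
        n_bscans=config.volume_shape[0],
        width_px=config.volume_shape[2],
        bscan_spacing_um=config.bscan_spacing_um,
        lateral_pitch_um=config.lateral_pitch_um,
        fovea=config.fovea,
        laterality=laterality,
    )
    masks = scaffold.register_grid(
        grid, geom, spot_diameter_um=scaffold.SPOT_DIAMETER_UM,
        um_per_degree=config.um_per_degree,
    )
    hvf, noise_free = simulate_visual_field(
        ez, deficit, config.sf_params, masks, grid, rng,
        pd_threshold_db=config.pd_threshold_db,
    )
    mferg = simulate_mferg(ez, config, rng)

    ez_frac = np.array(
        [scaffold.ez_fraction(ez, m) if m.valid else np.nan for m in masks]
    )
    dort = np.array(
        [
            float(np.mean(deficit[m.positions[:, 0], m.positions[:, 1]]))
            if m.valid
            else np.nan
            for m in masks
        ]
    )
    return EyeRecord(
        eye_id=f"{patient_id}_{laterality}",
        patient_id=patient_id,
        laterality=laterality,
        severity_group=severity,
        volume=volume,
        surfaces=surfaces,
        ez_map=ez,
        hvf=hvf,
        mferg=mferg,
        true_sensitivity_db=noise_free,
        true_ez_frac=ez_frac,
        true_ort_deficit_um=dort,
    )


_MILDER = {"4": "3", "3": "2", "2": "1", "1": "unaffected", "unaffected": "unaffected"}


def generate_cohort(config: SimulationConfig) -> list[PatientRecord]:
    """Generate the full cohort, reproducibly from ``config.seed``.

    Each patient gets two eyes of their severity group; with probability
    ``asymmetric_fraction`` the left eye is one group milder.  Every eye
    draws from its own seed stream so cohorts are stable under reordering.
    """
    if sum(config.n_patients_per_group.values()) == 0:
        raise ValueError("cohort is empty: all patient counts are zero")
    grid = scaffold.build_hvf10_2_grid()
    root = np.random.SeedSequence(config.seed)
    patients: list[PatientRecord] = []
    idx = 0
    for group in SEVERITY_GROUPS:
        for _ in range(config.n_patients_per_group.get(group, 0)):
            pid = f"P{idx:03d}"
            pss = root.spawn(1)[0]
            p_rng = np.random.default_rng(pss)
            os_group = group
            if group != "unaffected" and p_rng.random() < config.asymmetric_fraction:
                os_group = _MILDER[group]
            eyes = []
            for lat, g in (("OD", group), ("OS", os_group)):
                eye_rng = np.random.default_rng(pss.spawn(1)[0])
                eyes.append(
                    generate_eye(config, g, pid, lat, eye_rng, grid=grid)
                )
            patients.append(PatientRecord(patient_id=pid, eyes=eyes))
            idx += 1
    return patients


def iter_eyes(patients: list[PatientRecord]):
    for p in patients:
        yield from p.eyes
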