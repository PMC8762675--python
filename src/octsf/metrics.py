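"""Volume preprocessing and per-A-scan thickness / intensity metrics.

The preprocessing chain follows the order smooth -> normalize -> measure:
an edge-preserving bilateral filter suppresses speckle on each B-scan,
then the whole volume is rescaled so the mean inner-retina (ILM->OPL)
intensity matches a fixed target, which removes per-acquisition gain
differences before any intensity metric is read out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import LayerSurfaces, OctVolume

DEFAULT_TARGET_INNER_MEAN = 100.0


try:  # optional JIT path; the numpy fallback is exact but slower
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None


def _bilateral_numpy(
    image: np.ndarray, spatial_sigma: float, range_sigma: float, win_radius: int
) -> np.ndarray:
    r = int(win_radius)
    pad = [(0, 0)] * (image.ndim - 2) + [(r, r), (r, r)]
    padded = np.pad(image, pad, mode="edge")
    acc = np.zeros_like(image)
    wsum = np.zeros_like(image)
    h, w = image.shape[-2:]
    inv2ss = 1.0 / (2.0 * spatial_sigma**2)
    inv2sr = 1.0 / (2.0 * range_sigma**2)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            ws = np.exp(-(dy * dy + dx * dx) * inv2ss)
            shifted = padded[..., r + dy : r + dy + h, r + dx : r + dx + w]
            wgt = ws * np.exp(-((shifted - image) ** 2) * inv2sr)
            acc += wgt * shifted
            wsum += wgt
    return acc / wsum


if _numba is not None:

    @_numba.njit(cache=True, fastmath=False)
    def _bilateral_jit(padded, h, w, r, spatial_kernel, range_lut, lut_scale):
        out = np.empty((padded.shape[0], h, w))
        n_lut = range_lut.size
        for b in range(padded.shape[0]):
            for i in range(h):
                for j in range(w):
                    center = padded[b, i + r, j + r]
                    acc = 0.0
                    wsum = 0.0
                    for dy in range(2 * r + 1):
                        for dx in range(2 * r + 1):
                            v = padded[b, i + dy, j + dx]
                            idx = int(abs(v - center) * lut_scale)
                            if idx >= n_lut:
                                idx = n_lut - 1
                            wgt = spatial_kernel[dy, dx] * range_lut[idx]
                            acc += wgt * v
                            wsum += wgt
                    out[b, i, j] = acc / wsum
        return out


def bilateral_filter(
    image: np.ndarray,
    spatial_sigma: float,
    range_sigma: float,
    win_radius: int = 4,
) -> np.ndarray:
    """Edge-preserving bilateral filter over the last two axes.

    Classic formulation: each pixel is replaced by a weighted mean of its
    window, with Gaussian weights in both space and intensity, so genuine
    edges (intensity steps >> ``range_sigma``) are preserved while
    speckle is averaged away.  Borders use edge replication.  The window
    and the intensity weighting are symmetric, so the filter commutes
    with image mirroring.

    The fast path quantises the intensity Gaussian into a fine lookup
    table (8192 bins over 6 sigma); the quantisation step is << the
    weight curvature, and both paths agree to ~1e-3 relative.
    """
    image = np.asarray(image, dtype=np.float64)
    if spatial_sigma <= 0 or range_sigma <= 0:
        raise ValueError("sigmas must be positive")
    squeeze = image.ndim == 2
    if squeeze:
        image = image[None]
    if _numba is None:
        out = _bilateral_numpy(image, spatial_sigma, range_sigma, win_radius)
        return out[0] if squeeze else out
    r = int(win_radius)
    offs = np.arange(-r, r + 1, dtype=np.float64)
    spatial_kernel = np.exp(
        -(offs[:, None] ** 2 + offs[None, :] ** 2) / (2.0 * spatial_sigma**2)
    )
    n_lut = 8192
    max_diff = 6.0 * range_sigma
    diffs = np.linspace(0.0, max_diff, n_lut)
    range_lut = np.exp(-(diffs**2) / (2.0 * range_sigma**2))
    lut_scale = (n_lut - 1) / max_diff
    padded = np.pad(image, [(0, 0), (r, r), (r, r)], mode="edge")
    h, w = image.shape[-2:]
    out = _bilateral_jit(padded, h, w, r, spatial_kernel, range_lut, lut_scale)
    return out[0] if squeeze else out


@dataclass
class AscanMetricMaps:
    """En-face maps of the six per-A-scan OCT metrics.

    TRT/ORT are in micrometres; the four intensity maps are in the
    (normalized) intensity units of the input volume.  TR (total retina)
    spans ILM->RPE, OR (outer retina) spans OPL->RPE.
    """

    trt_um: np.ndarray
    ort_um: np.ndarray
    tr_meani: np.ndarray
    or_meani: np.ndarray
    tr_mini: np.ndarray
    or_mini: np.ndarray

    def __post_init__(self) -> None:
        shp = self.trt_um.shape
        for name in ("ort_um", "tr_meani", "or_meani", "tr_mini", "or_mini"):
            if getattr(self, name).shape != shp:
                raise ValueError("metric maps must share one en-face shape")
        if np.any(self.ort_um < 0) or np.any(self.trt_um < self.ort_um):
            raise ValueError("expected TRT >= ORT >= 0")


def smooth_volume(
    vol: OctVolume,
    spatial_sigma: float = 3.0,
    range_sigma: float | None = None,
    win_radius: int = 4,
) -> OctVolume:
    """Bilateral-filter each B-scan independently (2-D, edge preserving).

    ``range_sigma`` defaults to 10% of the volume's 99th-percentile
    intensity.  Filtering is per B-scan because the lattice is strongly
    anisotropic (B-scan spacing >> in-plane pitch).
    """
    if spatial_sigma <= 0:
        raise ValueError("spatial_sigma must be positive")
    data = vol.intensity
    if range_sigma is None:
        range_sigma = 0.1 * float(np.percentile(data, 99))
    if range_sigma <= 0:
        raise ValueError("range_sigma must be positive")
    out = bilateral_filter(data, spatial_sigma, range_sigma, win_radius=win_radius)
    return vol.with_intensity(out)


def _window_stats_py(data, lo, hi):
    """Sequential-order mean/min per A-scan over the closed depth window.

    Left-to-right accumulation keeps the result bit-identical to a naive
    per-voxel loop, so exact-equality oracles hold.
    """
    nb, _, nw = data.shape
    meani = np.empty((nb, nw))
    mini = np.empty((nb, nw))
    for b in range(nb):
        for j in range(nw):
            s = 0.0
            mn = np.inf
            for d in range(lo[b, j], hi[b, j] + 1):
                v = data[b, d, j]
                s += v
                if v < mn:
                    mn = v
            meani[b, j] = s / (hi[b, j] - lo[b, j] + 1)
            mini[b, j] = mn
    return meani, mini


if _numba is not None:
    _window_stats = _numba.njit(cache=True)(_window_stats_py)
else:  # pragma: no cover
    _window_stats = _window_stats_py


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=np.float64) + 0.5).astype(np.int64)


def _inner_retina_mask(vol: OctVolume, surf: LayerSurfaces) -> np.ndarray:
    depth_idx = np.arange(vol.depth_px)[None, :, None]
    lo = _round_half_up(surf.ilm)[:, None, :]
    hi = _round_half_up(surf.opl)[:, None, :]
    return (depth_idx >= lo) & (depth_idx <= hi)


def mean_inner_intensity(vol: OctVolume, surf: LayerSurfaces) -> float:
    """Mean intensity over the inner-retina (ILM->OPL) slab."""
    mask = _inner_retina_mask(vol, surf)
    return float(vol.intensity[mask].mean())


def normalize_intensity(
    vol: OctVolume,
    surf: LayerSurfaces,
    target_mean: float = DEFAULT_TARGET_INNER_MEAN,
) -> OctVolume:
    """Scale the volume so the mean inner-retina intensity equals ``target_mean``.

    A single multiplicative factor is applied to every voxel, making the
    operation idempotent and invariant to any prior global gain.
    """
    inner_mean = mean_inner_intensity(vol, surf)
    if inner_mean <= 1e-12 * target_mean:
        raise ValueError("inner-retina mean intensity is degenerate (~0)")
    return vol.with_intensity(vol.intensity * (target_mean / inner_mean))


def compute_ascan_metrics(vol: OctVolume, surf: LayerSurfaces) -> AscanMetricMaps:
    """Thickness and intensity metrics for every A-scan.

    Thicknesses use the sub-pixel surfaces directly:
    ``TRT = (rpe - ilm) * axial_pitch`` and ``ORT = (rpe - opl) * axial_pitch``.
    Intensity statistics are taken over voxels whose depth index lies in
    the closed window between the surfaces rounded to the nearest voxel
    (half-up); the total-retina window therefore contains the outer-retina
    window at every A-scan.
    """
    if surf.enface_shape != (vol.n_bscans, vol.width_px):
        raise ValueError("surfaces do not match the volume's en-face lattice")
    ilm_r = _round_half_up(surf.ilm)
    opl_r = _round_half_up(surf.opl)
    rpe_r = _round_half_up(surf.rpe)
    if ilm_r.min() < 0 or rpe_r.max() >= vol.depth_px:
        raise ValueError("surfaces fall outside the volume depth range")

    trt = (surf.rpe - surf.ilm) * vol.axial_pitch_um
    ort = (surf.rpe - surf.opl) * vol.axial_pitch_um

    data = vol.intensity
    tr_meani, tr_mini = _window_stats(data, ilm_r, rpe_r)
    or_meani, or_mini = _window_stats(data, opl_r, rpe_r)
    return AscanMetricMaps(
        trt_um=trt,
        ort_um=ort,
        tr_meani=tr_meani,
        or_meani=or_meani,
        tr_mini=tr_mini,
        or_mini=or_mini,
    )
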