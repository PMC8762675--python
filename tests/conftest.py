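import numpy as np
import pytest

from octsf import extract, scaffold, simulate


@pytest.fixture(scope="session")
def grid():
    return scaffold.build_hvf10_2_grid()


@pytest.fixture(scope="session")
def reduced_cfg():
    return simulate.reduced_config(seed=1)


@pytest.fixture(scope="session")
def reduced_cohort(reduced_cfg):
    return simulate.generate_cohort(reduced_cfg)


@pytest.fixture(scope="session")
def reduced_features(reduced_cohort, reduced_cfg, grid):
    return extract.extract_cohort_features(reduced_cohort, reduced_cfg, grid=grid)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_volume(
    intensity,
    axial_pitch_um=3.87,
    lateral_pitch_um=22.5,
    bscan_spacing_um=120.0,
    laterality="OD",
    fovea=None,
):
    """Small helper to wrap raw arrays into an OctVolume."""
    from octsf.types import OctVolume

    intensity = np.asarray(intensity, dtype=float)
    nb, _, nw = intensity.shape
    if fovea is None:
        fovea = ((nb - 1) / 2.0, (nw - 1) / 2.0)
    return OctVolume(
        intensity=intensity,
        axial_pitch_um=axial_pitch_um,
        lateral_pitch_um=lateral_pitch_um,
        bscan_spacing_um=bscan_spacing_um,
        laterality=laterality,
        fovea=fovea,
    )
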