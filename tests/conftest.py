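import numpy as np
import pytest

from myoatlas import (build_reference_geometry, make_annulus_study,
                      make_wedge_study)


@pytest.fixture(scope="session")
def ref_small():
    """Miniature reference geometry used throughout the cohort tests."""
    return build_reference_geometry(endo_radius=12, epi_radius=19,
                                    n_slices=11, grid_size=44,
                                    apex_scale=0.45)


@pytest.fixture(scope="session")
def annulus_study():
    return make_annulus_study(endo_radius=10, epi_radius=20, grid_size=64,
                              n_slices=9, junction_angle_deg=90)


@pytest.fixture(scope="session")
def wedge_study():
    return make_wedge_study()


def analytic_polar(grid_size: int, oversample: int):
    """(rho, theta) of the oversampled pixel centers about the grid center."""
    half = (grid_size - 1) / 2.0
    coarse = (np.arange(grid_size * oversample) - (oversample - 1) / 2.0) \
        / oversample
    ys, xs = np.meshgrid(coarse, coarse, indexing="ij")
    rho = np.hypot(xs - half, ys - half)
    theta = np.arctan2(-(ys - half), xs - half)
    return rho, theta


def circular_abs_diff(a, b):
    d = np.abs(np.asarray(a) - np.asarray(b)) % 1.0
    return np.minimum(d, 1.0 - d)
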