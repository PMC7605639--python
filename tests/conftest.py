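import numpy as np
import pytest

from ecotone import CovariateStack, Grid, GridGeometry, PairSpec, VegetationOccurrence


@pytest.fixture
def small_geometry():
    return GridGeometry(origin_x=0.0, origin_y=10.0, cell_size=1.0,
                        n_rows=10, n_cols=10, crs_tag="test")


@pytest.fixture
def pair():
    return PairSpec("II", "Pinus massoniana forest", "Pinus tabuliformis forest")


@pytest.fixture
def gradient_stack(small_geometry):
    """Two-layer stack: a north-south gradient and a constant layer."""
    rows = np.arange(10, dtype=float)[:, None] * np.ones((1, 10))
    return CovariateStack({
        "grad": Grid(rows, small_geometry),
        "flat": Grid(np.full((10, 10), 5.0), small_geometry),
    })


@pytest.fixture
def split_occurrence(small_geometry, pair):
    """Top half temperate (1), bottom half subtropical (0), all observed."""
    labels = np.where(np.arange(10)[:, None] < 5, 1, 0) * np.ones((1, 10), dtype=int)
    return VegetationOccurrence(labels, pair, small_geometry)


def brute_force_q(y, h):
    """Independent eta-squared oracle: 1 - SSW/SST via explicit loops."""
    y = np.asarray(y, dtype=float)
    h = np.asarray(h)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    if sst == 0:
        return 0.0
    ssw = 0.0
    for stratum in np.unique(h):
        sub = y[h == stratum]
        ssw += float(((sub - sub.mean()) ** 2).sum())
    return 1.0 - ssw / sst
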