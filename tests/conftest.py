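"""Shared fixtures: tiny grids, mask builders and fast phantom configs."""

import numpy as np
import pytest

from smritrack import BinaryMask, GridGeometry, MetaboliteMap, PhantomConfig


@pytest.fixture
def geom() -> GridGeometry:
    return GridGeometry((10, 10, 10), (1.0, 1.0, 1.0))


@pytest.fixture
def mask_factory(geom):
    def build(indices, label="GROUND_TRUTH", geometry=None):
        g = geometry or geom
        values = np.zeros(g.shape, dtype=bool)
        for idx in indices:
            values[tuple(idx)] = True
        return BinaryMask(label, values, g)

    return build


@pytest.fixture
def map_factory(geom):
    def build(values, metabolite="CHO", coverage=None, geometry=None):
        g = geometry or geom
        vals = np.full(g.shape, float(values)) if np.isscalar(values) else values
        cov = np.ones(g.shape, dtype=bool) if coverage is None else coverage
        vals = np.where(cov, vals, np.nan)
        return MetaboliteMap(metabolite, vals, cov, g)

    return build


# small phantom: ~7x faster per timepoint than the 64^3 default
SMALL_PHANTOM = dict(
    grid_shape=(36, 36, 36),
    voxel_spacing_mm=(3.0, 3.0, 3.0),
    brain_semi_axes_mm=(46.0, 50.0, 44.0),
    tumor_center_mm=(-20.0, 4.0, 2.0),
    tumor_radius_mm=10.0,
    coverage_erosion_mm=4.0,
)


@pytest.fixture
def small_config() -> PhantomConfig:
    return PhantomConfig(**SMALL_PHANTOM, noise_sd=0.1, seed=1)


@pytest.fixture
def noiseless_config() -> PhantomConfig:
    return PhantomConfig(**SMALL_PHANTOM, noise_sd=0.0, seed=1)
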