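import numpy as np
import pytest

from biomeshift import (
    BiomeGrid,
    BiomeScheme,
    GridGeometry,
    build_area_vector,
)


@pytest.fixture(scope="session")
def scheme():
    return BiomeScheme.default()


@pytest.fixture
def geom_small():
    """Global-closure 10x20 grid with 18-degree cells."""
    return GridGeometry(n_lat=10, n_lon=20, lat_step=18, lon_step=18,
                        origin=(81.0, -171.0))


@pytest.fixture
def geom_half_row():
    """Single equatorial row of four equal-area 90-degree cells."""
    return GridGeometry(n_lat=1, n_lon=4, lat_step=1.0, lon_step=90.0,
                        origin=(0.0, -135.0))


@pytest.fixture
def areas_small(geom_small):
    return build_area_vector(geom_small)


def make_grid(geometry, codes, label="2000-2020", level="biome"):
    return BiomeGrid(geometry=geometry,
                     codes=np.asarray(codes, dtype=np.int16),
                     slice_label=label, level=level)


@pytest.fixture
def grid_factory():
    return make_grid


def random_scheme_grid(rng, geometry, scheme, n_codes=6, sentinel_fraction=0.2,
                       label="2000-2020"):
    """Random biome-level grid using real scheme codes plus sentinel holes."""
    codes = rng.choice(scheme.biome_codes[:n_codes], size=geometry.shape)
    holes = rng.random(geometry.shape) < sentinel_fraction
    codes = np.where(holes, -1, codes).astype(np.int16)
    return make_grid(geometry, codes, label=label)
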