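from __future__ import annotations

import numpy as np
import pytest

from deforheat.forest_change import PixelClass, PixelClassMap
from deforheat.raster import GridSpec, Raster
from deforheat.surface_change import DeltaT
from deforheat.synthetic import TrendSpec, WorldParams, generate_world


def make_grid(n_rows: int = 40, n_cols: int = 40, res_arcsec: float = 36.0,
              lat_min: float = -0.2, lon_min: float = 0.0) -> GridSpec:
    res = res_arcsec / 3600.0
    return GridSpec(res_arcsec, lat_min, lat_min + n_rows * res,
                    lon_min, lon_min + n_cols * res)


def class_map(grid: GridSpec, codes: np.ndarray) -> PixelClassMap:
    return PixelClassMap(Raster(grid, np.asarray(codes, dtype=np.int16)))


def uniform_scene(grid: GridSpec, dt_value: float = 0.5, elev_value: float = 100.0):
    """All-control scene: every pixel NON_DEFORESTED with constant ΔT/elevation."""
    codes = np.full(grid.shape, int(PixelClass.NON_DEFORESTED), dtype=np.int16)
    dt = DeltaT(Raster(grid, np.full(grid.shape, dt_value)))
    elev = Raster(grid, np.full(grid.shape, elev_value))
    return class_map(grid, codes), dt, elev


def small_params(seed: int = 0, **overrides) -> WorldParams:
    defaults = dict(
        grid=make_grid(),
        seed=seed,
        beta=0.02,
        trend=TrendSpec("constant", 0.3),
        noise_sigma=0.0,
        n_clusters=4,
        cluster_radius_deg=0.04,
        n_gain_patches=0,
        n_regions=2,
        admins_per_region=2,
    )
    defaults.update(overrides)
    return WorldParams(**defaults)


@pytest.fixture(scope="session")
def small_world():
    """Noiseless 40x40 world with uniform background trend."""
    return generate_world(small_params(0))


@pytest.fixture(scope="session")
def noisy_world():
    return generate_world(small_params(7, noise_sigma=0.2))


@pytest.fixture(scope="session")
def medium_world():
    """120x120 world used by pipeline-level tests."""
    return generate_world(
        small_params(3, grid=make_grid(120, 120), n_clusters=8, n_gain_patches=1)
    )
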