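"""Grid data model, raster I/O, regridding and area weighting.

All rasters live on regular geographic (lat/lon) grids with cell-center
registration: a :class:`GridSpec` spans half-open cells
``[lat, lat + res) x [lon, lon + res)`` and cell centers sit at
``edge + res / 2``.  Row 0 is the southernmost row.  Missing data is
carried as an explicit boolean mask (``True`` = missing) alongside a
float value array.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import xarray as xr
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridSpec",
    "Raster",
    "AreaWeights",
    "RasterError",
    "cell_area_weights",
    "cell_band_areas",
    "read_raster",
    "write_raster",
    "regrid_bilinear",
    "regrid_area_weighted",
]

_ARCSEC_PER_DEG = 3600.0


class RasterError(ValueError):
    """Raised for invalid grids, mismatched rasters or unreadable files."""


def _count_cells(span: float, res_deg: float) -> int:
    n = span / res_deg
    n_int = round(n)
    if abs(n - n_int) > 1e-9 * max(1.0, abs(n)) or n_int < 1:
        raise RasterError(
            f"grid span {span} deg is not an integral multiple of the "
            f"resolution {res_deg} deg"
        )
    return int(n_int)


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid with cell-center registration.

    Parameters
    ----------
    resolution_arcsec:
        Angular cell size in arc-seconds (30 for the nominal analysis grid).
    lat_min, lat_max, lon_min, lon_max:
        Outer cell-edge bounds in decimal degrees.
    """

    resolution_arcsec: float
    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise RasterError(f"invalid latitude bounds [{self.lat_min}, {self.lat_max}]")
        if not (-180.0 <= self.lon_min < self.lon_max <= 180.0):
            raise RasterError(f"invalid longitude bounds [{self.lon_min}, {self.lon_max}]")
        if self.resolution_arcsec <= 0:
            raise RasterError("resolution must be positive")
        # validate integral cell counts eagerly
        _count_cells(self.lat_max - self.lat_min, self.res_deg)
        _count_cells(self.lon_max - self.lon_min, self.res_deg)

    @property
    def res_deg(self) -> float:
        return self.resolution_arcsec / _ARCSEC_PER_DEG

    @property
    def n_rows(self) -> int:
        return _count_cells(self.lat_max - self.lat_min, self.res_deg)

    @property
    def n_cols(self) -> int:
        return _count_cells(self.lon_max - self.lon_min, self.res_deg)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def lat_centers(self) -> np.ndarray:
        r = self.res_deg
        return self.lat_min + r * (np.arange(self.n_rows) + 0.5)

    @property
    def lon_centers(self) -> np.ndarray:
        r = self.res_deg
        return self.lon_min + r * (np.arange(self.n_cols) + 0.5)

    @property
    def lat_edges(self) -> np.ndarray:
        return self.lat_min + self.res_deg * np.arange(self.n_rows + 1)

    @property
    def lon_edges(self) -> np.ndarray:
        return self.lon_min + self.res_deg * np.arange(self.n_cols + 1)

    @classmethod
    def tropics(cls, resolution_arcsec: float = 30.0) -> "GridSpec":
        """The default study domain, 25°S–25°N, all longitudes."""
        return cls(resolution_arcsec, -25.0, 25.0, -180.0, 180.0)

    @classmethod
    def from_centers(cls, lat: np.ndarray, lon: np.ndarray) -> "GridSpec":
        """Reconstruct a grid from 1-D cell-center coordinate arrays."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        if lat.ndim != 1 or lon.ndim != 1 or lat.size < 1 or lon.size < 1:
            raise RasterError("coordinate arrays must be 1-D and non-empty")
        steps = []
        for c in (lat, lon):
            if c.size > 1:
                d = np.diff(c)
                if not np.allclose(d, d[0], rtol=0, atol=1e-7):
                    raise RasterError("irregular grid: coordinate spacing is not constant")
                steps.append(d[0])
        if not steps:
            raise RasterError("cannot infer resolution from single-cell grids")
        if len(steps) == 2 and not np.isclose(steps[0], steps[1], rtol=0, atol=1e-7):
            raise RasterError("anisotropic grids are not supported")
        res = float(steps[0])
        if res <= 0:
            raise RasterError("coordinates must be ascending")
        return cls(
            resolution_arcsec=res * _ARCSEC_PER_DEG,
            lat_min=float(lat[0] - res / 2),
            lat_max=float(lat[-1] + res / 2),
            lon_min=float(lon[0] - res / 2),
            lon_max=float(lon[-1] + res / 2),
        )


@dataclass
class Raster:
    """A 2-D field on a :class:`GridSpec` with an explicit missing mask."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.mask is None:
            self.mask = np.zeros(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape:
            raise RasterError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if self.mask.shape != self.values.shape:
            raise RasterError("mask shape does not match values shape")

    @classmethod
    def full(cls, grid: GridSpec, fill: float = 0.0, dtype=np.float64) -> "Raster":
        return cls(grid, np.full(grid.shape, fill, dtype=dtype))

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def filled(self, fill: float = np.nan) -> np.ndarray:
        """Values with masked cells replaced by ``fill``."""
        out = self.values.astype(np.float64, copy=True)
        out[self.mask] = fill
        return out

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.mask.copy())

    def same_grid(self, other: "Raster") -> bool:
        return self.grid == other.grid

    def require_same_grid(self, other: "Raster", what: str = "raster") -> None:
        if not self.same_grid(other):
            raise RasterError(f"grid mismatch between operands ({what})")


@dataclass(frozen=True)
class AreaWeights:
    """Relative cell areas (dimensionless, mean 1) for a grid.

    Weights are proportional to cos(latitude of the cell center) and thus
    constant along any row.
    """

    grid: GridSpec
    weight: np.ndarray


def cell_area_weights(grid: GridSpec) -> AreaWeights:
    """Per-cell relative area weights, normalised to mean 1.

    Raises if the grid touches a pole, where the cosine weight degenerates.
    """
    if grid.lat_max >= 90.0 or grid.lat_min <= -90.0:
        raise RasterError("grids touching a pole are not supported by cosine weighting")
    w_row = np.cos(np.deg2rad(grid.lat_centers))
    w = np.repeat(w_row[:, None], grid.n_cols, axis=1)
    return AreaWeights(grid, w / w.mean())


def cell_band_areas(grid: GridSpec) -> np.ndarray:
    """Exact spherical band areas per cell (unit sphere, steradian x rad).

    Uses ``sin(top edge) - sin(bottom edge)`` per row, so summed areas are
    exactly additive under regridding; used by conservation checks.
    """
    lat_e = np.deg2rad(grid.lat_edges)
    band = np.sin(lat_e[1:]) - np.sin(lat_e[:-1])
    return np.repeat(band[:, None], grid.n_cols, axis=1) * np.deg2rad(grid.res_deg)


# ---------------------------------------------------------------------------
# I/O (NetCDF, CF-style lat/lon coordinate variables)
# ---------------------------------------------------------------------------

def write_raster(raster: Raster, path: str | Path, variable: str = "data") -> None:
    """Write a raster to NetCDF with CF-style ``lat``/``lon`` coordinates.

    Missing cells are stored as NaN (float data) or as the ``_FillValue``
    attribute (integer data); the on-disk dtype is the in-memory dtype, so
    a float64 field round-trips bit-exactly.
    """
    vals = raster.values
    if np.issubdtype(vals.dtype, np.integer):
        fill = np.iinfo(vals.dtype).min
        data = vals.copy()
        data[raster.mask] = fill
        da = xr.DataArray(
            data,
            dims=("lat", "lon"),
            coords={"lat": raster.grid.lat_centers, "lon": raster.grid.lon_centers},
            attrs={"_FillValue_int": int(fill)},
        )
    else:
        data = vals.astype(np.float64, copy=True)
        data[raster.mask] = np.nan
        da = xr.DataArray(
            data,
            dims=("lat", "lon"),
            coords={"lat": raster.grid.lat_centers, "lon": raster.grid.lon_centers},
        )
    ds = xr.Dataset({variable: da})
    ds.attrs["resolution_arcsec"] = raster.grid.resolution_arcsec
    ds.to_netcdf(path)


def read_raster(path: str | Path, variable: str = "data") -> Raster:
    """Read a single 2-D variable from a NetCDF file written by this package
    (or any file with regular 1-D ``lat``/``lon`` coordinates)."""
    path = Path(path)
    if not path.exists():
        raise RasterError(f"no such file: {path}")
    try:
        ds = xr.open_dataset(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise RasterError(f"unreadable raster file {path}: {exc}") from exc
    with ds:
        if variable not in ds:
            raise RasterError(
                f"variable {variable!r} not found in {path}; "
                f"available: {sorted(ds.data_vars)}"
            )
        da = ds[variable]
        if set(da.dims) != {"lat", "lon"}:
            raise RasterError(f"variable {variable!r} is not a 2-D lat/lon field")
        da = da.transpose("lat", "lon")
        grid = GridSpec.from_centers(da["lat"].values, da["lon"].values)
        vals = da.values
        if np.issubdtype(vals.dtype, np.integer):
            fill = da.attrs.get("_FillValue_int", np.iinfo(vals.dtype).min)
            mask = vals == fill
        else:
            vals = np.asarray(vals, dtype=np.float64)
            mask = np.isnan(vals)
        return Raster(grid, vals.copy(), mask)


# ---------------------------------------------------------------------------
# Regridding
# ---------------------------------------------------------------------------

def regrid_bilinear(src: Raster, dst_grid: GridSpec) -> Raster:
    """Bilinear interpolation onto ``dst_grid`` cell centers.

    Output cells are a convex combination of the four surrounding source
    cell centers; any masked contributor masks the output cell (no
    renormalisation).  Destination centers must lie within the convex hull
    of the source centers.
    """
    lat_s, lon_s = src.grid.lat_centers, src.grid.lon_centers
    lat_d, lon_d = dst_grid.lat_centers, dst_grid.lon_centers
    eps = 1e-9
    if (
        lat_d[0] < lat_s[0] - eps
        or lat_d[-1] > lat_s[-1] + eps
        or lon_d[0] < lon_s[0] - eps
        or lon_d[-1] > lon_s[-1] + eps
    ):
        raise RasterError("destination grid exceeds source coverage")
    lat_d = np.clip(lat_d, lat_s[0], lat_s[-1])
    lon_d = np.clip(lon_d, lon_s[0], lon_s[-1])

    vals = src.values.astype(np.float64, copy=True)
    vals[src.mask] = 0.0  # contaminated outputs get masked below
    interp = RegularGridInterpolator((lat_s, lon_s), vals, method="linear")
    mask_interp = RegularGridInterpolator(
        (lat_s, lon_s), src.mask.astype(np.float64), method="linear"
    )
    glat, glon = np.meshgrid(lat_d, lon_d, indexing="ij")
    pts = np.stack([glat.ravel(), glon.ravel()], axis=-1)
    out = interp(pts).reshape(dst_grid.shape)
    bad = mask_interp(pts).reshape(dst_grid.shape) > 1e-12
    return Raster(dst_grid, out, bad)


def _overlap_matrix(src_edges: np.ndarray, dst_edges: np.ndarray, spherical: bool) -> np.ndarray:
    """(n_dst, n_src) matrix of overlap measures between 1-D cell intervals.

    ``spherical`` uses sin-latitude band measure (exact spherical area per
    unit longitude); otherwise plain interval length.
    """
    lo = np.maximum(dst_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(dst_edges[1:, None], src_edges[None, 1:])
    if spherical:
        lo_r, hi_r = np.deg2rad(lo), np.deg2rad(hi)
        w = np.where(hi > lo, np.sin(hi_r) - np.sin(lo_r), 0.0)
    else:
        w = np.clip(hi - lo, 0.0, None)
    return w


def regrid_area_weighted(src: Raster, dst_grid: GridSpec) -> Raster:
    """Conservative (area-weighted mean) regrid of a strictly finer source.

    Each destination cell is the spherical-area-weighted mean of the source
    cells overlapping it; masked source cells are excluded; destination
    cells with no valid coverage are masked.
    """
    if src.grid.res_deg >= dst_grid.res_deg - 1e-12:
        raise RasterError(
            "source grid is not strictly finer than destination; "
            "use regrid_bilinear for downscaling"
        )
    eps = 1e-9
    if (
        dst_grid.lat_min < src.grid.lat_min - eps
        or dst_grid.lat_max > src.grid.lat_max + eps
        or dst_grid.lon_min < src.grid.lon_min - eps
        or dst_grid.lon_max > src.grid.lon_max + eps
    ):
        raise RasterError("destination grid exceeds source coverage")

    w_lat = _overlap_matrix(src.grid.lat_edges, dst_grid.lat_edges, spherical=True)
    w_lon = _overlap_matrix(src.grid.lon_edges, dst_grid.lon_edges, spherical=False)
    valid = src.valid.astype(np.float64)
    vals = np.where(src.mask, 0.0, src.values.astype(np.float64))
    num = w_lat @ (vals * valid) @ w_lon.T
    den = w_lat @ valid @ w_lon.T
    out_mask = den <= 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_mask, np.nan, num / np.where(out_mask, 1.0, den))
    return Raster(dst_grid, out, out_mask)
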