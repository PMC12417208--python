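"""Quality screening and compositing of land surface temperature stacks.

The input is a stack of 8-day (or monthly) land surface temperature (LST)
layers in kelvin, each paired with per-pixel QC fields (emissivity error,
LST error).  Screening masks cells whose QC exceeds the declared
thresholds, compositing averages surviving layers by month and then over
multi-year windows, and the change field ``ΔT`` is the end-period mean
minus the start-period mean, reported in °C.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import xarray as xr

from deforheat.raster import GridSpec, Raster, RasterError

__all__ = [
    "LstStack",
    "DeltaT",
    "AirAdjustment",
    "QC_EMISSIVITY_MAX",
    "QC_LST_ERROR_MAX_K",
    "qc_filter",
    "monthly_composite",
    "period_mean",
    "delta_t",
    "apply_air_adjustment",
]

#: Exclusive QC thresholds: observations are dropped when *strictly greater*.
QC_EMISSIVITY_MAX = 0.02
QC_LST_ERROR_MAX_K = 1.0

_LST_PLAUSIBLE = (200.0, 350.0)


@dataclass
class LstStack:
    """A (layer, row, col) stack of LST observations with QC fields.

    ``lst`` is kelvin with NaN marking missing observations; ``periods``
    holds one ``(year, month)`` pair per layer (8-day periods straddling a
    month boundary are assigned to the month containing their start date).
    """

    grid: GridSpec
    lst: np.ndarray
    emissivity_error: np.ndarray | None
    lst_error: np.ndarray | None
    periods: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.lst = np.asarray(self.lst, dtype=np.float64)
        if self.lst.ndim != 3 or self.lst.shape[1:] != self.grid.shape:
            raise RasterError("lst stack shape does not match grid")
        if len(self.periods) != self.lst.shape[0]:
            raise RasterError("periods length does not match stack depth")
        for name in ("emissivity_error", "lst_error"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.float64)
                if arr.shape != self.lst.shape:
                    raise RasterError(f"{name} shape does not match lst stack")
                setattr(self, name, arr)

    @property
    def n_layers(self) -> int:
        return self.lst.shape[0]

    def to_netcdf(self, path: str | Path) -> None:
        years = [p[0] for p in self.periods]
        months = [p[1] for p in self.periods]
        data = {
            "lst": (("layer", "lat", "lon"), self.lst),
            "year": (("layer",), np.asarray(years, dtype=np.int32)),
            "month": (("layer",), np.asarray(months, dtype=np.int32)),
        }
        if self.emissivity_error is not None:
            data["emissivity_error"] = (("layer", "lat", "lon"), self.emissivity_error)
        if self.lst_error is not None:
            data["lst_error"] = (("layer", "lat", "lon"), self.lst_error)
        ds = xr.Dataset(
            data,
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers},
        )
        ds.attrs["resolution_arcsec"] = self.grid.resolution_arcsec
        ds.to_netcdf(path)

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "LstStack":
        with xr.open_dataset(path) as ds:
            grid = GridSpec.from_centers(ds["lat"].values, ds["lon"].values)
            periods = list(
                zip(
                    [int(y) for y in ds["year"].values],
                    [int(m) for m in ds["month"].values],
                )
            )
            emis = ds["emissivity_error"].values.copy() if "emissivity_error" in ds else None
            err = ds["lst_error"].values.copy() if "lst_error" in ds else None
            return cls(grid, ds["lst"].values.copy(), emis, err, periods)


@dataclass
class DeltaT:
    """Temperature change field in °C (end-period mean − start-period mean)."""

    raster: Raster

    def shifted(self, offset: float) -> "DeltaT":
        return DeltaT(Raster(self.raster.grid, self.raster.values + offset, self.raster.mask.copy()))


@dataclass(frozen=True)
class AirAdjustment:
    """Linear LST→2-m air temperature relationship for one region.

    Only the slope matters for temperature *differences*: the intercept
    cancels when adjusting ``ΔT``.
    """

    slope: float
    intercept: float = 0.0
    scope: str = "global"

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("air-adjustment slope must be positive")


def qc_filter(
    stack: LstStack,
    emissivity_max: float = QC_EMISSIVITY_MAX,
    lst_error_max: float = QC_LST_ERROR_MAX_K,
) -> LstStack:
    """Mask observations failing QC (strictly greater than the thresholds).

    A cell is dropped iff ``emissivity_error > emissivity_max`` OR
    ``lst_error > lst_error_max`` OR the observation is already missing or
    physically implausible.  Both QC layers are mandatory.
    """
    if stack.emissivity_error is None or stack.lst_error is None:
        raise RasterError("QC layers (emissivity_error, lst_error) are required; refusing to pass unscreened data")
    bad = (
        (stack.emissivity_error > emissivity_max)
        | (stack.lst_error > lst_error_max)
        | ~np.isfinite(stack.lst)
        | (stack.lst < _LST_PLAUSIBLE[0])
        | (stack.lst > _LST_PLAUSIBLE[1])
    )
    lst = stack.lst.copy()
    lst[bad] = np.nan
    return LstStack(
        stack.grid,
        lst,
        stack.emissivity_error.copy(),
        stack.lst_error.copy(),
        list(stack.periods),
    )


def monthly_composite(stack: LstStack, year: int, month: int) -> Raster:
    """Per-cell mean over the available (unmasked) layers of one month.

    No gap-filling: a cell is masked iff every layer is masked there.
    Raises if the stack holds no layers for the requested month.
    """
    idx = [k for k, (y, m) in enumerate(stack.periods) if y == year and m == month]
    if not idx:
        raise RasterError(f"no layers for {year}-{month:02d} in stack")
    sub = stack.lst[idx]
    counts = np.sum(~np.isnan(sub), axis=0)
    mask = counts == 0
    mean = np.where(mask, np.nan, np.nansum(sub, axis=0) / np.where(mask, 1, counts))
    return Raster(stack.grid, mean, mask)


def period_mean(monthly: Mapping[tuple[int, int], Raster], years: Iterable[int]) -> Raster:
    """Unweighted mean over all available months of the listed years.

    ``monthly`` maps ``(year, month)`` to composited rasters.  A cell is
    masked iff it is masked in every contributing month.
    """
    years = sorted(set(years))
    if not years:
        raise RasterError("empty year set")
    layers = [r for (y, _m), r in sorted(monthly.items()) if y in years]
    if not layers:
        raise RasterError(f"no monthly composites available for years {years}")
    grid = layers[0].grid
    stack = np.stack([r.filled(np.nan) for r in layers])
    counts = np.sum(~np.isnan(stack), axis=0)
    mask = counts == 0
    mean = np.where(mask, np.nan, np.nansum(stack, axis=0) / np.where(mask, 1, counts))
    return Raster(grid, mean, mask)


def delta_t(start: Raster, end: Raster) -> DeltaT:
    """End minus start, per cell; kelvin differences equal °C differences.

    Masked wherever either period mean is missing.
    """
    start.require_same_grid(end, "delta_t operands")
    mask = start.mask | end.mask
    vals = np.where(mask, np.nan, end.values - start.values)
    return DeltaT(Raster(start.grid, vals, mask))


def apply_air_adjustment(
    dt: DeltaT,
    adjustment: AirAdjustment | Mapping[int, AirAdjustment],
    regions: Raster | None = None,
) -> DeltaT:
    """Scale ``ΔT`` by the regional LST→air slope (intercepts cancel).

    Pass a single :class:`AirAdjustment` for a domain-wide slope, or a
    mapping ``region id -> AirAdjustment`` together with a region-ID
    raster.  An unmapped region on an unmasked cell is an error.
    """
    r = dt.raster
    if isinstance(adjustment, AirAdjustment):
        return DeltaT(Raster(r.grid, r.values * adjustment.slope, r.mask.copy()))
    if regions is None:
        raise RasterError("regional adjustments require a region-ID raster")
    r.require_same_grid(regions, "air adjustment regions")
    slope = np.full(r.grid.shape, np.nan)
    present = np.unique(regions.values[regions.valid & r.valid])
    for rid in present:
        if int(rid) not in adjustment:
            raise RasterError(f"no air adjustment for region {int(rid)}")
        slope[regions.values == rid] = adjustment[int(rid)].slope
    vals = r.values * slope
    mask = r.mask | ~np.isfinite(vals)
    return DeltaT(Raster(r.grid, np.where(mask, np.nan, vals), mask))
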