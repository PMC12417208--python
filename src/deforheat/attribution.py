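"""Moving-window counterfactual matching of deforested pixels.

For every deforested pixel with a valid temperature change, nearby
non-deforested pixels at similar elevation act as controls for the
background climate signal; the control-mean change is subtracted from the
central pixel to isolate the locally induced component.  The result is
normalised per percentage point of cover loss, smoothed over a small
rolling circle with a one-pass z-score outlier screen, and multiplied
back by the loss to give the final induced-change field.

Distances are great-circle central angles between cell centers expressed
in degrees (a ``degree_space_distance`` option falls back to plain
Euclidean distance in lat/lon degrees).  A tolerance of 1e-9 degrees is
added to every radius so that cells lying exactly on the circle are
included regardless of floating-point rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from deforheat.forest_change import CoverChange, PixelClass, PixelClassMap
from deforheat.raster import AreaWeights, Raster, RasterError
from deforheat.surface_change import DeltaT

__all__ = [
    "MatchParams",
    "AttributionResult",
    "RADIUS_NONE",
    "RADIUS_PRIMARY",
    "RADIUS_FALLBACK",
    "find_controls",
    "raw_attribution",
    "normalize_per_point",
    "smooth_per_point",
    "regional_mean_per_point",
    "reconstruct",
    "attribute",
]

RADIUS_NONE = 0
RADIUS_PRIMARY = 1
RADIUS_FALLBACK = 2

_DIST_TOL_DEG = 1e-9


@dataclass(frozen=True)
class MatchParams:
    """Search, screening and smoothing parameters for the matching."""

    primary_radius: float = 0.25  # degrees
    fallback_radius: float = 0.50  # degrees
    elevation_band: float = 50.0  # meters, +/-
    smooth_radius: float = 0.10  # degrees
    min_loss_for_smoothing: float = 5.0  # percentage points
    z_threshold: float = 3.0
    degree_space_distance: bool = False
    include_center_in_smoothing: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.primary_radius < self.fallback_radius:
            raise ValueError("need 0 < primary_radius < fallback_radius")
        for name in ("elevation_band", "smooth_radius", "min_loss_for_smoothing", "z_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class AttributionResult:
    """Per-pixel induced temperature change with provenance.

    ``dt_defor`` is masked exactly where no controls were found at either
    radius (``radius_used == RADIUS_NONE``); such pixels stay in the array
    with a missing indicator.
    """

    dt_defor_raw: Raster
    dt_per_point: Raster
    dt_per_point_smoothed: Raster
    dt_defor: Raster
    radius_used: np.ndarray  # int8 codes, RADIUS_* per deforested pixel
    regional_fallback_used: np.ndarray  # bool
    n_controls: np.ndarray  # int32
    n_smooth_neighbors: np.ndarray  # int32, qualifying-set size
    center_mask: np.ndarray = None  # type: ignore[assignment]  # bool, deforested centers

    def stats(self) -> dict[str, float]:
        n_defor = int(np.count_nonzero(self.center_mask))
        matched = int(np.count_nonzero(self.radius_used > RADIUS_NONE))
        return {
            "n_deforested_centers": n_defor,
            "n_matched": matched,
            "n_fallback_radius": int(np.count_nonzero(self.radius_used == RADIUS_FALLBACK)),
            "n_regional_fallback": int(np.count_nonzero(self.regional_fallback_used)),
            "frac_unmatched": (n_defor - matched) / n_defor if n_defor else 0.0,
        }


def _central_angle_deg(
    lat0: float, lon0: float, lats: np.ndarray, lons: np.ndarray
) -> np.ndarray:
    """Great-circle central angle (haversine), returned in degrees."""
    la0, lo0 = np.deg2rad(lat0), np.deg2rad(lon0)
    la, lo = np.deg2rad(lats), np.deg2rad(lons)
    s1 = np.sin((la - la0) / 2.0)
    s2 = np.sin((lo - lo0) / 2.0)
    h = s1 * s1 + np.cos(la0) * np.cos(la) * s2 * s2
    return np.rad2deg(2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def _distance_deg(
    lat0: float, lon0: float, lats: np.ndarray, lons: np.ndarray, degree_space: bool
) -> np.ndarray:
    if degree_space:
        return np.hypot(lats - lat0, lons - lon0)
    return _central_angle_deg(lat0, lon0, lats, lons)


def _window(grid, i: int, j: int, radius_deg: float, degree_space: bool):
    """Row/col slice bounds guaranteed to contain the search circle."""
    res = grid.res_deg
    di = int(np.ceil(radius_deg / res)) + 1
    if degree_space:
        dj = di
    else:
        lat_c = grid.lat_centers[i]
        band = min(89.0, abs(lat_c) + radius_deg)
        dj = int(np.ceil(radius_deg / (res * np.cos(np.deg2rad(band))))) + 1
    i0, i1 = max(0, i - di), min(grid.n_rows, i + di + 1)
    j0, j1 = max(0, j - dj), min(grid.n_cols, j + dj + 1)
    return i0, i1, j0, j1


def _select_in_circle(
    grid,
    i: int,
    j: int,
    radius_deg: float,
    candidate: np.ndarray,
    degree_space: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices (rows, cols) of candidate cells within the circle."""
    i0, i1, j0, j1 = _window(grid, i, j, radius_deg, degree_space)
    sub = candidate[i0:i1, j0:j1]
    if not sub.any():
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rows, cols = np.nonzero(sub)
    rows = rows + i0
    cols = cols + j0
    lat_c, lon_c = grid.lat_centers, grid.lon_centers
    dist = _distance_deg(lat_c[i], lon_c[j], lat_c[rows], lon_c[cols], degree_space)
    keep = dist <= radius_deg + _DIST_TOL_DEG
    return rows[keep], cols[keep]


def find_controls(
    center: tuple[int, int],
    classes: PixelClassMap,
    elevation: Raster,
    dt: DeltaT,
    params: MatchParams = MatchParams(),
) -> tuple[list[tuple[int, int]], int]:
    """Control pixels for one deforested center, and the radius code used.

    Controls are non-deforested pixels with valid ΔT and elevation, within
    the primary radius and ±``elevation_band`` m of the center elevation;
    if none exist the fallback radius is tried with the same elevation
    constraint; if still none the result is empty with ``RADIUS_NONE``.
    """
    i, j = center
    grid = classes.raster.grid
    if not classes.is_class(PixelClass.DEFORESTED)[i, j]:
        raise RasterError(f"center pixel {center} is not classified deforested")
    if dt.raster.mask[i, j] or elevation.mask[i, j]:
        raise RasterError(f"center pixel {center} lacks valid ΔT or elevation")

    candidate = (
        classes.is_class(PixelClass.NON_DEFORESTED) & dt.raster.valid & elevation.valid
    )
    elev_c = elevation.values[i, j]
    for radius, code in (
        (params.primary_radius, RADIUS_PRIMARY),
        (params.fallback_radius, RADIUS_FALLBACK),
    ):
        rows, cols = _select_in_circle(grid, i, j, radius, candidate, params.degree_space_distance)
        if rows.size:
            keep = np.abs(elevation.values[rows, cols] - elev_c) <= params.elevation_band
            rows, cols = rows[keep], cols[keep]
        if rows.size:
            return list(zip(rows.tolist(), cols.tolist())), code
    return [], RADIUS_NONE


def raw_attribution(
    dt: DeltaT,
    classes: PixelClassMap,
    elevation: Raster,
    params: MatchParams = MatchParams(),
) -> AttributionResult:
    """ΔT_center − mean(ΔT_controls) for every deforested pixel.

    Pixels without controls (or without valid ΔT/elevation) are masked but
    retained, with provenance recording the radius code and control count.
    The smoothed/final fields of the returned result are placeholders
    (fully masked); use :func:`attribute` for the full chain.
    """
    grid = dt.raster.grid
    dt.raster.require_same_grid(classes.raster, "attribution inputs")
    dt.raster.require_same_grid(elevation, "attribution elevation")

    defor = classes.is_class(PixelClass.DEFORESTED)
    candidate = (
        classes.is_class(PixelClass.NON_DEFORESTED) & dt.raster.valid & elevation.valid
    )
    raw = np.full(grid.shape, np.nan)
    radius_used = np.zeros(grid.shape, dtype=np.int8)
    n_controls = np.zeros(grid.shape, dtype=np.int32)

    dt_v = dt.raster.values
    elev_v = elevation.values
    for i, j in zip(*np.nonzero(defor)):
        if dt.raster.mask[i, j] or elevation.mask[i, j]:
            continue
        elev_c = elev_v[i, j]
        for radius, code in (
            (params.primary_radius, RADIUS_PRIMARY),
            (params.fallback_radius, RADIUS_FALLBACK),
        ):
            rows, cols = _select_in_circle(
                grid, i, j, radius, candidate, params.degree_space_distance
            )
            if rows.size:
                keep = np.abs(elev_v[rows, cols] - elev_c) <= params.elevation_band
                rows, cols = rows[keep], cols[keep]
            if rows.size:
                raw[i, j] = dt_v[i, j] - np.mean(dt_v[rows, cols])
                radius_used[i, j] = code
                n_controls[i, j] = rows.size
                break

    raw_mask = ~np.isfinite(raw)
    empty = Raster(grid, np.full(grid.shape, np.nan), np.ones(grid.shape, dtype=bool))
    return AttributionResult(
        dt_defor_raw=Raster(grid, raw, raw_mask),
        dt_per_point=empty.copy(),
        dt_per_point_smoothed=empty.copy(),
        dt_defor=empty.copy(),
        radius_used=radius_used,
        regional_fallback_used=np.zeros(grid.shape, dtype=bool),
        n_controls=n_controls,
        n_smooth_neighbors=np.zeros(grid.shape, dtype=np.int32),
        center_mask=defor.copy(),
    )


def normalize_per_point(raw: Raster, change: CoverChange) -> Raster:
    """Induced change per percentage point of cover loss.

    Divides by the positive loss (−change); classification guarantees the
    loss is strictly positive wherever a raw value exists.
    """
    raw.require_same_grid(change.raster, "normalize inputs")
    loss = change.loss_pct
    ok = raw.valid
    if np.any(~(loss[ok] > 0)):
        raise AssertionError("raw attribution present at a pixel without cover loss")
    vals = np.where(ok, raw.values / np.where(ok, loss, 1.0), np.nan)
    return Raster(raw.grid, vals, ~ok)


def regional_mean_per_point(
    per_point: Raster,
    change: CoverChange,
    classes: PixelClassMap,
    regions: Raster | None = None,
    weights: AreaWeights | None = None,
    min_loss: float = 5.0,
) -> dict[int, float]:
    """Area-weighted mean per-point value over qualifying deforested pixels
    (loss ≥ ``min_loss``) for each region ID (region 0 if no raster given)."""
    qual = (
        classes.is_class(PixelClass.DEFORESTED)
        & per_point.valid
        & (change.loss_pct >= min_loss)
    )
    w = weights.weight if weights is not None else np.ones(per_point.grid.shape)
    region_vals = (
        regions.values if regions is not None else np.zeros(per_point.grid.shape, dtype=int)
    )
    out: dict[int, float] = {}
    for rid in np.unique(region_vals[qual] if qual.any() else region_vals):
        sel = qual & (region_vals == rid)
        if not sel.any():
            raise RasterError(f"region {int(rid)} has no qualifying pixels for the regional mean")
        out[int(rid)] = float(np.sum(per_point.values[sel] * w[sel]) / np.sum(w[sel]))
    if not out:
        raise RasterError("no qualifying pixels anywhere for the regional mean")
    return out


def smooth_per_point(
    per_point: Raster,
    change: CoverChange,
    classes: PixelClassMap,
    params: MatchParams = MatchParams(),
    regional_mean: float | Mapping[int, float] | None = None,
    regions: Raster | None = None,
) -> tuple[Raster, np.ndarray, np.ndarray]:
    """Rolling-circle mean of the per-point field with an outlier screen.

    For every deforested pixel the qualifying set is the deforested pixels
    within ``smooth_radius`` (center included by default) with loss ≥
    ``min_loss_for_smoothing`` and a valid per-point value.  A single pass
    drops members whose |z| exceeds ``z_threshold`` (population standard
    deviation); the smoothed value is the mean of the survivors.  An empty
    qualifying set falls back to the regional mean (error if unavailable).

    Returns ``(smoothed, regional_fallback_used, n_smooth_neighbors)``.
    """
    grid = per_point.grid
    per_point.require_same_grid(change.raster, "smoothing inputs")
    defor = classes.is_class(PixelClass.DEFORESTED)
    loss = change.loss_pct
    with np.errstate(invalid="ignore"):
        qualifies = defor & per_point.valid & (loss >= params.min_loss_for_smoothing)

    smoothed = np.full(grid.shape, np.nan)
    fallback_used = np.zeros(grid.shape, dtype=bool)
    n_neighbors = np.zeros(grid.shape, dtype=np.int32)

    def _regional(i: int, j: int) -> float:
        if regional_mean is None:
            raise RasterError(
                f"pixel ({i}, {j}) has no qualifying smoothing neighbours and "
                "no regional mean was supplied"
            )
        if isinstance(regional_mean, Mapping):
            if regions is None:
                raise RasterError("regional mean mapping requires a region-ID raster")
            rid = int(regions.values[i, j])
            if rid not in regional_mean:
                raise RasterError(f"no regional mean for region {rid}")
            return float(regional_mean[rid])
        return float(regional_mean)

    vals = per_point.values
    for i, j in zip(*np.nonzero(defor)):
        rows, cols = _select_in_circle(
            grid, i, j, params.smooth_radius, qualifies, params.degree_space_distance
        )
        if not params.include_center_in_smoothing and rows.size:
            keep = ~((rows == i) & (cols == j))
            rows, cols = rows[keep], cols[keep]
        if rows.size == 0:
            smoothed[i, j] = _regional(i, j)
            fallback_used[i, j] = True
            continue
        members = vals[rows, cols]
        n_neighbors[i, j] = members.size
        mean = np.mean(members)
        sd = np.std(members)  # population sd, one screening pass
        if sd > 0:
            members = members[np.abs(members - mean) / sd <= params.z_threshold]
        smoothed[i, j] = np.mean(members)

    mask = ~np.isfinite(smoothed)
    return Raster(grid, smoothed, mask), fallback_used, n_neighbors


def reconstruct(per_point_smoothed: Raster, change: CoverChange) -> Raster:
    """Final induced change: smoothed per-point value × percentage-point loss."""
    per_point_smoothed.require_same_grid(change.raster, "reconstruct inputs")
    ok = per_point_smoothed.valid & change.raster.valid
    vals = np.where(ok, per_point_smoothed.values * change.loss_pct, np.nan)
    return Raster(per_point_smoothed.grid, vals, ~ok)


def attribute(
    dt: DeltaT,
    classes: PixelClassMap,
    elevation: Raster,
    change: CoverChange,
    params: MatchParams = MatchParams(),
    regions: Raster | None = None,
    weights: AreaWeights | None = None,
) -> AttributionResult:
    """Full chain: raw matching → normalisation → smoothing → reconstruction.

    The final ``dt_defor`` is masked exactly at deforested pixels where no
    controls were found at either radius (missing indicator), even when a
    smoothed neighbourhood value exists there.
    """
    result = raw_attribution(dt, classes, elevation, params)
    per_point = normalize_per_point(result.dt_defor_raw, change)

    try:
        regional = regional_mean_per_point(
            per_point, change, classes, regions, weights, params.min_loss_for_smoothing
        )
    except RasterError:
        regional = None  # only fatal if some pixel actually needs the fallback
    smoothed, fallback_used, n_neighbors = smooth_per_point(
        per_point, change, classes, params, regional, regions
    )
    final = reconstruct(smoothed, change)
    # pixels that never found controls keep their missing indicator
    unmatched = classes.is_class(PixelClass.DEFORESTED) & (result.radius_used == RADIUS_NONE)
    final_vals = np.where(unmatched, np.nan, final.values)
    final = Raster(final.grid, final_vals, final.mask | unmatched)

    result.dt_per_point = per_point
    result.dt_per_point_smoothed = smoothed
    result.dt_defor = final
    result.regional_fallback_used = fallback_used
    result.n_smooth_neighbors = n_neighbors
    return result
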