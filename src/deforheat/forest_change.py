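"""Forest-cover change and the treated/control pixel classification.

Cover evolves from a year-2000 canopy-cover fraction by zeroing fine cells
once their (binary) loss year has passed; aggregation to the analysis grid
is area-weighted.  Classification thresholds (all in percent or
percentage points of canopy cover):

- ``cover_threshold`` (10): minimum 2001 cover to count as forest;
- ``control_threshold`` (0.5): loss strictly below this -> non-deforested;
- ``loss_threshold`` (2, sensitivity 1): loss at or above this -> deforested;
- losses in between are *buffer* pixels, neither treated nor control;
- ``gain_threshold`` (50, sensitivity 20): extent increase strictly above
  this excludes the pixel from the temperature analysis altogether.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from deforheat.raster import GridSpec, Raster, RasterError, regrid_area_weighted

__all__ = [
    "PixelClass",
    "ForestCover",
    "CoverChange",
    "PixelClassMap",
    "annual_cover",
    "cover_change",
    "extent_gain_mask",
    "classify_pixels",
    "DEFAULT_COVER_THRESHOLD",
    "DEFAULT_CONTROL_THRESHOLD",
    "DEFAULT_LOSS_THRESHOLD",
    "DEFAULT_GAIN_THRESHOLD",
]

DEFAULT_COVER_THRESHOLD = 10.0
DEFAULT_CONTROL_THRESHOLD = 0.5
DEFAULT_LOSS_THRESHOLD = 2.0
DEFAULT_GAIN_THRESHOLD = 50.0


class PixelClass(IntEnum):
    NON_FOREST = 0
    DEFORESTED = 1
    NON_DEFORESTED = 2
    BUFFER = 3
    EXCLUDED_GAIN = 4


@dataclass
class ForestCover:
    """Canopy-cover fraction in percent (0–100) for one calendar year."""

    raster: Raster
    year: int

    def __post_init__(self) -> None:
        v = self.raster.values[self.raster.valid]
        if v.size and (v.min() < -1e-9 or v.max() > 100.0 + 1e-9):
            raise RasterError("forest cover must lie in [0, 100] percent")


@dataclass
class CoverChange:
    """Percentage-point cover change (end − start); negative = loss."""

    raster: Raster

    @property
    def loss_pct(self) -> np.ndarray:
        """Positive percentage-point loss (−change), NaN where masked."""
        return np.where(self.raster.mask, np.nan, -self.raster.values)


@dataclass
class PixelClassMap:
    """Integer category raster using :class:`PixelClass` codes."""

    raster: Raster

    def is_class(self, cls: PixelClass) -> np.ndarray:
        return self.raster.valid & (self.raster.values == int(cls))

    def counts(self) -> dict[str, int]:
        return {c.name.lower(): int(self.is_class(c).sum()) for c in PixelClass}


def annual_cover(
    cover2000: ForestCover,
    loss_year: Raster,
    year: int,
    analysis_grid: GridSpec | None = None,
) -> ForestCover:
    """Cover in ``year`` from year-2000 cover and a first-loss-year raster.

    At the fine resolution a cell keeps its 2000 cover until its loss year
    (0 = never lost) and is zero afterwards.  If ``analysis_grid`` is given,
    the fine field is aggregated to it with area-weighted regridding.
    """
    if not 2000 <= year <= 2020:
        raise RasterError(f"year {year} outside supported range 2000-2020")
    cover2000.raster.require_same_grid(loss_year, "annual_cover inputs")
    ly = loss_year.values
    lost = (ly != 0) & (ly <= year) & loss_year.valid
    vals = np.where(lost, 0.0, cover2000.raster.values)
    fine = Raster(cover2000.raster.grid, vals, cover2000.raster.mask | loss_year.mask)
    if analysis_grid is not None:
        fine = regrid_area_weighted(fine, analysis_grid)
    return ForestCover(fine, year)


def cover_change(c_start: ForestCover, c_end: ForestCover) -> CoverChange:
    """Percentage-point change between two annual cover fields."""
    c_start.raster.require_same_grid(c_end.raster, "cover_change inputs")
    mask = c_start.raster.mask | c_end.raster.mask
    vals = np.where(mask, np.nan, c_end.raster.values - c_start.raster.values)
    return CoverChange(Raster(c_start.raster.grid, vals, mask))


def extent_gain_mask(
    extent_start: Raster,
    extent_end: Raster,
    threshold: float = DEFAULT_GAIN_THRESHOLD,
) -> Raster:
    """Boolean raster: True where net extent increase strictly exceeds
    ``threshold`` percentage points (those cells are dropped from ΔT)."""
    if not 0.0 < threshold <= 100.0:
        raise RasterError(f"gain threshold {threshold} outside (0, 100]")
    extent_start.require_same_grid(extent_end, "extent_gain_mask inputs")
    gain = extent_end.values - extent_start.values
    flag = (gain > threshold) & extent_start.valid & extent_end.valid
    return Raster(extent_start.grid, flag, extent_start.mask | extent_end.mask)


def classify_pixels(
    c_start: ForestCover,
    change: CoverChange,
    gain: Raster | None = None,
    loss_threshold: float = DEFAULT_LOSS_THRESHOLD,
    cover_threshold: float = DEFAULT_COVER_THRESHOLD,
    control_threshold: float = DEFAULT_CONTROL_THRESHOLD,
) -> PixelClassMap:
    """Assign every unmasked cell exactly one :class:`PixelClass`.

    Order of precedence: below ``cover_threshold`` initial cover ->
    NON_FOREST; flagged extent gain -> EXCLUDED_GAIN; loss at or above
    ``loss_threshold`` (i.e. change <= -threshold) -> DEFORESTED; loss
    strictly below ``control_threshold`` (gains included) ->
    NON_DEFORESTED; otherwise BUFFER.
    """
    c_start.raster.require_same_grid(change.raster, "classify_pixels inputs")
    if gain is not None:
        c_start.raster.require_same_grid(gain, "classify_pixels gain mask")
    if loss_threshold <= control_threshold:
        raise RasterError("loss_threshold must exceed control_threshold")

    cov = c_start.raster.values
    chg = change.raster.values
    mask = c_start.raster.mask | change.raster.mask

    out = np.full(cov.shape, int(PixelClass.NON_FOREST), dtype=np.int16)
    forest = cov >= cover_threshold
    gained = np.zeros(cov.shape, dtype=bool) if gain is None else gain.values.astype(bool)
    with np.errstate(invalid="ignore"):
        deforested = forest & ~gained & (chg <= -loss_threshold)
        control = forest & ~gained & (chg > -control_threshold)
    out[forest & gained] = int(PixelClass.EXCLUDED_GAIN)
    out[deforested] = int(PixelClass.DEFORESTED)
    out[control] = int(PixelClass.NON_DEFORESTED)
    out[forest & ~gained & ~deforested & ~control] = int(PixelClass.BUFFER)
    out = out.astype(np.int16)
    return PixelClassMap(Raster(c_start.raster.grid, out, mask))
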