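"""Population exposure and weighted warming summaries.

All statistics are restricted to valid forest-loss pixels: deforested
cells with an unmasked induced-change value (gain-excluded and QC-masked
cells never enter).  "Exposed" means a strictly positive induced change,
and threshold counts use strict ``>`` comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from deforheat.forest_change import PixelClass, PixelClassMap
from deforheat.raster import AreaWeights, Raster, RasterError

__all__ = [
    "ExposureSummary",
    "population_weighted_mean",
    "area_weighted_mean",
    "exposure_counts",
    "DEFAULT_THRESHOLDS",
]

DEFAULT_THRESHOLDS = (0.0, 1.0, 2.0, 3.0)


@dataclass
class ExposureSummary:
    """Exposure tallies for one scope (region or whole domain)."""

    scope: str
    pop_total_forest_loss: float
    pop_exposed: float
    pop_above: dict[float, float] = field(default_factory=dict)
    popwgt_dt: float = float("nan")
    areawgt_dt: float = float("nan")

    @property
    def share_exposed(self) -> float:
        if self.pop_total_forest_loss <= 0:
            return float("nan")
        return self.pop_exposed / self.pop_total_forest_loss


def population_weighted_mean(field_r: Raster, pop: Raster, mask: np.ndarray) -> float:
    """Σ(pop·field)/Σ(pop) over unmasked pixels of ``mask``."""
    field_r.require_same_grid(pop, "population weighting")
    sel = np.asarray(mask, dtype=bool) & field_r.valid & pop.valid
    total = float(pop.values[sel].sum())
    if total <= 0:
        raise RasterError("zero total population over the requested pixel set")
    return float(np.sum(pop.values[sel] * field_r.values[sel]) / total)


def area_weighted_mean(field_r: Raster, weights: AreaWeights, mask: np.ndarray) -> float:
    """Σ(w·field)/Σ(w) over unmasked pixels of ``mask``."""
    sel = np.asarray(mask, dtype=bool) & field_r.valid
    if not sel.any():
        raise RasterError("empty pixel set for area-weighted mean")
    w = weights.weight[sel]
    return float(np.sum(w * field_r.values[sel]) / np.sum(w))


def exposure_counts(
    dt_defor: Raster,
    pop: Raster,
    classes: PixelClassMap,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    weights: AreaWeights | None = None,
    scope: str = "all",
    region_mask: np.ndarray | None = None,
) -> ExposureSummary:
    """Population exposure over valid forest-loss pixels of one scope.

    ``pop_total_forest_loss`` counts population on deforested pixels with
    valid induced change; ``pop_exposed`` restricts to strictly positive
    change; ``pop_above[t]`` to change strictly greater than ``t``.
    """
    if list(thresholds) != sorted(thresholds):
        raise RasterError("thresholds must be sorted ascending")
    dt_defor.require_same_grid(pop, "exposure inputs")
    valid_loss = classes.is_class(PixelClass.DEFORESTED) & dt_defor.valid & pop.valid
    if region_mask is not None:
        valid_loss &= np.asarray(region_mask, dtype=bool)

    pv = pop.values
    dv = dt_defor.values
    summary = ExposureSummary(
        scope=scope,
        pop_total_forest_loss=float(pv[valid_loss].sum()),
        pop_exposed=float(pv[valid_loss & (dv > 0)].sum()),
        pop_above={float(t): float(pv[valid_loss & (dv > t)].sum()) for t in thresholds},
    )
    if valid_loss.any():
        try:
            summary.popwgt_dt = population_weighted_mean(dt_defor, pop, valid_loss)
        except RasterError:
            pass  # zero population on the scope: leave NaN
        if weights is not None:
            summary.areawgt_dt = area_weighted_mean(dt_defor, weights, valid_loss)
    return summary
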