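"""Admin/region aggregation tables, shares and presentation rounding.

Internal values keep full precision; rounding (deaths to the nearest ten,
rates and shares to the nearest whole number) is applied only when a
presentation table is rendered.  Pooled rows (whole-domain) are computed
from the pooled pixel set, never by averaging region rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from deforheat.exposure import (
    DEFAULT_THRESHOLDS,
    area_weighted_mean,
    exposure_counts,
    population_weighted_mean,
)
from deforheat.forest_change import PixelClass, PixelClassMap
from deforheat.heat_mortality import MortalityField
from deforheat.raster import AreaWeights, Raster, RasterError

__all__ = [
    "aggregate_by_admin",
    "rate_per_100k",
    "warming_shares",
    "round_deaths",
    "round_rate",
    "RegionReport",
    "build_region_table",
    "render_table",
]


def aggregate_by_admin(
    field: Raster,
    admin: Raster,
    statistic: str = "sum",
    pop: Raster | None = None,
    weights: AreaWeights | None = None,
) -> pd.DataFrame:
    """One row per admin ID with the requested statistic over valid pixels.

    Admins with no valid pixels are absent from the table (blank in maps).
    ``statistic`` is one of ``sum``, ``popwgt_mean``, ``areawgt_mean``.
    """
    field.require_same_grid(admin, "admin aggregation")
    if statistic == "popwgt_mean" and pop is None:
        raise RasterError("popwgt_mean requires a population raster")
    if statistic == "areawgt_mean" and weights is None:
        raise RasterError("areawgt_mean requires area weights")

    rows = []
    valid = field.valid & admin.valid
    for aid in np.unique(admin.values[valid]):
        sel = valid & (admin.values == aid)
        if statistic == "sum":
            value = float(field.values[sel].sum())
        elif statistic == "popwgt_mean":
            value = population_weighted_mean(field, pop, sel)
        elif statistic == "areawgt_mean":
            value = area_weighted_mean(field, weights, sel)
        else:
            raise RasterError(f"unknown statistic {statistic!r}")
        rows.append({"admin_id": int(aid), "value": value, "n_pixels": int(sel.sum())})
    return pd.DataFrame(rows, columns=["admin_id", "value", "n_pixels"])


def rate_per_100k(deaths: float, pop: float) -> float:
    """Deaths per 100,000 people (full precision; round at presentation)."""
    if pop <= 0:
        raise RasterError("rate_per_100k requires a positive population")
    return deaths / pop * 1e5


def warming_shares(defor: float, total: float) -> float:
    """Induced share of total warming, in percent (full precision)."""
    if total == 0:
        raise RasterError("share of warming undefined for zero total warming")
    return 100.0 * defor / total


def round_deaths(x: float) -> int:
    """Presentation rounding: nearest ten."""
    return int(round(x / 10.0) * 10)


def round_rate(x: float) -> int:
    """Presentation rounding: nearest whole number."""
    return int(round(x))


@dataclass
class RegionReport:
    """One summary row (a region, a country, or the pooled domain)."""

    scope: str
    pop_forest_loss: float
    pop_exposed: float
    deaths_central: float
    deaths_low: float
    deaths_high: float
    rate_per_100k_forest_loss: float  # denominator: pop in forest-loss pixels
    rate_per_100k_exposed: float  # denominator: pop exposed to warming
    share_of_total_heat_mortality: float  # percent; may exceed 100
    share_of_nonacc_mortality: float  # percent
    areawgt_dt_total: float
    popwgt_dt_total: float
    areawgt_dt_defor: float
    popwgt_dt_defor: float

    def __post_init__(self) -> None:
        if not self.deaths_low <= self.deaths_central <= self.deaths_high:
            raise RasterError(
                f"{self.scope}: mortality bounds must bracket the central estimate"
            )


def _region_row(
    scope: str,
    sel: np.ndarray,
    dt_total: Raster,
    dt_defor: Raster,
    pop: Raster,
    weights: AreaWeights,
    classes: PixelClassMap,
    mortality: Mapping[str, MortalityField],
    total_mortality: MortalityField,
) -> RegionReport:
    summary = exposure_counts(
        dt_defor, pop, classes, DEFAULT_THRESHOLDS, weights, scope, sel
    )
    loss_sel = classes.is_class(PixelClass.DEFORESTED) & dt_defor.valid & sel
    deaths = {
        b: float(m.heat_mort.values[loss_sel & m.heat_mort.valid].sum())
        for b, m in mortality.items()
    }
    baseline = float(
        mortality["central"].nonacc_mort.values[
            loss_sel & mortality["central"].nonacc_mort.valid
        ].sum()
    )
    total_heat = float(
        total_mortality.heat_mort.values[loss_sel & total_mortality.heat_mort.valid].sum()
    )

    def _wgt(field: Raster, fn) -> float:
        try:
            return fn(field)
        except RasterError:
            return float("nan")

    return RegionReport(
        scope=scope,
        pop_forest_loss=summary.pop_total_forest_loss,
        pop_exposed=summary.pop_exposed,
        deaths_central=deaths["central"],
        deaths_low=deaths["low"],
        deaths_high=deaths["high"],
        rate_per_100k_forest_loss=(
            rate_per_100k(deaths["central"], summary.pop_total_forest_loss)
            if summary.pop_total_forest_loss > 0
            else float("nan")
        ),
        rate_per_100k_exposed=(
            rate_per_100k(deaths["central"], summary.pop_exposed)
            if summary.pop_exposed > 0
            else float("nan")
        ),
        share_of_total_heat_mortality=(
            100.0 * deaths["central"] / total_heat if total_heat > 0 else float("nan")
        ),
        share_of_nonacc_mortality=(
            100.0 * deaths["central"] / baseline if baseline > 0 else float("nan")
        ),
        areawgt_dt_total=_wgt(dt_total, lambda f: area_weighted_mean(f, weights, loss_sel)),
        popwgt_dt_total=_wgt(dt_total, lambda f: population_weighted_mean(f, pop, loss_sel)),
        areawgt_dt_defor=summary.areawgt_dt,
        popwgt_dt_defor=summary.popwgt_dt,
    )


def build_region_table(
    regions: Raster,
    region_names: Mapping[int, str],
    dt_total: Raster,
    dt_defor: Raster,
    pop: Raster,
    weights: AreaWeights,
    classes: PixelClassMap,
    mortality: Mapping[str, MortalityField],
    total_mortality: MortalityField,
    pooled_name: str = "all",
) -> pd.DataFrame:
    """One row per region plus a pooled row computed from pooled pixels."""
    rows = []
    everywhere = np.ones(regions.grid.shape, dtype=bool)
    rows.append(
        _region_row(
            pooled_name, everywhere, dt_total, dt_defor, pop, weights, classes,
            mortality, total_mortality,
        )
    )
    for rid in np.unique(regions.values[regions.valid]):
        name = region_names.get(int(rid), f"region_{int(rid)}")
        sel = regions.valid & (regions.values == rid)
        rows.append(
            _region_row(
                name, sel, dt_total, dt_defor, pop, weights, classes,
                mortality, total_mortality,
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


def render_table(table: pd.DataFrame) -> pd.DataFrame:
    """Presentation copy: deaths to the nearest ten, rates/shares rounded."""
    out = table.copy()
    for col in ("deaths_central", "deaths_low", "deaths_high"):
        out[col] = out[col].map(round_deaths)
    for col in (
        "rate_per_100k_forest_loss",
        "rate_per_100k_exposed",
        "share_of_total_heat_mortality",
        "share_of_nonacc_mortality",
    ):
        out[col] = out[col].map(lambda x: round_rate(x) if np.isfinite(x) else x)
    return out
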