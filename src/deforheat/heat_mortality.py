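"""Attributable heat mortality from per-pixel induced warming.

The chain, per pixel *i* with population ``pop_i``:

1. baseline deaths/yr:    ``nonacc_mort_i = pop_i * rate_admin / 1e5``
2. fractional increase:   ``f_i = (HVI_admin / 100) * dTdefor_i`` where
   ``dTdefor_i > 0`` on deforested pixels, else 0
3. counterfactual:        ``cf_mort_i = nonacc_mort_i / (1 + f_i)``
4. attributable:          ``heat_mort_i = nonacc_mort_i - cf_mort_i``
                          (algebraically ``nonacc_mort_i * f_i / (1 + f_i)``)

The heat vulnerability index (HVI) is the percentage-point increase in
excess mortality per °C; step 2 converts it to a fraction.  A
``literal_percent`` switch keeps raw percentage points in the denominator
of step 3 for comparison.  Uncertainty bounds rerun the chain with the
low/high ends of the mortality-rate confidence interval; the chain is
linear in the rate, so bounds scale exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Mapping

import numpy as np
import pandas as pd

from deforheat.forest_change import PixelClass, PixelClassMap
from deforheat.raster import Raster, RasterError
from deforheat.surface_change import DeltaT

__all__ = [
    "HVITable",
    "MortalityTable",
    "MortalityField",
    "baseline_mortality",
    "pct_increase",
    "counterfactual_mortality",
    "attributable_mortality",
    "mortality_chain",
    "mortality_with_bounds",
    "total_heat_mortality",
    "BOUNDS",
]

BOUNDS = ("central", "low", "high")


@dataclass
class HVITable:
    """Heat vulnerability indices (%-points of excess mortality per °C).

    ``entries`` maps a key (admin/country/continent) to its HVI;
    ``parents`` maps a key to the key consulted when no direct entry
    exists (admin → country → continent), applied transitively.
    """

    entries: dict[Hashable, float]
    parents: dict[Hashable, Hashable] = field(default_factory=dict)
    basis: str = "non_accidental"

    def __post_init__(self) -> None:
        for k, v in self.entries.items():
            if not v > 0:
                raise RasterError(f"HVI for {k!r} must be positive, got {v}")

    def resolve(self, key: Hashable) -> float:
        seen = set()
        k = key
        while True:
            if k in self.entries:
                return float(self.entries[k])
            if k in seen or k not in self.parents:
                raise RasterError(f"cannot resolve an HVI for key {key!r}")
            seen.add(k)
            k = self.parents[k]

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"key": k, "hvi_pct_per_C": v, "parent": "", "basis": self.basis}
            for k, v in self.entries.items()
        ]
        rows += [
            {"key": k, "hvi_pct_per_C": "", "parent": p, "basis": self.basis}
            for k, p in self.parents.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "HVITable":
        df = pd.read_csv(path)
        entries: dict[Hashable, float] = {}
        parents: dict[Hashable, Hashable] = {}
        basis = "non_accidental"
        for _, row in df.iterrows():
            key = _coerce_key(row["key"])
            if not pd.isna(row.get("hvi_pct_per_C")) and row.get("hvi_pct_per_C") != "":
                entries[key] = float(row["hvi_pct_per_C"])
            parent = row.get("parent")
            if isinstance(parent, str) and parent == "":
                parent = None
            if parent is not None and not (isinstance(parent, float) and np.isnan(parent)):
                parents[key] = _coerce_key(parent)
            if isinstance(row.get("basis"), str):
                basis = row["basis"]
        return cls(entries, parents, basis)


def _coerce_key(k):
    """CSV round-trips integer admin IDs through floats/strings."""
    if isinstance(k, (int, np.integer)):
        return int(k)
    if isinstance(k, (float, np.floating)) and float(k).is_integer():
        return int(k)
    if isinstance(k, str):
        try:
            return int(k)
        except ValueError:
            return k
    return k


@dataclass
class MortalityTable:
    """Per-admin annual mortality rates (deaths per 100,000) with 95% CI."""

    table: pd.DataFrame  # columns: admin_id, rate_per_100k, ci_low, ci_high

    REQUIRED = ("admin_id", "rate_per_100k", "ci_low", "ci_high")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise RasterError(f"mortality table missing columns {missing}")
        t = self.table
        bad = ~((t.ci_low > 0) & (t.ci_low <= t.rate_per_100k) & (t.rate_per_100k <= t.ci_high))
        if bad.any():
            raise RasterError(
                f"invalid CI ordering for admin ids {t.admin_id[bad].tolist()}"
            )

    def rate_map(self, bound: str = "central") -> dict[int, float]:
        col = {"central": "rate_per_100k", "low": "ci_low", "high": "ci_high"}[bound]
        return dict(zip(self.table.admin_id.astype(int), self.table[col].astype(float)))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MortalityTable":
        return cls(pd.read_csv(path))


@dataclass
class MortalityField:
    """Per-pixel rasters of the mortality chain for one rate bound."""

    nonacc_mort: Raster
    pct_increase: Raster  # stored as a fraction, not percent
    cf_mort: Raster
    heat_mort: Raster
    bound: str = "central"

    def total(self) -> float:
        return float(self.heat_mort.values[self.heat_mort.valid].sum())

    def baseline_total(self) -> float:
        return float(self.nonacc_mort.values[self.nonacc_mort.valid].sum())


def _admin_field(admin: Raster, mapping: Mapping[int, float], pop: Raster, what: str) -> np.ndarray:
    """Broadcast a per-admin value onto the grid; error on unmapped
    populated pixels."""
    out = np.full(admin.grid.shape, np.nan)
    ids = np.unique(admin.values[admin.valid])
    for aid in ids:
        aid = int(aid)
        if aid in mapping:
            out[admin.values == aid] = mapping[aid]
    unmapped = pop.valid & (pop.values > 0) & ~np.isfinite(out) & admin.valid
    if unmapped.any():
        bad = sorted({int(a) for a in admin.values[unmapped]})
        raise RasterError(f"populated pixels with no {what} for admin ids {bad}")
    return out


def baseline_mortality(
    pop: Raster, rates: MortalityTable, admin: Raster, bound: str = "central"
) -> Raster:
    """Per-pixel baseline deaths/yr: population × rate / 100,000."""
    pop.require_same_grid(admin, "baseline mortality inputs")
    rate = _admin_field(admin, rates.rate_map(bound), pop, "mortality rate")
    vals = pop.values * rate / 1e5
    mask = pop.mask | admin.mask | ~np.isfinite(vals)
    return Raster(pop.grid, np.where(mask, np.nan, vals), mask)


def pct_increase(
    dt_defor: Raster,
    hvi: HVITable,
    admin: Raster,
    classes: PixelClassMap | None = None,
    literal_percent: bool = False,
) -> Raster:
    """Fractional increase in heat-attributable excess mortality.

    ``f = (HVI / 100) × ΔTdefor`` on deforested pixels with strictly
    positive induced change; exactly zero elsewhere (cooling pixels
    contribute no attributable deaths).  ``literal_percent`` skips the
    /100 conversion for comparison runs.
    """
    dt_defor.require_same_grid(admin, "pct_increase inputs")
    ids = np.unique(admin.values[admin.valid])
    hvi_map = {int(a): hvi.resolve(int(a)) for a in ids}
    hvi_field = np.full(admin.grid.shape, np.nan)
    for aid, v in hvi_map.items():
        hvi_field[admin.values == aid] = v

    positive = dt_defor.valid & (dt_defor.values > 0)
    if classes is not None:
        positive &= classes.is_class(PixelClass.DEFORESTED)
    scale = 1.0 if literal_percent else 0.01
    f = np.where(positive, scale * hvi_field * dt_defor.values, 0.0)
    mask = ~np.isfinite(f)
    return Raster(dt_defor.grid, np.where(mask, np.nan, f), mask)


def counterfactual_mortality(baseline: Raster, f: Raster) -> Raster:
    """Baseline deaths deflated by the attributable increase: b / (1 + f)."""
    baseline.require_same_grid(f, "counterfactual inputs")
    fv = f.values
    if np.any(fv[f.valid] <= -1.0):
        raise AssertionError("fractional increase below -1 is impossible")
    mask = baseline.mask | f.mask
    vals = np.where(mask, np.nan, baseline.values / (1.0 + fv))
    return Raster(baseline.grid, vals, mask)


def attributable_mortality(baseline: Raster, cf: Raster) -> Raster:
    """Attributable deaths/yr: baseline − counterfactual."""
    baseline.require_same_grid(cf, "attributable inputs")
    mask = baseline.mask | cf.mask
    vals = np.where(mask, np.nan, baseline.values - cf.values)
    return Raster(baseline.grid, vals, mask)


def mortality_chain(
    pop: Raster,
    rates: MortalityTable,
    hvi: HVITable,
    admin: Raster,
    dt_defor: Raster,
    classes: PixelClassMap | None = None,
    bound: str = "central",
    literal_percent: bool = False,
) -> MortalityField:
    """Evaluate the full four-step chain for one rate bound."""
    baseline = baseline_mortality(pop, rates, admin, bound)
    f = pct_increase(dt_defor, hvi, admin, classes, literal_percent)
    cf = counterfactual_mortality(baseline, f)
    heat = attributable_mortality(baseline, cf)
    return MortalityField(baseline, f, cf, heat, bound)


def mortality_with_bounds(
    pop: Raster,
    rates: MortalityTable,
    hvi: HVITable,
    admin: Raster,
    dt_defor: Raster,
    classes: PixelClassMap | None = None,
    literal_percent: bool = False,
) -> dict[str, MortalityField]:
    """The chain at the central rate and both CI ends (low ≤ central ≤ high)."""
    return {
        b: mortality_chain(pop, rates, hvi, admin, dt_defor, classes, b, literal_percent)
        for b in BOUNDS
    }


def total_heat_mortality(
    dt_total: DeltaT,
    pop: Raster,
    rates: MortalityTable,
    hvi: HVITable,
    admin: Raster,
    classes: PixelClassMap | None = None,
    bound: str = "central",
    restrict_positive: bool = True,
    pixel_set: np.ndarray | None = None,
) -> MortalityField:
    """Same chain on the *total* temperature change over the same pixels.

    Supports the share statistic attributable/total, which can exceed 1
    where controls cooled on balance.  ``restrict_positive`` keeps the
    positive-change restriction (on by default); ``pixel_set`` optionally
    restricts to an explicit boolean pixel mask.
    """
    r = dt_total.raster
    vals = r.values.copy()
    mask = r.mask.copy()
    if pixel_set is not None:
        outside = ~np.asarray(pixel_set, dtype=bool)
        vals[outside] = np.nan
        mask |= outside
    if not restrict_positive:
        # negative totals still contribute zero (no cooling credit), but we
        # keep them unmasked so per-pixel shares stay defined
        pass
    dt_r = Raster(r.grid, np.where(mask, np.nan, vals), mask)
    return mortality_chain(pop, rates, hvi, admin, dt_r, classes, bound)
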