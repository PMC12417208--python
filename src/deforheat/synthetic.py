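"""Seeded synthetic input worlds with known ground truth.

A world emulates the statistical structure the analysis assumes: clustered
forest loss embedded in a continuous forested matrix, a spatially smooth
background warming trend, a warming signal proportional to the
percentage-point cover loss (slope ``beta``), optional heteroscedastic
noise, clustered population, admin units with mortality rates and CIs,
and per-region heat vulnerability indices.  The construction

    dT(pixel) = trend(pixel) + beta * loss_pct(pixel) + noise(pixel)

makes the true induced change ``beta * loss_pct`` known exactly, so the
whole attribution chain can be validated against ground truth.  Identical
seeds produce bit-identical worlds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from deforheat import forest_change as fc
from deforheat import heat_mortality as hm
from deforheat.attribution import AttributionResult
from deforheat.exposure import ExposureSummary
from deforheat.raster import GridSpec, Raster, RasterError, read_raster, write_raster
from deforheat.surface_change import DeltaT, LstStack

__all__ = [
    "TrendSpec",
    "WorldParams",
    "GroundTruth",
    "World",
    "generate_world",
    "recovery_metrics",
]


@dataclass(frozen=True)
class TrendSpec:
    """Background (non-deforestation) warming component of dT.

    ``constant``: uniform offset; ``gradient``: planar field
    ``c + g_lat*(lat-lat0) + g_lon*(lon-lon0)``; ``elevation_lapse``:
    ``c + lapse * elevation``.
    """

    kind: str = "constant"
    constant: float = 0.3
    grad_lat: float = 0.0
    grad_lon: float = 0.0
    lapse: float = 0.0  # °C per meter

    def evaluate(self, grid: GridSpec, elevation: np.ndarray) -> np.ndarray:
        lat, lon = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
        if self.kind == "constant":
            return np.full(grid.shape, self.constant)
        if self.kind == "gradient":
            lat0 = 0.5 * (grid.lat_min + grid.lat_max)
            lon0 = 0.5 * (grid.lon_min + grid.lon_max)
            return self.constant + self.grad_lat * (lat - lat0) + self.grad_lon * (lon - lon0)
        if self.kind == "elevation_lapse":
            return self.constant + self.lapse * elevation
        raise RasterError(f"unknown trend kind {self.kind!r}")


@dataclass(frozen=True)
class WorldParams:
    """Knobs for :func:`generate_world`; all scales strictly positive."""

    grid: GridSpec = field(default_factory=lambda: GridSpec(30.0, -1.25, 1.25, 0.0, 2.5))
    seed: int = 0
    beta: float = 0.02  # °C per %-pt loss
    trend: TrendSpec = field(default_factory=TrendSpec)
    noise_sigma: float = 0.0  # °C, i.i.d. per pixel
    correlated_noise_sigma: float = 0.0  # °C, smooth field
    n_clusters: int = 15
    cluster_radius_deg: float = 0.05
    loss_intensity_range: tuple[float, float] = (20.0, 60.0)  # peak %-pt loss
    background_cover_range: tuple[float, float] = (60.0, 95.0)
    nonforest_fraction: float = 0.10
    n_gain_patches: int = 1
    gain_magnitude: float = 60.0  # %-pt extent increase inside gain patches
    elevation_amplitude: float = 120.0  # meters
    pop_log_mu: float = 1.5
    pop_log_sigma: float = 1.0
    pop_cluster_factor: float = 25.0
    n_regions: int = 3
    admins_per_region: int = 3
    rate_range: tuple[float, float] = (500.0, 900.0)
    ci_width_frac: float = 0.15
    hvi_range: tuple[float, float] = (2.0, 6.0)
    qc_bad_fraction: float = 0.02
    lst_mode: str = "delta_only"  # or "stacks"
    periods_per_month: int = 3
    start_years: tuple[int, ...] = (2001, 2002, 2003)
    end_years: tuple[int, ...] = (2018, 2019, 2020)
    base_lst_k: float = 298.0

    def __post_init__(self) -> None:
        for name in ("cluster_radius_deg", "elevation_amplitude"):
            if getattr(self, name) <= 0:
                raise RasterError(f"{name} must be strictly positive")
        if self.noise_sigma < 0 or self.correlated_noise_sigma < 0:
            raise RasterError("noise scales must be non-negative")
        span = min(
            self.grid.lat_max - self.grid.lat_min, self.grid.lon_max - self.grid.lon_min
        )
        if 2 * self.cluster_radius_deg >= span:
            raise RasterError("cluster radius exceeds grid extent")
        if self.lst_mode not in ("delta_only", "stacks"):
            raise RasterError(f"unknown lst_mode {self.lst_mode!r}")


@dataclass
class GroundTruth:
    """Deterministic truth derived from the params before noise."""

    beta: float
    loss_pct: Raster  # positive %-pt loss, 0 outside clusters
    true_dt_defor: Raster  # beta * loss at deforested pixels, masked elsewhere
    true_exposed_pop: float
    true_heat_mort: float


@dataclass
class World:
    """A complete, seeded input set plus its ground truth."""

    params: WorldParams
    cover2001: fc.ForestCover
    cover2020: fc.ForestCover
    extent2000: Raster
    extent2020: Raster
    elevation: Raster
    population: Raster
    admin_ids: Raster
    regions: Raster
    dt_total: DeltaT
    rates: hm.MortalityTable
    hvi: hm.HVITable
    truth: GroundTruth
    lst_start: LstStack | None = None
    lst_end: LstStack | None = None

    def region_names(self) -> dict[int, str]:
        return {i: f"region_{i}" for i in range(self.params.n_regions)}

    # -- serialisation -----------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_raster(self.cover2001.raster, d / "cover2001.nc", "cover")
        write_raster(self.cover2020.raster, d / "cover2020.nc", "cover")
        write_raster(self.extent2000, d / "extent2000.nc", "extent")
        write_raster(self.extent2020, d / "extent2020.nc", "extent")
        write_raster(self.elevation, d / "elevation.nc", "elevation")
        write_raster(self.population, d / "population.nc", "population")
        write_raster(self.admin_ids, d / "admin_ids.nc", "admin_id")
        write_raster(self.regions, d / "regions.nc", "region_id")
        write_raster(self.dt_total.raster, d / "dt_total.nc", "dt")
        write_raster(self.truth.true_dt_defor, d / "true_dt_defor.nc", "dt")
        write_raster(self.truth.loss_pct, d / "true_loss_pct.nc", "loss")
        self.rates.to_csv(d / "rates.csv")
        self.hvi.to_csv(d / "hvi.csv")
        if self.lst_start is not None:
            self.lst_start.to_netcdf(d / "lst_start.nc")
        if self.lst_end is not None:
            self.lst_end.to_netcdf(d / "lst_end.nc")
        meta = {
            "seed": self.params.seed,
            "beta": self.params.beta,
            "true_exposed_pop": self.truth.true_exposed_pop,
            "true_heat_mort": self.truth.true_heat_mort,
            "n_regions": self.params.n_regions,
        }
        (d / "truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True))

    @classmethod
    def load(cls, directory: str | Path, params: WorldParams | None = None) -> "World":
        d = Path(directory)
        meta = json.loads((d / "truth.json").read_text())
        cover2001 = fc.ForestCover(read_raster(d / "cover2001.nc", "cover"), 2001)
        cover2020 = fc.ForestCover(read_raster(d / "cover2020.nc", "cover"), 2020)
        loss_pct = read_raster(d / "true_loss_pct.nc", "loss")
        true_dt = read_raster(d / "true_dt_defor.nc", "dt")
        truth = GroundTruth(
            beta=meta["beta"],
            loss_pct=loss_pct,
            true_dt_defor=true_dt,
            true_exposed_pop=meta["true_exposed_pop"],
            true_heat_mort=meta["true_heat_mort"],
        )
        lst_start = LstStack.from_netcdf(d / "lst_start.nc") if (d / "lst_start.nc").exists() else None
        lst_end = LstStack.from_netcdf(d / "lst_end.nc") if (d / "lst_end.nc").exists() else None
        if params is None:
            params = WorldParams(
                grid=cover2001.raster.grid,
                seed=meta["seed"],
                beta=meta["beta"],
                n_regions=meta["n_regions"],
            )
        return cls(
            params=params,
            cover2001=cover2001,
            cover2020=cover2020,
            extent2000=read_raster(d / "extent2000.nc", "extent"),
            extent2020=read_raster(d / "extent2020.nc", "extent"),
            elevation=read_raster(d / "elevation.nc", "elevation"),
            population=read_raster(d / "population.nc", "population"),
            admin_ids=read_raster(d / "admin_ids.nc", "admin_id"),
            regions=read_raster(d / "regions.nc", "region_id"),
            dt_total=DeltaT(read_raster(d / "dt_total.nc", "dt")),
            rates=hm.MortalityTable.from_csv(d / "rates.csv"),
            hvi=hm.HVITable.from_csv(d / "hvi.csv"),
            truth=truth,
            lst_start=lst_start,
            lst_end=lst_end,
        )


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma_cells: float) -> np.ndarray:
    """Zero-mean unit-variance smooth random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _admin_layout(grid: GridSpec, n_regions: int, admins_per_region: int) -> tuple[np.ndarray, np.ndarray]:
    """Regions as longitude stripes, admins as latitude stripes within them."""
    cols = np.arange(grid.n_cols)
    region = np.minimum((cols * n_regions) // grid.n_cols, n_regions - 1)
    region_2d = np.broadcast_to(region[None, :], grid.shape).copy()
    rows = np.arange(grid.n_rows)
    admin_row = np.minimum((rows * admins_per_region) // grid.n_rows, admins_per_region - 1)
    admin_2d = region_2d * 100 + np.broadcast_to(admin_row[:, None], grid.shape)
    return region_2d.astype(np.int32), admin_2d.astype(np.int32)


def _build_stack(
    grid: GridSpec,
    target: np.ndarray,
    years: tuple[int, ...],
    periods_per_month: int,
    qc_bad_fraction: float,
    rng: np.random.Generator,
) -> LstStack:
    """8-day-style layers whose per-month (and period) mean equals ``target``.

    The monthly climatology is flat, so QC dropouts cannot bias the period
    mean.  A configurable fraction of observations get failing QC values
    and a deliberately corrupted LST, so screening is observable.
    """
    periods = [(y, m) for y in years for m in range(1, 13) for _ in range(periods_per_month)]
    n = len(periods)
    lst = np.broadcast_to(target, (n,) + grid.shape).copy()
    emis = np.full((n,) + grid.shape, 0.01)
    err = np.full((n,) + grid.shape, 0.5)
    if qc_bad_fraction > 0:
        bad = rng.random((n,) + grid.shape) < qc_bad_fraction
        half = rng.random((n,) + grid.shape) < 0.5
        emis[bad & half] = 0.03
        err[bad & ~half] = 1.5
        lst[bad] += 5.0  # corrupted values must be screened out
    return LstStack(grid, lst, emis, err, periods)


def generate_world(params: WorldParams) -> World:
    """Generate a complete input world; identical seeds are bit-identical."""
    grid = params.grid
    rng = np.random.default_rng(params.seed)
    shape = grid.shape
    res = grid.res_deg
    sigma_cells = max(3.0, min(shape) / 8.0)

    # elevation: smooth, mild local relief so the ±50 m screen rarely binds
    elevation_v = params.elevation_amplitude * _smooth_field(rng, shape, sigma_cells)
    elevation = Raster(grid, elevation_v)

    # year-2001 canopy cover: smooth forested matrix with non-forest patches
    cover_lo, cover_hi = params.background_cover_range
    cover_v = cover_lo + (cover_hi - cover_lo) * (
        0.5 * (_smooth_field(rng, shape, sigma_cells) + 1.0)
    )
    cover_v = np.clip(cover_v, 0.0, 100.0)
    nonforest_score = _smooth_field(rng, shape, sigma_cells / 2.0)
    nf_cut = np.quantile(nonforest_score, params.nonforest_fraction)
    cover_v[nonforest_score < nf_cut] = 5.0

    # clustered loss: Gaussian-profile clusters away from the domain edge
    lat_c, lon_c = np.meshgrid(grid.lat_centers, grid.lon_centers, indexing="ij")
    loss_v = np.zeros(shape)
    r = params.cluster_radius_deg
    lo_i, hi_i = params.loss_intensity_range
    for _ in range(params.n_clusters):
        cy = rng.uniform(grid.lat_min + 2 * r, grid.lat_max - 2 * r)
        cx = rng.uniform(grid.lon_min + 2 * r, grid.lon_max - 2 * r)
        peak = rng.uniform(lo_i, hi_i)
        d2 = (lat_c - cy) ** 2 + (lon_c - cx) ** 2
        prof = peak * np.exp(-d2 / (2 * (r / 2.0) ** 2))
        prof[prof < 0.5] = 0.0  # clip far tails: clean control matrix
        loss_v = np.maximum(loss_v, prof)
    loss_v = np.minimum(loss_v, cover_v)  # cannot lose more than exists
    loss_v[cover_v < fc.DEFAULT_COVER_THRESHOLD] = 0.0

    cover2020_v = cover_v - loss_v
    cover2001 = fc.ForestCover(Raster(grid, cover_v), 2001)
    cover2020 = fc.ForestCover(Raster(grid, cover2020_v), 2020)

    # forest extent: proxied by cover, plus isolated regrowth patches that
    # start from low extent in 2000 so the net gain exceeds the threshold
    extent2000_v = cover_v.copy()
    extent2020_v = np.clip(cover2020_v.copy(), 0.0, 100.0)
    for _ in range(params.n_gain_patches):
        cy = rng.uniform(grid.lat_min + 2 * r, grid.lat_max - 2 * r)
        cx = rng.uniform(grid.lon_min + 2 * r, grid.lon_max - 2 * r)
        patch = ((lat_c - cy) ** 2 + (lon_c - cx) ** 2) < (r / 2.0) ** 2
        patch &= loss_v == 0.0  # regrowth where nothing was lost
        extent2000_v[patch] = 15.0
        extent2020_v[patch] = np.clip(15.0 + params.gain_magnitude, 0.0, 100.0)
    extent2000 = Raster(grid, extent2000_v)
    extent2020 = Raster(grid, np.minimum(extent2020_v, 100.0))

    # population: log-normal base, amplified near a subset of loss clusters
    pop_v = np.exp(rng.normal(params.pop_log_mu, params.pop_log_sigma, shape))
    pop_bump = np.zeros(shape)
    for _ in range(max(1, params.n_clusters // 3)):
        cy = rng.uniform(grid.lat_min + 2 * r, grid.lat_max - 2 * r)
        cx = rng.uniform(grid.lon_min + 2 * r, grid.lon_max - 2 * r)
        d2 = (lat_c - cy) ** 2 + (lon_c - cx) ** 2
        pop_bump += np.exp(-d2 / (2 * r**2))
    pop_v = pop_v * (1.0 + params.pop_cluster_factor * pop_bump)
    population = Raster(grid, pop_v)

    region_v, admin_v = _admin_layout(grid, params.n_regions, params.admins_per_region)
    regions = Raster(grid, region_v)
    admin_ids = Raster(grid, admin_v)

    # admin mortality rates with CIs; HVIs per region, resolved via parents
    admin_list = sorted(np.unique(admin_v).tolist())
    rates_c = rng.uniform(*params.rate_range, size=len(admin_list))
    rates = hm.MortalityTable(
        pd.DataFrame(
            {
                "admin_id": admin_list,
                "rate_per_100k": rates_c,
                "ci_low": rates_c * (1.0 - params.ci_width_frac),
                "ci_high": rates_c * (1.0 + params.ci_width_frac),
                "year": 2019,
            }
        )
    )
    hvi_vals = rng.uniform(*params.hvi_range, size=params.n_regions)
    hvi = hm.HVITable(
        entries={int(rid): float(hvi_vals[rid]) for rid in range(params.n_regions)},
        parents={int(a): int(a) // 100 for a in admin_list},
    )

    # temperature change: trend + beta * loss + noise
    trend_v = params.trend.evaluate(grid, elevation_v)
    dt_v = trend_v + params.beta * loss_v
    if params.correlated_noise_sigma > 0:
        dt_v = dt_v + params.correlated_noise_sigma * _smooth_field(rng, shape, sigma_cells / 2.0)
    if params.noise_sigma > 0:
        dt_v = dt_v + rng.normal(0.0, params.noise_sigma, shape)
    dt_total = DeltaT(Raster(grid, dt_v))

    lst_start = lst_end = None
    if params.lst_mode == "stacks":
        base = params.base_lst_k - 6.5e-3 * elevation_v  # standard lapse rate
        lst_start = _build_stack(
            grid, base, params.start_years, params.periods_per_month,
            params.qc_bad_fraction, rng,
        )
        lst_end = _build_stack(
            grid, base + dt_v, params.end_years, params.periods_per_month,
            params.qc_bad_fraction, rng,
        )

    # ground truth from the pre-noise construction
    gain_mask = fc.extent_gain_mask(extent2000, extent2020)
    classes = fc.classify_pixels(cover2001, fc.cover_change(cover2001, cover2020), gain_mask)
    defor = classes.is_class(fc.PixelClass.DEFORESTED)
    true_dt_v = np.where(defor, params.beta * loss_v, np.nan)
    true_dt = Raster(grid, true_dt_v, ~defor)
    true_exposed = float(pop_v[defor & (params.beta * loss_v > 0)].sum())
    truth_mort = hm.mortality_chain(
        population, rates, hvi, admin_ids, true_dt, classes, "central"
    )
    truth = GroundTruth(
        beta=params.beta,
        loss_pct=Raster(grid, loss_v.copy()),
        true_dt_defor=true_dt,
        true_exposed_pop=true_exposed,
        true_heat_mort=truth_mort.total(),
    )

    return World(
        params=params,
        cover2001=cover2001,
        cover2020=cover2020,
        extent2000=extent2000,
        extent2020=extent2020,
        elevation=elevation,
        population=population,
        admin_ids=admin_ids,
        regions=regions,
        dt_total=dt_total,
        rates=rates,
        hvi=hvi,
        truth=truth,
        lst_start=lst_start,
        lst_end=lst_end,
    )


def recovery_metrics(
    truth: GroundTruth,
    estimate: AttributionResult,
    exposure: ExposureSummary | None = None,
    attributable_deaths: float | None = None,
) -> dict[str, float]:
    """Bias/RMSE of the recovered induced change against ground truth,
    plus relative errors of exposure and deaths when supplied."""
    est = estimate.dt_defor
    if est.grid != truth.true_dt_defor.grid:
        raise RasterError("estimate and truth live on different grids")
    both = est.valid & truth.true_dt_defor.valid
    diff = est.values[both] - truth.true_dt_defor.values[both]
    out: dict[str, float] = {
        "n_compared": float(both.sum()),
        "bias": float(diff.mean()) if diff.size else float("nan"),
        "rmse": float(np.sqrt(np.mean(diff**2))) if diff.size else float("nan"),
    }
    loss = truth.loss_pct.values[both]
    with np.errstate(invalid="ignore", divide="ignore"):
        per_point = est.values[both] / loss
    ok = np.isfinite(per_point)
    out["beta_hat"] = float(per_point[ok].mean()) if ok.any() else float("nan")
    if exposure is not None and truth.true_exposed_pop > 0:
        out["rel_err_exposed_pop"] = (
            exposure.pop_exposed - truth.true_exposed_pop
        ) / truth.true_exposed_pop
    if attributable_deaths is not None and truth.true_heat_mort > 0:
        out["rel_err_heat_mort"] = (
            attributable_deaths - truth.true_heat_mort
        ) / truth.true_heat_mort
    return out
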