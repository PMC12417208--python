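"""End-to-end orchestration from a single structured config.

Stage order is fixed: forest → ΔT → attribution → exposure → mortality →
report.  Every threshold lands in the run manifest together with a config
hash, so reruns with an identical config are reproducible bit for bit
(no timestamps are recorded).  Output directories are write-once: a
directory already holding a manifest is refused.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

import deforheat
from deforheat import forest_change as fc
from deforheat import heat_mortality as hm
from deforheat import surface_change as sc
from deforheat.attribution import MatchParams, attribute
from deforheat.exposure import exposure_counts
from deforheat.raster import Raster, RasterError, cell_area_weights, write_raster
from deforheat.reporting import build_region_table, render_table
from deforheat.synthetic import World

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """All inputs, thresholds and sensitivity toggles for one run.

    Defaults correspond to the primary analysis configuration; the
    sensitivity toggles mirror the documented alternatives
    (loss threshold 1 vs 2 %-pt, gain threshold 20 vs 50 %-pt,
    alternative year windows, LST→air adjustment, mortality basis).
    """

    world_dir: str = ""
    out_dir: str = ""
    seed: int = 0
    # forest stage
    loss_threshold: float = fc.DEFAULT_LOSS_THRESHOLD
    control_threshold: float = fc.DEFAULT_CONTROL_THRESHOLD
    cover_threshold: float = fc.DEFAULT_COVER_THRESHOLD
    gain_threshold: float = fc.DEFAULT_GAIN_THRESHOLD
    # temperature stage
    qc_emissivity: float = sc.QC_EMISSIVITY_MAX
    qc_lst_error: float = sc.QC_LST_ERROR_MAX_K
    start_years: list[int] = field(default_factory=lambda: [2001, 2002, 2003])
    end_years: list[int] = field(default_factory=lambda: [2018, 2019, 2020])
    air_adjustment_slope: float | None = None
    # attribution stage
    primary_radius: float = 0.25
    fallback_radius: float = 0.50
    elevation_band: float = 50.0
    smooth_radius: float = 0.10
    min_loss_for_smoothing: float = 5.0
    z_threshold: float = 3.0
    degree_space_distance: bool = False
    # exposure / mortality
    thresholds: list[float] = field(default_factory=lambda: [0.0, 1.0, 2.0, 3.0])
    mortality_basis: str = "non_accidental"
    literal_percent: bool = False
    restrict_total_positive: bool = True

    def match_params(self) -> MatchParams:
        return MatchParams(
            primary_radius=self.primary_radius,
            fallback_radius=self.fallback_radius,
            elevation_band=self.elevation_band,
            smooth_radius=self.smooth_radius,
            min_loss_for_smoothing=self.min_loss_for_smoothing,
            z_threshold=self.z_threshold,
            degree_space_distance=self.degree_space_distance,
        )

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # output location cannot change results
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML config file, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        wrapped.__name__ = fn.__name__
        return wrapped

    return deco


@_stage("forest")
def forest_stage(world: World, config: PipelineConfig):
    change = fc.cover_change(world.cover2001, world.cover2020)
    gain = fc.extent_gain_mask(world.extent2000, world.extent2020, config.gain_threshold)
    classes = fc.classify_pixels(
        world.cover2001,
        change,
        gain,
        loss_threshold=config.loss_threshold,
        cover_threshold=config.cover_threshold,
        control_threshold=config.control_threshold,
    )
    return change, gain, classes


@_stage("delta_t")
def delta_t_stage(world: World, config: PipelineConfig, gain: Raster) -> sc.DeltaT:
    if world.lst_start is not None and world.lst_end is not None:
        dt = _delta_t_from_stacks(world, config)
    else:
        dt = world.dt_total
    if config.air_adjustment_slope is not None:
        dt = sc.apply_air_adjustment(dt, sc.AirAdjustment(config.air_adjustment_slope))
    # extent-gain pixels are removed from the temperature data entirely
    r = dt.raster
    mask = r.mask | gain.values.astype(bool)
    return sc.DeltaT(Raster(r.grid, np.where(mask, np.nan, r.values), mask))


def _delta_t_from_stacks(world: World, config: PipelineConfig) -> sc.DeltaT:
    def period(stack: sc.LstStack, years: list[int]) -> Raster:
        screened = sc.qc_filter(stack, config.qc_emissivity, config.qc_lst_error)
        monthly = {}
        for y, m in sorted(set(screened.periods)):
            if y in years:
                monthly[(y, m)] = sc.monthly_composite(screened, y, m)
        return sc.period_mean(monthly, years)

    start = period(world.lst_start, config.start_years)
    end = period(world.lst_end, config.end_years)
    return sc.delta_t(start, end)


def run_pipeline(config: PipelineConfig, world: World | None = None) -> dict[str, Any]:
    """Run all stages; write outputs and return the manifest."""
    if world is None:
        if not config.world_dir:
            raise PipelineError("config must set world_dir (or pass a World)")
        world = World.load(config.world_dir)
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        if (out / "manifest.json").exists():
            raise PipelineError(f"output directory {out} already holds a run (write-once)")
        out.mkdir(parents=True, exist_ok=True)

    change, gain, classes = forest_stage(world, config)
    dt_total = delta_t_stage(world, config, gain)
    weights = cell_area_weights(world.params.grid if world.params else dt_total.raster.grid)

    try:
        result = attribute(
            dt_total,
            classes,
            world.elevation,
            change,
            config.match_params(),
            regions=world.regions,
            weights=weights,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'attribution' failed: {exc}") from exc

    try:
        summary = exposure_counts(
            result.dt_defor,
            world.population,
            classes,
            tuple(config.thresholds),
            weights,
            scope="all",
        )
    except Exception as exc:
        raise PipelineError(f"stage 'exposure' failed: {exc}") from exc

    try:
        mortality = hm.mortality_with_bounds(
            world.population,
            world.rates,
            world.hvi,
            world.admin_ids,
            result.dt_defor,
            classes,
            literal_percent=config.literal_percent,
        )
        pixel_set = classes.is_class(fc.PixelClass.DEFORESTED) & result.dt_defor.valid
        total_mort = hm.total_heat_mortality(
            dt_total,
            world.population,
            world.rates,
            world.hvi,
            world.admin_ids,
            classes,
            restrict_positive=config.restrict_total_positive,
            pixel_set=pixel_set,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'mortality' failed: {exc}") from exc

    try:
        table = build_region_table(
            world.regions,
            world.region_names(),
            dt_total.raster,
            result.dt_defor,
            world.population,
            weights,
            classes,
            mortality,
            total_mort,
        )
    except Exception as exc:
        raise PipelineError(f"stage 'report' failed: {exc}") from exc

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "package_version": deforheat.__version__,
        "stage_stats": {
            "pixel_classes": classes.counts(),
            "attribution": result.stats(),
            "pop_exposed": summary.pop_exposed,
            "pop_forest_loss": summary.pop_total_forest_loss,
            "deaths_central": mortality["central"].heat_mort.values[
                mortality["central"].heat_mort.valid
            ].sum(),
        },
    }

    if out is not None:
        write_raster(result.dt_defor, out / "dt_defor.nc", "dt")
        write_raster(result.dt_defor_raw, out / "dt_defor_raw.nc", "dt")
        write_raster(result.dt_per_point_smoothed, out / "dt_per_point_smoothed.nc", "dtpp")
        write_raster(mortality["central"].heat_mort, out / "heat_mort_central.nc", "deaths")
        table.to_csv(out / "region_report.csv", index=False)
        render_table(table).to_csv(out / "region_report_rounded.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=float)
        )

    manifest["_objects"] = {
        "classes": classes,
        "dt_total": dt_total,
        "attribution": result,
        "exposure": summary,
        "mortality": mortality,
        "total_mortality": total_mort,
        "report": table,
    }
    return manifest
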