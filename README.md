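# deforheat

Quantifies the local surface warming induced by tropical forest loss from
gridded temperature-change data, and converts that warming into population
exposure and heat-attributable non-accidental mortality.

The core algorithm is a moving-window counterfactual match: for every
"deforested" pixel (≥ 2 percentage points of canopy-cover loss on ≥ 10 %
initial cover), the mean temperature change of nearby elevation-matched
"non-deforested" pixels (< 0.5 %-pt loss, within 0.25°–0.50° and ±50 m)
is subtracted to remove the background climate signal. The residual is
normalised per percentage point of loss, smoothed over a 0.10° rolling
circle with a one-pass z-score outlier screen (|z| > 3 dropped, members
need ≥ 5 %-pt loss; regional-mean fallback otherwise), and multiplied
back by the loss. Positive induced warming is then fed through a
vulnerability-index mortality chain:

    baseline  = pop × rate / 100,000
    f         = (HVI / 100) × ΔT_induced        (only where ΔT_induced > 0)
    counterfactual = baseline / (1 + f)
    attributable   = baseline − counterfactual  = baseline · f / (1 + f)

with uncertainty bounds propagated from the 95 % CI of the mortality rates.

Because the real satellite/population/mortality inputs are terabyte-scale,
the package ships a seeded synthetic-world generator
(`deforheat.synthetic`) that emulates their statistical structure with
known ground truth (`ΔT = trend + β·loss + noise`), so every stage — and
the full pipeline — is testable offline.

## Layout

| module | role |
| --- | --- |
| `deforheat.raster` | grid model, NetCDF I/O, bilinear + area-weighted regridding, cos-latitude weights |
| `deforheat.surface_change` | QC screening (emissivity error > 0.02, LST error > 1 K), monthly/3-year compositing, ΔT, LST→air adjustment |
| `deforheat.forest_change` | annual cover, %-pt change, extent-gain exclusion (> 50 %-pt), pixel classification |
| `deforheat.attribution` | the counterfactual matching chain described above |
| `deforheat.exposure` | population/area-weighted warming, exposure counts above thresholds |
| `deforheat.heat_mortality` | HVI + mortality tables, the four-step attributable-mortality chain, CI bounds, total-warming variant |
| `deforheat.reporting` | admin/region tables, rates per 100,000, warming shares, presentation rounding |
| `deforheat.synthetic` | seeded worlds with ground truth, recovery metrics |
| `deforheat.pipeline` / `deforheat.cli` | YAML-configured orchestration and the `deforheat` CLI |

## CLI

```bash
# generate a seeded synthetic world (optionally with 8-day LST stacks)
deforheat synth --seed 42 --beta 0.02 --noise 0.2 --out world/

# full chain: forest → ΔT → attribution → exposure → mortality → report
deforheat run --world world/ --out run1/

# individual stages / sensitivity switches
deforheat forest --world world/ --loss-threshold 1.0 --gain-threshold 20
deforheat attribute --world world/ --radius 0.25 --elev-band 50 --z 3 --out attr/
deforheat report --world world/
```

`deforheat run` writes per-pixel NetCDF outputs, region report CSVs
(full-precision and rounded), and a `manifest.json` recording the config
hash and per-stage pixel counts; identical configs reproduce outputs
bit-identically, and a run directory is write-once.

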