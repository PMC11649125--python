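# agbpipe

Grassland aboveground-biomass (AGB) analysis as a tested, reusable
pipeline: light-use-efficiency NPP estimation from NDVI and meteorology,
root:shoot allocation of production to standing biomass, grazing-intensity
estimation, per-pixel trend/stability mapping, and random-forest driver
attribution — exercised end-to-end on synthetic gridded scenarios with
known ground truth.

It is written for ecologists and remote-sensing analysts who run this kind
of regional analysis (arid and semi-arid rangelands monitored with
coarse-resolution vegetation indices) and want every stage to be a tested
library call rather than a one-off script.

## The model

Monthly net primary production per pixel combines absorbed radiation with a
stress-damped light-use efficiency:

```
NPP(x,t) = APAR(x,t) · ε(x,t)
APAR     = SOL · FPAR(NDVI) · 0.5
ε        = Tε1(T_opt) · Tε2(T, T_opt) · Wε(PPT, PET) · ε_max
```

Annual NPP (g C/m²) becomes aboveground biomass with per-type root:shoot
ratios R/S and carbon fractions Ca, Cb:

```
AGB = NPP / (Ca + (R/S)·Cb)        # conserves carbon: NPP = Ca·AGB + Cb·(R/S)·AGB
```

carbon density is 0.45·AGB, and grazing intensity balances production
against standing biomass per livestock unit:

```
GI = (ANPP_t − AGB_t) / (P·T)      # P = daily intake, T = grazing days
```

Trends use the Theil-Sen slope and Mann-Kendall test per pixel (five
improvement/degradation classes), stability the coefficient of variation
(five quantile levels), and attribution per-pixel Pearson correlation
(SN/NSN/NSP/SP classes) plus random-forest permutation importance of the
seven drivers T, PPT, VPD, SR, RH, SM and GI. `docs/methods.md` documents
every sub-model, default and design choice.

Because the real archives (AVHRR-era NDVI, station meteorology, reanalysis
soil moisture) cannot ship with a package, the `synthio` module generates
scenarios with the same statistical structure — seasonal NDVI with gaps and
spike outliers, trending meteorology, two-layer soil moisture, contiguous
type maps — together with the exact truth (clean NDVI, NPP surface,
injected slopes, planted driver effects), so recovery is measured, not
assumed.

## Worked example

```
agbpipe run-all --config configs/demo.yaml
```

or equivalently in Python:

```python
from agbpipe import PipelineConfig, run_pipeline
cfg = PipelineConfig(seed=1, output_dir="results/demo",
                     scenario={"n_years": 10, "grid_shape": (12, 12)})
manifest = run_pipeline(cfg)
```

On the demo scenario (12×12 grid, 10 years, biweekly NDVI with 5% gaps and
2% spikes) the stages report:

```
filled 1728 gaps, removed 699 outliers         # all 691 planted spikes found
mean annual NPP 797.9 g C/m2                   # truth-recovery RMSE 3.8 ≤ bound 7.9
mean AGB 295.7 g/m2 (carbon_partition)
mean GI 0.89 LSU/ha
```

Numbers to read: the preprocessing screen recalls 100% of the planted ×2
spikes (8 false positives in 34 560 cells) and gap-filled cells deviate
from the noise-free truth by 0.019 NDVI on average, inside the 0.02
observation noise; the NPP field reproduces the generator's truth surface
within its noise-propagation bound; per-type AGB follows the allocation
parameters (the alpine meadow's R/S = 6.8 keeps its biomass below the
typical steppe's despite similar production).

The numbered scripts under `analysis/` walk the same analysis stage by
stage (`01_generate_scenario.py` … `06_driver_attribution.py`), printing
what each stage found and writing its tables under `results/analysis/`.

On a 35-year scenario with a known 1 g/m²/yr biomass trend against
10 g/m² interannual noise, the pixel-median Theil-Sen slope comes back as
0.985 and Mann-Kendall flags 100% of pixels at α = 0.05; with no trend the
false-positive rate is 0.048. With planted driver effects ordered
GI > SM > PPT ≫ others, the random forest puts GI first and the planted
trio in the top three.

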