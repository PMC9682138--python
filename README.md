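# stabdim

Dimensionality of ecosystem stability from gridded vegetation-index and
climate time series.

Ecosystem stability is not one number: the temporal invariability of
productivity, its resistance to climate anomalies, and its resilience
(speed of return after perturbation) can vary independently — or move in
lockstep. `stabdim` quantifies how coupled these three components are
across a landscape and how that coupling changes between two study
periods, the workflow used in regional grassland studies built on
satellite NDVI, interpolated climate surfaces and county livestock
records. It is aimed at researchers in remote-sensing ecology and
ecosystem-stability analysis who want the full pipeline — from raw
monthly grids to attribution — as tested, seedable Python.

## The statistics at the core

Per pixel and period, after detrending and z-scoring, a lag-1
autoregressive model links the NDVI anomaly to climate anomalies:

    x_t = α·T_t + β·P_t + γ·R_t + δ·x_{t−1} + ε_t

Small |α|, |β|, |γ| mean high **resistance** (score −(|α|+|β|+|γ|)/3),
small |δ| means high **resilience** (score −|δ|), and **invariability**
is mean/SD of the series (SD from detrended residuals). Scores are
min–max normalized to 0–100 per period.

Within each county × grassland-type unit, the three pairwise Pearson
correlations among the components form a 3×3 correlation matrix with
eigenvalues λ₁ ≥ λ₂ ≥ λ₃. Its ellipsoid (semi-axes √λᵢ, volume
V = π^{n/2}/Γ(n/2+1)·∏λᵢ^{1/2}) is normalized by the largest semi-axis
and by the unit-sphere volume, giving the **dimensionality of stability**

    D = ∏ᵢ √(λᵢ/λ_max) ∈ [0, 1]

— 1 when the components are independent (sphere), 0 when fully coupled
(cigar). Between-period changes ΔD are attributed to trends in mean
annual temperature, precipitation, radiation and grazing intensity
(standard sheep units per hectare; sheep/goat = 1 SHU, yak/donkey/horse
= 4 SHU) via bivariate regressions and a random forest with out-of-bag
permutation importance (%IncMSE).

A synthetic-data module generates landscapes, climate, NDVI (by running
the same autoregressive model forward with known coefficients) and
livestock records, so every stage is testable against ground truth
without external downloads.

## Worked example

```python
from stabdim.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(seed=1)   # 8 counties x 3 types x 40 pixels, 2000-2017
result = run_pipeline(config, "out/")

m = result["manifest"]
print("retained pixels:", m["n_pixels_retained"])
print(m["delta_summary"])
for period, table in result["dimensionality"]["ellipsoids"].items():
    print(period, "mean dimensionality:", round(table["dimensionality"].mean(), 3))
```

prints

```
retained pixels: 960
{'mean_delta': -0.02368365306435994, 'pct_decreasing': 58.333333333333336,
 'pct_of_decreasing_above_threshold': 57.142857142857146}
2000-2008 mean dimensionality: 0.288
2009-2017 mean dimensionality: 0.265
```

All 960 simulated pixels pass the annual-NDVI ≥ 0.1 filter; the mean
dimensionality over the 24 county × type units drops from 0.288 to 0.265
between the periods, D decreases in 58 % of the (pixel-weighted) area,
and 57 % of that decreasing share drops by more than 20 % in relative
terms. `out/` receives `stability_pixels.csv` (per-pixel components),
`ellipsoids.csv` (per-unit correlations, eigenvalues, D),
`delta_dimensionality.csv`, `attribution.csv` and a `manifest.json`
recording the configuration hash and seed.

The same run is available from a shell:

```bash
stabdim simulate --seed 1 --workdir inputs/
stabdim run-all --seed 1 --from-inputs inputs/ --workdir out/
```

Two generator presets probe the statistic: `low_dimensionality` (a
shared latent factor couples the components across pixels, loading 0.8)
versus `high_dimensionality` (independent draws). The coupled preset
yields strictly lower mean D on the same landscape and seed — see
`stabdim.preset_scenario`.

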