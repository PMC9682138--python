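"""Two-period pipeline binding the stages together, with file I/O.

The flow mirrors the study design: simulate (or load) gridded NDVI and
climate plus county livestock records; preprocess each period into anomaly
series; compute per-pixel stability components; group them into county x
grassland-type spatial datasets and compute each unit's dimensionality of
stability; difference the two periods; and attribute the change to
between-period differences in climate and grazing trends.

Gridded inputs travel as NetCDF (pixel x time, classic format via the scipy
backend), tabular data as CSV, and every run writes a JSON manifest with the
configuration hash and seeds so outputs are traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import __version__ as _version
from . import attribution as attribution_mod
from . import dimensionality as dim_mod
from . import grazing, preprocessing, stability, synthetic
from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """All tunables of the two-period pipeline (defaults match the study
    design: periods 2000-2008 and 2009-2017, NDVI cutoff 0.1, 5-point
    quadratic Savitzky-Golay smoothing, 30-pixel minimum per spatial unit,
    500 forest trees)."""

    periods: tuple = ((2000, 2008), (2009, 2017))
    ndvi_threshold: float = 0.1
    sg_window: int | None = 5  # None skips smoothing (artifact-free inputs)
    sg_polyorder: int = 2
    min_pixels: int = 30
    resistance_combiner: str = "mean"
    weight_by_pixels: bool = True
    rf_trees: int = 500
    rf_max_features: float = 1 / 3
    rf_variant: str = "percent"
    seed: int = 0
    # synthetic-scenario shape
    n_counties: int = 8
    types_per_county: int = 3
    pixels_per_group: int = 40
    latent_loading: float = 0.4
    livestock_trend_per_period: tuple = (0.0, -0.02)

    def __post_init__(self) -> None:
        self.periods = tuple(tuple(int(y) for y in p) for p in self.periods)
        for start, end in self.periods:
            if end - start + 1 < 3:
                raise InvalidArgumentError("each period must span at least 3 years")
        for (s1, e1), (s2, e2) in zip(self.periods, self.periods[1:]):
            if s2 <= e1:
                raise InvalidArgumentError("periods must be non-overlapping and ordered")
        if self.ndvi_threshold <= 0 or self.min_pixels <= 0:
            raise InvalidArgumentError("thresholds must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)


# ---------------------------------------------------------------------------
# Input I/O
# ---------------------------------------------------------------------------


@dataclass
class PipelineInputs:
    landscape: synthetic.Landscape
    ndvi: xr.DataArray
    climate: dict[str, xr.DataArray]
    livestock: pd.DataFrame


def simulate_inputs(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineInputs:
    """Generate scenario inputs from the config's root seed (optionally
    writing them to ``outdir`` in the on-disk input layout)."""
    scenario = synthetic.generate_scenario(
        seed=config.seed,
        n_counties=config.n_counties,
        types_per_county=config.types_per_county,
        pixels_per_group=config.pixels_per_group,
        latent_loading=config.latent_loading,
        periods=config.periods,
        livestock_trend_per_period=list(config.livestock_trend_per_period)[
            : len(config.periods)
        ],
    )
    if outdir is not None:
        scenario.write(outdir)
    return PipelineInputs(
        landscape=scenario.landscape,
        ndvi=scenario.ndvi,
        climate=scenario.climate,
        livestock=scenario.livestock,
    )


def load_inputs(indir: str | Path) -> PipelineInputs:
    """Load the input layout written by :meth:`synthetic.Scenario.write`."""
    indir = Path(indir)
    landscape = synthetic.Landscape.from_frame(pd.read_csv(indir / "landscape.csv"))
    grids = {}
    for name in ("ndvi", "temperature", "precipitation", "radiation"):
        path = indir / f"{name}.nc"
        if not path.exists():
            raise InvalidArgumentError(f"missing input file {path}")
        with xr.open_dataset(path, engine="scipy") as ds:
            grids[name] = ds[name].load()
    livestock = pd.read_csv(indir / "livestock.csv")
    return PipelineInputs(
        landscape=landscape,
        ndvi=grids["ndvi"],
        climate={k: grids[k] for k in ("temperature", "precipitation", "radiation")},
        livestock=livestock,
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def preprocess_stage(
    inputs: PipelineInputs, config: PipelineConfig
) -> list[preprocessing.PreparedPeriod]:
    return preprocessing.prepare_periods(
        inputs.ndvi,
        inputs.climate,
        config.periods,
        ndvi_threshold=config.ndvi_threshold,
        sg_window=config.sg_window,
        sg_polyorder=config.sg_polyorder,
    )


def stability_stage(
    prepared: list[preprocessing.PreparedPeriod], config: PipelineConfig
) -> pd.DataFrame:
    """Long-format per-pixel stability table with a ``period`` column."""
    frames = []
    for prep in prepared:
        table = stability.stability_table(
            prep, resistance_combiner=config.resistance_combiner
        )
        table = table.reset_index()
        table.insert(0, "period", f"{prep.period[0]}-{prep.period[1]}")
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


def dimensionality_stage(
    stability_pixels: pd.DataFrame,
    landscape: synthetic.Landscape,
    config: PipelineConfig,
) -> dict:
    """Per-period ellipsoid tables plus the between-period delta (if any)."""
    per_period: dict[str, pd.DataFrame] = {}
    for period_label, group in stability_pixels.groupby("period", sort=True):
        triplets = group.set_index("pixel")[
            ["invariability", "resistance", "resilience"]
        ]
        datasets = dim_mod.group_space_for_time(
            triplets, landscape, min_pixels=config.min_pixels
        )
        per_period[period_label] = dim_mod.ellipsoid_table(datasets)

    result: dict = {"ellipsoids": per_period}
    if len(per_period) == 2:
        labels = sorted(per_period)
        shared = per_period[labels[0]].index.intersection(per_period[labels[1]].index)
        delta, summary = dim_mod.delta_dimensionality(
            per_period[labels[0]].loc[shared],
            per_period[labels[1]].loc[shared],
            weight_by_pixels=config.weight_by_pixels,
        )
        result["delta"] = delta
        result["delta_summary"] = summary
    return result


def _annual_unit_climate(
    inputs: PipelineInputs, mask: pd.Series, landscape: synthetic.Landscape
) -> dict[str, pd.DataFrame]:
    """Unit x year tables of MAT (degC), AP (mm) and AR (MJ m-2)."""
    unit_of_pixel = landscape.unit_ids().set_axis(landscape.pixels["pixel_id"])
    tables = {}
    for tag, var, statistic in (
        ("MAT", "temperature", "mean"),
        ("AP", "precipitation", "sum"),
        ("AR", "radiation", "sum"),
    ):
        annual = preprocessing.aggregate(
            preprocessing.apply_mask(inputs.climate[var], mask), "annual", statistic
        )
        frame = pd.DataFrame(
            annual.values,
            index=pd.Index(annual["pixel"].values, name="pixel_id"),
            columns=pd.DatetimeIndex(annual["time"].values).year,
        )
        tables[tag] = frame.groupby(unit_of_pixel.reindex(frame.index)).mean()
    return tables


def attribution_stage(
    inputs: PipelineInputs,
    mask: pd.Series,
    dim_result: dict,
    config: PipelineConfig,
) -> dict:
    """Trend deltas, bivariate slopes and random-forest importance."""
    if "delta" not in dim_result:
        return {"skipped": "attribution requires two periods"}
    annual = _annual_unit_climate(inputs, mask, inputs.landscape)

    gi = grazing.grazing_intensity_table(
        inputs.livestock, inputs.landscape.county_area_ha
    )
    # livestock records are county-level: each unit inherits its county's GI
    units = annual["MAT"].index
    county_of_unit = pd.Series(
        [int(u.split("_", 1)[0][1:]) for u in units], index=units
    )
    annual["GI"] = gi.loc[county_of_unit.to_numpy()].set_axis(units)

    trend_deltas = grazing.compute_trend_deltas(annual, config.periods)
    table = attribution_mod.assemble_attribution_table(
        trend_deltas, dim_result["delta"]["delta_D"]
    )
    result = attribution_mod.random_forest_attribution(
        table,
        n_trees=config.rf_trees,
        seed=config.seed,
        max_features=config.rf_max_features,
        variant=config.rf_variant,
    )
    return {"trend_deltas": trend_deltas, "table": table, "result": result}


# ---------------------------------------------------------------------------
# Full run
# ---------------------------------------------------------------------------


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    inputs: PipelineInputs | None = None,
) -> dict:
    """Run every stage and write the output tables and manifest.

    Without explicit ``inputs`` a synthetic scenario is generated from the
    config. With a single configured period the delta and attribution stages
    are skipped with a notice in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if inputs is None:
        inputs = simulate_inputs(config)

    prepared = preprocess_stage(inputs, config)
    stab = stability_stage(prepared, config)
    dim_result = dimensionality_stage(stab, inputs.landscape, config)
    attr = attribution_stage(inputs, prepared[0].mask, dim_result, config)

    written: list[str] = []

    def _write(frame: pd.DataFrame, name: str, index: bool = True) -> None:
        path = outdir / name
        frame.sort_index().to_csv(path, index=index, float_format="%.10g")
        written.append(name)

    _write(stab.sort_values(["period", "pixel"]), "stability_pixels.csv", index=False)
    ellipsoids = pd.concat(
        dim_result["ellipsoids"], names=["period", "unit_id"]
    ).reset_index()
    _write(ellipsoids, "ellipsoids.csv", index=False)

    notices: list[str] = []
    if "delta" in dim_result:
        _write(dim_result["delta"], "delta_dimensionality.csv")
    else:
        notices.append("single period: delta stage skipped")
    if "result" in attr:
        res: attribution_mod.AttributionResult = attr["result"]
        report = res.bivariate.copy()
        report["importance"] = res.importance
        report["importance_se"] = res.importance_se
        report["r2_oob"] = res.r2_oob
        _write(report, "attribution.csv")
    else:
        notices.append(attr.get("skipped", "attribution skipped"))

    manifest = {
        "package_version": _version,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_pixels_total": int(inputs.landscape.n_pixels),
        "n_pixels_retained": int(prepared[0].mask.sum()),
        "outputs": written,
        "notices": notices,
    }
    if "delta_summary" in dim_result:
        manifest["delta_summary"] = dim_result["delta_summary"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "inputs": inputs,
        "prepared": prepared,
        "stability_pixels": stab,
        "dimensionality": dim_result,
        "attribution": attr,
        "manifest": manifest,
    }
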