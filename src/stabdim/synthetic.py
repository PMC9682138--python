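"""Synthetic landscapes, climate, vegetation-index and livestock inputs.

The generator emulates the inputs of a two-period grassland-stability study:
a mosaic of counties and grassland types, monthly temperature / precipitation
/ radiation surfaces, a vegetation index (NDVI-like) driven by a lag-1
autoregressive climate-sensitivity model with pixel-varying coefficients, and
county-level livestock records. Every draw is controlled by explicit seeds so
the downstream pipeline can be tested against known ground truth.

The NDVI anomaly of pixel *p* follows the same model the analysis later fits:

    x_t = alpha * T_t + beta * P_t + gamma * R_t + delta * x_{t-1} + eps_t

where T, P, R are per-pixel z-scored climate series, |delta| < 1 and
eps_t ~ N(0, noise_sd^2). The observed NDVI is a smooth mean profile plus a
scaled copy of the anomaly, clipped to the physical range [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .errors import (
    AlignmentError,
    InvalidArgumentError,
    NonstationaryError,
    TooShortSeriesError,
)

logger = logging.getLogger(__name__)

GRASSLAND_TYPES = ("alpine_meadow", "alpine_steppe", "desert_steppe")
SPECIES = ("sheep", "goat", "yak", "donkey", "horse")

#: Fraction of a county's total sheep-unit load carried by each species.
SPECIES_SHU_SHARE = {
    "sheep": 0.45,
    "goat": 0.25,
    "yak": 0.20,
    "donkey": 0.04,
    "horse": 0.06,
}
_SHU_PER_HEAD = {"sheep": 1, "goat": 1, "yak": 4, "donkey": 4, "horse": 4}

DEFAULT_PERIODS = ((2000, 2008), (2009, 2017))

#: Monthly climate defaults: mean level, seasonal amplitude, white-noise SD,
#: linear trend per year and the calendar month of the seasonal peak
#: (0 = January). The peaks are spread 4 months apart so the three z-scored
#: regressors are far from collinear and the AR coefficients stay identifiable.
CLIMATE_DEFAULTS: dict[str, dict[str, float]] = {
    "temperature": dict(
        mean=5.0, seasonal_amplitude=10.0, noise_sd=2.0, trend=0.0, peak_month=6
    ),
    "precipitation": dict(
        mean=50.0, seasonal_amplitude=40.0, noise_sd=20.0, trend=0.0, peak_month=10
    ),
    "radiation": dict(
        mean=550.0, seasonal_amplitude=250.0, noise_sd=60.0, trend=0.0, peak_month=2
    ),
}
CLIMATE_UNITS = {
    "temperature": "degC",
    "precipitation": "mm",
    "radiation": "MJ m-2 month-1",
}


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


@dataclass
class Landscape:
    """County x grassland-type mosaic on a 1-D pixel axis.

    ``pixels`` has one row per pixel with columns ``pixel_id``, ``county_id``
    and ``grassland_type``; ``county_area_ha`` maps each county to its natural
    grassland area in hectares.
    """

    pixels: pd.DataFrame
    county_area_ha: pd.Series

    def __post_init__(self) -> None:
        required = {"pixel_id", "county_id", "grassland_type"}
        if not required.issubset(self.pixels.columns):
            raise InvalidArgumentError(f"landscape table needs columns {required}")
        if (self.county_area_ha <= 0).any():
            raise InvalidArgumentError("every county must have positive area")

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def pixel_ids(self) -> np.ndarray:
        return self.pixels["pixel_id"].to_numpy()

    def unit_ids(self) -> pd.Series:
        """County x type unit label per pixel, e.g. ``c3_alpine_steppe``."""
        return (
            "c"
            + self.pixels["county_id"].astype(str)
            + "_"
            + self.pixels["grassland_type"].astype(str)
        )

    def n_groups(self) -> int:
        return self.pixels.groupby(["county_id", "grassland_type"]).ngroups

    def to_frame(self) -> pd.DataFrame:
        out = self.pixels.copy()
        out["county_area_ha"] = out["county_id"].map(self.county_area_ha)
        return out

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Landscape":
        areas = frame.groupby("county_id")["county_area_ha"].first()
        return cls(
            pixels=frame[["pixel_id", "county_id", "grassland_type"]].reset_index(
                drop=True
            ),
            county_area_ha=areas,
        )


def make_landscape(
    n_counties: int,
    types_per_county: int,
    pixels_per_group: int,
    seed: int,
    group_dropout: float = 0.0,
    area_range_ha: tuple[float, float] = (5e4, 5e5),
) -> Landscape:
    """Build a landscape of ``n_counties`` x ``types_per_county`` groups.

    Each retained group receives ``pixels_per_group`` pixels. With
    ``group_dropout`` > 0 each county x type group is independently removed
    with that probability (every county keeps at least one group), which
    mimics counties that do not host every grassland type.
    """
    if n_counties < 1 or types_per_county < 1 or pixels_per_group < 1:
        raise InvalidArgumentError("all landscape dimensions must be >= 1")
    if types_per_county > len(GRASSLAND_TYPES):
        raise InvalidArgumentError(
            f"at most {len(GRASSLAND_TYPES)} grassland types are available"
        )
    if not 0.0 <= group_dropout < 1.0:
        raise InvalidArgumentError("group_dropout must be in [0, 1)")

    rng = np.random.default_rng(seed)
    rows: list[tuple[int, int, str]] = []
    pixel = 0
    for county in range(1, n_counties + 1):
        types = list(GRASSLAND_TYPES[:types_per_county])
        if group_dropout > 0 and len(types) > 1:
            keep = rng.random(len(types)) >= group_dropout
            if not keep.any():
                keep[rng.integers(len(types))] = True
            types = [t for t, k in zip(types, keep) if k]
        for gtype in types:
            for _ in range(pixels_per_group):
                rows.append((pixel, county, gtype))
                pixel += 1
    pixels = pd.DataFrame(rows, columns=["pixel_id", "county_id", "grassland_type"])
    areas = pd.Series(
        rng.uniform(*area_range_ha, size=n_counties),
        index=pd.RangeIndex(1, n_counties + 1, name="county_id"),
        name="county_area_ha",
    )
    return Landscape(pixels=pixels, county_area_ha=areas)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-pixel generating parameters of the NDVI anomaly model."""

    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    noise_sd: np.ndarray
    rng_seed: int
    latent_loading: float = 0.0
    ndvi_mean: np.ndarray | None = None  # per-pixel mean NDVI level

    def __post_init__(self) -> None:
        if np.any(np.abs(self.delta) >= 1):
            raise NonstationaryError("|delta| must be < 1 for a stationary AR(1)")
        if np.any(self.noise_sd < 0):
            raise InvalidArgumentError("noise_sd must be non-negative")

    @property
    def n_pixels(self) -> int:
        return self.alpha.size

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rng_seed": int(self.rng_seed),
            "latent_loading": float(self.latent_loading),
            **{
                k: np.asarray(getattr(self, k)).tolist()
                for k in ("alpha", "beta", "gamma", "delta", "noise_sd")
            },
        }
        if self.ndvi_mean is not None:
            payload["ndvi_mean"] = np.asarray(self.ndvi_mean).tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            alpha=np.asarray(payload["alpha"], dtype=float),
            beta=np.asarray(payload["beta"], dtype=float),
            gamma=np.asarray(payload["gamma"], dtype=float),
            delta=np.asarray(payload["delta"], dtype=float),
            noise_sd=np.asarray(payload["noise_sd"], dtype=float),
            rng_seed=int(payload["rng_seed"]),
            latent_loading=float(payload["latent_loading"]),
            ndvi_mean=(
                np.asarray(payload["ndvi_mean"], dtype=float)
                if "ndvi_mean" in payload
                else None
            ),
        )


def draw_ground_truth(
    landscape: Landscape,
    seed: int,
    latent_loading: float = 0.0,
    coef_mean: Sequence[float] = (0.4, 0.3, 0.1, 0.3),
    coef_sd: Sequence[float] = (0.10, 0.08, 0.05, 0.15),
    noise_sd_mean: float = 0.10,
    noise_sd_sd: float = 0.04,
    ndvi_mean_mean: float = 0.30,
    ndvi_mean_sd: float = 0.08,
) -> GroundTruth:
    """Draw pixel-varying AR coefficients with a shared latent factor.

    Each pixel gets a latent score f ~ N(0, 1); every parameter is
    ``mean + sd * (loading * f + sqrt(1 - loading^2) * e)`` with independent
    e ~ N(0, 1). ``latent_loading`` = 0 makes the parameters (and hence the
    derived stability components) independent across pixels; a loading near 1
    couples them, which is how the low-dimensionality scenario is produced.

    The mean NDVI level loads on the factor with the opposite sign, so a
    high-f pixel is simultaneously climate-sensitive (low resistance), slow
    to recover (low resilience) and sparse/noisy (low invariability): all
    three derived components then co-vary across pixels.
    """
    if not 0.0 <= latent_loading <= 1.0:
        raise InvalidArgumentError("latent_loading must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = landscape.n_pixels
    f = rng.standard_normal(n)
    resid_scale = np.sqrt(1.0 - latent_loading**2)

    def _draw(mean: float, sd: float, sign: float = 1.0) -> np.ndarray:
        e = rng.standard_normal(n)
        return mean + sd * (sign * latent_loading * f + resid_scale * e)

    # Loading signs follow the direction each parameter pushes the derived
    # components, so one latent factor amplifies — rather than cancels — the
    # correlation pattern the fitting procedure itself induces: a high-f
    # pixel is noisy, slow to recover and sparse at once.
    alpha = _draw(coef_mean[0], coef_sd[0], sign=-1.0)
    beta = _draw(coef_mean[1], coef_sd[1], sign=-1.0)
    gamma = _draw(coef_mean[2], coef_sd[2], sign=-1.0)
    delta = np.clip(_draw(coef_mean[3], coef_sd[3]), -0.95, 0.95)
    noise = np.clip(_draw(noise_sd_mean, noise_sd_sd), 0.01, None)
    ndvi_mean = np.clip(_draw(ndvi_mean_mean, ndvi_mean_sd, sign=-1.0), 0.15, 0.85)
    return GroundTruth(
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        delta=delta,
        noise_sd=noise,
        rng_seed=seed,
        latent_loading=latent_loading,
        ndvi_mean=ndvi_mean,
    )


def constant_ground_truth(
    landscape: Landscape,
    alpha: float = 0.4,
    beta: float = 0.3,
    gamma: float = 0.1,
    delta: float = 0.3,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> GroundTruth:
    """Ground truth with identical coefficients at every pixel."""
    n = landscape.n_pixels
    ones = np.ones(n)
    return GroundTruth(
        alpha=alpha * ones,
        beta=beta * ones,
        gamma=gamma * ones,
        delta=delta * ones,
        noise_sd=noise_sd * ones,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


def _merge_params(
    override: Mapping[str, float] | float | None, key: str
) -> dict[str, float]:
    params = {var: dict(defs) for var, defs in CLIMATE_DEFAULTS.items()}
    if override is None:
        return params
    if isinstance(override, Mapping):
        for var, value in override.items():
            if var not in params:
                raise InvalidArgumentError(f"unknown climate variable {var!r}")
            params[var][key] = float(value)
    else:
        for var in params:
            params[var][key] = float(override)
    return params


def simulate_climate(
    landscape: Landscape,
    n_months: int,
    seed: int,
    start: str = "2000-01-01",
    seasonal_amplitude: Mapping[str, float] | float | None = None,
    noise_sd: Mapping[str, float] | float | None = None,
    trend: Mapping[str, float] | float | None = None,
    mean: Mapping[str, float] | float | None = None,
) -> dict[str, xr.DataArray]:
    """Monthly temperature, precipitation and radiation surfaces.

    Each series is a seasonal harmonic plus a linear trend (units per year)
    plus per-pixel white noise; precipitation is clipped at zero. Overrides
    may be a scalar (applied to all variables) or a dict keyed by variable.
    """
    if n_months < 24:
        raise TooShortSeriesError("need at least 24 monthly steps (two years)")
    params = _merge_params(None, "")
    for key, override in (
        ("seasonal_amplitude", seasonal_amplitude),
        ("noise_sd", noise_sd),
        ("trend", trend),
        ("mean", mean),
    ):
        merged = _merge_params(override, key)
        for var in params:
            params[var][key] = merged[var][key]
    for var, p in params.items():
        if p["noise_sd"] < 0:
            raise InvalidArgumentError(f"noise_sd for {var} must be >= 0")

    rng = np.random.default_rng(seed)
    time = pd.date_range(start, periods=n_months, freq="MS")
    months = np.arange(n_months)
    n_pix = landscape.n_pixels
    out: dict[str, xr.DataArray] = {}
    for var in ("temperature", "precipitation", "radiation"):
        p = params[var]
        seasonal = p["seasonal_amplitude"] * np.cos(
            2 * np.pi * (months % 12 - p["peak_month"]) / 12.0
        )
        base = p["mean"] + seasonal + p["trend"] * (months / 12.0)
        noise = p["noise_sd"] * rng.standard_normal((n_pix, n_months))
        values = base[None, :] + noise
        if var == "precipitation":
            values = np.clip(values, 0.0, None)
        out[var] = xr.DataArray(
            values,
            dims=("pixel", "time"),
            coords={"pixel": landscape.pixel_ids, "time": time},
            name=var,
            attrs={"units": CLIMATE_UNITS[var]},
        )
    return out


def _check_aligned(*arrays: xr.DataArray) -> None:
    ref = arrays[0]
    for other in arrays[1:]:
        if not np.array_equal(ref["pixel"].values, other["pixel"].values) or not (
            np.array_equal(ref["time"].values, other["time"].values)
        ):
            raise AlignmentError("climate series must share pixel and time axes")


def climate_anomalies(
    climate: Mapping[str, xr.DataArray],
) -> dict[str, xr.DataArray]:
    """Per-pixel z-scores of each climate series (the AR model regressors)."""
    out = {}
    for var, da in climate.items():
        mu = da.mean("time")
        sd = da.std("time", ddof=1)
        out[var] = ((da - mu) / sd).assign_attrs(units="z-score")
    return out


# ---------------------------------------------------------------------------
# NDVI
# ---------------------------------------------------------------------------


def simulate_ndvi(
    climate: Mapping[str, xr.DataArray],
    truth: GroundTruth,
    base_mean: float = 0.3,
    anomaly_scale: float = 0.08,
    seasonal_amplitude: float = 0.0,
    peak_month: int = 6,
    trend_per_year: float = 0.0,
    seed: int | None = None,
    return_anomaly: bool = False,
) -> xr.DataArray | tuple[xr.DataArray, xr.DataArray]:
    """Generate NDVI by iterating the autoregressive climate model.

    The climate series are z-scored per pixel, the anomaly recursion
    ``x_t = alpha*T_t + beta*P_t + gamma*R_t + delta*x_{t-1} + eps_t`` is run
    forward, and the observed series is ``base_mean`` + optional seasonal
    profile + linear trend + ``anomaly_scale`` * x, clipped to [0, 1]. Because
    the z-scored climate retains its seasonal cycle, the anomaly itself — and
    hence NDVI — is seasonal even with ``seasonal_amplitude`` = 0.
    """
    temp, precip, rad = (
        climate["temperature"],
        climate["precipitation"],
        climate["radiation"],
    )
    _check_aligned(temp, precip, rad)
    n_pix, n_t = temp.shape
    if truth.n_pixels != n_pix:
        raise AlignmentError("ground truth and climate pixel axes differ")

    anom = climate_anomalies({"temperature": temp, "precipitation": precip, "radiation": rad})
    T = anom["temperature"].values
    P = anom["precipitation"].values
    R = anom["radiation"].values

    rng = np.random.default_rng(truth.rng_seed + 1 if seed is None else seed)
    eps = rng.standard_normal((n_pix, n_t)) * truth.noise_sd[:, None]
    forcing = (
        truth.alpha[:, None] * T + truth.beta[:, None] * P + truth.gamma[:, None] * R
    )
    x = np.empty((n_pix, n_t))
    x[:, 0] = forcing[:, 0] + eps[:, 0]
    for t in range(1, n_t):
        x[:, t] = forcing[:, t] + truth.delta * x[:, t - 1] + eps[:, t]

    months = np.arange(n_t)
    level = (
        truth.ndvi_mean[:, None]
        if truth.ndvi_mean is not None
        else np.full((n_pix, 1), base_mean)
    )
    profile = seasonal_amplitude * np.cos(
        2 * np.pi * (months % 12 - peak_month) / 12.0
    ) + trend_per_year * (months / 12.0)
    ndvi_values = np.clip(level + profile[None, :] + anomaly_scale * x, 0.0, 1.0)

    coords = {"pixel": temp["pixel"].values, "time": temp["time"].values}
    ndvi = xr.DataArray(
        ndvi_values, dims=("pixel", "time"), coords=coords, name="ndvi",
        attrs={"units": "1"},
    )
    if not return_anomaly:
        return ndvi
    anomaly = xr.DataArray(
        x, dims=("pixel", "time"), coords=coords, name="ndvi_anomaly",
        attrs={"units": "z-scale"},
    )
    return ndvi, anomaly


# ---------------------------------------------------------------------------
# Livestock
# ---------------------------------------------------------------------------


def simulate_livestock(
    landscape: Landscape,
    years: Sequence[int],
    base_shu_density: float = 0.5,
    trend_per_year: float | Sequence[float] = 0.0,
    periods: Sequence[tuple[int, int]] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    county_spread: float = 0.2,
) -> pd.DataFrame:
    """County-level annual head counts for the five grazing species.

    A sheep-unit density trajectory (SHU per hectare) starts at
    ``base_shu_density`` and evolves with ``trend_per_year`` — either a single
    slope or one slope per entry of ``periods``, applied piecewise and
    continuously. Each county carries a fixed lognormal multiplier
    (``county_spread``), and multiplicative noise is applied per county-year.
    The implied SHU load is split across species by :data:`SPECIES_SHU_SHARE`
    and rounded to whole heads.
    """
    years = list(years)
    if not years or any(b <= a for a, b in zip(years, years[1:])):
        raise InvalidArgumentError("years must be non-empty and strictly increasing")
    if base_shu_density < 0:
        raise InvalidArgumentError("base_shu_density must be >= 0")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")

    if np.isscalar(trend_per_year):
        slope_of_year = {y: float(trend_per_year) for y in years}
    else:
        if periods is None or len(periods) != len(trend_per_year):
            raise InvalidArgumentError(
                "per-period trends require a matching `periods` sequence"
            )
        slope_of_year = {}
        for y in years:
            for (start, end), slope in zip(periods, trend_per_year):
                if start <= y <= end:
                    slope_of_year[y] = float(slope)
                    break
            else:
                raise InvalidArgumentError(f"year {y} not covered by any period")

    density = {}
    level = base_shu_density
    for i, y in enumerate(years):
        if i > 0:
            level = max(level + slope_of_year[y] * (y - years[i - 1]), 0.0)
        density[y] = level

    rng = np.random.default_rng(seed)
    counties = landscape.county_area_ha.index.to_numpy()
    county_factor = np.exp(county_spread * rng.standard_normal(len(counties)))
    rows = []
    for ci, county in enumerate(counties):
        area = float(landscape.county_area_ha.loc[county])
        for y in years:
            noise = 1.0 + noise_sd * rng.standard_normal() if noise_sd > 0 else 1.0
            shu_total = max(density[y] * county_factor[ci] * noise, 0.0) * area
            row = {"county_id": county, "year": y}
            for sp in SPECIES:
                row[sp] = int(
                    np.rint(shu_total * SPECIES_SHU_SHARE[sp] / _SHU_PER_HEAD[sp])
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """A complete synthetic study: inputs plus the generating ground truth."""

    landscape: Landscape
    truth: GroundTruth
    climate: dict[str, xr.DataArray]
    ndvi: xr.DataArray
    ndvi_anomaly: xr.DataArray
    livestock: pd.DataFrame
    periods: tuple[tuple[int, int], ...]
    seed: int

    def write(self, outdir: str | Path) -> list[Path]:
        """Write NetCDF (one file per gridded variable), CSV and JSON inputs."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, da in {**self.climate, "ndvi": self.ndvi}.items():
            path = outdir / f"{name}.nc"
            da.to_dataset(name=name).to_netcdf(path, engine="scipy")
            written.append(path)
        land_path = outdir / "landscape.csv"
        self.landscape.to_frame().to_csv(land_path, index=False)
        live_path = outdir / "livestock.csv"
        self.livestock.to_csv(live_path, index=False)
        truth_path = outdir / "ground_truth.json"
        self.truth.to_json(truth_path)
        written += [land_path, live_path, truth_path]
        return written


def generate_scenario(
    seed: int = 0,
    n_counties: int = 8,
    types_per_county: int = 3,
    pixels_per_group: int = 40,
    latent_loading: float = 0.0,
    periods: Sequence[tuple[int, int]] = DEFAULT_PERIODS,
    climate_trend_per_period: Mapping[str, Sequence[float]] | None = None,
    livestock_trend_per_period: Sequence[float] | None = None,
    base_shu_density: float = 0.5,
    livestock_noise_sd: float = 0.05,
    group_dropout: float = 0.0,
    **truth_kwargs,
) -> Scenario:
    """Generate a full two-period (or single-period) study from one root seed.

    Sub-seeds for the landscape, coefficients, climate and livestock are
    spawned deterministically from ``seed``, so the landscape is identical
    across scenarios that share the root seed while noise draws differ when
    the root seed changes.
    """
    periods = tuple(tuple(p) for p in periods)
    ss = np.random.SeedSequence(seed)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(5)]
    land_seed, truth_seed, clim_seed, ndvi_seed, live_seed = sub

    landscape = make_landscape(
        n_counties, types_per_county, pixels_per_group, seed=land_seed,
        group_dropout=group_dropout,
    )
    truth = draw_ground_truth(
        landscape, seed=truth_seed, latent_loading=latent_loading, **truth_kwargs
    )

    pieces: dict[str, list[xr.DataArray]] = {v: [] for v in CLIMATE_DEFAULTS}
    for k, (start, end) in enumerate(periods):
        n_months = 12 * (end - start + 1)
        trends = None
        if climate_trend_per_period is not None:
            trends = {v: s[k] for v, s in climate_trend_per_period.items()}
        clim = simulate_climate(
            landscape, n_months, seed=clim_seed + k, start=f"{start}-01-01",
            trend=trends,
        )
        for v, da in clim.items():
            pieces[v].append(da)
    climate = {v: xr.concat(parts, dim="time") for v, parts in pieces.items()}

    ndvi, anomaly = simulate_ndvi(climate, truth, seed=ndvi_seed, return_anomaly=True)

    years = list(range(periods[0][0], periods[-1][1] + 1))
    if livestock_trend_per_period is None:
        livestock_trend_per_period = [0.0] * len(periods)
    livestock = simulate_livestock(
        landscape, years, base_shu_density=base_shu_density,
        trend_per_year=list(livestock_trend_per_period), periods=periods,
        noise_sd=livestock_noise_sd, seed=live_seed,
    )
    return Scenario(
        landscape=landscape, truth=truth, climate=climate, ndvi=ndvi,
        ndvi_anomaly=anomaly, livestock=livestock, periods=periods, seed=seed,
    )


#: Scenario presets used to probe the dimensionality statistic: a shared
#: latent factor couples the stability components across pixels (low
#: dimensionality), independent draws leave them uncoupled (high). The
#: spread parameters give each component a strong driver of its own — the
#: mean level for invariability, noise variance for resistance, delta for
#: resilience — so the loading, not a shared mechanical factor, controls
#: the cross-component correlations.
_PRESET_TRUTH = dict(
    coef_sd=(0.12, 0.10, 0.06, 0.12),
    noise_sd_mean=0.45,
    noise_sd_sd=0.15,
    ndvi_mean_sd=0.10,
)
PRESETS: dict[str, dict] = {
    "low_dimensionality": dict(latent_loading=0.8, **_PRESET_TRUTH),
    "high_dimensionality": dict(latent_loading=0.0, **_PRESET_TRUTH),
}


def preset_scenario(name: str, seed: int = 0, **overrides) -> Scenario:
    """A compact single-period, six-unit scenario under a named preset."""
    if name not in PRESETS:
        raise InvalidArgumentError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kwargs = dict(
        n_counties=3, types_per_county=2, pixels_per_group=80,
        periods=((2000, 2008),),
    )
    kwargs.update(PRESETS[name])
    kwargs.update(overrides)
    return generate_scenario(seed=seed, **kwargs)
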