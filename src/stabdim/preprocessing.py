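"""Cleaning and transformation of gridded series into model-ready anomalies.

The pipeline order is fixed: Savitzky–Golay smoothing of the vegetation
index, removal of sparsely vegetated pixels (annual mean below a threshold in
any year), linear detrending, and per-pixel z-scoring. A pixel dropped by the
filter never re-enters downstream stages. Daily station-style inputs can be
aggregated to monthly values, and the FAO-56 Angstrom–Prescott chain converts
sunshine hours to solar radiation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.signal import savgol_filter

from .errors import (
    DegeneratePixelError,
    InsufficientDataError,
    InvalidArgumentError,
)

logger = logging.getLogger(__name__)

_SOLAR_CONSTANT = 0.0820  # MJ m-2 min-1 (FAO-56)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def savitzky_golay_smooth(
    series: xr.DataArray, window: int = 5, polyorder: int = 2
) -> xr.DataArray:
    """Per-pixel Savitzky–Golay smoothing along the time axis.

    Endpoints are handled by fitting the edge-window polynomial and
    evaluating it at the boundary samples (``mode='interp'``).
    """
    if window % 2 == 0:
        raise InvalidArgumentError("window must be odd")
    if window <= polyorder:
        raise InvalidArgumentError("window must exceed polyorder")
    if series.sizes["time"] < window:
        raise InvalidArgumentError("series shorter than the smoothing window")
    smoothed = savgol_filter(
        series.values, window_length=window, polyorder=polyorder, axis=-1,
        mode="interp",
    )
    return series.copy(data=smoothed)


# ---------------------------------------------------------------------------
# Low-vegetation filter
# ---------------------------------------------------------------------------


def filter_low_ndvi(ndvi: xr.DataArray, threshold: float = 0.1) -> pd.Series:
    """Keep-mask over pixels: annual (calendar-year mean) NDVI >= threshold.

    A pixel is excluded when its mean NDVI over any complete calendar year
    falls below ``threshold``. Returns a boolean Series indexed by pixel id.
    """
    if ndvi.sizes["time"] == 0:
        raise InvalidArgumentError("empty NDVI series")
    years = pd.DatetimeIndex(ndvi["time"].values).year
    counts = pd.Series(years).value_counts()
    complete = counts[counts == 12].index
    if len(complete) == 0:
        raise InvalidArgumentError("need at least one complete calendar year")
    keep = np.ones(ndvi.sizes["pixel"], dtype=bool)
    for year in complete:
        annual_mean = ndvi.values[:, years == year].mean(axis=1)
        keep &= annual_mean >= threshold
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("NDVI filter removed %d of %d pixels", n_drop, keep.size)
    return pd.Series(keep, index=pd.Index(ndvi["pixel"].values, name="pixel"))


def apply_mask(series: xr.DataArray, mask: pd.Series) -> xr.DataArray:
    """Restrict a gridded series to the pixels retained by a keep-mask."""
    kept = mask.index[mask.values]
    return series.sel(pixel=kept.to_numpy())


# ---------------------------------------------------------------------------
# Detrending and z-scoring
# ---------------------------------------------------------------------------


def _time_in_years(time_values: np.ndarray) -> np.ndarray:
    t = pd.DatetimeIndex(time_values)
    return (t - t[0]).days.to_numpy() / 365.25


def detrend_linear(
    series: xr.DataArray,
) -> tuple[xr.DataArray, np.ndarray, np.ndarray]:
    """Remove a per-pixel OLS line over time.

    Returns the residual series plus the fitted slope (units per year) and
    intercept per pixel; residuals have zero mean by construction.
    """
    if series.sizes["time"] < 3:
        raise InsufficientDataError("detrending needs at least 3 time points")
    t = _time_in_years(series["time"].values)
    coeffs = np.polyfit(t, series.values.T, deg=1)  # (2, n_pixels)
    slope, intercept = coeffs[0], coeffs[1]
    fitted = slope[:, None] * t[None, :] + intercept[:, None]
    residuals = series.copy(data=series.values - fitted)
    return residuals, slope, intercept


@dataclass
class AnomalySeries:
    """Detrended, z-scored series with the parameters needed to invert it.

    ``values`` holds per-pixel z-scores of the detrended residuals; ``slope``
    (units/year), ``intercept``, ``mean`` and ``std`` reconstruct the input:
    ``x = values * std + mean + slope * t + intercept``.
    """

    values: xr.DataArray
    slope: np.ndarray
    intercept: np.ndarray
    mean: np.ndarray
    std: np.ndarray

    @property
    def pixel(self) -> np.ndarray:
        return self.values["pixel"].values

    def inverse(self) -> xr.DataArray:
        t = _time_in_years(self.values["time"].values)
        detrended = self.values.values * self.std[:, None] + self.mean[:, None]
        trend = self.slope[:, None] * t[None, :] + self.intercept[:, None]
        return self.values.copy(data=detrended + trend)


def zscore_anomalies(
    series: xr.DataArray,
    slope: np.ndarray | None = None,
    intercept: np.ndarray | None = None,
    ddof: int = 1,
) -> AnomalySeries:
    """Per-pixel z-scores; mean 0 and SD 1 within 1e-10 after the transform.

    ``slope``/``intercept`` carry a previously removed trend through to the
    stored scaling parameters so :meth:`AnomalySeries.inverse` reconstructs
    the original (pre-detrend) series.
    """
    values = series.values
    mean = values.mean(axis=1)
    std = values.std(axis=1, ddof=ddof)
    degenerate = np.flatnonzero(std == 0)
    if degenerate.size:
        pix = series["pixel"].values[degenerate[0]]
        raise DegeneratePixelError(
            f"pixel {pix} has zero variance; cannot z-score"
        )
    n_pix = values.shape[0]
    z = (values - mean[:, None]) / std[:, None]
    return AnomalySeries(
        values=series.copy(data=z),
        slope=np.zeros(n_pix) if slope is None else np.asarray(slope, dtype=float),
        intercept=np.zeros(n_pix) if intercept is None else np.asarray(intercept, dtype=float),
        mean=mean,
        std=std,
    )


def anomalies(series: xr.DataArray) -> AnomalySeries:
    """Detrend then z-score: the transform every model variable receives."""
    residuals, slope, intercept = detrend_linear(series)
    return zscore_anomalies(residuals, slope=slope, intercept=intercept)


# ---------------------------------------------------------------------------
# FAO-56 radiation from sunshine hours
# ---------------------------------------------------------------------------


def extraterrestrial_radiation(latitude: float, day_of_year) -> np.ndarray:
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1), FAO-56 eq. 21-25."""
    if abs(latitude) >= 66.5:
        raise InvalidArgumentError("polar latitudes are not supported")
    j = np.asarray(day_of_year, dtype=float)
    phi = np.deg2rad(latitude)
    dr = 1 + 0.033 * np.cos(2 * np.pi * j / 365.0)
    decl = 0.409 * np.sin(2 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(-np.tan(phi) * np.tan(decl))
    ra = (
        24 * 60 / np.pi
        * _SOLAR_CONSTANT
        * dr
        * (ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws))
    )
    return ra


def daylight_hours(latitude: float, day_of_year) -> np.ndarray:
    """Maximum possible sunshine duration N (hours), FAO-56 eq. 34."""
    if abs(latitude) >= 66.5:
        raise InvalidArgumentError("polar latitudes are not supported")
    j = np.asarray(day_of_year, dtype=float)
    phi = np.deg2rad(latitude)
    decl = 0.409 * np.sin(2 * np.pi * j / 365.0 - 1.39)
    ws = np.arccos(-np.tan(phi) * np.tan(decl))
    return 24 / np.pi * ws


def fao_radiation_from_sunshine(
    sunshine_hours,
    latitude: float,
    day_of_year,
    a_s: float = 0.25,
    b_s: float = 0.50,
) -> np.ndarray:
    """Daily solar radiation Rs = (a_s + b_s * n/N) * Ra (MJ m-2 day-1).

    Angstrom–Prescott with the FAO-56 default coefficients: the a_s fraction
    of extraterrestrial radiation reaches the ground on fully overcast days,
    a_s + b_s on clear days.
    """
    n = np.asarray(sunshine_hours, dtype=float)
    if np.any(n < 0):
        raise InvalidArgumentError("sunshine hours must be >= 0")
    big_n = daylight_hours(latitude, day_of_year)
    if np.any(n > big_n + 1e-9):
        raise InvalidArgumentError("sunshine hours exceed daylight hours")
    ra = extraterrestrial_radiation(latitude, day_of_year)
    return (a_s + b_s * n / big_n) * ra


# ---------------------------------------------------------------------------
# Temporal aggregation
# ---------------------------------------------------------------------------

#: Aggregation statistic conventionally used per variable.
DEFAULT_STATISTIC = {
    "temperature": "mean",
    "precipitation": "sum",
    "radiation": "sum",
    "ndvi": "mean",
}

_RESOLUTION_ORDER = {"daily": 0, "monthly": 1, "annual": 2}


def _infer_resolution(time_values: np.ndarray) -> str:
    if len(time_values) < 2:
        raise InvalidArgumentError("cannot infer resolution from one time stamp")
    step = np.median(np.diff(pd.DatetimeIndex(time_values).values)).astype(
        "timedelta64[h]"
    ).astype(float) / 24.0
    if step < 2:
        return "daily"
    if step < 40:
        return "monthly"
    return "annual"


def aggregate(series: xr.DataArray, to: str, statistic: str) -> xr.DataArray:
    """Aggregate a daily or monthly series to monthly or annual resolution.

    Only complete target periods are emitted (a partial first or last month
    or year is dropped). ``statistic`` is ``mean`` or ``sum``; see
    :data:`DEFAULT_STATISTIC` for the per-variable conventions.
    """
    if to not in ("monthly", "annual"):
        raise InvalidArgumentError("target resolution must be 'monthly' or 'annual'")
    if statistic not in ("mean", "sum"):
        raise InvalidArgumentError("statistic must be 'mean' or 'sum'")
    source = _infer_resolution(series["time"].values)
    if _RESOLUTION_ORDER[to] <= _RESOLUTION_ORDER[source]:
        raise InvalidArgumentError(
            f"target resolution {to!r} is not coarser than the source ({source})"
        )
    times = pd.DatetimeIndex(series["time"].values)
    period = times.to_period("M" if to == "monthly" else "Y")
    frame = pd.DataFrame(series.values.T, index=period)
    grouped = frame.groupby(level=0)
    counts = grouped.size()
    if to == "monthly":
        expected = counts.index.map(lambda p: p.days_in_month)
    elif source == "daily":
        expected = counts.index.map(lambda p: 366 if p.is_leap_year else 365)
    else:
        expected = pd.Series(12, index=counts.index)
    complete = counts.index[counts.to_numpy() == np.asarray(expected)]
    if len(complete) == 0:
        raise InvalidArgumentError("no complete target period in the series")
    agg = getattr(grouped, statistic)().loc[complete]
    new_time = complete.to_timestamp()
    return xr.DataArray(
        agg.to_numpy().T,
        dims=("pixel", "time"),
        coords={"pixel": series["pixel"].values, "time": new_time},
        name=series.name,
        attrs=dict(series.attrs),
    )


# ---------------------------------------------------------------------------
# Period-wise preparation for the stability model
# ---------------------------------------------------------------------------


@dataclass
class PreparedPeriod:
    """All inputs for one study period, filtered to retained pixels."""

    period: tuple[int, int]
    ndvi_raw: xr.DataArray  # smoothed, filtered, un-detrended NDVI
    ndvi: AnomalySeries
    temperature: AnomalySeries
    precipitation: AnomalySeries
    radiation: AnomalySeries
    mask: pd.Series  # keep-mask over the full pixel axis


def select_period(series: xr.DataArray, period: tuple[int, int]) -> xr.DataArray:
    years = pd.DatetimeIndex(series["time"].values).year
    inside = (years >= period[0]) & (years <= period[1])
    return series.isel(time=np.flatnonzero(inside))


def prepare_periods(
    ndvi: xr.DataArray,
    climate: dict[str, xr.DataArray],
    periods,
    ndvi_threshold: float = 0.1,
    sg_window: int | None = 5,
    sg_polyorder: int = 2,
) -> list[PreparedPeriod]:
    """Run the fixed preprocessing order for each study period.

    Smoothing and the low-NDVI filter act on the full record (the exclusion
    is study-wide); detrending and z-scoring are computed per period, since
    every stability quantity is defined within a period.

    ``sg_window=None`` skips the smoothing step. The smoother targets
    observation artifacts (clouds, atmospheric noise); on artifact-free
    series it only injects its own lag-1 autocorrelation, which biases the
    autoregressive coefficient upward.
    """
    logger.info("preprocessing: smooth -> filter -> detrend -> z-score")
    if sg_window is None:
        smoothed = ndvi
    else:
        smoothed = savitzky_golay_smooth(ndvi, window=sg_window, polyorder=sg_polyorder)
    mask = filter_low_ndvi(smoothed, threshold=ndvi_threshold)
    smoothed = apply_mask(smoothed, mask)
    climate = {v: apply_mask(da, mask) for v, da in climate.items()}

    prepared = []
    for period in periods:
        ndvi_p = select_period(smoothed, tuple(period))
        prepared.append(
            PreparedPeriod(
                period=tuple(period),
                ndvi_raw=ndvi_p,
                ndvi=anomalies(ndvi_p),
                temperature=anomalies(select_period(climate["temperature"], tuple(period))),
                precipitation=anomalies(select_period(climate["precipitation"], tuple(period))),
                radiation=anomalies(select_period(climate["radiation"], tuple(period))),
                mask=mask,
            )
        )
    return prepared
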