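"""Per-pixel stability components of vegetation productivity.

Three components are computed from a vegetation-index series and co-located
climate anomalies:

* **temporal invariability** — long-term mean of the raw index divided by the
  standard deviation of its detrended residuals (the inverse coefficient of
  variation);
* **resistance** — small absolute standardized sensitivities (alpha, beta,
  gamma) of the index anomaly to temperature, precipitation and radiation
  anomalies in the lag-1 autoregressive model
  ``x_t = alpha*T_t + beta*P_t + gamma*R_t + delta*x_{t-1} + eps``;
* **resilience** — a small absolute lag-1 coefficient |delta|: the weaker the
  memory of the previous state, the faster the return to baseline.

Raw scores are oriented so that larger means more stable, then min-max
rescaled to 0–100 across the retained pixels of one period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .errors import (
    DegenerateNormalizationError,
    InsufficientDataError,
    InvalidArgumentError,
)
from .preprocessing import AnomalySeries, PreparedPeriod, detrend_linear

logger = logging.getLogger(__name__)

COMPONENTS = ("invariability", "resistance", "resilience")


# ---------------------------------------------------------------------------
# Temporal invariability
# ---------------------------------------------------------------------------


def temporal_invariability(
    ndvi_raw: xr.DataArray, residuals: xr.DataArray | None = None, ddof: int = 1
) -> np.ndarray:
    """Mean of the raw series over the detrended residual SD, per pixel.

    If ``residuals`` is omitted the series is detrended internally. Pixels
    with zero residual variance are returned as NaN (undefined, to be
    excluded) rather than infinity.
    """
    if ndvi_raw.sizes["time"] < 3:
        raise InsufficientDataError("invariability needs at least 3 time points")
    if residuals is None:
        residuals, _, _ = detrend_linear(ndvi_raw)
    mean = ndvi_raw.values.mean(axis=1)
    sd = residuals.values.std(axis=1, ddof=ddof)
    out = np.full(mean.shape, np.nan)
    ok = sd > 0
    out[ok] = mean[ok] / sd[ok]
    if (~ok).any():
        logger.warning("%d pixels have zero residual SD; invariability undefined", (~ok).sum())
    return out


# ---------------------------------------------------------------------------
# AR climate-sensitivity fit
# ---------------------------------------------------------------------------


@dataclass
class ARFit:
    """Per-pixel coefficients of the lag-1 climate-sensitivity regression."""

    pixel: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    se: np.ndarray  # (n_pixels, 4) standard errors, same order
    residual_variance: np.ndarray
    n_obs: int
    flagged: np.ndarray  # ill-conditioned design, coefficients unreliable

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha": self.alpha,
                "beta": self.beta,
                "gamma": self.gamma,
                "delta": self.delta,
                "se_alpha": self.se[:, 0],
                "se_beta": self.se[:, 1],
                "se_gamma": self.se[:, 2],
                "se_delta": self.se[:, 3],
                "residual_variance": self.residual_variance,
                "flagged": self.flagged,
            },
            index=pd.Index(self.pixel, name="pixel"),
        )


def _as_values(series: AnomalySeries | xr.DataArray) -> tuple[np.ndarray, np.ndarray]:
    da = series.values if isinstance(series, AnomalySeries) else series
    return da.values, da["pixel"].values


def fit_ar_climate_model(
    ndvi: AnomalySeries | xr.DataArray,
    temperature: AnomalySeries | xr.DataArray,
    precipitation: AnomalySeries | xr.DataArray,
    radiation: AnomalySeries | xr.DataArray,
    condition_threshold: float = 1e8,
    min_obs: int = 12,
) -> ARFit:
    """OLS fit of the lag-1 model at every pixel, without intercept.

    All inputs are centered anomalies, so the regression goes through the
    origin; the first time step is dropped to form the lag. Pixels whose
    design matrix has a condition number above ``condition_threshold`` are
    flagged (near-collinear regressors).
    """
    y_full, pixel = _as_values(ndvi)
    regressors = []
    for series in (temperature, precipitation, radiation):
        vals, pix = _as_values(series)
        if vals.shape != y_full.shape or not np.array_equal(pix, pixel):
            raise InvalidArgumentError("anomaly series are not aligned")
        regressors.append(vals)

    n_used = y_full.shape[1] - 1
    if n_used < min_obs:
        raise InsufficientDataError(
            f"only {n_used} usable observations after lagging; need >= {min_obs}"
        )
    y = y_full[:, 1:]
    design = np.stack(
        [regressors[0][:, 1:], regressors[1][:, 1:], regressors[2][:, 1:], y_full[:, :-1]],
        axis=-1,
    )  # (pixel, time-1, 4)

    xtx = np.einsum("ptk,ptl->pkl", design, design)
    xty = np.einsum("ptk,pt->pk", design, y)
    coef = np.linalg.solve(xtx, xty[:, :, None])[:, :, 0]

    fitted = np.einsum("ptk,pk->pt", design, coef)
    ssr = ((y - fitted) ** 2).sum(axis=1)
    dof = n_used - 4
    sigma2 = ssr / dof
    xtx_inv = np.linalg.inv(xtx)
    se = np.sqrt(np.einsum("pkk->pk", xtx_inv) * sigma2[:, None])

    eig = np.linalg.eigvalsh(xtx)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.sqrt(eig[:, -1] / np.maximum(eig[:, 0], 0.0))
    flagged = ~np.isfinite(cond) | (cond > condition_threshold)
    if flagged.any():
        logger.warning("%d pixels flagged for ill-conditioned design", flagged.sum())

    return ARFit(
        pixel=pixel,
        alpha=coef[:, 0],
        beta=coef[:, 1],
        gamma=coef[:, 2],
        delta=coef[:, 3],
        se=se,
        residual_variance=sigma2,
        n_obs=n_used,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Component scores
# ---------------------------------------------------------------------------


def resistance_score(fit: ARFit, combiner: str = "mean") -> np.ndarray:
    """Composite raw resistance: the negated size of the climate sensitivities.

    ``mean`` gives -(|alpha| + |beta| + |gamma|)/3, ``max`` the negated
    largest sensitivity. Zero is the maximum (a climate-insensitive pixel);
    flagged fits propagate as NaN.
    """
    stacked = np.abs(np.stack([fit.alpha, fit.beta, fit.gamma], axis=0))
    if combiner == "mean":
        raw = -stacked.mean(axis=0)
    elif combiner == "max":
        raw = -stacked.max(axis=0)
    else:
        raise InvalidArgumentError(f"unknown resistance combiner {combiner!r}")
    raw = raw.copy()
    raw[fit.flagged] = np.nan
    return raw


def resilience_score(fit: ARFit) -> np.ndarray:
    """Raw resilience -|delta|: zero (no memory) is the maximum."""
    raw = -np.abs(fit.delta)
    raw[fit.flagged] = np.nan
    return raw


def normalize_0_100(values: np.ndarray) -> np.ndarray:
    """Min-max rescale finite values to [0, 100]; NaN stays NaN."""
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if np.unique(finite).size < 2:
        raise DegenerateNormalizationError(
            "need at least two distinct finite values to normalize"
        )
    lo, hi = finite.min(), finite.max()
    return (values - lo) / (hi - lo) * 100.0


# ---------------------------------------------------------------------------
# Per-period stability table
# ---------------------------------------------------------------------------


def stability_table(
    prepared: PreparedPeriod,
    resistance_combiner: str = "mean",
    normalize: bool = True,
) -> pd.DataFrame:
    """Raw and 0–100 normalized stability components for one period.

    The normalization domain is the full set of retained pixels of the
    period, so normalized values are comparable across pixels within it.
    """
    fit = fit_ar_climate_model(
        prepared.ndvi,
        prepared.temperature,
        prepared.precipitation,
        prepared.radiation,
    )
    inv_raw = temporal_invariability(prepared.ndvi_raw)
    rst_raw = resistance_score(fit, combiner=resistance_combiner)
    rsl_raw = resilience_score(fit)

    table = fit.to_frame()
    table["invariability_raw"] = inv_raw
    table["resistance_raw"] = rst_raw
    table["resilience_raw"] = rsl_raw
    if normalize:
        for comp, raw in (
            ("invariability", inv_raw),
            ("resistance", rst_raw),
            ("resilience", rsl_raw),
        ):
            table[comp] = normalize_0_100(raw)
    return table
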