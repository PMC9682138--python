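"""Livestock pressure: sheep units, grazing intensity, and per-period trends.

Livestock counts are converted to standard sheep units (SHU) — one sheep or
goat counts as one SHU, one yak, donkey or horse as four — and grazing
intensity (GI) is the SHU load per hectare of natural grassland in a county.
Annual trends of GI and of the unit-level climate summaries (mean annual
temperature, annual precipitation, annual radiation) are OLS slopes against
calendar year, computed per study period; their between-period differences
feed the attribution stage.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidArgumentError

logger = logging.getLogger(__name__)

#: Standard sheep units per head of each species.
SHU_PER_HEAD = {"sheep": 1.0, "goat": 1.0, "yak": 4.0, "donkey": 4.0, "horse": 4.0}

TREND_VARIABLES = ("MAT", "AP", "AR", "GI")


def to_sheep_units(counts: Mapping[str, float] | pd.DataFrame) -> float | pd.Series:
    """Convert per-species head counts to standard sheep units.

    Accepts a mapping (returns a float) or a DataFrame with species columns
    (returns a per-row Series). Missing species are treated as zero with a
    logged warning; negative counts are rejected.
    """
    if isinstance(counts, pd.DataFrame):
        total = pd.Series(0.0, index=counts.index)
        for species, factor in SHU_PER_HEAD.items():
            if species not in counts.columns:
                logger.warning("species %r missing; treated as 0", species)
                continue
            col = counts[species]
            if (col < 0).any():
                raise InvalidArgumentError(f"negative {species} count")
            total = total + factor * col
        return total
    total = 0.0
    for species, factor in SHU_PER_HEAD.items():
        value = counts.get(species, None)
        if value is None:
            logger.warning("species %r missing; treated as 0", species)
            continue
        if value < 0:
            raise InvalidArgumentError(f"negative {species} count")
        total += factor * value
    return total


def grazing_intensity(shu: float, area_ha: float) -> float:
    """Grazing intensity: sheep units per hectare of natural grassland."""
    if area_ha <= 0:
        raise InvalidArgumentError("grassland area must be positive")
    return shu / area_ha


def grazing_intensity_table(
    livestock: pd.DataFrame, county_area_ha: pd.Series
) -> pd.DataFrame:
    """County x year grazing intensity from annual livestock records.

    ``livestock`` needs columns county_id, year and the species counts.
    Returns a DataFrame indexed by county_id with one column per year.
    """
    shu = to_sheep_units(livestock)
    frame = livestock[["county_id", "year"]].copy()
    frame["gi"] = shu.to_numpy() / frame["county_id"].map(county_area_ha).to_numpy()
    if frame["gi"].isna().any():
        missing = frame.loc[frame["gi"].isna(), "county_id"].unique()
        raise InvalidArgumentError(f"no grassland area for counties {missing}")
    table = frame.pivot_table(index="county_id", columns="year", values="gi")
    return table


def linear_trend(values: Sequence[float], years: Sequence[int] | None = None) -> float:
    """OLS slope of an annual series against calendar year."""
    if isinstance(values, pd.Series) and years is None:
        years = values.index.to_numpy(dtype=float)
    values = np.asarray(values, dtype=float)
    if years is None:
        raise InvalidArgumentError("years must be given for non-Series input")
    years = np.asarray(years, dtype=float)
    ok = np.isfinite(values)
    if ok.sum() < 3:
        raise InsufficientDataError("trend needs at least 3 annual values")
    slope, _ = np.polyfit(years[ok], values[ok], deg=1)
    return float(slope)


def _period_slopes(table: pd.DataFrame, periods) -> pd.DataFrame:
    """OLS slope of each row of a (unit x year) table within each period."""
    out = {}
    years = table.columns.to_numpy(dtype=int)
    for k, (start, end) in enumerate(periods, start=1):
        cols = (years >= start) & (years <= end)
        if cols.sum() < 3:
            raise InsufficientDataError(f"period {start}-{end} has < 3 annual values")
        sub = table.loc[:, table.columns[cols]]
        out[f"p{k}"] = sub.apply(
            lambda row: linear_trend(row.to_numpy(), years[cols]), axis=1
        )
    return pd.DataFrame(out)


def compute_trend_deltas(
    annual_tables: Mapping[str, pd.DataFrame],
    periods: Sequence[tuple[int, int]],
) -> pd.DataFrame:
    """Per-unit, per-period trends and their between-period differences.

    ``annual_tables`` maps a variable tag (MAT, AP, AR, GI) to a unit x year
    table of annual values. For each variable the output holds
    ``Trend_<var>_p1``, ``Trend_<var>_p2`` (units per year) and
    ``dTrend_<var>`` = period-2 slope minus period-1 slope.
    """
    if len(periods) != 2:
        raise InvalidArgumentError("trend deltas are defined for exactly two periods")
    missing = [var for var in TREND_VARIABLES if var not in annual_tables]
    if missing:
        raise InvalidArgumentError(f"missing annual tables for {missing}")
    parts = []
    for var in TREND_VARIABLES:
        slopes = _period_slopes(annual_tables[var], periods)
        part = pd.DataFrame(
            {
                f"Trend_{var}_p1": slopes["p1"],
                f"Trend_{var}_p2": slopes["p2"],
                f"dTrend_{var}": slopes["p2"] - slopes["p1"],
            }
        )
        parts.append(part)
    return pd.concat(parts, axis=1)
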