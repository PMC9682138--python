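"""Dimensionality of stability: the normalized ellipsoid-volume statistic.

Variation across the pixels of one county x grassland-type unit (a
space-for-time substitution) yields Pearson correlations among the three
stability components. The 3x3 correlation matrix defines an ellipsoid whose
semi-axes are the square roots of its eigenvalues,

    V = pi^(n/2) / Gamma(n/2 + 1) * prod_i lambda_i^(1/2),    n = 3.

After dividing every semi-axis by the largest one, the ratio of the
ellipsoid volume to the unit-sphere volume is the dimensionality

    D = prod_i sqrt(lambda_i / lambda_max)  in [0, 1],

1 when the components are uncorrelated (a perfect sphere: three independent
ways of being stable) and 0 when they are fully coupled (a degenerate
"cigar": one effective dimension).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import gamma, pi

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError, InvalidMatrixError, UnitMismatchError
from .synthetic import Landscape

logger = logging.getLogger(__name__)

COMPONENT_PAIRS = (
    ("invariability", "resistance"),
    ("invariability", "resilience"),
    ("resistance", "resilience"),
)
_EIG_CLIP = 1e-10
_SHORT = {"invariability": "inv", "resistance": "rst", "resilience": "rsl"}


# ---------------------------------------------------------------------------
# Space-for-time grouping
# ---------------------------------------------------------------------------


@dataclass
class SpatialDataset:
    """Stability components of all pixels in one county x type unit."""

    unit_id: str
    county_id: int
    grassland_type: str
    data: pd.DataFrame  # columns: invariability, resistance, resilience

    @property
    def n_pixels(self) -> int:
        return len(self.data)

    @property
    def pixel_ids(self) -> np.ndarray:
        return self.data.index.to_numpy()


def group_space_for_time(
    triplets: pd.DataFrame, landscape: Landscape, min_pixels: int = 30
) -> list[SpatialDataset]:
    """Split per-pixel stability triplets into county x type spatial datasets.

    ``triplets`` is indexed by pixel id with the three component columns.
    Pixels with any missing component are dropped; units retaining fewer than
    ``min_pixels`` valid pixels are discarded with a logged count.
    """
    if landscape.n_pixels == 0:
        raise InvalidArgumentError("empty landscape")
    cols = ["invariability", "resistance", "resilience"]
    merged = landscape.pixels.set_index("pixel_id").join(triplets[cols], how="inner")
    merged = merged.dropna(subset=cols)
    datasets: list[SpatialDataset] = []
    dropped = 0
    for (county, gtype), group in sorted(
        merged.groupby(["county_id", "grassland_type"], sort=True)
    ):
        if len(group) < min_pixels:
            dropped += 1
            continue
        datasets.append(
            SpatialDataset(
                unit_id=f"c{county}_{gtype}",
                county_id=county,
                grassland_type=gtype,
                data=group[cols].copy(),
            )
        )
    if dropped:
        logger.info("dropped %d units with fewer than %d valid pixels", dropped, min_pixels)
    return datasets


# ---------------------------------------------------------------------------
# Correlations and the ellipsoid
# ---------------------------------------------------------------------------


def pairwise_correlations(dataset: SpatialDataset) -> dict[tuple[str, str], tuple[float, float]]:
    """Pearson r and two-sided p for the three component pairs.

    A component with zero variance across the unit's pixels yields NaN for
    its pairs (undefined correlation).
    """
    if dataset.n_pixels < 3:
        raise InvalidArgumentError("need at least 3 pixels for correlations")
    out = {}
    for a, b in COMPONENT_PAIRS:
        x = dataset.data[a].to_numpy()
        y = dataset.data[b].to_numpy()
        if x.std() == 0 or y.std() == 0:
            logger.warning("unit %s: zero variance in (%s, %s)", dataset.unit_id, a, b)
            out[(a, b)] = (np.nan, np.nan)
            continue
        r, p = stats.pearsonr(x, y)
        out[(a, b)] = (float(r), float(p))
    return out


def correlation_matrix(
    correlations: dict[tuple[str, str], tuple[float, float]]
) -> np.ndarray:
    """Assemble the symmetric unit-diagonal 3x3 matrix from the three r's."""
    order = ("invariability", "resistance", "resilience")
    mat = np.eye(3)
    for (a, b), (r, _) in correlations.items():
        i, j = order.index(a), order.index(b)
        mat[i, j] = mat[j, i] = r
    return mat


@dataclass
class StabilityEllipsoid:
    """Ellipsoid summary of one unit's stability-component correlations."""

    matrix: np.ndarray
    eigenvalues: np.ndarray  # descending, clipped at 0
    semi_axes: np.ndarray  # sqrt(eigenvalues)
    volume: float
    dimensionality: float
    unit_id: str | None = None
    correlations: dict | None = None
    n_pixels: int | None = None


def ellipsoid_volume(semi_axes: np.ndarray) -> float:
    """Volume of an n-ellipsoid with the given semi-axis lengths."""
    n = len(semi_axes)
    return pi ** (n / 2) / gamma(n / 2 + 1) * float(np.prod(semi_axes))


def ellipsoid_dimensionality(
    matrix: np.ndarray, tol: float = 1e-8
) -> StabilityEllipsoid:
    """Dimensionality of stability from a component correlation matrix.

    Eigenvalues in [-1e-10, 0) are clipped to zero (numerical noise of
    rank-deficient matrices); anything more negative, an asymmetric matrix or
    a non-unit diagonal is rejected.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] != matrix.shape[1]:
        raise InvalidMatrixError("correlation matrix must be square")
    if not np.allclose(matrix, matrix.T, atol=tol):
        raise InvalidMatrixError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(matrix), 1.0, atol=tol):
        raise InvalidMatrixError("correlation matrix must have a unit diagonal")
    if np.isnan(matrix).any():
        raise InvalidMatrixError("correlation matrix contains NaN")

    eig = np.linalg.eigvalsh(matrix)[::-1]  # descending
    if eig[-1] < -_EIG_CLIP:
        raise InvalidMatrixError(
            f"matrix is indefinite (min eigenvalue {eig[-1]:.3e})"
        )
    if (eig < 0).any():
        logger.debug("clipped negative eigenvalues %s to 0", eig[eig < 0])
        eig = np.clip(eig, 0.0, None)

    semi_axes = np.sqrt(eig)
    volume = ellipsoid_volume(semi_axes)
    dimensionality = float(np.prod(semi_axes / semi_axes[0]))
    return StabilityEllipsoid(
        matrix=matrix,
        eigenvalues=eig,
        semi_axes=semi_axes,
        volume=volume,
        dimensionality=dimensionality,
    )


def stability_ellipsoid(dataset: SpatialDataset) -> StabilityEllipsoid:
    """Correlations, eigenstructure and dimensionality for one unit."""
    correlations = pairwise_correlations(dataset)
    ellipsoid = ellipsoid_dimensionality(correlation_matrix(correlations))
    ellipsoid.unit_id = dataset.unit_id
    ellipsoid.correlations = correlations
    ellipsoid.n_pixels = dataset.n_pixels
    return ellipsoid


def ellipsoid_table(datasets: list[SpatialDataset]) -> pd.DataFrame:
    """One row per unit: correlations, eigenvalues, volume, dimensionality."""
    rows = []
    for ds in datasets:
        ell = stability_ellipsoid(ds)
        row = {
            "unit_id": ds.unit_id,
            "county_id": ds.county_id,
            "grassland_type": ds.grassland_type,
            "n_pixels": ds.n_pixels,
        }
        for (a, b), (r, p) in ell.correlations.items():
            tag = f"{_SHORT[a]}_{_SHORT[b]}"
            row[f"r_{tag}"] = r
            row[f"p_{tag}"] = p
        for i, lam in enumerate(ell.eigenvalues, start=1):
            row[f"lambda_{i}"] = lam
        row["volume"] = ell.volume
        row["dimensionality"] = ell.dimensionality
        rows.append(row)
    return pd.DataFrame(rows).set_index("unit_id")


# ---------------------------------------------------------------------------
# Between-period change
# ---------------------------------------------------------------------------


def delta_dimensionality(
    d1: pd.DataFrame,
    d2: pd.DataFrame,
    weight_by_pixels: bool = True,
    large_decrease: float = 0.20,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-unit change in dimensionality between two periods plus summaries.

    ``d1``/``d2`` are :func:`ellipsoid_table` outputs. The summary reports
    the mean change, the percentage of units (pixel-weighted by default) in
    which dimensionality decreased, and the percentage of that decreasing
    share whose relative decrease exceeds ``large_decrease``.
    """
    missing = d1.index.symmetric_difference(d2.index)
    if len(missing):
        raise UnitMismatchError(f"units present in only one period: {list(missing)}")
    units = d1.index
    table = pd.DataFrame(
        {
            "n_pixels": d1["n_pixels"],
            "D_p1": d1["dimensionality"],
            "D_p2": d2.loc[units, "dimensionality"],
        }
    )
    table["delta_D"] = table["D_p2"] - table["D_p1"]
    table["relative_change"] = table["delta_D"] / table["D_p1"]

    weights = (
        table["n_pixels"].to_numpy(dtype=float)
        if weight_by_pixels
        else np.ones(len(table))
    )
    decreasing = (table["delta_D"] < 0).to_numpy()
    w_total = weights.sum()
    w_dec = weights[decreasing].sum()
    big = decreasing & (table["relative_change"].to_numpy() < -large_decrease)
    summary = {
        "mean_delta": float(np.average(table["delta_D"], weights=weights)),
        "pct_decreasing": float(100.0 * w_dec / w_total),
        "pct_of_decreasing_above_threshold": float(
            100.0 * weights[big].sum() / w_dec if w_dec > 0 else 0.0
        ),
    }
    return table, summary
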