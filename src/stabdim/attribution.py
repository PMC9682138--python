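"""Attribution of between-period dimensionality change to climate and grazing.

The unit of analysis is the county x grassland-type spatial dataset. Each
unit carries the between-period differences of four annual trends — mean
annual temperature (MAT), annual precipitation (AP), annual radiation (AR)
and grazing intensity (GI) — as predictors of the change in dimensionality.
Two complementary views are produced: simple bivariate OLS slopes, and a
random-forest regression whose out-of-bag (OOB) permutation importance
(%IncMSE) ranks the predictors.

The forest is built tree by tree on bootstrap samples so that, for every
tree, the OOB rows provide an honest test set: %IncMSE for a predictor is
the increase in OOB mean squared error when that predictor's column is
permuted, averaged over trees. Two conventions are exposed: ``percent``
(default) divides the mean increase by the baseline OOB MSE and multiplies
by 100; ``scaled`` divides it by its standard error across trees (the
convention of the classical randomForest importance output).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeRegressor

from .errors import InsufficientDataError, InvalidArgumentError

logger = logging.getLogger(__name__)

PREDICTORS = ("dTrend_MAT", "dTrend_AP", "dTrend_AR", "dTrend_GI")
RESPONSE = "delta_D"


def assemble_attribution_table(
    trend_deltas: pd.DataFrame, delta_dim: pd.Series | pd.DataFrame
) -> pd.DataFrame:
    """Join per-unit trend differences with the dimensionality change.

    Rows with any missing value are dropped with a logged warning; an empty
    join is an error.
    """
    if isinstance(delta_dim, pd.DataFrame):
        delta_dim = delta_dim[RESPONSE]
    delta_dim = delta_dim.rename(RESPONSE)
    table = trend_deltas[list(PREDICTORS)].join(delta_dim, how="inner")
    n_missing = int(table.isna().any(axis=1).sum())
    if n_missing:
        logger.warning("dropping %d units with missing predictors", n_missing)
        table = table.dropna()
    if table.empty:
        raise InvalidArgumentError("no units left after joining predictors and response")
    return table


def bivariate_relationships(table: pd.DataFrame, min_rows: int = 10) -> pd.DataFrame:
    """Simple OLS of the dimensionality change on each predictor separately.

    Returns slope, intercept, r and two-sided p per predictor; a constant
    predictor yields NaN (undefined slope).
    """
    if len(table) < min_rows:
        raise InsufficientDataError(f"need >= {min_rows} rows, got {len(table)}")
    y = table[RESPONSE].to_numpy()
    rows = {}
    for pred in PREDICTORS:
        x = table[pred].to_numpy()
        if np.std(x) == 0:
            logger.warning("predictor %s is constant; slope undefined", pred)
            rows[pred] = dict(slope=np.nan, intercept=np.nan, r=np.nan, p=np.nan)
            continue
        res = stats.linregress(x, y)
        rows[pred] = dict(
            slope=res.slope, intercept=res.intercept, r=res.rvalue, p=res.pvalue
        )
    return pd.DataFrame(rows).T


@dataclass
class AttributionResult:
    """Random-forest importance of the four trend predictors."""

    importance: pd.Series  # %IncMSE per predictor, chosen variant
    importance_se: pd.Series  # Monte-Carlo SE of the raw MSE increase
    r2_oob: float  # R^2 of out-of-bag predictions vs observed
    oob_predictions: pd.Series
    bivariate: pd.DataFrame
    n_trees: int
    seed: int
    variant: str


def random_forest_attribution(
    table: pd.DataFrame,
    n_trees: int = 500,
    seed: int = 0,
    max_features: float = 1 / 3,
    variant: str = "percent",
    min_rows: int = 20,
) -> AttributionResult:
    """Regression forest with out-of-bag permutation importance (%IncMSE).

    Each tree is grown on a bootstrap sample (unlimited depth, a third of
    the predictors tried per split); its OOB rows yield a baseline MSE and,
    per predictor, the MSE after permuting that column. The fit quality is
    the R^2 between observed values and OOB-aggregated predictions.
    """
    if variant not in ("percent", "scaled"):
        raise InvalidArgumentError("variant must be 'percent' or 'scaled'")
    if len(table) < min_rows:
        raise InsufficientDataError(f"need >= {min_rows} rows, got {len(table)}")
    X = table[list(PREDICTORS)].to_numpy()
    y = table[RESPONSE].to_numpy()
    n, p = X.shape

    rng = np.random.default_rng(seed)
    increase = np.full((n_trees, p), np.nan)
    baseline = np.full(n_trees, np.nan)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n)

    for b in range(n_trees):
        boot = rng.integers(0, n, size=n)
        in_bag = np.zeros(n, dtype=bool)
        in_bag[boot] = True
        oob = np.flatnonzero(~in_bag)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            continue
        pred = tree.predict(X[oob])
        base = float(np.mean((y[oob] - pred) ** 2))
        baseline[b] = base
        oob_sum[oob] += pred
        oob_count[oob] += 1
        for j in range(p):
            permuted = X[oob].copy()
            permuted[:, j] = permuted[rng.permutation(oob.size), j]
            mse_j = float(np.mean((y[oob] - tree.predict(permuted)) ** 2))
            increase[b, j] = mse_j - base

    raw_mean = np.nanmean(increase, axis=0)
    raw_se = np.nanstd(increase, axis=0, ddof=1) / np.sqrt(
        np.sum(np.isfinite(increase), axis=0)
    )
    base_mse = float(np.nanmean(baseline))
    if variant == "percent":
        importance = 100.0 * raw_mean / base_mse
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            importance = np.where(raw_se > 0, raw_mean / raw_se, 0.0)

    seen = oob_count > 0
    oob_pred = np.full(n, np.nan)
    oob_pred[seen] = oob_sum[seen] / oob_count[seen]
    resid = y[seen] - oob_pred[seen]
    r2 = 1.0 - float(np.mean(resid**2)) / float(np.var(y[seen]))

    index = pd.Index(PREDICTORS, name="predictor")
    return AttributionResult(
        importance=pd.Series(importance, index=index, name=f"IncMSE_{variant}"),
        importance_se=pd.Series(raw_se, index=index, name="IncMSE_se"),
        r2_oob=r2,
        oob_predictions=pd.Series(oob_pred, index=table.index, name="oob_prediction"),
        bivariate=bivariate_relationships(table),
        n_trees=n_trees,
        seed=seed,
        variant=variant,
    )
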