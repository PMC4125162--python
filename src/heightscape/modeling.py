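"""Richness model comparison: correlation screening, BPHM selection, linear
models with BCa bootstrap intervals, and random forests with OOB
permutation importance.

Conventions
-----------
* adj_r2 = 1 - (1 - R^2)(n - 1)/(n - p - 1).
* AIC = n ln(RSS / n) + 2(p + 2) (Gaussian profile likelihood with an
  intercept and a variance parameter).  Only AIC differences are
  interpreted, so the additive constant convention is internal.
* Bootstrap resamples whole routes (cases); intervals are bias-corrected
  and accelerated (BCa), with z0 from the proportion of bootstrap
  statistics below the point estimate and acceleration from the jackknife
  skewness.  3000 replicates by default.
* Random forests use 2000 trees, mtry = p/3 (regression default of the
  reference implementation); variable importance is %IncMSE: the mean
  per-tree increase in out-of-bag MSE after permuting one predictor,
  expressed as a percentage of the forest's OOB MSE.
* Predictors enter on their raw scales.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.tree import DecisionTreeRegressor

from .habitat_metrics import METRIC_NAMES, METRIC_SETS, SET_C, SET_D

log = logging.getLogger(__name__)

DEFAULT_N_BOOT = 3000
DEFAULT_N_TREES = 2000

#: Predictor-set names of the model suite, in reporting order.
LINEAR_SETS: tuple[str, ...] = ("A", "B", "C", "D", "A+BPHM", "B+BPHM")
RF_SETS: tuple[str, ...] = LINEAR_SETS + ("ALL",)


@dataclass
class LinearFit:
    adj_r2: float
    aic: float
    r2: float
    coefs: np.ndarray
    n: int
    p: int


@dataclass
class ForestFit:
    var_explained: float
    oob_mse: float
    importance: pd.Series
    n_trees: int
    seed: int


# ----------------------------------------------------------------------
# Correlation screen and BPHM selection
# ----------------------------------------------------------------------
def correlate(metrics: pd.DataFrame, richness: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of each metric with each guild's mean richness.

    ``metrics`` is route-indexed with metric columns; ``richness`` has
    route_id, guild, mean_richness.  Zero-variance metrics come back NaN.
    Returns metrics x guilds.
    """
    cols = [c for c in metrics.columns if c in METRIC_NAMES]
    out = {}
    for guild, sub in richness.groupby("guild"):
        joined = metrics[cols].join(sub.set_index("route_id")["mean_richness"], how="inner")
        if len(joined) < 3:
            raise ValueError(f"need >= 3 complete routes for guild {guild!r}")
        y = joined["mean_richness"].to_numpy(dtype=float)
        rs = {}
        for c in cols:
            x = joined[c].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                rs[c] = np.nan
            else:
                rs[c] = float(np.corrcoef(x[ok], y[ok])[0, 1])
        out[guild] = rs
    return pd.DataFrame(out).loc[cols]


def select_bphm(correlations: pd.DataFrame) -> list[str]:
    """Best-performing height-structured metrics: the 2 metrics from each of
    sets C and D with the highest mean |r| across guilds.

    Ties break alphabetically with a logged warning.
    """
    if correlations.shape[1] == 0:
        raise ValueError("correlation table has no guild columns")
    mean_abs = correlations.abs().mean(axis=1)
    picks: list[str] = []
    for set_names in (SET_C, SET_D):
        avail = [m for m in set_names if m in mean_abs.index]
        if len(avail) < 2:
            raise ValueError("correlations missing for some set C/D metrics")
        scores = mean_abs.loc[avail]
        ranked = scores.sort_values(ascending=False, kind="stable")
        cut = ranked.iloc[1]
        if (scores == cut).sum() > 1 and len(avail) > 2:
            log.warning("tie at the selection cutoff; breaking alphabetically")
            ranked = scores.sort_index().sort_values(ascending=False, kind="stable")
        picks.extend(ranked.index[:2].tolist())
    return picks


def predictor_names(set_name: str, bphm: list[str] | None = None) -> list[str]:
    """Expand a predictor-set label into metric column names."""
    if set_name == "ALL":
        return list(METRIC_NAMES)
    if set_name.endswith("+BPHM"):
        if not bphm:
            raise ValueError("BPHM metrics required for combined sets")
        base = list(METRIC_SETS[set_name[0]])
        return base + [m for m in bphm if m not in base]
    return list(METRIC_SETS[set_name])


# ----------------------------------------------------------------------
# Linear models
# ----------------------------------------------------------------------
def _ols_stats(X: np.ndarray, y: np.ndarray) -> tuple[float, float, float, np.ndarray]:
    n, p = X.shape
    design = np.column_stack([np.ones(n), X])
    coefs, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coefs
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    if rss <= max(tss, 1.0) * 1e-12:
        raise ValueError("perfect fit (RSS = 0): AIC undefined")
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    aic = n * np.log(rss / n) + 2 * (p + 2)
    return r2, adj, aic, coefs


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    design = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(design)
    if rank >= design.shape[1]:
        return []
    bad = []
    for j, name in enumerate(names):
        reduced = np.delete(design, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(name)
    return bad


def fit_linear(data: pd.DataFrame, predictors: list[str], response: str = "mean_richness") -> LinearFit:
    """Ordinary least squares of ``response`` on ``predictors``.

    Rows with missing values are deleted.  Raises on rank-deficient designs
    (naming the collinear columns) and on perfect fits.
    """
    sub = data[predictors + [response]].dropna()
    n, p = len(sub), len(predictors)
    if n <= p + 2:
        raise ValueError(f"need n > p + 2 ({n} rows, {p} predictors)")
    X = sub[predictors].to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)
    bad = _collinear_columns(X, predictors)
    if bad:
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    r2, adj, aic, coefs = _ols_stats(X, y)
    return LinearFit(adj, aic, r2, coefs, n, p)


# ----------------------------------------------------------------------
# BCa bootstrap
# ----------------------------------------------------------------------
def _bca_interval(
    boot: np.ndarray, theta_hat: float, jack: np.ndarray, level: float
) -> tuple[float, float]:
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        return (np.nan, np.nan)
    if np.allclose(boot, boot[0]):
        return (float(boot[0]), float(boot[0]))
    alpha = (1.0 - level) / 2.0
    prop = np.mean(boot < theta_hat)
    if prop <= 0.0 or prop >= 1.0:
        warnings.warn(
            "degenerate bootstrap distribution; falling back to percentile",
            RuntimeWarning,
            stacklevel=2,
        )
        return tuple(np.quantile(boot, [alpha, 1 - alpha]))
    z0 = norm.ppf(prop)
    jm = jack.mean()
    num = ((jm - jack) ** 3).sum()
    den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
    a = num / den if den > 0 else 0.0
    z = norm.ppf([alpha, 1 - alpha])
    adj = norm.cdf(z0 + (z0 + z) / (1 - a * (z0 + z)))
    lo, hi = np.quantile(boot, adj)
    return float(lo), float(hi)


def bootstrap_bca(
    data: pd.DataFrame,
    statistic,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Case-resampling BCa intervals for one or more statistics.

    ``statistic(frame) -> dict[str, float]`` is evaluated on the original
    data, on ``n_boot`` row-resamples and on the n leave-one-out jackknife
    frames.  Returns {name: (lo, hi)}.
    """
    n = len(data)
    if n < 20:
        raise ValueError("need n >= 20 rows for a stable bootstrap")
    rng = np.random.default_rng(seed)
    point = statistic(data)
    names = list(point)
    boots = {k: np.empty(n_boot) for k in names}
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            res = statistic(data.iloc[idx])
        except ValueError:
            res = {k: np.nan for k in names}
        for k in names:
            boots[k][b] = res[k]
    jacks = {k: np.empty(n) for k in names}
    for i in range(n):
        res = statistic(data.drop(data.index[i]))
        for k in names:
            jacks[k][i] = res[k]
    return {
        k: _bca_interval(boots[k], point[k], jacks[k], level) for k in names
    }


# ----------------------------------------------------------------------
# Random forest with OOB permutation importance
# ----------------------------------------------------------------------
def fit_rf(
    data: pd.DataFrame,
    predictors: list[str],
    response: str = "mean_richness",
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    compute_importance: bool = True,
) -> ForestFit:
    """Random-forest regression with out-of-bag error and %IncMSE importance.

    Trees are fit on bootstrap samples with mtry = max(1, p // 3) candidate
    features per split.  var_explained = 1 - OOB MSE / Var(y).  Importance
    for predictor j is the per-tree increase in OOB MSE after permuting
    column j among that tree's OOB cases, averaged over trees and expressed
    as a percentage of the forest OOB MSE.
    """
    if n_trees < 100:
        warnings.warn("n_trees < 100: OOB error may not have converged", RuntimeWarning)
    sub = data[predictors + [response]].dropna()
    X = sub[predictors].to_numpy(dtype=float)
    y = sub[response].to_numpy(dtype=float)
    n, p = X.shape
    if n < 10:
        raise ValueError("too few rows for a forest")
    rng = np.random.default_rng(seed)
    mtry = max(1, p // 3)

    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    tree_mse = np.empty(n_trees)
    perm_increase = np.zeros((n_trees, p)) if compute_importance else None
    all_idx = np.arange(n)
    for t in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(all_idx, boot, assume_unique=False)
        tree = DecisionTreeRegressor(
            max_features=mtry, random_state=int(rng.integers(0, 2**31 - 1))
        )
        tree.fit(X[boot], y[boot])
        if oob.size == 0:
            tree_mse[t] = np.nan
            continue
        pred = tree.predict(X[oob])
        oob_sum[oob] += pred
        oob_cnt[oob] += 1
        base_mse = float(np.mean((y[oob] - pred) ** 2))
        tree_mse[t] = base_mse
        if compute_importance:
            for j in range(p):
                Xp = X[oob].copy()
                Xp[:, j] = Xp[rng.permutation(oob.size), j]
                pj = tree.predict(Xp)
                perm_increase[t, j] = float(np.mean((y[oob] - pj) ** 2)) - base_mse

    seen = oob_cnt > 0
    oob_pred = np.full(n, np.nan)
    oob_pred[seen] = oob_sum[seen] / oob_cnt[seen]
    oob_mse = float(np.mean((y[seen] - oob_pred[seen]) ** 2))
    var_y = float(np.mean((y - y.mean()) ** 2))
    var_explained = 1.0 - oob_mse / var_y if var_y > 0 else np.nan

    if compute_importance:
        with np.errstate(invalid="ignore"):
            mean_inc = np.nanmean(perm_increase, axis=0)
        importance = pd.Series(100.0 * mean_inc / oob_mse, index=predictors, name="pct_inc_mse")
        importance = importance.sort_values(ascending=False)
    else:
        importance = pd.Series(dtype=float, name="pct_inc_mse")
    return ForestFit(var_explained, oob_mse, importance, n_trees, seed)


# ----------------------------------------------------------------------
# The full suite
# ----------------------------------------------------------------------
@dataclass
class SuiteResult:
    """Everything the model-comparison stage produces."""

    results: pd.DataFrame
    correlations: pd.DataFrame
    bphm: list[str]
    importances: dict[tuple[str, str], pd.Series] = field(default_factory=dict)


def run_model_suite(
    metrics: pd.DataFrame,
    richness: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    n_trees: int = DEFAULT_N_TREES,
    seed: int = 0,
    guilds: list[str] | None = None,
) -> SuiteResult:
    """Per guild: 6 linear models (with BCa intervals for adj_r2 and AIC)
    and 7 random-forest models ({A, B, C, D, A+BPHM, B+BPHM} plus ALL).

    ``metrics`` is route-indexed (26 columns); ``richness`` is long
    (route_id, guild, mean_richness).  Fully deterministic under ``seed``.
    """
    corr = correlate(metrics, richness)
    bphm = select_bphm(corr)
    if guilds is None:
        guilds = sorted(richness["guild"].unique())
    rows = []
    importances: dict[tuple[str, str], pd.Series] = {}
    rng = np.random.default_rng(seed)
    for guild in guilds:
        sub = richness.loc[richness["guild"] == guild]
        data = metrics.join(sub.set_index("route_id")["mean_richness"], how="inner").dropna()
        for set_name in LINEAR_SETS:
            preds = predictor_names(set_name, bphm)
            fit = fit_linear(data, preds)

            def stat(frame, _preds=preds):
                f = fit_linear(frame, _preds)
                return {"adj_r2": f.adj_r2, "aic": f.aic}

            cis = bootstrap_bca(data, stat, n_boot=n_boot, seed=int(rng.integers(0, 2**31 - 1)))
            rows.append(
                {
                    "guild": guild, "model": "linear", "predictor_set": set_name,
                    "n": fit.n, "adj_r2": fit.adj_r2, "aic": fit.aic,
                    "adj_r2_lo": cis["adj_r2"][0], "adj_r2_hi": cis["adj_r2"][1],
                    "aic_lo": cis["aic"][0], "aic_hi": cis["aic"][1],
                    "var_explained": np.nan, "n_boot": n_boot, "n_trees": 0,
                }
            )
        for set_name in RF_SETS:
            preds = predictor_names(set_name, bphm)
            ff = fit_rf(data, preds, n_trees=n_trees, seed=int(rng.integers(0, 2**31 - 1)))
            importances[(guild, set_name)] = ff.importance
            rows.append(
                {
                    "guild": guild, "model": "rf", "predictor_set": set_name,
                    "n": len(data), "adj_r2": np.nan, "aic": np.nan,
                    "adj_r2_lo": np.nan, "adj_r2_hi": np.nan,
                    "aic_lo": np.nan, "aic_hi": np.nan,
                    "var_explained": ff.var_explained,
                    "n_boot": 0, "n_trees": n_trees,
                }
            )
    return SuiteResult(pd.DataFrame(rows), corr, bphm, importances)
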