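"""Cross-validation battery, accuracy metrics, "within" R2, and permutation XAI.

Random (sample-based) cross-validation flatters spatiotemporal models:
held-out rows sit next to training rows in space and time.  The battery
here therefore holds out whole *units* -- stations, days, 1-degree grid
clusters, states, ISO weeks, calendar months, and continent-stratified
station folds -- which is what separates interpolation skill from genuine
predictive skill at unmonitored places and dates.

Metrics follow the scatter-plot convention: ``r2`` is the squared Pearson
correlation between observations and predictions (``r2_ss``, the
1 - SSE/SST variant, is also computed); RMSE, NRMSE (RMSE over the mean of
observations), MAE, and the least-squares slope/intercept of pred on obs.

The "within" R2 removes additive station and year effects from both series
(two-way demeaning, iterated to convergence) before correlating, isolating
skill at tracking within-location variation over time.  Permutation
importance scores a feature by how much shuffling it degrades held-out
RMSE, normalized to percent contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stet_model

CV_UNITS = ("sample", "station", "day", "gridcell", "state", "week", "month",
            "continent_stratified")


@dataclass(frozen=True)
class CVScheme:
    unit: str = "sample"
    k: int = 10
    cluster_size: float = 1.0  # degrees, for unit="gridcell"
    seed: int = 0

    def __post_init__(self):
        if self.unit not in CV_UNITS:
            raise ValueError(f"unknown CV unit {self.unit!r}; one of {CV_UNITS}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.unit == "gridcell" and self.cluster_size <= 0:
            raise ValueError("gridcell unit requires cluster_size > 0")


@dataclass
class Metrics:
    r2: float
    r2_ss: float
    rmse: float
    nrmse: float
    mae: float
    slope: float
    intercept: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("r2", "r2_ss", "rmse", "nrmse", "mae", "slope", "intercept", "n")}


def compute_metrics(obs, pred) -> Metrics:
    """Accuracy metrics of predictions against observations."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("obs and pred must be 1-D arrays of equal length")
    n = len(obs)
    if n == 0:
        raise ValueError("empty input")
    err = pred - obs
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    mean_obs = float(np.mean(obs))
    nrmse = rmse / mean_obs if mean_obs != 0 else np.nan
    sst = float(np.sum((obs - mean_obs) ** 2))
    r2_ss = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else np.nan
    if n < 2 or np.std(obs) == 0 or np.std(pred) == 0:
        r2 = np.nan
        slope = np.nan
        intercept = np.nan
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
        r2 = r * r
        slope = float(np.cov(obs, pred, ddof=0)[0, 1] / np.var(obs))
        intercept = float(np.mean(pred) - slope * mean_obs)
    return Metrics(r2=r2, r2_ss=r2_ss, rmse=rmse, nrmse=nrmse, mae=mae,
                   slope=slope, intercept=intercept, n=n)


def _unit_labels(table: pd.DataFrame, scheme: CVScheme) -> pd.Series:
    unit = scheme.unit
    if unit == "sample":
        return pd.Series(np.arange(len(table)), index=table.index)
    if unit == "station":
        return table["station_id"]
    if unit == "day":
        return pd.to_datetime(table["date"]).dt.normalize()
    if unit == "gridcell":
        lat_bin = np.floor(table["lat"] / scheme.cluster_size).astype(int)
        lon_bin = np.floor(table["lon"] / scheme.cluster_size).astype(int)
        return lat_bin.astype(str) + "_" + lon_bin.astype(str)
    if unit == "state":
        return table["state"]
    if unit == "week":
        iso = pd.to_datetime(table["date"]).dt.isocalendar()
        return iso["year"].astype(str) + "-W" + iso["week"].astype(str)
    if unit == "month":
        return pd.to_datetime(table["date"]).dt.to_period("M").astype(str)
    raise ValueError(f"make_folds does not handle unit {unit!r} directly")


def make_folds(table: pd.DataFrame, scheme: CVScheme) -> np.ndarray:
    """Assign a fold id in [0, k) to every row.

    Folds partition the *unit* set (stations, days, clusters, ...) as evenly
    as possible; for unit="sample" they partition the rows themselves.
    Deterministic under ``scheme.seed``.
    """
    if scheme.unit == "continent_stratified":
        raise ValueError(
            "continent_stratified folds are built per continent; "
            "use cross_validate or make_folds on a per-continent subset"
        )
    labels = _unit_labels(table, scheme)
    units = labels.unique()
    if len(units) < scheme.k:
        raise ValueError(
            f"{len(units)} {scheme.unit} units < k={scheme.k}; use a smaller k"
        )
    rng = np.random.default_rng(scheme.seed)
    order = rng.permutation(len(units))
    fold_of_unit = {
        units[idx]: int(pos % scheme.k) for pos, idx in enumerate(order)
    }
    return labels.map(fold_of_unit).to_numpy()


@dataclass
class CVResult:
    pooled: Metrics
    per_fold: list = field(default_factory=list)
    obs: np.ndarray | None = None
    pred: np.ndarray | None = None
    per_continent: dict | None = None


def cross_validate(
    table: pd.DataFrame,
    scheme: CVScheme,
    train_fn,
    predict_fn,
    target: str = "pm25_daily",
) -> CVResult:
    """k-fold cross-validation with unit-level holdout.

    ``train_fn(train_df) -> model`` and ``predict_fn(model, test_df) ->
    array``.  Every row is predicted exactly once while held out; pooled
    metrics are computed over the concatenated held-out predictions and
    per-fold metrics reported alongside.  For unit="continent_stratified" a
    separate station-unit k-fold runs within each continent and metrics are
    reported per continent.
    """
    if scheme.unit == "continent_stratified":
        per_continent = {}
        all_obs, all_pred = [], []
        for cont, sub in table.groupby("continent"):
            inner = CVScheme(unit="station", k=scheme.k, seed=scheme.seed)
            res = cross_validate(sub, inner, train_fn, predict_fn, target)
            per_continent[cont] = res
            all_obs.append(res.obs)
            all_pred.append(res.pred)
        obs = np.concatenate(all_obs)
        pred = np.concatenate(all_pred)
        return CVResult(pooled=compute_metrics(obs, pred),
                        per_fold=[], obs=obs, pred=pred,
                        per_continent=per_continent)

    folds = make_folds(table, scheme)
    obs = np.full(len(table), np.nan)
    pred = np.full(len(table), np.nan)
    per_fold = []
    for f in range(scheme.k):
        test_mask = folds == f
        train_df = table.iloc[~test_mask]
        test_df = table.iloc[test_mask]
        if test_df.empty:
            continue
        try:
            model = train_fn(train_df)
        except Exception as e:
            raise RuntimeError(f"training failed on fold {f}: {e}") from e
        p = np.asarray(predict_fn(model, test_df), dtype=float)
        obs[test_mask] = test_df[target].to_numpy(dtype=float)
        pred[test_mask] = p
        per_fold.append(compute_metrics(obs[test_mask], pred[test_mask]))
    if np.isnan(pred).any():
        raise RuntimeError("some rows were never predicted")
    return CVResult(pooled=compute_metrics(obs, pred), per_fold=per_fold,
                    obs=obs, pred=pred)


def stet_cv_fns(target: str, predictors: list[str],
                config=None):
    """(train_fn, predict_fn) pair running the extra-trees core."""
    def train_fn(df):
        return stet_model.fit(df, target=target, predictors=predictors,
                              config=config)

    def predict_fn(model, df):
        return stet_model.predict(model, df)

    return train_fn, predict_fn


def two_way_demean(values, group_a, group_b, tol: float = 1e-10,
                   max_iter: int = 200) -> np.ndarray:
    """Remove additive group-a and group-b effects by iterated demeaning."""
    resid = np.asarray(values, dtype=float).copy()
    a = pd.Series(group_a).reset_index(drop=True)
    b = pd.Series(group_b).reset_index(drop=True)
    s = pd.Series(resid)
    for _ in range(max_iter):
        before = s.to_numpy().copy()
        s = s - s.groupby(a).transform("mean")
        s = s - s.groupby(b).transform("mean")
        if np.max(np.abs(s.to_numpy() - before)) < tol:
            break
    return s.to_numpy() - s.mean()


def within_r2(obs, pred, station_ids, year_ids) -> float:
    """Squared Pearson correlation after removing station and year effects.

    Returns NaN (with a warning) if the demeaned observations have no
    variance left -- e.g. when observations are constant within stations.
    """
    station_ids = pd.Series(station_ids).reset_index(drop=True)
    year_ids = pd.Series(year_ids).reset_index(drop=True)
    if station_ids.nunique() < 2:
        raise ValueError("within_r2 needs >= 2 stations")
    ro = two_way_demean(obs, station_ids, year_ids)
    rp = two_way_demean(pred, station_ids, year_ids)
    if np.allclose(ro.std(), 0.0) or np.allclose(rp.std(), 0.0):
        warnings.warn("within R2 undefined: zero residual variance",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    r = float(np.corrcoef(ro, rp)[0, 1])
    return r * r


def permutation_importance(
    model,
    table: pd.DataFrame,
    target: str,
    feature_groups: dict[str, list[str]] | None = None,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Percent contribution of each feature (and group) to held-out RMSE.

    Importance of a feature is the mean RMSE increase over ``n_repeats``
    column shuffles, floored at zero; percent contributions normalize the
    importances to 100.  ``feature_groups`` maps group name -> member
    features; a group's contribution is the sum of its members' percents.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    features = model.feature_names
    y = table[target].to_numpy(dtype=float)
    base_rmse = float(np.sqrt(np.mean(
        (stet_model.predict(model, table) - y) ** 2)))
    importances = {}
    for f in features:
        deltas = []
        for _ in range(n_repeats):
            shuffled = table.copy()
            shuffled[f] = rng.permutation(shuffled[f].to_numpy())
            rmse = float(np.sqrt(np.mean(
                (stet_model.predict(model, shuffled) - y) ** 2)))
            deltas.append(rmse - base_rmse)
        importances[f] = max(0.0, float(np.mean(deltas)))
    total = sum(importances.values())
    if total > 0:
        percents = {f: 100.0 * v / total for f, v in importances.items()}
    else:
        percents = {f: 0.0 for f in importances}
    out = {
        "baseline_rmse": base_rmse,
        "importance": importances,
        "percent": percents,
    }
    if feature_groups:
        out["group_percent"] = {
            g: float(sum(percents.get(f, 0.0) for f in members))
            for g, members in feature_groups.items()
        }
    return out
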