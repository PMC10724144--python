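"""Extra-trees learning core with a fixed training/prediction contract.

Both pipeline stages (AOD gap filling and PM2.5 retrieval) share this wrapper
around scikit-learn's :class:`~sklearn.ensemble.ExtraTreesRegressor`.  The
wrapper owns the parts that downstream code relies on and that a bare
estimator does not guarantee:

* a recorded feature-name manifest, enforced at prediction time;
* determinism under a fixed seed;
* refusal of missing or non-numeric predictors with a column-level message;
* predictions bounded by the training-target range (a structural property of
  ensembles of leaf means, surfaced here as an explicit check).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesRegressor


@dataclass(frozen=True)
class StetConfig:
    """Hyperparameters of the extremely randomized ensemble.

    Defaults: 100 trees, minimum leaf size 2, all features eligible at each
    split (the canonical extra-trees regression setting), one worker.
    """

    n_trees: int = 100
    min_leaf: int = 2
    max_features: float | int | str | None = 1.0
    seed: int = 0
    n_jobs: int = 1

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainedEnsemble:
    """A fitted forest plus the manifest and summary the contract requires."""

    forest: ExtraTreesRegressor
    feature_names: list[str]
    config: StetConfig
    n_rows: int
    target_mean: float
    target_min: float
    target_max: float

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "TrainedEnsemble":
        obj = joblib.load(path)
        if not isinstance(obj, TrainedEnsemble):
            raise TypeError(f"{path} does not contain a TrainedEnsemble")
        return obj


def _check_predictors(X: pd.DataFrame, names: list[str]) -> np.ndarray:
    missing_cols = [c for c in names if X[c].isna().any()]
    if missing_cols:
        raise ValueError(f"missing values in predictor columns: {missing_cols}")
    bad_type = [c for c in names if not np.issubdtype(X[c].dtype, np.number)]
    if bad_type:
        raise TypeError(f"non-numeric predictor columns: {bad_type}")
    return X[names].to_numpy(dtype=float)


def fit(
    table: pd.DataFrame,
    target: str,
    predictors: list[str] | None = None,
    config: StetConfig | None = None,
) -> TrainedEnsemble:
    """Fit an extra-trees ensemble on a feature table.

    Parameters
    ----------
    table : DataFrame
        At least 10 rows; must contain ``target`` and every predictor.
    target : str
        Name of the target column.
    predictors : list of str, optional
        Predictor columns in manifest order; default: every numeric column
        except the target.
    config : StetConfig, optional

    Returns
    -------
    TrainedEnsemble
    """
    config = config or StetConfig()
    if target not in table.columns:
        raise ValueError(f"target column {target!r} not in table")
    if predictors is None:
        predictors = [
            c
            for c in table.columns
            if c != target and np.issubdtype(table[c].dtype, np.number)
        ]
    if not predictors:
        raise ValueError("no predictor columns")
    if len(table) < 10:
        raise ValueError(f"need >= 10 rows to fit, got {len(table)}")
    y = table[target].to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError(f"missing values in target column {target!r}")
    X = _check_predictors(table, list(predictors))
    forest = ExtraTreesRegressor(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_leaf,
        max_features=config.max_features,
        random_state=config.seed,
        bootstrap=False,
        n_jobs=config.n_jobs,
    )
    forest.fit(X, y)
    return TrainedEnsemble(
        forest=forest,
        feature_names=list(predictors),
        config=config,
        n_rows=len(table),
        target_mean=float(np.mean(y)),
        target_min=float(np.min(y)),
        target_max=float(np.max(y)),
    )


def predict(model: TrainedEnsemble, table: pd.DataFrame) -> np.ndarray:
    """Predict with manifest enforcement.

    Raises
    ------
    ValueError
        On a column-manifest mismatch, naming missing and extra columns
        (extra non-predictor columns in ``table`` are permitted; only the
        manifest columns are consumed).
    """
    missing = [c for c in model.feature_names if c not in table.columns]
    if missing:
        raise ValueError(
            f"feature manifest mismatch: missing columns {missing}; "
            f"manifest is {model.feature_names}"
        )
    X = _check_predictors(table, model.feature_names)
    pred = model.forest.predict(X)
    if not np.all(np.isfinite(pred)):
        raise RuntimeError("non-finite prediction from fitted forest")
    return pred
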