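"""Stage 1: merge the two satellite AOD views and fill cloud gaps.

Satellites see the ground only where clouds (and snow, and swath geometry)
allow; on a typical day roughly a third of cells have no AOD retrieval.
This stage (a) merges the morning and afternoon overpasses -- the second
view is mapped onto the first's scale by an ordinary-least-squares
conversion line fitted over coincident cell-days -- and (b) trains the
space-time extra-trees model on the merged *observed* AOD against spatially
complete predictors (CTM AOD, meteorology, terrain/vegetation, space-time
terms), then predicts every unobserved cell-day.  Observed values pass
through bit-unchanged; the output carries an origin flag per cell-day so
downstream accuracy can be split by observed vs predicted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stet_model
from .features import GAPFILL_PREDICTORS, ST_COLUMNS, bundle_gapfill_table
from .stet_model import StetConfig, TrainedEnsemble

ORIGIN_OBSERVED = 0
ORIGIN_PREDICTED = 1


class InsufficientOverlapError(ValueError):
    """Fewer coincident cell-days than the conversion fit requires."""


@dataclass
class GaplessField:
    """A daily gridded field with a value in every cell.

    ``origin`` is 0 where the value is an untouched observation and 1 where
    it was predicted by the gap-fill model.
    """

    values: np.ndarray
    origin: np.ndarray
    units: str = ""

    def __post_init__(self):
        if self.values.shape != self.origin.shape:
            raise ValueError("values/origin shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("GaplessField must not contain missing values")

    @property
    def coverage_percent(self) -> float:
        return 100.0 * np.isfinite(self.values).mean()

    @property
    def observed_fraction(self) -> float:
        return float((self.origin == ORIGIN_OBSERVED).mean())


def coverage_percent(masked: np.ndarray) -> float:
    """Percent of cell-days carrying a finite value."""
    return 100.0 * np.isfinite(masked).mean()


def merge_terra_aqua(
    terra: np.ndarray, aqua: np.ndarray, min_overlap: int = 30
) -> tuple[np.ndarray, dict]:
    """Combine two masked AOD fields via a linear conversion model.

    The second view (``aqua``) is regressed against the first over all
    coincident cell-days (OLS of terra on aqua) and mapped onto the terra
    scale.  The merged value is terra where only terra reports, the
    converted aqua value where only aqua reports, and the unweighted mean of
    the two where both do.

    Returns
    -------
    (merged, coeffs)
        ``coeffs`` has keys ``slope``, ``intercept``, ``n_coincident``,
        ``direction`` (always "aqua_to_terra").
    """
    terra = np.asarray(terra, dtype=float)
    aqua = np.asarray(aqua, dtype=float)
    if terra.shape != aqua.shape:
        raise ValueError("terra/aqua shape mismatch")
    both = np.isfinite(terra) & np.isfinite(aqua)
    n = int(both.sum())
    if n < min_overlap:
        raise InsufficientOverlapError(
            f"only {n} coincident cell-days; need >= {min_overlap}"
        )
    x = aqua[both]
    y = terra[both]
    # closed-form simple OLS (tests cross-check against scipy.stats.linregress)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0.0:
        raise InsufficientOverlapError("aqua values constant over overlap")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)

    aqua_conv = slope * aqua + intercept
    merged = np.where(
        np.isfinite(terra) & np.isfinite(aqua_conv),
        0.5 * (terra + aqua_conv),
        np.where(np.isfinite(terra), terra, aqua_conv),
    )
    coeffs = {
        "slope": slope,
        "intercept": intercept,
        "n_coincident": n,
        "direction": "aqua_to_terra",
    }
    return merged, coeffs


def train_gapfill(
    merged_obs: np.ndarray,
    feature_table: pd.DataFrame,
    config: StetConfig | None = None,
    predictors: list[str] | None = None,
    max_train_rows: int = 150_000,
) -> TrainedEnsemble:
    """Train the gap-fill model on observed AOD cell-days.

    Parameters
    ----------
    merged_obs : (n_days, n_lat, n_lon) masked array
        Merged satellite AOD; NaN where unobserved.  This field is the
        *target* only and never appears among the predictors.
    feature_table : DataFrame
        One row per cell-day in C-order over (day, lat, lon); every
        predictor column complete.
    config : StetConfig
        Default: 40 trees, leaf size 5 -- a deliberately light forest so the
        default 40x80x365 grid trains inside the stated runtime budget.
    max_train_rows : int
        Observed cell-days are subsampled (deterministically from
        ``config.seed``) to at most this many training rows.
    """
    config = config or StetConfig(n_trees=40, min_leaf=5)
    predictors = predictors or (GAPFILL_PREDICTORS + ST_COLUMNS)
    target = merged_obs.reshape(-1)
    if len(target) != len(feature_table):
        raise ValueError("feature table does not match field shape")
    obs = np.isfinite(target)
    if obs.sum() < 10:
        raise ValueError("fewer than 10 observed cell-days to train on")
    idx = np.where(obs)[0]
    if len(idx) > max_train_rows:
        rng = np.random.default_rng(config.seed)
        idx = np.sort(rng.choice(idx, size=max_train_rows, replace=False))
    train = feature_table.iloc[idx].copy()
    train["aod_obs"] = target[idx]
    return stet_model.fit(train, target="aod_obs", predictors=predictors,
                          config=config)


def fill_gaps(
    model: TrainedEnsemble,
    merged: np.ndarray,
    feature_table: pd.DataFrame,
    units: str = "",
) -> GaplessField:
    """Predict every unobserved cell-day; pass observations through bit-exact.

    Raises an internal-consistency error if any output value is missing --
    by construction this cannot happen when the predictors are complete.
    """
    shape = merged.shape
    flat = merged.reshape(-1)
    if len(flat) != len(feature_table):
        raise ValueError("feature table does not match field shape")
    obs = np.isfinite(flat)
    out = np.empty_like(flat)
    out[obs] = flat[obs]
    if (~obs).any():
        out[~obs] = stet_model.predict(model, feature_table.iloc[~obs])
    if np.isnan(out).any():  # pragma: no cover - contract violation
        raise RuntimeError("internal consistency error: missing values remain")
    origin = np.where(obs, ORIGIN_OBSERVED, ORIGIN_PREDICTED).astype(np.int8)
    return GaplessField(values=out.reshape(shape),
                        origin=origin.reshape(shape), units=units)


def validate_points(
    gapless: GaplessField,
    points: pd.DataFrame,
    grid,
    dates: pd.DatetimeIndex,
) -> dict:
    """Compare a gapless field against point truth (ground photometers).

    ``points`` columns: lat, lon, date, aod.  Each point is matched to its
    containing cell and day; correlation R and RMSE are reported overall and
    separately for origin=observed vs origin=predicted cell-days.  A subset
    with undefined correlation (constant field or truth) reports NaN with a
    warning rather than raising.
    """
    required = {"lat", "lon", "date", "aod"}
    if not required.issubset(points.columns):
        raise ValueError(f"points table needs columns {sorted(required)}")
    date_index = pd.DatetimeIndex(dates)
    rows = []
    for _, p in points.iterrows():
        if not grid.contains(p["lat"], p["lon"]):
            continue
        i, j = grid.cell_of(p["lat"], p["lon"])
        d = date_index.get_indexer([pd.Timestamp(p["date"]).normalize()])[0]
        if d < 0:
            continue
        rows.append(
            (float(p["aod"]), float(gapless.values[d, i, j]),
             int(gapless.origin[d, i, j]))
        )
    if len(rows) < 3:
        raise ValueError("fewer than 3 matched points")
    arr = np.array(rows)

    def _stats(sub: np.ndarray) -> dict:
        if len(sub) == 0:
            return {"r": np.nan, "rmse": np.nan, "n": 0}
        truth, pred = sub[:, 0], sub[:, 1]
        rmse = float(np.sqrt(np.mean((pred - truth) ** 2)))
        if len(sub) < 2 or np.std(truth) == 0 or np.std(pred) == 0:
            warnings.warn("correlation undefined (degenerate variance); "
                          "reporting NaN", RuntimeWarning, stacklevel=3)
            r = np.nan
        else:
            r = float(np.corrcoef(truth, pred)[0, 1])
        return {"r": r, "rmse": rmse, "n": int(len(sub))}

    return {
        "overall": _stats(arr),
        "observed": _stats(arr[arr[:, 2] == ORIGIN_OBSERVED]),
        "predicted": _stats(arr[arr[:, 2] == ORIGIN_PREDICTED]),
    }


def write_field(field: GaplessField, path, grid, dates) -> None:
    """Write a gapless field (value + origin companion layer) to NetCDF."""
    import xarray as xr

    ds = xr.Dataset(
        {
            "value": (("date", "lat", "lon"), field.values),
            "origin": (("date", "lat", "lon"), field.origin.astype(np.int8)),
        },
        coords={"date": dates, "lat": grid.lats, "lon": grid.lons},
        attrs={"units": field.units},
    )
    ds.to_netcdf(path, engine="scipy")


def read_field(path) -> tuple[GaplessField, "pd.DatetimeIndex"]:
    """Read a gapless field written by :func:`write_field`."""
    import xarray as xr

    ds = xr.open_dataset(path, engine="scipy").load()
    field = GaplessField(
        values=ds["value"].values,
        origin=ds["origin"].values.astype(np.int8),
        units=ds.attrs.get("units", ""),
    )
    return field, pd.DatetimeIndex(ds["date"].values)


def run_gapfill(
    bundle,
    config: StetConfig | None = None,
    max_train_rows: int = 150_000,
) -> tuple[GaplessField, dict]:
    """Convenience driver: merge the bundle's satellite views, train, fill.

    Returns the gapless AOD field and a report dict with the conversion
    coefficients and before/after coverage percentages.
    """
    merged, coeffs = merge_terra_aqua(bundle.terra_aod, bundle.aqua_aod)
    table = bundle_gapfill_table(bundle)
    cov_before = coverage_percent(merged)
    model = train_gapfill(merged, table, config=config,
                          max_train_rows=max_train_rows)
    gapless = fill_gaps(model, merged, table, units="AOD")
    report = {
        "conversion": coeffs,
        "coverage_before_percent": cov_before,
        "coverage_after_percent": gapless.coverage_percent,
    }
    return gapless, report
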