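"""Stage 2: learn the AOD-PM2.5 relationship at stations, predict everywhere.

Ground monitors give accurate but point-wise PM2.5; the gap-filled AOD field
and auxiliary covariates exist on every cell-day.  Training pairs are formed
by colocating each station's QC'd daily mean with the predictor values of
the grid cell containing it (half-open cell bounds, left/bottom inclusive).
One space-time extra-trees model spans the whole grid and period -- the
space-time terms carry regional and seasonal heterogeneity -- and its
predictions form a gapless daily PM2.5 field (origin=predicted everywhere;
station cells are deliberately not overwritten with observations, so the
field is a single consistent model product).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stet_model
from .aod_gapfill import ORIGIN_PREDICTED, GaplessField
from .features import RETRIEVAL_PREDICTORS, ST_COLUMNS, bundle_retrieval_table
from .stet_model import StetConfig, TrainedEnsemble

logger = logging.getLogger(__name__)


def build_training_table(
    daily: pd.DataFrame,
    stations: pd.DataFrame,
    feature_table: pd.DataFrame,
    grid,
    dates: pd.DatetimeIndex,
    predictors: list[str] | None = None,
) -> pd.DataFrame:
    """One row per (station, day): daily PM2.5 target plus colocated predictors.

    Parameters
    ----------
    daily : DataFrame
        station_id, date, pm25_daily (QC'd daily means).
    stations : DataFrame
        station_id, lat, lon (and optionally country); stations outside the
        grid are reported, their rows dropped.
    feature_table : DataFrame
        Cell-day predictor table in C-order over (day, lat, lon).
    grid, dates
        Working grid and calendar used to index ``feature_table``.

    Returns
    -------
    DataFrame with predictor columns, ``pm25_daily`` target, and
    station_id / cell_i / cell_j / date / lat / lon keys.
    """
    predictors = predictors or (RETRIEVAL_PREDICTORS + ST_COLUMNS)
    meta_cols = [c for c in ("country",) if c in stations.columns]
    st = stations[["station_id", "lat", "lon", *meta_cols]].copy()
    outside = [
        row.station_id
        for row in st.itertuples()
        if not grid.contains(row.lat, row.lon)
    ]
    if outside:
        logger.warning("dropping %d stations outside the grid: %s",
                       len(outside), outside[:10])
        st = st[~st["station_id"].isin(outside)]
    if st.empty:
        raise ValueError("no stations fall inside the grid")
    cells = np.array([grid.cell_of(la, lo)
                      for la, lo in zip(st["lat"], st["lon"])])
    st["cell_i"], st["cell_j"] = cells[:, 0], cells[:, 1]

    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    merged = daily.merge(st, on="station_id", how="inner")
    if merged.empty:
        raise ValueError("no QC'd daily rows for in-grid stations")

    n_lat, n_lon = grid.shape
    date_index = pd.DatetimeIndex(dates)
    day_idx = date_index.get_indexer(merged["date"])
    in_cal = day_idx >= 0
    if not in_cal.all():
        logger.warning("dropping %d rows outside the calendar",
                       int((~in_cal).sum()))
        merged = merged[in_cal]
        day_idx = day_idx[in_cal]
    flat_idx = (day_idx * n_lat * n_lon
                + merged["cell_i"].to_numpy() * n_lon
                + merged["cell_j"].to_numpy())
    feat = feature_table.iloc[flat_idx][predictors].reset_index(drop=True)
    out = pd.concat(
        [merged[["station_id", "date", "lat", "lon", "cell_i", "cell_j",
                 *meta_cols, "pm25_daily"]].reset_index(drop=True), feat],
        axis=1,
    )
    complete = out[predictors].notna().all(axis=1)
    if not complete.all():
        logger.warning("dropping %d rows with missing predictors",
                       int((~complete).sum()))
        out = out[complete].reset_index(drop=True)
    if out.empty:
        raise ValueError("training table empty after predictor completeness")
    return out


def fit_retrieval(
    table: pd.DataFrame,
    config: StetConfig | None = None,
    predictors: list[str] | None = None,
) -> TrainedEnsemble:
    """Fit the stage-2 model on a training table (target ``pm25_daily``)."""
    predictors = predictors or (RETRIEVAL_PREDICTORS + ST_COLUMNS)
    return stet_model.fit(table, target="pm25_daily", predictors=predictors,
                          config=config or StetConfig())


def retrieve_pm25(
    table: pd.DataFrame,
    feature_table: pd.DataFrame,
    shape: tuple[int, int, int],
    config: StetConfig | None = None,
    predictors: list[str] | None = None,
    model: TrainedEnsemble | None = None,
) -> tuple[GaplessField, TrainedEnsemble]:
    """Train on station-days and predict PM2.5 on every cell-day.

    Returns a :class:`GaplessField` (units ug/m3, origin=predicted
    everywhere) and the fitted model.  Predictions inherit the ensemble's
    range-boundedness: with non-negative targets they are non-negative, and
    never exceed the training maximum.
    """
    predictors = predictors or (RETRIEVAL_PREDICTORS + ST_COLUMNS)
    if model is None:
        model = fit_retrieval(table, config=config, predictors=predictors)
    pred = stet_model.predict(model, feature_table)
    if len(pred) != int(np.prod(shape)):
        raise ValueError("feature table does not match requested shape")
    values = pred.reshape(shape)
    origin = np.full(shape, ORIGIN_PREDICTED, dtype=np.int8)
    return GaplessField(values=values, origin=origin, units="ug/m3"), model


def compose(field: np.ndarray, dates: pd.DatetimeIndex,
            period: str = "month") -> tuple[np.ndarray, list]:
    """Unweighted per-cell means of daily values over months or years.

    Returns ``(composites, labels)`` where composites has one leading slot
    per period.
    """
    if period not in ("month", "year"):
        raise ValueError("period must be 'month' or 'year'")
    keys = dates.to_period("M" if period == "month" else "Y")
    labels = list(keys.unique())
    out = np.stack([field[keys == k].mean(axis=0) for k in labels])
    return out, labels


def run_retrieval(
    bundle,
    gapless_aod,
    config: StetConfig | None = None,
    min_completeness: float = 0.2,
):
    """Convenience driver: QC the bundle's stations, build the table, retrieve.

    Returns ``(pm_field, model, training_table)``.
    """
    from . import station_qc

    hourly = station_qc.qc_hourly(bundle.station_hourly)
    daily = station_qc.daily_mean(hourly, min_completeness=min_completeness)
    feature_table = bundle_retrieval_table(bundle, gapless_aod.values)
    table = build_training_table(
        daily, bundle.stations, feature_table, bundle.grid, bundle.dates
    )
    shape = (len(bundle.dates),) + bundle.grid.shape
    pm_field, model = retrieve_pm25(table, feature_table, shape, config=config)
    return pm_field, model, table
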