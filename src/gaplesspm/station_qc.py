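"""Station quality control, daily aggregation, and grid harmonization.

Hourly PM2.5 records from heterogeneous monitoring networks carry three
recurrent defect classes: physically impossible negatives, stuck-instrument
repeats, and gross spikes.  QC here removes (a) negative values, (b) runs of
identical values lasting more than three continuous hours, and (c) values
above the station's 99.9th percentile; removed entries become missing but the
timeline is never shortened.  Days with at least 20% of valid hourly values
(>= 5 of 24) are averaged to daily means.  Gridded covariates at mixed native
resolutions are harmonized to the working grid by block-averaging finer
sources and bilinearly interpolating coarser ones at target cell centers.

Conventions fixed here (the source rules leave them open):

* the extreme-value quantile is computed per station over its full record
  after negative removal, with the 'higher' order-statistic sample quantile
  (an attained value, so only values strictly above it are cut and a short
  clean record never loses its own maximum);
* "more than three continuous hours" means run length >= 4 at exactly hourly
  spacing -- any time gap (or removed value) breaks a run;
* the daily completeness denominator is always 24 hours.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

HOURLY_COLUMNS = ["station_id", "datetime_utc", "pm25"]
DAILY_COLUMNS = ["station_id", "date", "pm25_daily", "n_valid"]


def _require_hourly(df: pd.DataFrame) -> pd.DataFrame:
    if df.empty:
        raise ValueError("empty hourly series")
    missing = [c for c in HOURLY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hourly table lacks columns {missing}")
    out = df.copy()
    out["datetime_utc"] = pd.to_datetime(out["datetime_utc"])
    return out


def _flag_repeats(ts: np.ndarray, vals: np.ndarray, max_run: int) -> np.ndarray:
    """Boolean mask of values inside identical-value runs longer than max_run.

    ts is int64 nanoseconds; contiguity requires exactly one hour between
    consecutive samples.  NaNs never extend a run.
    """
    n = len(vals)
    flag = np.zeros(n, dtype=bool)
    if n == 0:
        return flag
    hour_ns = 3_600_000_000_000
    start = 0
    for i in range(1, n + 1):
        contiguous = (
            i < n
            and ts[i] - ts[i - 1] == hour_ns
            and not np.isnan(vals[i])
            and not np.isnan(vals[i - 1])
            and vals[i] == vals[i - 1]
        )
        if not contiguous:
            if i - start > max_run and not np.isnan(vals[start]):
                flag[start:i] = True
            start = i
    return flag


def qc_hourly(
    df: pd.DataFrame, quantile_cut: float = 0.999, max_run: int = 3
) -> pd.DataFrame:
    """Apply outlier removal to an hourly station table.

    Removal order per station: negatives first; then identical-value runs
    exceeding ``max_run`` continuous hours; then values strictly above the
    station's ``quantile_cut`` quantile of its negative-free record.  Removed
    values become NaN; the row count is preserved.

    Parameters
    ----------
    df : DataFrame with columns station_id, datetime_utc, pm25
    quantile_cut : float
        Per-station extreme cut (default 0.999, i.e. the 99.9th percentile).
    max_run : int
        Longest tolerated run of identical consecutive hourly values.
    """
    df = _require_hourly(df)
    if not (0.0 < quantile_cut <= 1.0):
        raise ValueError("quantile_cut must be in (0, 1]")
    pieces = []
    for sid, g in df.groupby("station_id", sort=False):
        g = g.sort_values("datetime_utc").copy()
        v = g["pm25"].to_numpy(dtype=float)
        v[v < 0] = np.nan
        ts = g["datetime_utc"].to_numpy().astype("datetime64[ns]").astype(np.int64)
        v[_flag_repeats(ts, v, max_run)] = np.nan
        finite = v[~np.isnan(v)]
        if finite.size:
            # order-statistic ('higher') quantile: the cut is an attained
            # value, so a short clean record never loses its own maximum
            cut = np.quantile(finite, quantile_cut, method="higher")
            v[v > cut] = np.nan
        g["pm25"] = v
        pieces.append(g)
    return pd.concat(pieces, ignore_index=True)


def daily_mean(df: pd.DataFrame, min_completeness: float = 0.2) -> pd.DataFrame:
    """Aggregate a QC'd hourly table to daily station means.

    A UTC calendar day is emitted only when valid hours / 24 >=
    ``min_completeness`` (default 0.2, i.e. at least 5 valid hours).

    Returns
    -------
    DataFrame with columns station_id, date, pm25_daily, n_valid; one row per
    (station, day) that passed the completeness rule.
    """
    df = _require_hourly(df)
    work = df[["station_id", "datetime_utc", "pm25"]].copy()
    work["date"] = work["datetime_utc"].dt.normalize()
    grouped = work.groupby(["station_id", "date"], sort=True)["pm25"]
    agg = grouped.agg(pm25_daily="mean", n_valid="count").reset_index()
    keep = agg["n_valid"] / 24.0 >= min_completeness
    out = agg.loc[keep].reset_index(drop=True)
    out["n_valid"] = out["n_valid"].astype(int)
    return out[DAILY_COLUMNS]


def to_utc(df: pd.DataFrame, offset_hours) -> pd.DataFrame:
    """Shift local timestamps to UTC; values are untouched.

    ``offset_hours`` is the station's UTC offset (local = UTC + offset), an
    integer or a mapping ``station_id -> integer offset``.  UTC timestamps
    are local minus offset, so a 23:00 local value at offset -2 lands at
    01:00 on the next UTC day.
    """
    df = _require_hourly(df)
    if isinstance(offset_hours, dict):
        off = df["station_id"].map(offset_hours)
        if off.isna().any():
            unknown = sorted(df.loc[off.isna(), "station_id"].unique())
            raise ValueError(f"no UTC offset for stations {unknown}")
        delta = pd.to_timedelta(off.astype(int), unit="h")
    else:
        delta = pd.Timedelta(hours=int(offset_hours))
    out = df.copy()
    out["datetime_utc"] = out["datetime_utc"] - delta
    return out


class GridSpec:
    """Regular lat/lon grid with cell-center coordinates.

    Cells are ``cell_deg`` wide; ``lats``/``lons`` are the cell centers in
    increasing order.  Bounds are half-open: a point on a shared edge belongs
    to the cell on its left/bottom-inclusive side.
    """

    def __init__(self, lats: np.ndarray, lons: np.ndarray):
        self.lats = np.asarray(lats, dtype=float)
        self.lons = np.asarray(lons, dtype=float)
        if len(self.lats) < 1 or len(self.lons) < 1:
            raise ValueError("grid needs at least one cell")
        dl = np.diff(self.lats)
        dn = np.diff(self.lons)
        if (len(dl) and not np.allclose(dl, dl[0])) or (
            len(dn) and not np.allclose(dn, dn[0])
        ):
            raise ValueError("grid must be regular")
        self.cell_deg = float(dl[0]) if len(dl) else float(dn[0]) if len(dn) else 1.0

    @classmethod
    def regular(cls, n_lat: int, n_lon: int, cell_deg: float,
                lat0: float | None = None, lon0: float | None = None) -> "GridSpec":
        """Grid of n_lat x n_lon cells centred on (0, 0) unless origins given.

        ``lat0``/``lon0`` are the lower edges of the first cell.
        """
        if lat0 is None:
            lat0 = -n_lat * cell_deg / 2.0
        if lon0 is None:
            lon0 = -n_lon * cell_deg / 2.0
        lats = lat0 + cell_deg * (np.arange(n_lat) + 0.5)
        lons = lon0 + cell_deg * (np.arange(n_lon) + 0.5)
        return cls(lats, lons)

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.lats), len(self.lons)

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Containing cell index (i, j); half-open, left/bottom inclusive."""
        half = self.cell_deg / 2.0
        i = int(np.floor((lat - (self.lats[0] - half)) / self.cell_deg))
        j = int(np.floor((lon - (self.lons[0] - half)) / self.cell_deg))
        ni, nj = self.shape
        if not (0 <= i < ni and 0 <= j < nj):
            raise ValueError(f"point ({lat}, {lon}) outside grid")
        return i, j

    def contains(self, lat: float, lon: float) -> bool:
        try:
            self.cell_of(lat, lon)
            return True
        except ValueError:
            return False


def harmonize_grid(
    field: np.ndarray,
    src: GridSpec,
    dst: GridSpec,
) -> np.ndarray:
    """Bring a gridded field at its native resolution onto the target grid.

    Finer-than-target sources are block-averaged over target cells; coarser
    (or equal-resolution, offset) sources are bilinearly interpolated at
    target cell centers, clamping to the source hull so a complete source
    yields a complete output.

    Parameters
    ----------
    field : 2-D array matching ``src.shape``
    src, dst : GridSpec

    Raises
    ------
    ValueError
        If the grids do not overlap.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != src.shape:
        raise ValueError(f"field shape {field.shape} != source grid {src.shape}")
    half_s = src.cell_deg / 2.0
    half_d = dst.cell_deg / 2.0
    overlap_lat = (src.lats[0] - half_s <= dst.lats[-1] + half_d) and (
        dst.lats[0] - half_d <= src.lats[-1] + half_s
    )
    overlap_lon = (src.lons[0] - half_s <= dst.lons[-1] + half_d) and (
        dst.lons[0] - half_d <= src.lons[-1] + half_s
    )
    if not (overlap_lat and overlap_lon):
        raise ValueError("source and target grids do not overlap")

    if src.cell_deg < dst.cell_deg:  # finer source: block average
        out = np.full(dst.shape, np.nan)
        lat_edges = np.concatenate(
            [dst.lats - half_d, [dst.lats[-1] + half_d]]
        )
        lon_edges = np.concatenate(
            [dst.lons - half_d, [dst.lons[-1] + half_d]]
        )
        li = np.digitize(src.lats, lat_edges) - 1
        lj = np.digitize(src.lons, lon_edges) - 1
        for ii in range(dst.shape[0]):
            rows = np.where(li == ii)[0]
            if not rows.size:
                continue
            for jj in range(dst.shape[1]):
                cols = np.where(lj == jj)[0]
                if not cols.size:
                    continue
                block = field[np.ix_(rows, cols)]
                out[ii, jj] = np.nanmean(block)
        return out

    # coarser (or equal) source: bilinear at target cell centers, clamped
    interp = RegularGridInterpolator(
        (src.lats, src.lons), field, method="linear",
        bounds_error=False, fill_value=None,
    )
    qlat = np.clip(dst.lats, src.lats[0], src.lats[-1])
    qlon = np.clip(dst.lons, src.lons[0], src.lons[-1])
    pts_lat, pts_lon = np.meshgrid(qlat, qlon, indexing="ij")
    pts = np.column_stack([pts_lat.ravel(), pts_lon.ravel()])
    return interp(pts).reshape(dst.shape)
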