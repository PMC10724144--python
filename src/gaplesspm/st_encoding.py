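"""Four-dimensional space-time feature encoding.

Tree ensembles split on raw latitude/longitude poorly: longitude wraps at the
antimeridian and degrees of longitude shrink toward the poles.  Mapping each
site onto the unit sphere (x, y, z) makes Euclidean feature-space distance a
monotone proxy for great-circle distance, and encoding day-of-year as a point
on the unit circle plus a linear term -- a helix -- makes late December
adjacent to early January while keeping distinct dates distinguishable across
years.  These six derived columns are what upgrade a plain extra-trees
regressor into the space-time variant used throughout this package.

Reserved column names: ``st_x, st_y, st_z, st_tsin, st_tcos, st_tlin``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Column names appended by :func:`attach_terms`, in order.
TERM_COLUMNS = ["st_x", "st_y", "st_z", "st_tsin", "st_tcos", "st_tlin"]


def encode_space(lat, lon):
    """Map geographic coordinates onto the unit sphere.

    Parameters
    ----------
    lat, lon : float or array-like
        Degrees; latitude in [-90, 90], longitude in [-180, 180].

    Returns
    -------
    (x, y, z) : tuple of ndarray (or scalars)
        ``x = cos(lat) cos(lon)``, ``y = cos(lat) sin(lon)``, ``z = sin(lat)``
        with angles in radians.  Satisfies ``x**2 + y**2 + z**2 == 1`` to
        floating-point precision.

    Raises
    ------
    ValueError
        If any coordinate is outside its valid range or not finite.
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not np.all(np.isfinite(lat)) or not np.all(np.isfinite(lon)):
        raise ValueError("lat/lon must be finite")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90] degrees")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude outside [-180, 180] degrees")
    lat_r = np.deg2rad(lat)
    lon_r = np.deg2rad(lon)
    x = np.cos(lat_r) * np.cos(lon_r)
    y = np.cos(lat_r) * np.sin(lon_r)
    z = np.sin(lat_r)
    return x, y, z


def encode_time(dates, period_days: int = 365, epoch=None):
    """Encode dates as a periodic (sin, cos) pair plus a linear day index.

    The angle is ``theta = 2*pi*(day_of_year - 1)/period_days`` so January 1
    is the phase origin (sin 0, cos 1).  ``t_lin`` counts whole days since
    ``epoch`` (default: the earliest date passed in), making the full
    (t_sin, t_cos, t_lin) triple injective over multi-year spans.

    Parameters
    ----------
    dates : datetime-like or array of datetimes
    period_days : int
        365 or 366; the seasonal period.
    epoch : datetime-like, optional
        Origin for the linear term; no date may precede it.

    Returns
    -------
    (t_sin, t_cos, t_lin) : tuple of ndarray (or scalars)
    """
    if period_days not in (365, 366):
        raise ValueError(f"period_days must be 365 or 366, got {period_days}")
    scalar = np.isscalar(dates) or isinstance(dates, (pd.Timestamp,)) or (
        hasattr(dates, "year") and not hasattr(dates, "__len__")
    )
    idx = pd.DatetimeIndex(pd.to_datetime([dates] if scalar else dates))
    if epoch is None:
        epoch = idx.min()
    epoch = pd.Timestamp(epoch)
    t_lin = (idx.normalize() - epoch.normalize()).days.to_numpy(dtype=float)
    if np.any(t_lin < 0):
        raise ValueError("date precedes epoch")
    doy = idx.dayofyear.to_numpy(dtype=float)
    theta = 2.0 * np.pi * (doy - 1.0) / float(period_days)
    t_sin = np.sin(theta)
    t_cos = np.cos(theta)
    if scalar:
        return float(t_sin[0]), float(t_cos[0]), float(t_lin[0])
    return t_sin, t_cos, t_lin


def attach_terms(
    df: pd.DataFrame,
    lat_col: str = "lat",
    lon_col: str = "lon",
    date_col: str = "date",
    period_days: int = 365,
    epoch=None,
) -> pd.DataFrame:
    """Append the six space-time columns to a feature table.

    Existing columns are never altered.  Rows with missing coordinates or
    dates raise a ``ValueError`` naming the offending row positions.
    """
    for col in (lat_col, lon_col, date_col):
        if col not in df.columns:
            raise ValueError(f"feature table lacks required column {col!r}")
    bad = df.index[
        df[lat_col].isna() | df[lon_col].isna() | pd.isna(df[date_col])
    ].tolist()
    if bad:
        raise ValueError(f"rows with missing coordinates/dates: {bad[:20]}")
    out = df.copy()
    x, y, z = encode_space(out[lat_col].to_numpy(), out[lon_col].to_numpy())
    t_sin, t_cos, t_lin = encode_time(
        out[date_col], period_days=period_days, epoch=epoch
    )
    out["st_x"] = np.atleast_1d(x)
    out["st_y"] = np.atleast_1d(y)
    out["st_z"] = np.atleast_1d(z)
    out["st_tsin"] = np.atleast_1d(t_sin)
    out["st_tcos"] = np.atleast_1d(t_cos)
    out["st_tlin"] = np.atleast_1d(t_lin)
    return out
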