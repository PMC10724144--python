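"""Cell-day feature tables shared by the two pipeline stages.

Both the AOD gap-fill model and the PM2.5 retrieval model consume one row
per (grid cell, day) with dynamic fields, static covariates, and the six
space-time terms.  This module flattens gridded arrays into that table once,
so stage code stays free of indexing arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .st_encoding import attach_terms
from .station_qc import GridSpec

#: Predictors of the AOD gap-fill stage (spatially complete by construction).
GAPFILL_PREDICTORS = [
    "ctm_aod", "pblh", "rh", "temp", "wind", "pressure",
    "ndvi", "elevation",
]

#: Predictors of the PM2.5 retrieval stage (gap-filled AOD leads).
RETRIEVAL_PREDICTORS = [
    "aod_filled", "ctm_pm25", "emissions",
    "pblh", "rh", "temp", "wind", "pressure", "precip", "evap",
    "ndvi", "nightlights", "elevation", "population",
]

ST_COLUMNS = ["st_x", "st_y", "st_z", "st_tsin", "st_tcos", "st_tlin"]


def cellday_table(
    grid: GridSpec,
    dates: pd.DatetimeIndex,
    fields_3d: dict[str, np.ndarray],
    fields_2d: dict[str, np.ndarray] | None = None,
    period_days: int | None = None,
) -> pd.DataFrame:
    """Flatten gridded fields into one row per (day, cell).

    Row order is C-order over (day, lat, lon), so a column can be reshaped
    back to ``(n_days, n_lat, n_lon)`` without bookkeeping.
    """
    n_lat, n_lon = grid.shape
    n_days = len(dates)
    if period_days is None:
        period_days = 366 if dates[0].is_leap_year else 365
    ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    df = pd.DataFrame(
        {
            "date": np.repeat(dates.to_numpy(), n_lat * n_lon),
            "cell_i": np.tile(ii.ravel(), n_days),
            "cell_j": np.tile(jj.ravel(), n_days),
            "lat": np.tile(grid.lats[ii.ravel()], n_days),
            "lon": np.tile(grid.lons[jj.ravel()], n_days),
        }
    )
    for name, arr in fields_3d.items():
        if arr.shape != (n_days, n_lat, n_lon):
            raise ValueError(f"field {name!r} has shape {arr.shape}, "
                             f"expected {(n_days, n_lat, n_lon)}")
        df[name] = arr.reshape(-1)
    for name, arr in (fields_2d or {}).items():
        if arr.shape != (n_lat, n_lon):
            raise ValueError(f"static field {name!r} has shape {arr.shape}, "
                             f"expected {(n_lat, n_lon)}")
        df[name] = np.tile(arr.reshape(-1), n_days)
    return attach_terms(df, period_days=period_days, epoch=dates[0])


def bundle_gapfill_table(bundle) -> pd.DataFrame:
    """Gap-fill predictor table (complete fields only) for a WorldBundle."""
    return cellday_table(
        bundle.grid, bundle.dates,
        fields_3d={
            "ctm_aod": bundle.ctm_aod,
            "pblh": bundle.met["pblh"],
            "rh": bundle.met["rh"],
            "temp": bundle.met["temp"],
            "wind": bundle.met["wind"],
            "pressure": bundle.met["pressure"],
        },
        fields_2d={
            "ndvi": bundle.static["ndvi"],
            "elevation": bundle.static["elevation"],
        },
        period_days=bundle.config.n_days,
    )


def bundle_retrieval_table(bundle, aod_filled: np.ndarray) -> pd.DataFrame:
    """Retrieval predictor table for a WorldBundle given gap-filled AOD."""
    return cellday_table(
        bundle.grid, bundle.dates,
        fields_3d={
            "aod_filled": aod_filled,
            "ctm_pm25": bundle.ctm_pm25,
            "pblh": bundle.met["pblh"],
            "rh": bundle.met["rh"],
            "temp": bundle.met["temp"],
            "wind": bundle.met["wind"],
            "pressure": bundle.met["pressure"],
            "precip": bundle.met["precip"],
            "evap": bundle.met["evap"],
        },
        fields_2d={
            "emissions": bundle.static["emissions"],
            "ndvi": bundle.static["ndvi"],
            "nightlights": bundle.static["nightlights"],
            "elevation": bundle.static["elevation"],
            "population": bundle.static["population"],
        },
        period_days=bundle.config.n_days,
    )
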