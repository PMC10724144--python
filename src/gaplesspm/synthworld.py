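"""Seeded synthetic world for the gapless-PM2.5 pipeline.

Real inputs to this kind of analysis -- satellite AOD swaths, chemical
transport model (CTM) fields, reanalysis meteorology, an uneven station
network -- are terabyte-scale downloads.  This module generates a small
world with the *statistical structure* the pipeline assumes, so every
downstream stage is testable on a desk:

* daily "true" AOD and PM2.5 fields with spatial correlation, a seasonal
  cycle whose phase flips between hemispheres, and smooth day-to-day
  variation;
* Terra/Aqua-like satellite views of the AOD truth, linearly related and
  masked by spatially coherent cloud fields;
* coarse, biased CTM counterparts (block-averaged truth plus smooth bias)
  regridded back to the working grid;
* static covariates (population, elevation, NDVI, nightlights, emissions);
* stations placed with probability proportional to population, reporting
  hourly PM2.5 with injected negative / stuck-repeat / extreme outliers
  (and a log of every injection, so QC recall is measurable);
* per-country stringency-index series and baseline mortality rates.

PM2.5 truth is a documented closed form of AOD, relative humidity,
boundary-layer height and emissions (coefficients recorded in
``WorldBundle.meta``), which is what makes parameter-recovery tests
possible.  The same seed always reproduces the same bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from .station_qc import GridSpec

#: Earth-ish kilometres per degree used for cell areas and densities.
KM_PER_DEG = 111.32


class ConfigError(ValueError):
    """Invalid world configuration; the message names the offending field."""


class BundleFormatError(ValueError):
    """A bundle on disk is malformed; the message names the component."""


@dataclass(frozen=True)
class WorldConfig:
    """Knobs of the synthetic world.

    Defaults describe the stated world: a 40 x 80 cell grid at 0.5 degrees
    (20 x 40 degrees, straddling the equator so both hemispheres exist), one
    365-day year, 150 stations, 12 countries, 36% AOD missingness, 5 ug/m3
    hourly observation noise, and small outlier-injection rates.
    """

    n_lat: int = 40
    n_lon: int = 80
    cell_deg: float = 0.5
    n_days: int = 365
    year_is_leap: bool = False
    n_stations: int = 150
    n_countries: int = 12
    missing_frac: float = 0.36
    noise_sd: float = 5.0
    outlier_rates: dict = field(
        default_factory=lambda: {"negative": 0.002, "repeat": 0.001, "extreme": 0.001}
    )
    seed: int = 0
    #: Multiplies the PM2.5 truth (and hence station data); used to compose
    #: lockdown-style year-to-year differences from single-year bundles.
    pm_scale: float = 1.0

    def validate(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ConfigError("n_lat/n_lon must be >= 1")
        if not (1 <= self.n_countries <= self.n_lat * self.n_lon):
            raise ConfigError(
                "n_countries must satisfy 1 <= n_countries <= n_lat*n_lon"
            )
        if not (0.0 < self.missing_frac < 1.0):
            raise ConfigError("missing_frac must be in (0, 1)")
        expected = 366 if self.year_is_leap else 365
        if self.n_days != expected:
            raise ConfigError(
                f"n_days={self.n_days} inconsistent with year_is_leap="
                f"{self.year_is_leap} (expected {expected})"
            )
        if self.n_stations < 1:
            raise ConfigError("n_stations must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        for k in ("negative", "repeat", "extreme"):
            if k not in self.outlier_rates:
                raise ConfigError(f"outlier_rates missing rate {k!r}")
            if not (0.0 <= self.outlier_rates[k] < 0.2):
                raise ConfigError(f"outlier_rates[{k!r}] must be in [0, 0.2)")
        if self.cell_deg <= 0:
            raise ConfigError("cell_deg must be > 0")

    @property
    def year(self) -> int:
        # Any leap/non-leap pair works; these keep real-calendar week/month CV.
        return 2020 if self.year_is_leap else 2021

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "WorldConfig":
        return WorldConfig(**d)


@dataclass
class WorldBundle:
    """Everything the pipeline consumes, in memory.

    All 3-D fields are ``(n_days, n_lat, n_lon)`` float64; ``cloud_mask`` is
    boolean with True meaning the merged satellite AOD is missing there.
    """

    config: WorldConfig
    grid: GridSpec
    dates: pd.DatetimeIndex
    true_aod: np.ndarray
    true_pm25: np.ndarray
    terra_aod: np.ndarray
    aqua_aod: np.ndarray
    ctm_aod: np.ndarray
    ctm_pm25: np.ndarray
    met: dict              # pblh, rh, temp, wind, pressure, precip, evap
    static: dict           # population, elevation, ndvi, nightlights, emissions
    cloud_mask: np.ndarray
    stations: pd.DataFrame          # station_id, lat, lon, country, cell_i, cell_j
    station_hourly: pd.DataFrame    # station_id, datetime_utc, pm25
    si: pd.DataFrame                # country, date, si
    bmr: pd.DataFrame               # country, bmr
    regions: pd.DataFrame           # cell_i, cell_j, lat, lon, country, state, continent
    outlier_log: pd.DataFrame       # station_id, datetime_utc, kind
    meta: dict

    def equals(self, other: "WorldBundle") -> bool:
        """Bit-level equality of every component (used by round-trip tests)."""
        arrays_self = [self.true_aod, self.true_pm25, self.terra_aod,
                       self.aqua_aod, self.ctm_aod, self.ctm_pm25,
                       self.cloud_mask]
        arrays_other = [other.true_aod, other.true_pm25, other.terra_aod,
                        other.aqua_aod, other.ctm_aod, other.ctm_pm25,
                        other.cloud_mask]
        for a, b in zip(arrays_self, arrays_other):
            if not np.array_equal(a, b, equal_nan=True):
                return False
        for k in self.met:
            if k not in other.met or not np.array_equal(self.met[k], other.met[k]):
                return False
        for k in self.static:
            if k not in other.static or not np.array_equal(
                self.static[k], other.static[k]
            ):
                return False
        frames = ["stations", "station_hourly", "si", "bmr", "regions",
                  "outlier_log"]
        for name in frames:
            a, b = getattr(self, name), getattr(other, name)
            try:
                pd.testing.assert_frame_equal(
                    a.reset_index(drop=True), b.reset_index(drop=True),
                    check_dtype=False, check_exact=True,
                )
            except AssertionError:
                return False
        return bool(self.dates.equals(other.dates))


def _smooth2(rng, shape, sigma):
    """Standardized smooth 2-D Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (f - f.mean()) / (f.std() + 1e-12)


def _smooth3(rng, shape, sigma):
    """Standardized smooth 3-D (time, lat, lon) Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="wrap")
    return (f - f.mean()) / (f.std() + 1e-12)


def _season(doy: np.ndarray, lats: np.ndarray, n_lon: int, period: int,
            phase_north: float, phase_south: float) -> np.ndarray:
    """Hemisphere-phased seasonal harmonic, shape (n_days, n_lat, n_lon)."""
    theta = 2.0 * np.pi * (doy - 1.0) / period
    phase = np.where(lats >= 0.0, phase_north, phase_south)
    s = np.cos(theta[:, None] - phase[None, :])
    return np.repeat(s[:, :, None], n_lon, axis=2)


def _tile_countries(grid: GridSpec, n_countries: int) -> pd.DataFrame:
    """Partition the grid into contiguous rectangular countries and states."""
    n_lat, n_lon = grid.shape
    n_rows = max(1, int(np.floor(np.sqrt(n_countries))))
    base, extra = divmod(n_countries, n_rows)
    per_row = [base + (1 if r < extra else 0) for r in range(n_rows)]
    lat_edges = np.linspace(0, n_lat, n_rows + 1).astype(int)
    country = np.empty(grid.shape, dtype=object)
    cid = 0
    for r in range(n_rows):
        ncols = per_row[r]
        lon_edges = np.linspace(0, n_lon, ncols + 1).astype(int)
        for c in range(ncols):
            country[lat_edges[r]:lat_edges[r + 1],
                    lon_edges[c]:lon_edges[c + 1]] = f"C{cid:02d}"
            cid += 1
    # states: split each country into up to 4 lat sub-bands
    state = np.empty(grid.shape, dtype=object)
    for name in np.unique(country.astype(str)):
        rows = np.where((country == name).any(axis=1))[0]
        bands = np.array_split(rows, min(4, len(rows)))
        for s_i, band in enumerate(bands):
            for i in band:
                mask = country[i] == name
                state[i, mask] = f"{name}_S{s_i}"
    # continents: contiguous groups of countries, ~3 groups
    n_cont = min(3, n_countries)
    cont_of = {
        f"C{c:02d}": f"K{int(c * n_cont / n_countries)}" for c in range(n_countries)
    }
    ii, jj = np.meshgrid(np.arange(n_lat), np.arange(n_lon), indexing="ij")
    return pd.DataFrame(
        {
            "cell_i": ii.ravel(),
            "cell_j": jj.ravel(),
            "lat": grid.lats[ii.ravel()],
            "lon": grid.lons[jj.ravel()],
            "country": country.ravel().astype(str),
            "state": state.ravel().astype(str),
            "continent": [cont_of[c] for c in country.ravel().astype(str)],
        }
    )


def cell_area_km2(grid: GridSpec) -> np.ndarray:
    """Approximate area of each cell in km^2, shape (n_lat, n_lon)."""
    dlat_km = KM_PER_DEG * grid.cell_deg
    dlon_km = KM_PER_DEG * grid.cell_deg * np.cos(np.deg2rad(grid.lats))
    return np.repeat((dlat_km * dlon_km)[:, None], len(grid.lons), axis=1)


def _coarsen_and_bias(field3: np.ndarray, grid: GridSpec, factor: int,
                      bias_mult: np.ndarray, bias_add: float) -> np.ndarray:
    """Block-average truth to a coarse grid, bias it, and bilinearly return.

    Emulates a CTM: spatially complete, right on average, wrong in detail.
    """
    from .station_qc import harmonize_grid

    n_days, n_lat, n_lon = field3.shape
    ni, nj = n_lat // factor, n_lon // factor
    trimmed = field3[:, : ni * factor, : nj * factor]
    coarse = trimmed.reshape(n_days, ni, factor, nj, factor).mean(axis=(2, 4))
    coarse_grid = GridSpec(
        grid.lats[: ni * factor].reshape(ni, factor).mean(axis=1),
        grid.lons[: nj * factor].reshape(nj, factor).mean(axis=1),
    )
    out = np.empty_like(field3)
    for d in range(n_days):
        out[d] = harmonize_grid(coarse[d], coarse_grid, grid)
    return out * (1.0 + bias_mult[None, :, :]) + bias_add


def generate_world(config: WorldConfig) -> WorldBundle:
    """Generate the full synthetic world; pure function of ``config``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    grid = GridSpec.regular(config.n_lat, config.n_lon, config.cell_deg)
    n_days, n_lat, n_lon = config.n_days, config.n_lat, config.n_lon
    dates = pd.date_range(f"{config.year}-01-01", periods=n_days, freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    phase_north, phase_south = 0.0, np.pi
    season = _season(doy, grid.lats, n_lon, n_days, phase_north, phase_south)

    # --- truth AOD: smooth base + seasonal + smooth space-time anomaly
    aod_base = 0.35 + 0.15 * _smooth2(rng, (n_lat, n_lon), sigma=3.0)
    aod_anom = _smooth3(rng, (n_days, n_lat, n_lon), sigma=(1.5, 2.0, 2.0))
    true_aod = np.clip(
        aod_base[None] + 0.12 * season + 0.15 * aod_anom, 0.02, None
    )

    # --- static covariates
    elev = np.clip(500.0 + 600.0 * _smooth2(rng, (n_lat, n_lon), 3.0), 0.0, None)
    pop_field = _smooth2(rng, (n_lat, n_lon), 2.5)
    population = 2000.0 * np.exp(2.2 * pop_field)          # persons per cell
    pop_norm = (population - population.min()) / np.ptp(population)
    ndvi = np.clip(
        0.45 + 0.25 * _smooth2(rng, (n_lat, n_lon), 3.0) - 0.2 * pop_norm,
        -0.1, 0.9,
    )
    nightlights = np.clip(
        np.log1p(population / 500.0) + 0.3 * _smooth2(rng, (n_lat, n_lon), 2.0),
        0.0, None,
    )
    emissions = np.clip(
        0.6 * pop_norm + 0.4 * (0.5 + 0.5 * _smooth2(rng, (n_lat, n_lon), 2.0)),
        0.0, None,
    )
    static = {
        "population": population,
        "elevation": elev,
        "ndvi": ndvi,
        "nightlights": nightlights,
        "emissions": emissions,
    }

    # --- meteorology (space-time smooth, physically plausible ranges)
    pblh = np.clip(
        800.0
        + 300.0 * _smooth2(rng, (n_lat, n_lon), 3.0)[None]
        + 250.0 * _smooth3(rng, (n_days, n_lat, n_lon), (1.5, 2.0, 2.0))
        + 120.0 * season,
        200.0, None,
    )
    rh = np.clip(
        0.55
        + 0.12 * _smooth2(rng, (n_lat, n_lon), 3.0)[None]
        + 0.12 * _smooth3(rng, (n_days, n_lat, n_lon), (1.5, 2.0, 2.0)),
        0.05, 0.98,
    )
    temp = (
        288.0
        - 0.4 * np.abs(grid.lats)[None, :, None]
        + 8.0 * season
        + 2.0 * _smooth3(rng, (n_days, n_lat, n_lon), (1.5, 2.0, 2.0))
    )
    wind = np.clip(
        4.0 + 2.0 * _smooth3(rng, (n_days, n_lat, n_lon), (1.0, 2.0, 2.0)),
        0.2, None,
    )
    pressure = (
        1013.0 - elev[None] / 8.0
        + 3.0 * _smooth3(rng, (n_days, n_lat, n_lon), (1.0, 2.0, 2.0))
    )
    precip = np.clip(
        np.exp(1.0 + 1.2 * _smooth3(rng, (n_days, n_lat, n_lon), (1.0, 2.0, 2.0)))
        - 2.0,
        0.0, None,
    )
    evap = np.clip(
        2.0 + 1.0 * _smooth3(rng, (n_days, n_lat, n_lon), (1.0, 2.0, 2.0)),
        0.0, None,
    )
    met = {
        "pblh": pblh, "rh": rh, "temp": temp, "wind": wind,
        "pressure": pressure, "precip": precip, "evap": evap,
    }

    # --- PM2.5 truth: documented closed form (coefficients go to meta)
    beta1, beta2, beta3 = 55.0, 1.0, 20.0
    pblh_ref, pblh_min = 800.0, 200.0
    season_amp_pm = 6.0
    process_noise_frac = 0.5  # field-level noise sd = this * noise_sd
    eps_sd = process_noise_frac * config.noise_sd
    eps = eps_sd * rng.standard_normal((n_days, n_lat, n_lon)) if eps_sd > 0 else 0.0
    true_pm25 = config.pm_scale * np.clip(
        beta1 * true_aod * (1.0 + beta2 * rh) * (pblh_ref / np.maximum(pblh, pblh_min))
        + beta3 * emissions[None]
        + season_amp_pm * season
        + eps,
        0.0, None,
    )

    # --- CTM fields: coarse biased truth
    factor = max(2, min(4, n_lat // 4, n_lon // 4))
    ctm_aod = np.clip(
        _coarsen_and_bias(true_aod, grid, factor,
                          0.10 * _smooth2(rng, (n_lat, n_lon), 4.0), 0.02),
        0.0, None,
    )
    ctm_pm25 = np.clip(
        _coarsen_and_bias(true_pm25, grid, factor,
                          0.12 * _smooth2(rng, (n_lat, n_lon), 4.0), 1.0),
        0.0, None,
    )

    # --- satellite views and cloud mask
    alpha_aqua, beta_aqua = 0.9, 0.05
    terra_true = np.clip(true_aod + 0.02 * rng.standard_normal(true_aod.shape),
                         0.0, None)
    aqua_true = np.clip(
        alpha_aqua * terra_true + beta_aqua
        + 0.01 * rng.standard_normal(true_aod.shape),
        0.0, None,
    )
    cloud_field = _smooth3(rng, (n_days, n_lat, n_lon), sigma=(1.0, 3.0, 3.0))
    cloud_mask = cloud_field < np.quantile(cloud_field, config.missing_frac)
    # view-specific extra gaps, disjoint outside the joint cloud mask so the
    # *merged* missingness equals cloud_mask exactly
    u = rng.random((n_days, n_lat, n_lon))
    terra_aod = terra_true.copy()
    aqua_aod = aqua_true.copy()
    terra_aod[cloud_mask | (u < 0.15)] = np.nan
    aqua_aod[cloud_mask | (u > 0.85)] = np.nan

    # --- regions, stations
    regions = _tile_countries(grid, config.n_countries)
    country_of_cell = regions.set_index(["cell_i", "cell_j"])["country"]

    p = (population / population.sum()).ravel()
    n_cells = n_lat * n_lon
    replace = config.n_stations > n_cells
    chosen = rng.choice(n_cells, size=config.n_stations, replace=replace, p=p)
    st_i, st_j = np.unravel_index(chosen, (n_lat, n_lon))
    jit = rng.uniform(-0.4, 0.4, size=(2, config.n_stations)) * config.cell_deg
    st_lat = grid.lats[st_i] + jit[0]
    st_lon = grid.lons[st_j] + jit[1]
    stations = pd.DataFrame(
        {
            "station_id": [f"S{k:04d}" for k in range(config.n_stations)],
            "lat": st_lat,
            "lon": st_lon,
            "country": [country_of_cell.loc[(i, j)] for i, j in zip(st_i, st_j)],
            "cell_i": st_i,
            "cell_j": st_j,
        }
    )

    # --- hourly station series with injected outliers
    diurnal_rel_amp = 0.10
    hours = np.arange(24)
    psi = rng.uniform(0, 2 * np.pi, size=config.n_stations)
    base = true_pm25[:, st_i, st_j].T                 # (n_st, n_days)
    diurnal = 1.0 + diurnal_rel_amp * np.cos(
        2.0 * np.pi * hours[None, None, :] / 24.0 + psi[:, None, None]
    )
    vals = base[:, :, None] * diurnal                 # (n_st, n_days, 24)
    if config.noise_sd > 0:
        vals = vals + config.noise_sd * rng.standard_normal(vals.shape)

    n_hours = n_days * 24
    times = dates[0] + pd.to_timedelta(np.arange(n_hours), unit="h")
    flat = vals.reshape(config.n_stations, n_hours)
    log_rows = []
    rates = config.outlier_rates
    for s in range(config.n_stations):
        sid = stations["station_id"].iloc[s]
        series = flat[s]
        taken = np.zeros(n_hours, dtype=bool)

        def _draw(n_target, width):
            """Anchor indices with >= width clearance, greedy, reproducible."""
            anchors = []
            for idx in rng.permutation(n_hours - width):
                if len(anchors) >= n_target:
                    break
                if not taken[idx: idx + width].any():
                    anchors.append(idx)
                    taken[max(0, idx - 1): idx + width + 1] = True
            return anchors

        for a in _draw(round(rates["negative"] * n_hours), 1):
            series[a] = -abs(series[a]) - rng.uniform(1.0, 10.0)
            log_rows.append((sid, times[a], "negative"))
        for a in _draw(round(rates["repeat"] * n_hours), 9):
            run = int(rng.integers(4, 9))
            series[a: a + run] = series[a]
            for k in range(run):
                log_rows.append((sid, times[a + k], "repeat"))
        for a in _draw(round(rates["extreme"] * n_hours), 1):
            series[a] = max(abs(series[a]), 1.0) * rng.uniform(8.0, 15.0)
            log_rows.append((sid, times[a], "extreme"))

    station_hourly = pd.DataFrame(
        {
            "station_id": np.repeat(stations["station_id"].to_numpy(), n_hours),
            "datetime_utc": np.tile(times.to_numpy(), config.n_stations),
            "pm25": flat.ravel(),
        }
    )
    outlier_log = pd.DataFrame(
        log_rows, columns=["station_id", "datetime_utc", "kind"]
    )

    # --- stringency index and baseline mortality per country
    countries = sorted(regions["country"].unique())
    si_rows = []
    si_meta = {}
    for c_i, c in enumerate(countries):
        quiet = rng.random() < 0.15
        max_si = rng.uniform(5.0, 18.0) if quiet else rng.uniform(40.0, 95.0)
        start = int(rng.integers(40, 80))
        ramp_up, plateau, ramp_down = (
            int(rng.integers(5, 15)), int(rng.integers(25, 55)),
            int(rng.integers(10, 30)),
        )
        s = np.zeros(n_days)
        up_end = min(start + ramp_up, n_days)
        s[start:up_end] = np.linspace(0, max_si, up_end - start, endpoint=False)
        pl_end = min(up_end + plateau, n_days)
        s[up_end:pl_end] = max_si
        dn_end = min(pl_end + ramp_down, n_days)
        s[pl_end:dn_end] = np.linspace(max_si, 0, dn_end - pl_end, endpoint=False)
        si_rows.append(pd.DataFrame({"country": c, "date": dates, "si": s}))
        si_meta[c] = {"max_si": float(max_si), "plateau": [int(up_end), int(pl_end)]}
    si = pd.concat(si_rows, ignore_index=True)
    bmr = pd.DataFrame(
        {"country": countries,
         "bmr": rng.uniform(0.005, 0.012, size=len(countries))}
    )

    meta = {
        "pm_coeffs": {
            "beta1": beta1, "beta2": beta2, "beta3": beta3,
            "pblh_ref": pblh_ref, "pblh_min": pblh_min,
            "season_amp_pm": season_amp_pm,
            "process_noise_sd": float(eps_sd),
            "pm_scale": float(config.pm_scale),
        },
        "aod": {"alpha_aqua": alpha_aqua, "beta_aqua": beta_aqua,
                "season_amp_aod": 0.12},
        "season": {
            "phase_north": float(phase_north),
            "phase_south": float(phase_south),
            "period_days": int(n_days),
        },
        "diurnal_rel_amp": diurnal_rel_amp,
        "si": si_meta,
        "config": config.to_dict(),
    }

    return WorldBundle(
        config=config, grid=grid, dates=dates,
        true_aod=true_aod, true_pm25=true_pm25,
        terra_aod=terra_aod, aqua_aod=aqua_aod,
        ctm_aod=ctm_aod, ctm_pm25=ctm_pm25,
        met=met, static=static, cloud_mask=cloud_mask,
        stations=stations, station_hourly=station_hourly,
        si=si, bmr=bmr, regions=regions, outlier_log=outlier_log,
        meta=meta,
    )


# ---------------------------------------------------------------- bundle I/O

_GRID_COMPONENT = "grids.nc"
_CSV_COMPONENTS = ["stations", "station_hourly", "si", "bmr", "regions",
                   "outlier_log"]


def write_bundle(bundle: WorldBundle, path) -> None:
    """Write a bundle to a directory: one NetCDF of gridded fields plus
    plain CSV tables and YAML config/metadata."""
    import pathlib

    import xarray as xr

    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    coords = {"date": bundle.dates, "lat": bundle.grid.lats,
              "lon": bundle.grid.lons}
    data = {
        "true_aod": (("date", "lat", "lon"), bundle.true_aod),
        "true_pm25": (("date", "lat", "lon"), bundle.true_pm25),
        "terra_aod": (("date", "lat", "lon"), bundle.terra_aod),
        "aqua_aod": (("date", "lat", "lon"), bundle.aqua_aod),
        "ctm_aod": (("date", "lat", "lon"), bundle.ctm_aod),
        "ctm_pm25": (("date", "lat", "lon"), bundle.ctm_pm25),
        "cloud_mask": (("date", "lat", "lon"),
                       bundle.cloud_mask.astype(np.int8)),
    }
    for k, v in bundle.met.items():
        data[f"met_{k}"] = (("date", "lat", "lon"), v)
    for k, v in bundle.static.items():
        data[f"static_{k}"] = (("lat", "lon"), v)
    ds = xr.Dataset(data, coords=coords)
    ds.to_netcdf(path / _GRID_COMPONENT, engine="scipy")
    for name in _CSV_COMPONENTS:
        getattr(bundle, name).to_csv(path / f"{name}.csv", index=False)
    with open(path / "config.yaml", "w") as f:
        yaml.safe_dump(bundle.config.to_dict(), f)
    with open(path / "meta.yaml", "w") as f:
        yaml.safe_dump(_pyify(bundle.meta), f)


def _pyify(obj):
    """Make a nested structure YAML-safe (numpy scalars -> python)."""
    if isinstance(obj, dict):
        return {k: _pyify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_pyify(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_bundle(path) -> WorldBundle:
    """Read a bundle written by :func:`write_bundle`.

    Raises
    ------
    BundleFormatError
        Naming the offending component if any file is missing or malformed.
    """
    import pathlib

    import xarray as xr

    path = pathlib.Path(path)
    try:
        with open(path / "config.yaml") as f:
            config = WorldConfig.from_dict(yaml.safe_load(f))
        with open(path / "meta.yaml") as f:
            meta = yaml.safe_load(f)
    except (OSError, yaml.YAMLError, TypeError) as e:
        raise BundleFormatError(f"config/meta component unreadable: {e}") from e
    try:
        ds = xr.open_dataset(path / _GRID_COMPONENT, engine="scipy").load()
    except Exception as e:
        raise BundleFormatError(f"gridded component {_GRID_COMPONENT}: {e}") from e
    required = {"true_aod", "true_pm25", "terra_aod", "aqua_aod", "ctm_aod",
                "ctm_pm25", "cloud_mask"}
    if not required.issubset(ds.data_vars):
        raise BundleFormatError(
            f"gridded component lacks variables {sorted(required - set(ds.data_vars))}"
        )
    frames = {}
    for name in _CSV_COMPONENTS:
        try:
            # round_trip parser: the CSVs are written at full repr precision
            frames[name] = pd.read_csv(path / f"{name}.csv",
                                       float_precision="round_trip")
        except Exception as e:
            raise BundleFormatError(f"table component {name}.csv: {e}") from e
    for name in ("station_hourly", "si", "outlier_log"):
        if "datetime_utc" in frames[name].columns:
            frames[name]["datetime_utc"] = pd.to_datetime(
                frames[name]["datetime_utc"]
            )
        if "date" in frames[name].columns:
            frames[name]["date"] = pd.to_datetime(frames[name]["date"])
    grid = GridSpec(ds["lat"].values, ds["lon"].values)
    met = {k[len("met_"):]: ds[k].values for k in ds.data_vars
           if k.startswith("met_")}
    static = {k[len("static_"):]: ds[k].values for k in ds.data_vars
              if k.startswith("static_")}
    return WorldBundle(
        config=config, grid=grid,
        dates=pd.DatetimeIndex(ds["date"].values),
        true_aod=ds["true_aod"].values,
        true_pm25=ds["true_pm25"].values,
        terra_aod=ds["terra_aod"].values,
        aqua_aod=ds["aqua_aod"].values,
        ctm_aod=ds["ctm_aod"].values,
        ctm_pm25=ds["ctm_pm25"].values,
        met=met, static=static,
        cloud_mask=ds["cloud_mask"].values.astype(bool),
        stations=frames["stations"],
        station_hourly=frames["station_hourly"],
        si=frames["si"], bmr=frames["bmr"], regions=frames["regions"],
        outlier_log=frames["outlier_log"],
        meta=meta,
    )
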