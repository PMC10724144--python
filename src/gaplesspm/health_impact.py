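"""Short-term exposure risk, acute mortality burden, and lockdown differencing.

Exposure risk counts, per cell, how many days of the year exceed (strictly)
the 2021 WHO short-term guideline of 15 ug/m3 daily PM2.5 and its four
interim targets (25, 37.5, 50, 75 ug/m3).  Exposure-relevant averages weight
concentration by population.

The acute mortality burden uses a log-linear exposure-response function
calibrated to a meta-analytic all-cause relative risk of 1.0065 (95% CI
1.0044-1.0086) per 10 ug/m3 daily PM2.5:

    RR(C) = exp(beta * max(C - c0, 0)),   beta = ln(1.0065) / 10

and, per grid cell g and day d,

    MB = (RR - 1)/RR * POP * BMR / N

with POP the (country-total aligned) population of the cell, BMR the
country's baseline all-cause mortality rate per person-year, and N the days
in the year.  (RR-1)/RR is the attributable fraction.  Confidence bounds
substitute the CI slopes.  Absolute burden depends on the counterfactual
c0 (default 0) and is labelled as such; period *differences*, which the
lockdown analysis reports, cancel it.

The strictest-lockdown window of a country is located from its daily
stringency index (SI, 0-100): if the maximum SI surpasses 20, the window is
the maximal contiguous run around the (earliest) SI maximum staying at or
above half the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ThresholdSet:
    """WHO 2021 short-term guideline and interim targets, ug/m3, strict >."""

    aqg: float = 15.0
    it4: float = 25.0
    it3: float = 37.5
    it2: float = 50.0
    it1: float = 75.0

    def __post_init__(self):
        ladder = self.as_ladder()
        if not all(a < b for a, b in zip(ladder.values(), list(ladder.values())[1:])):
            raise ValueError("thresholds must strictly increase AQG -> IT1")

    def as_ladder(self) -> dict:
        """Name -> level, in increasing order of stringency breach."""
        return {"aqg": self.aqg, "it4": self.it4, "it3": self.it3,
                "it2": self.it2, "it1": self.it1}


@dataclass(frozen=True)
class RiskModel:
    """Log-linear exposure-response parameters for all-cause acute mortality."""

    rr_per_10: float = 1.0065
    rr_lo: float = 1.0044
    rr_hi: float = 1.0086
    c0: float = 0.0  # counterfactual concentration, ug/m3

    def __post_init__(self):
        if not (1.0 < self.rr_lo <= self.rr_per_10 <= self.rr_hi):
            raise ValueError("require 1 < rr_lo <= rr_per_10 <= rr_hi")
        if self.c0 < 0:
            raise ValueError("counterfactual c0 must be >= 0")

    @property
    def beta(self) -> float:
        """Slope per ug/m3: ln(rr_per_10)/10."""
        return float(np.log(self.rr_per_10) / 10.0)

    @property
    def beta_lo(self) -> float:
        return float(np.log(self.rr_lo) / 10.0)

    @property
    def beta_hi(self) -> float:
        return float(np.log(self.rr_hi) / 10.0)


def relative_risk(c, model: RiskModel | None = None, beta: float | None = None):
    """RR = exp(beta * max(C - c0, 0)); RR(c0) = 1, monotone in C."""
    model = model or RiskModel()
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    b = model.beta if beta is None else beta
    rr = np.exp(b * np.maximum(c - model.c0, 0.0))
    return float(rr) if rr.ndim == 0 else rr


def exceedance_stats(series, thresholds: ThresholdSet | None = None) -> dict:
    """Days (and percent of days-with-data) strictly above each threshold.

    ``series`` is one cell's daily concentrations; missing days are excluded
    from numerator and denominator alike.
    """
    thresholds = thresholds or ThresholdSet()
    v = np.asarray(series, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("all-missing series")
    out = {}
    for name, level in thresholds.as_ladder().items():
        count = int(np.sum(v > level))
        out[name] = {"days": count, "percent": 100.0 * count / v.size}
    return out


def exceedance_days_grid(cube: np.ndarray, level: float) -> np.ndarray:
    """Per-cell count of days strictly above ``level`` in a (day, lat, lon) cube."""
    return np.sum(np.asarray(cube) > level, axis=0)


def population_weighted_mean(values, pop, region_mask=None) -> float:
    """Sum(pop * value) / Sum(pop) over non-missing cells in the region."""
    values = np.asarray(values, dtype=float)
    pop = np.asarray(pop, dtype=float)
    if region_mask is None:
        region_mask = np.ones(values.shape, dtype=bool)
    ok = region_mask & np.isfinite(values)
    w = pop[ok]
    if w.sum() <= 0:
        raise ValueError("zero total population in region")
    return float(np.sum(w * values[ok]) / w.sum())


def populated_area_fractions(
    exceed_days: dict[str, np.ndarray] | np.ndarray,
    density: np.ndarray,
    durations: tuple[int, ...] = (1, 7, 30),
    density_cut: float = 1.0,
) -> dict:
    """Percent of populated cells with >= k exceedance days, per threshold and k.

    ``exceed_days`` maps threshold name -> per-cell exceedance-day counts
    (a single array is treated as one unnamed threshold).  Populated means
    density strictly above ``density_cut`` persons per km^2.
    """
    if isinstance(exceed_days, np.ndarray):
        exceed_days = {"threshold": exceed_days}
    populated = np.asarray(density, dtype=float) > density_cut
    n_pop = int(populated.sum())
    if n_pop == 0:
        raise ValueError("no cells with population density above the cut")
    out = {}
    for name, days in exceed_days.items():
        days = np.asarray(days)
        out[name] = {
            int(k): 100.0 * float(np.sum(days[populated] >= k)) / n_pop
            for k in durations
        }
    return out


def adjust_population(
    pop: np.ndarray, country_of_cell: np.ndarray, totals: dict[str, float]
) -> np.ndarray:
    """Scale each country's cells so they sum to the reported country total."""
    pop = np.asarray(pop, dtype=float)
    country_of_cell = np.asarray(country_of_cell)
    out = pop.copy()
    for c in np.unique(country_of_cell):
        if c not in totals:
            raise ValueError(f"no reported total for country {c!r}")
        mask = country_of_cell == c
        s = pop[mask].sum()
        total = float(totals[c])
        if s == 0.0:
            if total != 0.0:
                raise ValueError(f"country {c!r} has zero grid population "
                                 f"but nonzero reported total")
            continue
        out[mask] = pop[mask] * (total / s)
    return out


def mortality_burden(
    c, pop, bmr, n_days_in_year: int, model: RiskModel | None = None
) -> dict:
    """Eq-of-record acute burden: MB = (RR-1)/RR * POP * BMR / N.

    Broadcasts over arrays; returns central estimate and the CI pair from
    the lower/upper slopes.  MB is zero wherever C <= c0.
    """
    model = model or RiskModel()
    if n_days_in_year not in (365, 366):
        raise ValueError("n_days_in_year must be 365 or 366")
    pop = np.asarray(pop, dtype=float)
    bmr = np.asarray(bmr, dtype=float)
    if np.any(pop < 0):
        raise ValueError("population must be >= 0")
    if np.any((bmr < 0) | (bmr > 1)):
        raise ValueError("baseline mortality rate must be in [0, 1]")

    def _mb(beta):
        rr = relative_risk(c, model, beta=beta)
        rr = np.asarray(rr, dtype=float)
        af = (rr - 1.0) / rr  # attributable fraction
        mb = af * pop * bmr / float(n_days_in_year)
        return float(mb) if mb.ndim == 0 else mb

    return {
        "mb": _mb(model.beta),
        "mb_lo": _mb(model.beta_lo),
        "mb_hi": _mb(model.beta_hi),
    }


def detect_lockdown_window(
    si, min_max_si: float = 20.0, plateau_frac: float = 0.5
) -> tuple[int, int] | None:
    """Locate the strictest-lockdown window in a daily SI series.

    Returns half-open day indices ``(start, stop)`` of the maximal
    contiguous interval containing the (earliest) SI argmax on which
    SI >= plateau_frac * max(SI); or None when the maximum does not surpass
    ``min_max_si``.
    """
    v = np.asarray(si, dtype=float)
    if v.size == 0 or np.isnan(v).any():
        raise ValueError("SI series must be complete")
    m = float(v.max())
    if m <= min_max_si:
        return None
    peak = int(np.argmax(v))  # earliest argmax
    level = plateau_frac * m
    start = peak
    while start > 0 and v[start - 1] >= level:
        start -= 1
    stop = peak + 1
    while stop < v.size and v[stop] >= level:
        stop += 1
    return start, stop


def period_difference(
    pm_year: np.ndarray,
    pm_baseline: np.ndarray,
    window: tuple[int, int],
    pop: np.ndarray,
    bmr,
    n_days_in_year: int,
    model: RiskModel | None = None,
) -> dict:
    """Lockdown-window change of year A against a baseline year (or mean of years).

    Returns the relative percent change of the window's population-weighted
    mean PM2.5 and the summed mortality-burden difference (with CI pair).
    """
    model = model or RiskModel()
    a, b = window
    if not (0 <= a < b <= pm_year.shape[0] and b <= pm_baseline.shape[0]):
        raise ValueError("window outside the cubes' calendars")
    wa = pm_year[a:b]
    wb = pm_baseline[a:b]
    pwm_a = population_weighted_mean(wa.mean(axis=0), pop)
    pwm_b = population_weighted_mean(wb.mean(axis=0), pop)
    if pwm_b == 0:
        raise ValueError("baseline population-weighted mean is zero")
    pct_change = 100.0 * (pwm_a - pwm_b) / pwm_b

    mb_a = mortality_burden(wa, pop[None], bmr, n_days_in_year, model)
    mb_b = mortality_burden(wb, pop[None], bmr, n_days_in_year, model)
    return {
        "pwm_percent_change": pct_change,
        "pwm_year": pwm_a,
        "pwm_baseline": pwm_b,
        "delta_deaths": float(np.sum(mb_a["mb"]) - np.sum(mb_b["mb"])),
        "delta_deaths_lo": float(np.sum(mb_a["mb_lo"]) - np.sum(mb_b["mb_lo"])),
        "delta_deaths_hi": float(np.sum(mb_a["mb_hi"]) - np.sum(mb_b["mb_hi"])),
    }
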