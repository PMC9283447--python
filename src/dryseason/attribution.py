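"""Decompose the potential-evapotranspiration trend into driver contributions.

The contribution of one meteorological driver I (temperature T, relative
humidity RH, 2-m wind u2, or net radiation Rn) to the Ep trend is measured
by the climatological-fixing method: recompute Ep with driver I replaced,
day by day, by its day-of-year climatological value while the other drivers
keep their observed values, and take

    C_I(t) = Ep_all(t) - Ep_(I fixed)(t).

Trending each C_I series gives the driver's share of the Ep trend; because
Penman-Monteith is nonlinear, the shares need not add up exactly, and the
difference (nonlinearity residual) is always reported, never redistributed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import demand
from .season import smooth_doy, DAYS_PER_YEAR
from .trends import TrendResult, ols_trend

__all__ = ["DRIVERS", "AttributionResult", "doy_climatology",
           "ep_contribution", "attribute_ep_trend"]

DRIVERS = ("T", "RH", "u2", "Rn")


def doy_climatology(series: np.ndarray, smooth: bool = True) -> np.ndarray:
    """Day-of-year mean over all years, 30-day circular-smoothed by default.

    Smoothing mirrors the season detector's climatology so that "fixed at
    daily climatological values" means the same thing in both places.
    """
    x = np.asarray(series, dtype=float)
    if x.size % DAYS_PER_YEAR:
        raise ValueError("series length must be a multiple of 365")
    clim = x.reshape(-1, DAYS_PER_YEAR).mean(axis=0)
    return smooth_doy(clim) if smooth else clim


def _ep_from(met: dict, p_surf) -> np.ndarray:
    return demand.penman_monteith_ep(met["T"], met["RH"], met["u2"], met["Rn"],
                                     p_surf=p_surf)


def _as_met_dict(met) -> dict:
    out = {}
    for v in DRIVERS:
        if v not in met:
            raise ValueError(f"missing driver variable {v!r}")
        out[v] = np.asarray(met[v], dtype=float)
    return out


def ep_contribution(met, driver: str, p_surf=demand.DEFAULT_PRESSURE_KPA) -> np.ndarray:
    """Daily contribution series C_I of one driver to Ep (mm d-1).

    ``met`` maps T, RH, u2, Rn to full daily series (a dict, DataFrame or
    Dataset of aligned 1-D arrays whose length is a multiple of 365).
    """
    if driver not in DRIVERS:
        raise ValueError(f"driver must be one of {DRIVERS}")
    m = _as_met_dict(met)
    n_years = m["T"].size // DAYS_PER_YEAR
    ep_all = _ep_from(m, p_surf)
    fixed = dict(m)
    fixed[driver] = np.tile(doy_climatology(m[driver]), n_years)
    if driver == "RH":
        fixed["RH"] = np.clip(fixed["RH"], 0.0, 100.0)
    ep_fixed = _ep_from(fixed, p_surf)
    return ep_all - ep_fixed


@dataclass(frozen=True)
class AttributionResult:
    """Driver contributions to the Ep trend over a day-of-year window.

    ``contribution_series`` holds the full daily C_I series; trends are OLS
    slopes (per year) of annual window means. ``residual_trend`` is the part
    of the Ep trend the per-driver contributions do not add up to.
    """

    ep_trend: TrendResult
    contribution_trends: dict
    contribution_series: dict
    residual_trend: float
    window: tuple | None

    def ranked_drivers(self):
        """Drivers ordered by |trend of contribution|, largest first."""
        return sorted(self.contribution_trends,
                      key=lambda d: -abs(self.contribution_trends[d].slope))


def _annual_window_means(series: np.ndarray, window) -> np.ndarray:
    x = np.asarray(series, dtype=float).reshape(-1, DAYS_PER_YEAR)
    if window is None:
        return x.mean(axis=1)
    lo, hi = window
    days = np.arange(lo - 1, lo - 1 + (hi - lo) % DAYS_PER_YEAR + 1) % DAYS_PER_YEAR
    return x[:, days].mean(axis=1)


def attribute_ep_trend(met, window: tuple | None = None,
                       p_surf=demand.DEFAULT_PRESSURE_KPA) -> AttributionResult:
    """Trend of Ep and of each driver's contribution over a DOY window.

    ``window`` is an inclusive (start_doy, end_doy) pair, wrapping across 31
    Dec when start > end (e.g. a dry season from the season detector); None
    uses the whole year. Requires at least 10 years of daily data.
    """
    m = _as_met_dict(met)
    n_years = m["T"].size // DAYS_PER_YEAR
    if n_years < 10:
        raise ValueError("attribution needs at least 10 years of daily data")
    if window is not None:
        lo, hi = window
        if not (1 <= lo <= DAYS_PER_YEAR and 1 <= hi <= DAYS_PER_YEAR):
            raise ValueError("window days must lie in 1..365")
    ep_all = _ep_from(m, p_surf)
    ep_trend = ols_trend(_annual_window_means(ep_all, window))
    series = {}
    trends = {}
    for drv in DRIVERS:
        c = ep_contribution(m, drv, p_surf=p_surf)
        series[drv] = c
        trends[drv] = ols_trend(_annual_window_means(c, window))
    residual = ep_trend.slope - sum(t.slope for t in trends.values())
    return AttributionResult(ep_trend=ep_trend, contribution_trends=trends,
                             contribution_series=series, residual_trend=float(residual),
                             window=window)
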