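"""Synthetic daily tropical climate with known seasonality and trends.

Every downstream stage (season detection, trend estimation, attribution) is
exercised against series produced here, so the generator is deliberately
transparent: rainfall is a one- or two-harmonic annual cycle with
multiplicative gamma noise, meteorology (T, RH, u2, Rn) is a mean + annual
harmonic + linear trend, and actual evapotranspiration comes from a
single-layer bucket that reduces potential evapotranspiration by an
evaporative stress factor S = W/W_max (E = S * Ep + Ei).

The calendar is strictly 365 days per year; day-of-year is 1-based.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from . import demand

__all__ = [
    "DAYS_PER_YEAR",
    "MetCycle",
    "GeneratorConfig",
    "generate_point_series",
    "generate_daily_climate",
    "bucket_evaporation",
    "add_bucket_e",
]

DAYS_PER_YEAR = 365


@dataclass(frozen=True)
class MetCycle:
    """Mean annual cycle of one meteorological variable.

    ``phase`` is the day of year of the annual maximum; ``trend`` shifts the
    mean linearly, in variable units per decade.
    """

    mean: float
    amplitude: float = 0.0
    phase: float = 15.0
    trend: float = 0.0


def _default_met_cycles() -> dict:
    # Savanna-like tropical point: warm, RH peaking with the rains, light
    # winds, strong radiation. Phases align RH with the rainfall maximum.
    return {
        "T": MetCycle(mean=25.0, amplitude=2.0, phase=288.0),
        "RH": MetCycle(mean=70.0, amplitude=12.0, phase=288.0),
        "u2": MetCycle(mean=2.0, amplitude=0.4, phase=105.0),
        "Rn": MetCycle(mean=14.0, amplitude=2.5, phase=340.0),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground-truth configuration of the synthetic climate.

    Rainfall: P(doy, t) = (map_total/365) * (1 + a1(t) cos(2 pi (doy - phi1(t))/365)
    + a2 cos(4 pi (doy - phi2)/365)), clipped at 0, times mean-1 gamma noise
    with coefficient of variation ``noise_cv``. Trends are linear in time:
    phi1(t) = p_phase1 + phase_trend * t/10, a1(t) = p_amp1 * (1 + amp_trend * t/10),
    with t in years since the record start.
    """

    n_years: int = 34
    start_year: int = 1983
    map_total: float = 1200.0          # mm yr-1
    p_amp1: float = 0.8                # relative annual amplitude
    p_amp2: float = 0.0                # relative semiannual amplitude
    p_phase1: float = 288.0            # doy of the annual rainfall maximum
    p_phase2: float = 288.0
    noise_cv: float = 0.3
    phase_trend: float = 0.0           # d per decade added to p_phase1
    amp_trend: float = 0.0             # relative change of p_amp1 per decade
    met_cycles: dict = field(default_factory=_default_met_cycles)
    w_max: float = 200.0               # bucket capacity, mm
    w0: float = 100.0                  # initial store, mm
    ei: float = 0.0                    # interception evaporation, mm d-1
    seed: int = 0

    def validate(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be >= 3")
        if self.map_total < 0:
            raise ValueError("map_total must be non-negative")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        if self.p_amp1 < 0 or self.p_amp2 < 0:
            raise ValueError("harmonic amplitudes must be non-negative")
        if not (self.w_max > 0 and 0 <= self.w0 <= self.w_max):
            raise ValueError("require w_max > 0 and 0 <= w0 <= w_max")


def _rain_deterministic(cfg: GeneratorConfig, doy: np.ndarray,
                        t_years: np.ndarray) -> np.ndarray:
    phi1 = cfg.p_phase1 + cfg.phase_trend * t_years / 10.0
    a1 = cfg.p_amp1 * (1.0 + cfg.amp_trend * t_years / 10.0)
    base = cfg.map_total / DAYS_PER_YEAR
    p = base * (1.0
                + a1 * np.cos(2.0 * np.pi * (doy - phi1) / DAYS_PER_YEAR)
                + cfg.p_amp2 * np.cos(4.0 * np.pi * (doy - cfg.p_phase2) / DAYS_PER_YEAR))
    return np.maximum(p, 0.0)


def generate_point_series(cfg: GeneratorConfig,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Generate one grid point as a DataFrame with columns P, T, RH, u2, Rn.

    The index is the absolute day number (0-based); ``year`` and ``doy``
    columns give the 365-day calendar position. Identical config and seed
    give bit-identical output.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.n_years * DAYS_PER_YEAR
    day = np.arange(n)
    doy = day % DAYS_PER_YEAR + 1
    t_years = (day + 0.5) / DAYS_PER_YEAR

    p = _rain_deterministic(cfg, doy, t_years)
    if cfg.noise_cv > 0:
        shape = 1.0 / cfg.noise_cv**2
        p = p * rng.gamma(shape, 1.0 / shape, size=n)

    out = {"P": p}
    for var, cyc in cfg.met_cycles.items():
        x = (cyc.mean + cyc.trend * t_years / 10.0
             + cyc.amplitude * np.cos(2.0 * np.pi * (doy - cyc.phase) / DAYS_PER_YEAR))
        if var == "RH":
            x = np.clip(x, 0.0, 100.0)
        elif var == "u2":
            x = np.maximum(x, 0.0)
        out[var] = x

    df = pd.DataFrame(out, index=pd.Index(day, name="day"))
    df["year"] = cfg.start_year + day // DAYS_PER_YEAR
    df["doy"] = doy
    return df


def generate_daily_climate(cfg: GeneratorConfig,
                           lats=(0.0,), lons=(0.0,)) -> xr.Dataset:
    """Generate a lat x lon grid of independent realizations of ``cfg``.

    All points share the deterministic cycle; daily noise is independent per
    point (no spatial correlation is modeled). Returns an xarray Dataset with
    dims (time, lat, lon) on a 365-day calendar.
    """
    cfg.validate()
    lats = np.atleast_1d(np.asarray(lats, dtype=float))
    lons = np.atleast_1d(np.asarray(lons, dtype=float))
    n = cfg.n_years * DAYS_PER_YEAR
    streams = np.random.SeedSequence(cfg.seed).spawn(lats.size * lons.size)

    variables = ["P"] + list(cfg.met_cycles)
    data = {v: np.empty((n, lats.size, lons.size)) for v in variables}
    k = 0
    for i in range(lats.size):
        for j in range(lons.size):
            df = generate_point_series(cfg, rng=np.random.default_rng(streams[k]))
            for v in variables:
                data[v][:, i, j] = df[v].values
            k += 1

    day = np.arange(n, dtype=np.int32)
    ds = xr.Dataset(
        {v: (("time", "lat", "lon"), data[v]) for v in variables},
        coords={
            "time": ("time", day),
            "year": ("time", (cfg.start_year + day // DAYS_PER_YEAR).astype(np.int32)),
            "doy": ("time", (day % DAYS_PER_YEAR + 1).astype(np.int32)),
            "lat": ("lat", lats),
            "lon": ("lon", lons),
        },
    )
    ds["P"].attrs.update(units="mm d-1", long_name="precipitation")
    if "T" in ds:
        ds["T"].attrs.update(units="degC")
    if "RH" in ds:
        ds["RH"].attrs.update(units="%")
    if "u2" in ds:
        ds["u2"].attrs.update(units="m s-1")
    if "Rn" in ds:
        ds["Rn"].attrs.update(units="MJ m-2 d-1")
    ds.attrs.update(calendar="365_day", start_year=cfg.start_year)
    return ds


def bucket_evaporation(p, ep, w_max: float, w0: float, ei: float = 0.0):
    """Single-layer bucket: E = S * Ep + Ei with stress factor S = W/W_max.

    Per day: S = W/W_max; E = S Ep + Ei (capped at W + P so the store never
    goes negative and the balance closes exactly); W <- min(W + P - E, W_max),
    the excess above W_max leaving as runoff.

    Returns (E, S, W, runoff); W[t] is the store at the start of day t, and
    W(t+1) - W(t) = P - E - runoff holds exactly every step.
    """
    p = np.asarray(p, dtype=float)
    ep = np.asarray(ep, dtype=float)
    if p.shape != ep.shape:
        raise ValueError("P and Ep series must be aligned")
    if np.any(p < 0) or np.any(ep < 0):
        raise ValueError("P and Ep must be non-negative")
    if not (w_max > 0 and 0 <= w0 <= w_max):
        raise ValueError("require w_max > 0 and 0 <= w0 <= w_max")
    n = p.size
    e = np.empty(n)
    s = np.empty(n)
    w = np.empty(n)
    runoff = np.empty(n)
    wt = float(w0)
    for t in range(n):
        w[t] = wt
        s[t] = wt / w_max
        e[t] = min(s[t] * ep[t] + ei, wt + p[t])
        wnew = wt + p[t] - e[t]
        runoff[t] = max(wnew - w_max, 0.0)
        wt = wnew - runoff[t]
    return e, s, w, runoff


def add_bucket_e(grid: xr.Dataset, w_max: float = 200.0, w0: float = 100.0,
                 ei: float = 0.0) -> xr.Dataset:
    """Add supply-limited E (and stress factor S) to a grid that carries Ep."""
    if "Ep" not in grid:
        raise ValueError("grid must carry Ep (run demand.add_ep first)")
    out = grid.copy()
    shape = grid["P"].shape
    e = np.empty(shape)
    s = np.empty(shape)
    for i in range(shape[1]):
        for j in range(shape[2]):
            e[:, i, j], s[:, i, j], _, _ = bucket_evaporation(
                grid["P"].values[:, i, j], grid["Ep"].values[:, i, j],
                w_max=w_max, w0=w0, ei=ei)
    out["E"] = (grid["P"].dims, e)
    out["E"].attrs.update(units="mm d-1", long_name="actual evapotranspiration (bucket)")
    out["S"] = (grid["P"].dims, s)
    out["S"].attrs.update(units="1", long_name="evaporative stress factor W/W_max")
    return out
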