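"""Atmospheric water demand: vapor pressure deficit and FAO-56 Penman-Monteith
potential evapotranspiration (Ep).

All operations are element-wise and accept scalars or numpy arrays. Units
follow FAO-56: temperature in deg C, relative humidity in %, wind speed in
m s-1 at 2 m, net radiation and soil heat flux in MJ m-2 d-1, pressures in
kPa, Ep in mm d-1.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "PsychrometricState",
    "psychrometrics",
    "penman_monteith_ep",
    "wind_to_2m",
    "add_ep",
]

#: Default surface pressure (kPa) when no pressure field is supplied.
DEFAULT_PRESSURE_KPA = 101.3


@dataclass(frozen=True)
class PsychrometricState:
    """Saturation/actual vapor pressure, VPD, and the two Penman constants.

    ``es`` and ``ea`` are in kPa, ``vpd = es - ea`` (kPa), ``delta`` is the
    slope of the saturation vapor-pressure curve (kPa degC-1) and ``gamma``
    the psychrometric constant (kPa degC-1).
    """

    es: np.ndarray
    ea: np.ndarray
    vpd: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray


def _validate_rh(rh) -> None:
    rh = np.asarray(rh, dtype=float)
    if np.any(~np.isfinite(rh)) or np.any(rh < 0.0) or np.any(rh > 100.0):
        raise ValueError("relative humidity must be finite and within [0, 100] %")


def psychrometrics(t, rh, p_surf=DEFAULT_PRESSURE_KPA) -> PsychrometricState:
    """Tetens saturation vapor pressure, VPD and Penman auxiliary constants.

    es = 0.6108 exp(17.27 T / (T + 237.3));  ea = es RH/100;
    delta = 4098 es / (T + 237.3)^2;  gamma = 0.665e-3 p_surf.
    """
    t = np.asarray(t, dtype=float)
    _validate_rh(rh)
    rh = np.asarray(rh, dtype=float)
    p_surf = np.asarray(p_surf, dtype=float)
    if np.any(p_surf <= 0):
        raise ValueError("surface pressure must be positive (kPa)")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    ea = es * rh / 100.0
    vpd = es * (1.0 - rh / 100.0)
    delta = 4098.0 * es / (t + 237.3) ** 2
    gamma = 0.665e-3 * p_surf
    return PsychrometricState(es=es, ea=ea, vpd=vpd, delta=delta, gamma=gamma)


def penman_monteith_ep(t, rh, u2, rn, g=0.0, p_surf=DEFAULT_PRESSURE_KPA,
                       clip_negative=True):
    """Daily FAO-56 Penman-Monteith potential evapotranspiration (mm d-1).

    Ep = [0.408 Delta (Rn - G) + gamma 900/(T+273) u2 (es - ea)]
         / [Delta + gamma (1 + 0.34 u2)]

    Soil heat flux G defaults to 0 (negligible at daily steps). Negative Ep
    (possible under strongly negative net radiation) is clipped to 0 by
    default: a season detector comparing supply against demand treats
    negative demand as no demand.
    """
    t = np.asarray(t, dtype=float)
    u2 = np.asarray(u2, dtype=float)
    rn = np.asarray(rn, dtype=float)
    g = np.asarray(g, dtype=float)
    for name, arr in (("T", t), ("u2", u2), ("Rn", rn), ("G", g)):
        if np.any(~np.isfinite(arr)):
            raise ValueError(f"non-finite values in {name}")
    if np.any(u2 < 0):
        raise ValueError("wind speed must be non-negative")
    ps = psychrometrics(t, rh, p_surf)
    num = 0.408 * ps.delta * (rn - g) + ps.gamma * (900.0 / (t + 273.0)) * u2 * ps.vpd
    den = ps.delta + ps.gamma * (1.0 + 0.34 * u2)
    ep = num / den
    if clip_negative:
        ep = np.maximum(ep, 0.0)
    return ep


def wind_to_2m(u_h, h: float):
    """Scale wind speed measured at height ``h`` (m) to 2 m.

    FAO-56 logarithmic profile: u2 = u_h * 4.87 / ln(67.8 h - 5.42).
    Exact identity at h = 2.
    """
    if h <= 5.42 / 67.8:
        raise ValueError("measurement height must exceed 5.42/67.8 m")
    u_h = np.asarray(u_h, dtype=float)
    if h == 2.0:
        return u_h * 1.0
    return u_h * 4.87 / np.log(67.8 * h - 5.42)


def add_ep(grid: xr.Dataset, clip_negative: bool = True) -> xr.Dataset:
    """Return a copy of a daily climate dataset with an ``Ep`` variable.

    Requires T (degC), RH (%), u2 (m s-1), Rn (MJ m-2 d-1); uses the
    ``p_surf`` variable when present, otherwise the standard 101.3 kPa.
    """
    for v in ("T", "RH", "u2", "Rn"):
        if v not in grid:
            raise ValueError(f"missing required variable {v!r} for Ep")
    p = grid["p_surf"].values if "p_surf" in grid else DEFAULT_PRESSURE_KPA
    ep = penman_monteith_ep(grid["T"].values, grid["RH"].values,
                            grid["u2"].values, grid["Rn"].values,
                            p_surf=p, clip_negative=clip_negative)
    out = grid.copy()
    out["Ep"] = (grid["T"].dims, ep)
    out["Ep"].attrs.update(units="mm d-1", long_name="potential evapotranspiration (FAO-56 Penman-Monteith)")
    return out
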