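"""Dry-season detection from cumulative supply-minus-demand curves.

The dry season at a point is read from the cumulative sum of daily
precipitation minus a demand term, under three definitions of demand:

* ``P_lt_Pbar`` — demand is the multi-year mean daily precipitation P-bar;
* ``P_lt_Ep``   — demand is potential evapotranspiration (atmospheric);
* ``P_lt_E``    — demand is actual evapotranspiration (supply-limited).

The cumulative curve rises on days when precipitation exceeds demand and
falls when it does not; the day of its maximum marks the dry-season arrival
(DSA), the day of its minimum the end (DSE), and the drop between them is
the water deficit (WD). Rainfall modality (one vs two dry seasons per year)
is classified from the ratio of the semiannual to annual Fourier amplitude
of the full daily series; a ratio above 0.75 marks a bimodal regime with two
dry seasons, for which the two longest are retained.

Climatological seasons are found on the 30-day-smoothed day-of-year
climatology as maximal circular runs of negative supply-minus-demand (each
run is one local max-to-min pair of the cumulative curve; this is robust to
the secular drift of cumulative P - Ep). Year-by-year timing re-runs the
curve on that year's smoothed daily values inside a window of +/- 60 days
(+/- 45 in bimodal regimes) around the climatological season; first and last
years of the record are never scored because their windows can leave the
record.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import DAYS_PER_YEAR

__all__ = [
    "DEFINITIONS",
    "BIMODAL_RATIO_THRESHOLD",
    "SeasonalityClass",
    "SeasonTiming",
    "SeasonList",
    "Climatology",
    "smooth_doy",
    "smooth_running",
    "harmonic_ratio",
    "classify_seasonality",
    "build_climatology",
    "climatological_season",
    "annual_season",
    "water_deficit",
    "PointSeasons",
]

DEFINITIONS = ("P_lt_Pbar", "P_lt_Ep", "P_lt_E")
BIMODAL_RATIO_THRESHOLD = 0.75
SMOOTH_WINDOW = 30
# centered-but-even window: day d averages days d-15 ... d+14
_SMOOTH_OFFSETS = np.arange(-15, 15)
ANNUAL_MARGIN_UNIMODAL = 60
ANNUAL_MARGIN_BIMODAL = 45


@dataclass(frozen=True)
class SeasonalityClass:
    """Semiannual:annual amplitude ratio and the modality it implies."""

    ratio: float
    modality: str  # "unimodal" | "bimodal"
    flagged_infinite: bool = False


@dataclass(frozen=True)
class SeasonTiming:
    """One detected dry season (climatological or for a single year).

    ``dsa``/``dse`` are 1-based days of year; ``dsl = (dse - dsa) mod 365``
    days; ``wd`` is the cumulative water deficit (mm, non-negative).
    """

    definition: str
    dsa: int
    dse: int
    dsl: int
    wd: float
    season_index: int = 1
    year: object = "climatology"


class SeasonList(list):
    """List of SeasonTiming with a ``reason`` code when empty."""

    def __init__(self, seasons: Sequence[SeasonTiming] = (), reason: str | None = None):
        super().__init__(seasons)
        self.reason = reason


def smooth_doy(series_365: np.ndarray) -> np.ndarray:
    """Circular 30-day running mean of a day-of-year climatology.

    The window is day d-15 ... d+14; circularity preserves the annual mean
    exactly and keeps seasons spanning 31 Dec intact.
    """
    x = np.asarray(series_365, dtype=float)
    if x.shape != (DAYS_PER_YEAR,):
        raise ValueError(f"expected a length-{DAYS_PER_YEAR} day-of-year series")
    padded = np.concatenate([x[_SMOOTH_OFFSETS[0]:], x, x[: _SMOOTH_OFFSETS[-1]]])
    kernel = np.full(SMOOTH_WINDOW, 1.0 / SMOOTH_WINDOW)
    return np.convolve(padded, kernel, mode="valid")


def smooth_running(series: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Linear (non-circular) running mean with the same d-15 ... d+14 offsets.

    Edges are averaged over the days actually available; only the first and
    last 15 days of a record are affected, and those fall in the excluded
    first/last years of annual detection.
    """
    x = np.asarray(series, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="full")
    den = np.convolve(np.ones_like(x), kernel, mode="full")
    # align so position i covers x[i-15 : i+15] (even window: offsets -w/2 .. w/2-1)
    off = window // 2 - 1 if window % 2 == 0 else window // 2
    sl = slice(off, off + x.size)
    return num[sl] / den[sl]


def harmonic_ratio(daily_series: np.ndarray) -> tuple[float, bool]:
    """Semiannual-to-annual Fourier amplitude ratio of a full daily record.

    Amplitudes are read at the exact 1- and 2-cycles-per-year bins of the
    length-(365 n) transform. Returns ``(ratio, flagged)`` where ``flagged``
    marks an annual amplitude at machine-epsilon level (ratio = +inf).
    """
    x = np.asarray(daily_series, dtype=float)
    if x.size == 0 or x.size % DAYS_PER_YEAR:
        raise ValueError("series length must be a positive multiple of 365")
    n_years = x.size // DAYS_PER_YEAR
    spectrum = np.fft.rfft(x)
    a1 = np.abs(spectrum[n_years])
    a2 = np.abs(spectrum[2 * n_years])
    scale = max(np.abs(spectrum[0]), 1.0)
    if a1 <= np.finfo(float).eps * scale:
        return float("inf"), True
    return float(a2 / a1), False


def classify_seasonality(ratio: float, flagged_infinite: bool = False) -> SeasonalityClass:
    """Bimodal iff the amplitude ratio strictly exceeds 0.75."""
    if not flagged_infinite and not np.isinf(ratio) and ratio < 0:
        raise ValueError("amplitude ratio must be non-negative")
    modality = "bimodal" if ratio > BIMODAL_RATIO_THRESHOLD else "unimodal"
    return SeasonalityClass(ratio=float(ratio), modality=modality,
                            flagged_infinite=flagged_infinite or bool(np.isinf(ratio)))


@dataclass(frozen=True)
class Climatology:
    """Smoothed day-of-year climatologies and the multi-year mean rainfall."""

    p_smooth: np.ndarray
    pbar: float
    n_years: int
    ep_smooth: np.ndarray | None = None
    e_smooth: np.ndarray | None = None
    p_raw: np.ndarray = field(default=None, repr=False)
    seasonality: SeasonalityClass | None = None

    def demand(self, definition: str):
        """Demand term for a definition: scalar P-bar or a 365-day series."""
        if definition == "P_lt_Pbar":
            return self.pbar
        if definition == "P_lt_Ep":
            if self.ep_smooth is None:
                raise ValueError("Ep climatology not available")
            return self.ep_smooth
        if definition == "P_lt_E":
            if self.e_smooth is None:
                raise ValueError("E climatology not available")
            return self.e_smooth
        raise ValueError(f"unknown definition {definition!r}")


def _doy_mean(series: np.ndarray) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    return x.reshape(-1, DAYS_PER_YEAR).mean(axis=0)


def build_climatology(p: np.ndarray, ep: np.ndarray | None = None,
                      e: np.ndarray | None = None) -> Climatology:
    """Day-of-year climatology (30-day smoothed) from full daily series.

    Rainfall modality is classified from precipitation only, matching the
    observation that the annual/semiannual structure of rainfall sets the
    number of dry seasons; the classifier can be re-run on any series via
    :func:`harmonic_ratio` if a per-definition variant is wanted.
    """
    p = np.asarray(p, dtype=float)
    if p.size % DAYS_PER_YEAR:
        raise ValueError("series length must be a multiple of 365")
    n_years = p.size // DAYS_PER_YEAR
    p_raw = _doy_mean(p)
    ratio, flagged = harmonic_ratio(p)
    return Climatology(
        p_smooth=smooth_doy(p_raw),
        pbar=float(p.mean()),
        n_years=n_years,
        ep_smooth=None if ep is None else smooth_doy(_doy_mean(ep)),
        e_smooth=None if e is None else smooth_doy(_doy_mean(e)),
        p_raw=p_raw,
        seasonality=classify_seasonality(ratio, flagged),
    )


def _circular_negative_runs(delta: np.ndarray):
    """Maximal circular runs where delta < 0, as (start, length, depth)."""
    neg = delta < 0
    n = neg.size
    if neg.all() or not neg.any():
        return []
    starts = np.flatnonzero(neg & ~np.roll(neg, 1))
    runs = []
    for s in starts:
        length = 0
        depth = 0.0
        i = s
        while neg[i % n] and length < n:
            depth -= delta[i % n]
            length += 1
            i += 1
        runs.append((int(s), int(length), float(depth)))
    return runs


def climatological_season(clim: Climatology, definition: str,
                          modality: str | None = None) -> SeasonList:
    """Detect the climatological dry season(s) under one definition.

    Returns one season for unimodal regimes (the deepest deficit run) and up
    to two for bimodal regimes (the two longest, ranked by length then
    depth). Returns an empty list with ``reason='no_climatological_season'``
    when the supply-minus-demand series never changes sign (arid or humid
    limit, or no seasonality at all).
    """
    if modality is None:
        modality = clim.seasonality.modality if clim.seasonality else "unimodal"
    demand = clim.demand(definition)
    delta = clim.p_smooth - demand
    scale = max(abs(clim.pbar), float(np.max(np.abs(delta), initial=0.0)), 1e-30)
    if np.max(np.abs(delta)) <= 1e-9 * scale:
        return SeasonList([], reason="no_climatological_season")
    runs = _circular_negative_runs(delta)
    if not runs:
        return SeasonList([], reason="no_climatological_season")

    if modality == "bimodal":
        picked = sorted(runs, key=lambda r: (-r[1], -r[2]))[:2]
    else:
        picked = [max(runs, key=lambda r: r[2])]
    picked.sort(key=lambda r: r[0])

    seasons = []
    for k, (start, length, depth) in enumerate(picked, start=1):
        dsa = (start - 1) % DAYS_PER_YEAR + 1
        dse = (start + length - 1) % DAYS_PER_YEAR + 1
        seasons.append(SeasonTiming(definition=definition, dsa=dsa, dse=dse,
                                    dsl=length, wd=depth, season_index=k))
    return SeasonList(seasons)


def water_deficit(p_smooth: np.ndarray, demand, dsa: int, dse: int) -> float:
    """Cumulative demand-minus-supply (mm) over the circular season (dsa, dse].

    ``demand`` is a scalar (P-bar) or 365-day series; the result is the drop
    of the cumulative supply-minus-demand curve between its max at DSA and
    min at DSE, reported as a non-negative magnitude.
    """
    if not (1 <= dsa <= DAYS_PER_YEAR and 1 <= dse <= DAYS_PER_YEAR):
        raise ValueError("dsa/dse must be days of year in 1..365")
    delta = np.asarray(p_smooth, dtype=float) - demand
    days = np.arange(dsa, dsa + (dse - dsa) % DAYS_PER_YEAR) % DAYS_PER_YEAR
    return float(-delta[days].sum())


def annual_season(p_smooth_full: np.ndarray, demand_full, clim_timing: SeasonTiming,
                  year_index: int, n_years: int,
                  margin: int = ANNUAL_MARGIN_UNIMODAL) -> SeasonTiming | None:
    """Dry-season timing for one year inside a window around the climatology.

    ``p_smooth_full`` is the 30-day-smoothed full record; ``demand_full`` is
    a scalar (the multi-year P-bar, never a per-year mean) or a smoothed full
    series. The window runs from DSA_clim - margin to DSE_clim + margin in
    absolute days, crossing calendar-year boundaries as needed. Returns None
    for the first and last year of the record or when the window leaves it.
    """
    if year_index <= 0 or year_index >= n_years - 1:
        return None
    dsa0 = clim_timing.dsa - 1
    dse0 = clim_timing.dse - 1
    if dse0 < dsa0:
        dse0 += DAYS_PER_YEAR
    w_start = year_index * DAYS_PER_YEAR + dsa0 - margin
    w_end = year_index * DAYS_PER_YEAR + dse0 + margin
    n = np.asarray(p_smooth_full).size
    if w_start < 0 or w_end >= n:
        return None
    window = slice(w_start, w_end + 1)
    if np.isscalar(demand_full) or np.ndim(demand_full) == 0:
        delta = np.asarray(p_smooth_full)[window] - float(demand_full)
    else:
        delta = np.asarray(p_smooth_full)[window] - np.asarray(demand_full)[window]
    curve = np.cumsum(delta)
    # deepest deficit segment: the pair i < j maximizing curve[i] - curve[j]
    # (max drawdown). Identical to the global argmax/argmin for drift-free
    # P - Pbar curves, but robust when cumulative P - Ep or P - E drifts and
    # the raw extrema land on the window boundary.
    runmax = np.maximum.accumulate(curve)
    imin = int(np.argmax(runmax - curve))
    imax = int(np.argmax(curve[: imin + 1]))
    dsl = imin - imax
    if dsl <= 0 or curve[imax] - curve[imin] <= 0:
        return None
    dsa = (w_start + imax) % DAYS_PER_YEAR + 1
    dse = (w_start + imin) % DAYS_PER_YEAR + 1
    return SeasonTiming(definition=clim_timing.definition, dsa=dsa, dse=dse,
                        dsl=dsl, wd=float(curve[imax] - curve[imin]),
                        season_index=clim_timing.season_index, year=year_index)


class PointSeasons:
    """End-to-end season detection for one grid point.

    Wraps climatology construction, modality classification, climatological
    detection and the per-year re-detection, and renders results as tidy
    DataFrames.
    """

    def __init__(self, p: np.ndarray, ep: np.ndarray | None = None,
                 e: np.ndarray | None = None, start_year: int = 1983):
        self.p = np.asarray(p, dtype=float)
        self.n_years = self.p.size // DAYS_PER_YEAR
        self.start_year = start_year
        self.clim = build_climatology(self.p, ep, e)
        self.modality = self.clim.seasonality.modality
        self._p_smooth_full = smooth_running(self.p)
        self._demand_full = {"P_lt_Pbar": self.clim.pbar}
        if ep is not None:
            self._demand_full["P_lt_Ep"] = smooth_running(np.asarray(ep, dtype=float))
        if e is not None:
            self._demand_full["P_lt_E"] = smooth_running(np.asarray(e, dtype=float))

    def available_definitions(self):
        return tuple(d for d in DEFINITIONS if d in self._demand_full)

    def climatological(self, definition: str) -> SeasonList:
        return climatological_season(self.clim, definition, self.modality)

    def annual(self, definition: str) -> list[SeasonTiming]:
        """Per-year seasons for all interior years, all season indices."""
        clim_seasons = self.climatological(definition)
        margin = (ANNUAL_MARGIN_BIMODAL if self.modality == "bimodal"
                  else ANNUAL_MARGIN_UNIMODAL)
        out = []
        for cs in clim_seasons:
            for iy in range(1, self.n_years - 1):
                st = annual_season(self._p_smooth_full, self._demand_full[definition],
                                   cs, iy, self.n_years, margin=margin)
                if st is not None:
                    out.append(SeasonTiming(definition=st.definition, dsa=st.dsa,
                                            dse=st.dse, dsl=st.dsl, wd=st.wd,
                                            season_index=st.season_index,
                                            year=self.start_year + iy))
        return out

    def annual_table(self, definitions: Sequence[str] | None = None) -> pd.DataFrame:
        """Tidy table of per-year seasons: definition, season_index, year, dsa, dse, dsl, wd."""
        if definitions is None:
            definitions = self.available_definitions()
        rows = []
        for d in definitions:
            for st in self.annual(d):
                rows.append({"definition": d, "season_index": st.season_index,
                             "year": st.year, "dsa": st.dsa, "dse": st.dse,
                             "dsl": st.dsl, "wd": st.wd})
        return pd.DataFrame(rows, columns=["definition", "season_index", "year",
                                           "dsa", "dse", "dsl", "wd"])
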