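"""Trend estimation and multi-dataset consistency labelling.

Annual dry-season diagnostics (DSL, DSA, DSE, WD) are trended with ordinary
least squares (two-tailed t test on the slope) and cross-checked with the
nonparametric Mann-Kendall test (tie-corrected variance, continuity
correction). Agreement across an ensemble of precipitation datasets is
summarized with a categorical consistency label; significance is P < 0.05
two-sided throughout, with no multiple-testing correction across grid
points.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TrendResult",
    "ConsistencyLabel",
    "ols_trend",
    "mann_kendall",
    "trend",
    "consistency_classify",
    "classify_counts",
    "area_weighted_mean",
    "climate_bin_summary",
    "percent_area_by_category",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TrendResult:
    """OLS slope (per year) with t-test p, and Mann-Kendall S statistic with p."""

    slope: float
    intercept: float
    p_ols: float
    mk_s: float = float("nan")
    p_mk: float = float("nan")
    n: int = 0

    @property
    def slope_per_decade(self) -> float:
        return 10.0 * self.slope

    @property
    def significant(self) -> bool:
        return self.p_ols < ALPHA

    @property
    def sign(self) -> int:
        return int(np.sign(self.slope))


def _clean(y, min_n: int):
    y = np.asarray(y, dtype=float)
    x = np.arange(y.size, dtype=float)
    ok = np.isfinite(y)
    y, x = y[ok], x[ok]
    if y.size < min_n:
        raise ValueError(f"need at least {min_n} non-missing annual values, got {y.size}")
    return x, y


def ols_trend(annual_series) -> TrendResult:
    """Least-squares linear trend against the year index, slope per year.

    A constant series returns slope 0 with p = 1 (no evidence of trend),
    sidestepping the undefined t statistic.
    """
    x, y = _clean(annual_series, min_n=3)
    if np.ptp(y) == 0.0:
        return TrendResult(slope=0.0, intercept=float(y[0]), p_ols=1.0, n=y.size)
    res = stats.linregress(x, y)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    return TrendResult(slope=float(res.slope), intercept=float(res.intercept),
                       p_ols=p, n=y.size)


def mann_kendall(annual_series) -> TrendResult:
    """Mann-Kendall monotonic-trend test.

    S = sum of signs over all pairs; Var(S) uses the tie correction
    [n(n-1)(2n+5) - sum_t t(t-1)(2t+5)] / 18; the normal approximation with
    continuity correction gives a two-sided p. Slope/intercept fields carry
    the OLS fit of the same series for convenience.
    """
    x, y = _clean(annual_series, min_n=4)
    n = y.size
    diffs = np.sign(y[None, :] - y[:, None])
    s = float(np.sum(np.triu(diffs, k=1)))
    _, counts = np.unique(y, return_counts=True)
    ties = counts[counts > 1]
    var = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var <= 0:  # all values tied
        return TrendResult(slope=0.0, intercept=float(y[0]), p_ols=1.0,
                           mk_s=0.0, p_mk=1.0, n=n)
    if s > 0:
        z = (s - 1.0) / np.sqrt(var)
    elif s < 0:
        z = (s + 1.0) / np.sqrt(var)
    else:
        z = 0.0
    p_mk = float(2.0 * stats.norm.sf(abs(z)))
    base = ols_trend(y)
    return TrendResult(slope=base.slope, intercept=base.intercept, p_ols=base.p_ols,
                       mk_s=s, p_mk=p_mk, n=n)


def trend(annual_series) -> TrendResult:
    """OLS trend with the Mann-Kendall cross-check attached."""
    return mann_kendall(annual_series)


@dataclass(frozen=True)
class ConsistencyLabel:
    """Ensemble agreement on a trend: category plus the counts behind it."""

    category: str  # e.g. "very_likely_increase", "uncertain", "no_change"
    n_sig_pos: int
    n_sig_neg: int
    n_nonsig: int

    @property
    def n_total(self) -> int:
        return self.n_sig_pos + self.n_sig_neg + self.n_nonsig


def classify_counts(n_sig_pos: int, n_sig_neg: int, n_total: int = 8) -> ConsistencyLabel:
    """Consistency category from counts of significant trends by sign.

    Conflicting significant signs give "uncertain"; no significant trend at
    all gives "no_change"; otherwise the count k of significant same-sign
    datasets maps, for an 8-member ensemble, to very_likely (6-8), likely
    (4-5) or probably (1-3), suffixed with the direction. Other ensemble
    sizes use the same fractions (>= 3/4, >= 1/2, > 0).
    """
    if n_total <= 0:
        raise ValueError("ensemble must be non-empty")
    if n_sig_pos < 0 or n_sig_neg < 0 or n_sig_pos + n_sig_neg > n_total:
        raise ValueError("invalid significance counts")
    n_nonsig = n_total - n_sig_pos - n_sig_neg
    if n_sig_pos > 0 and n_sig_neg > 0:
        cat = "uncertain"
    elif n_sig_pos == 0 and n_sig_neg == 0:
        cat = "no_change"
    else:
        k = max(n_sig_pos, n_sig_neg)
        direction = "increase" if n_sig_pos > 0 else "decrease"
        if k >= np.ceil(0.75 * n_total):
            cat = f"very_likely_{direction}"
        elif k >= np.ceil(0.5 * n_total):
            cat = f"likely_{direction}"
        else:
            cat = f"probably_{direction}"
    return ConsistencyLabel(category=cat, n_sig_pos=n_sig_pos,
                            n_sig_neg=n_sig_neg, n_nonsig=n_nonsig)


def consistency_classify(per_dataset_trends) -> ConsistencyLabel:
    """Label an ensemble from (sign, significant) pairs or TrendResults."""
    items = list(per_dataset_trends)
    if not items:
        raise ValueError("ensemble must be non-empty")
    pairs = []
    for it in items:
        if isinstance(it, TrendResult):
            pairs.append((it.sign, it.significant))
        else:
            sign, sig = it
            pairs.append((int(np.sign(sign)), bool(sig)))
    n_sig_pos = sum(1 for sign, sig in pairs if sig and sign > 0)
    n_sig_neg = sum(1 for sign, sig in pairs if sig and sign < 0)
    return classify_counts(n_sig_pos, n_sig_neg, n_total=len(pairs))


def area_weighted_mean(values, latitudes) -> float:
    """cos(latitude)-weighted mean over finite entries; NaN if none."""
    v = np.asarray(values, dtype=float).ravel()
    lat = np.asarray(latitudes, dtype=float).ravel()
    w = np.cos(np.deg2rad(lat))
    ok = np.isfinite(v)
    if not ok.any():
        return float("nan")
    return float(np.average(v[ok], weights=w[ok]))


def climate_bin_summary(dsl_by_definition: dict, mat, map_, mat_edges, map_edges) -> pd.DataFrame:
    """Mean pairwise DSL differences binned by mean annual temperature/precipitation.

    ``dsl_by_definition`` maps definition name to a per-point DSL array.
    Returns one row per (MAT bin, MAP bin) cell with the mean difference for
    every ordered definition pair present and the point count; empty cells
    carry count 0 and NaN means.
    """
    defs = list(dsl_by_definition)
    df = pd.DataFrame({d: np.asarray(dsl_by_definition[d], dtype=float).ravel()
                       for d in defs})
    df["mat_bin"] = pd.cut(np.asarray(mat, dtype=float).ravel(), mat_edges)
    df["map_bin"] = pd.cut(np.asarray(map_, dtype=float).ravel(), map_edges)
    pairs = [(a, b) for i, a in enumerate(defs) for b in defs[i + 1:]]
    for a, b in pairs:
        df[f"dsl_{a}_minus_{b}"] = df[a] - df[b]
    cols = [f"dsl_{a}_minus_{b}" for a, b in pairs]
    grouped = df.groupby(["mat_bin", "map_bin"], observed=False)
    out = grouped[cols].mean()
    out["count"] = grouped[defs[0]].count()
    return out.reset_index()


def percent_area_by_category(labels, latitudes, exclusion_mask=None) -> dict:
    """cos-lat-weighted percent area per consistency category.

    Points flagged in ``exclusion_mask`` (e.g. arid/humid points with no
    climatological dry or wet season) are removed before percentages are
    taken; the remaining categories sum to 100 %. All-excluded input raises.
    """
    labels = np.asarray(labels, dtype=object).ravel()
    lat = np.asarray(latitudes, dtype=float).ravel()
    if exclusion_mask is None:
        keep = np.ones(labels.size, dtype=bool)
    else:
        keep = ~np.asarray(exclusion_mask, dtype=bool).ravel()
    w = np.cos(np.deg2rad(lat))[keep]
    labels = labels[keep]
    total = w.sum()
    if total <= 0:
        raise ValueError("all points excluded; percent area undefined")
    return {cat: float(100.0 * w[labels == cat].sum() / total)
            for cat in sorted(set(labels.tolist()))}
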