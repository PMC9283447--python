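"""Reference synthetic scenarios with closed-form or designed expectations.

These bundles define the study conditions used throughout the test-suite and
the reproduction script: a sinusoidal rainfall year whose dry-season timing
and deficit are known analytically, two-harmonic regimes with dry seasons
centred in DJF and JJA, humid- and arid-limit points that separate the three
dry-season definitions, an ensemble trend-recovery experiment at the
diagnostic level, and a Mann-Kendall calibration run.
"""
from __future__ import annotations

import numpy as np

from . import trends
from .demand import penman_monteith_ep
from .season import PointSeasons
from .synthetic import (GeneratorConfig, MetCycle, bucket_evaporation,
                        generate_point_series)

__all__ = [
    "sinusoid_config", "bimodal_config", "humid_config", "arid_config",
    "point_with_fluxes", "dsl_by_definition", "sinusoid_benchmark",
    "ensemble_trend_experiment", "mk_type1_rate",
]


def sinusoid_config(n_years: int = 4) -> GeneratorConfig:
    """Mean 3 mm/d, relative amplitude 0.5, rainfall minimum at day 200.

    P crosses its mean at days ~108.75 and ~291.25 (dry-season length
    182.5 d) and the deficit lobe integrates to 1.5 * 365/pi ~ 174.3 mm.
    """
    return GeneratorConfig(n_years=n_years, map_total=3.0 * 365, p_amp1=0.5,
                           p_phase1=200.0 - 182.5, noise_cv=0.0)


def bimodal_config(ratio: float, a1: float = 0.3, n_years: int = 6) -> GeneratorConfig:
    """Two-harmonic rainfall with dry seasons centred in DJF and JJA.

    Semiannual minima sit at days 25 and 207.5 (mid-Jan, late Jul); the
    annual harmonic is placed 135 deg from the first minimum so that both
    minima stay dry and both maxima (Apr, Oct) stay wet for any amplitude
    ratio above ~0.71, i.e. throughout the bimodal classification range.
    """
    return GeneratorConfig(n_years=n_years, map_total=1400.0, p_amp1=a1,
                           p_amp2=a1 * ratio, p_phase1=253.125,
                           p_phase2=298.75, noise_cv=0.0)


def humid_config() -> GeneratorConfig:
    """Rainforest-like point: P >> Ep and a bucket that is never stressed."""
    return GeneratorConfig(
        n_years=8, map_total=2800.0, p_amp1=0.5, p_phase1=288.0, noise_cv=0.0,
        met_cycles={"T": MetCycle(27.0, 1.5, 288.0), "RH": MetCycle(75.0, 8.0, 288.0),
                    "u2": MetCycle(2.0, 0.3, 105.0), "Rn": MetCycle(16.0, 2.0, 340.0)},
        w_max=2000.0, w0=2000.0)


def arid_config() -> GeneratorConfig:
    """Semi-arid point: Ep >> P on average, bucket chronically stressed."""
    return GeneratorConfig(
        n_years=8, map_total=900.0, p_amp1=1.0, p_phase1=288.0, noise_cv=0.0,
        met_cycles={"T": MetCycle(26.0, 2.5, 105.0), "RH": MetCycle(55.0, 15.0, 288.0),
                    "u2": MetCycle(2.5, 0.4, 105.0), "Rn": MetCycle(14.0, 3.0, 105.0)},
        w_max=50.0, w0=15.0)


def point_with_fluxes(cfg: GeneratorConfig) -> dict:
    """Generate one point and derive Ep (Penman-Monteith) and E (bucket)."""
    df = generate_point_series(cfg)
    ep = penman_monteith_ep(df["T"].values, df["RH"].values,
                            df["u2"].values, df["Rn"].values)
    e, s, w, runoff = bucket_evaporation(df["P"].values, ep, cfg.w_max, cfg.w0,
                                         ei=cfg.ei)
    return {"cfg": cfg, "P": df["P"].values, "Ep": ep, "E": e, "S": s}


def dsl_by_definition(point: dict) -> dict:
    """Climatological DSL under each definition for a generated point."""
    pt = PointSeasons(point["P"], point["Ep"], point["E"])
    out = {}
    for d in ("P_lt_Pbar", "P_lt_Ep", "P_lt_E"):
        seasons = pt.climatological(d)
        out[d] = seasons[0].dsl if seasons else None
    return out


def sinusoid_benchmark() -> dict:
    """Detected climatological timing of the analytic sinusoid scenario."""
    p = generate_point_series(sinusoid_config())["P"].values
    pt = PointSeasons(p)
    s = pt.climatological("P_lt_Pbar")[0]
    return {"dsa": s.dsa, "dse": s.dse, "dsl": s.dsl, "wd": s.wd}


def ensemble_trend_experiment(seed: int, n_repeats: int = 200,
                              trend_d_per_decade: float = 8.0,
                              sigma_dse: float = 6.0, n_years: int = 34,
                              n_members: int = 8) -> dict:
    """Recover an imposed dry-season-end delay from a noisy ensemble.

    Each repeat draws ``n_members`` member series sharing the truth
    DSL(y) = 150 + (trend/10) * y with independent N(0, sigma_dse) noise,
    fits the OLS trend per member, and labels the ensemble. Returns the mean
    estimated slope (d/decade) and the fraction of repeats labelled
    very_likely or likely (the confident tiers).
    """
    rng = np.random.default_rng(seed)
    years = np.arange(n_years, dtype=float)
    truth = 150.0 + trend_d_per_decade / 10.0 * years
    slopes = []
    confident = 0
    for _ in range(n_repeats):
        member_trends = []
        for _ in range(n_members):
            y = truth + rng.normal(0.0, sigma_dse, n_years)
            tr = trends.ols_trend(y)
            member_trends.append(tr)
            slopes.append(tr.slope_per_decade)
        label = trends.consistency_classify(member_trends)
        if label.category.startswith(("very_likely", "likely")):
            confident += 1
    return {"mean_slope_d_per_decade": float(np.mean(slopes)),
            "confident_rate": confident / n_repeats,
            "n_repeats": n_repeats, "n_members": n_members}


def mk_type1_rate(seed: int, n_reps: int = 2000, n: int = 34,
                  alpha: float = 0.05) -> float:
    """Empirical Mann-Kendall rejection rate on iid Gaussian series."""
    rng = np.random.default_rng(seed)
    rejections = sum(trends.mann_kendall(rng.normal(size=n)).p_mk < alpha
                     for _ in range(n_reps))
    return rejections / n_reps
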