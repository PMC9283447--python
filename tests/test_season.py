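"""Season detection: smoothing, modality, climatological and annual timing."""
import numpy as np
import pytest

from dryseason.season import (BIMODAL_RATIO_THRESHOLD, DAYS_PER_YEAR, PointSeasons,
                              annual_season, build_climatology, classify_seasonality,
                              climatological_season, harmonic_ratio, smooth_doy,
                              smooth_running, water_deficit)
from dryseason.synthetic import GeneratorConfig, generate_point_series

DOY = np.arange(1, DAYS_PER_YEAR + 1)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(smooth_doy(np.full(365, 3.7)), 3.7)

    def test_circular_mean_preserved(self):
        rng = np.random.default_rng(5)
        x = rng.gamma(1.0, 3.0, 365)
        assert smooth_doy(x).mean() == pytest.approx(x.mean(), rel=1e-12)

    def test_annual_cosine_attenuation(self):
        # discrete 30-day window attenuates a unit annual cosine to ~0.9889
        x = np.cos(2 * np.pi * DOY / 365)
        sm = smooth_doy(x)
        attenuation = (sm.max() - sm.min()) / (x.max() - x.min())
        assert attenuation == pytest.approx(0.98894, abs=2e-3)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            smooth_doy(np.zeros(366))

    def test_linear_matches_circular_on_periodic_interior(self):
        x1 = np.cos(2 * np.pi * DOY / 365) + 2.0
        full = np.tile(x1, 3)
        lin = smooth_running(full)[365:730]
        np.testing.assert_allclose(lin, smooth_doy(x1), rtol=1e-12)


class TestHarmonicRatio:
    def test_pure_annual_has_no_semiannual_power(self):
        series = np.tile(3.0 + np.cos(2 * np.pi * DOY / 365), 4)
        ratio, flagged = harmonic_ratio(series)
        assert not flagged and ratio == pytest.approx(0.0, abs=1e-10)

    def test_pure_semiannual_flagged_infinite(self):
        series = np.tile(3.0 + np.cos(4 * np.pi * DOY / 365), 4)
        ratio, flagged = harmonic_ratio(series)
        assert flagged and np.isinf(ratio)
        assert classify_seasonality(ratio, flagged).modality == "bimodal"

    def test_known_amplitude_ratio(self):
        series = np.tile(5.0 + 1.0 * np.cos(2 * np.pi * DOY / 365)
                         + 0.8 * np.cos(4 * np.pi * (DOY - 40) / 365), 5)
        ratio, _ = harmonic_ratio(series)
        assert ratio == pytest.approx(0.8, rel=1e-9)

    def test_partial_year_rejected(self):
        with pytest.raises(ValueError):
            harmonic_ratio(np.zeros(500))

    @pytest.mark.parametrize("ratio,modality", [
        (0.5, "unimodal"), (0.74, "unimodal"),
        (0.75, "unimodal"),  # boundary is strict
        (0.76, "bimodal"), (1.2, "bimodal"),
    ])
    def test_modality_threshold(self, ratio, modality):
        assert classify_seasonality(ratio).modality == modality

    def test_negative_ratio_rejected(self):
        with pytest.raises(ValueError):
            classify_seasonality(-0.1)


class TestClimatologicalSeason:
    def test_sinusoid_timing_and_deficit(self, sinusoid_config):
        # analytic crossings of P = P-bar at days 108.75 / 291.25; deficit
        # lobe 1.5 * 365/pi = 174.3 mm (30-day smoothing attenuates ~1.1%)
        p = generate_point_series(sinusoid_config)["P"].values
        clim = build_climatology(p)
        seasons = climatological_season(clim, "P_lt_Pbar")
        assert len(seasons) == 1
        s = seasons[0]
        assert abs(s.dsa - 109) <= 3
        assert abs(s.dse - 291) <= 3
        assert abs(s.dsl - 182) <= 4
        assert s.wd == pytest.approx(1.5 * 365 / np.pi, rel=0.02)

    def test_constant_rainfall_has_no_season(self):
        clim = build_climatology(np.full(3 * 365, 3.0))
        seasons = climatological_season(clim, "P_lt_Pbar")
        assert len(seasons) == 0
        assert seasons.reason == "no_climatological_season"

    def test_arid_limit_no_season_under_ep(self):
        # P always below Ep: no wet season, hence no detectable dry season
        p = np.tile(1.0 + 0.5 * np.cos(2 * np.pi * DOY / 365), 4)
        ep = np.full(4 * 365, 6.0)
        clim = build_climatology(p, ep=ep)
        assert len(climatological_season(clim, "P_lt_Ep")) == 0

    def test_dry_and_wet_tile_the_year(self, sinusoid_config):
        # unimodal P < P-bar: dry length + wet length = 365
        p = generate_point_series(sinusoid_config)["P"].values
        clim = build_climatology(p)
        dry = climatological_season(clim, "P_lt_Pbar")[0]
        delta = clim.p_smooth - clim.pbar
        wet_len = int((delta >= 0).sum())
        assert dry.dsl + wet_len == 365

    def test_bimodal_two_seasons_djf_and_jja(self, bimodal_config_factory):
        p = generate_point_series(bimodal_config_factory(1.2))["P"].values
        clim = build_climatology(p)
        seasons = climatological_season(clim, "P_lt_Pbar")
        assert len(seasons) == 2
        dsas = sorted(s.dsa for s in seasons)
        assert 152 <= dsas[0] <= 243          # Jun-Aug arrival
        assert dsas[1] >= 335 or dsas[1] <= 59  # Dec-Feb arrival

    def test_water_deficit_oracle(self):
        # 30-day season with unit daily shortfall -> 30 mm; balanced -> 0
        p = np.full(365, 3.0)
        p[100:130] = 2.0
        assert water_deficit(p, 3.0, dsa=100, dse=130) == pytest.approx(30.0)
        assert water_deficit(np.full(365, 3.0), 3.0, 10, 40) == 0.0
        with pytest.raises(ValueError):
            water_deficit(p, 3.0, dsa=0, dse=400)


class TestAnnualSeason:
    def test_identical_years_match_climatology(self, sinusoid_config):
        p = generate_point_series(sinusoid_config)["P"].values
        pt = PointSeasons(p, start_year=2000)
        clim_s = pt.climatological("P_lt_Pbar")[0]
        annual = pt.annual("P_lt_Pbar")
        assert len(annual) == sinusoid_config.n_years - 2
        for st in annual:
            assert abs(st.dsa - clim_s.dsa) <= 1
            assert abs(st.dse - clim_s.dse) <= 1
            assert st.wd == pytest.approx(clim_s.wd, rel=0.02)

    def test_shift_equivariance_under_phase_trend(self):
        # +10 d/yr phase drift moves DSA and DSE by ~+10 d per year
        cfg = GeneratorConfig(n_years=6, map_total=1095.0, p_amp1=0.5,
                              p_phase1=17.5, phase_trend=100.0, noise_cv=0.0)
        pt = PointSeasons(generate_point_series(cfg)["P"].values)
        annual = sorted(pt.annual("P_lt_Pbar"), key=lambda s: s.year)
        dsa = np.array([s.dsa for s in annual], dtype=float)
        dse = np.array([s.dse for s in annual], dtype=float)
        assert np.all(np.abs(np.diff(dsa) - 10) <= 2)
        assert np.all(np.abs(np.diff(dse) - 10) <= 2)

    def test_first_and_last_years_not_scored(self, sinusoid_config):
        p = generate_point_series(sinusoid_config)["P"].values
        pt = PointSeasons(p, start_year=2000)
        years = {s.year for s in pt.annual("P_lt_Pbar")}
        assert 2000 not in years
        assert 2000 + sinusoid_config.n_years - 1 not in years
        clim_s = pt.climatological("P_lt_Pbar")[0]
        assert annual_season(pt._p_smooth_full, pt.clim.pbar, clim_s, 0,
                             pt.n_years) is None

    def test_bimodal_annual_table_has_both_seasons(self, bimodal_config_factory):
        cfg = bimodal_config_factory(1.2)
        pt = PointSeasons(generate_point_series(cfg)["P"].values)
        table = pt.annual_table(["P_lt_Pbar"])
        per_year = table.groupby("year")["season_index"].apply(set)
        assert all(v == {1, 2} for v in per_year)

    def test_pbar_threshold_is_multi_year(self):
        # a uniformly wetter year still uses the record-wide P-bar: its
        # dry season shrinks rather than staying fixed at the annual mean
        cfg = GeneratorConfig(n_years=5, map_total=1095.0, p_amp1=0.5,
                              p_phase1=17.5, noise_cv=0.0)
        p = generate_point_series(cfg)["P"].values.copy()
        p[2 * 365:3 * 365] *= 1.4
        pt = PointSeasons(p, start_year=2000)
        by_year = {s.year: s for s in pt.annual("P_lt_Pbar")}
        assert by_year[2002].dsl < by_year[2001].dsl - 10
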