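"""Trend statistics, consistency labelling and spatial summaries."""
import numpy as np
import pytest
from scipy import stats

from dryseason.trends import (area_weighted_mean, classify_counts,
                              climate_bin_summary, consistency_classify,
                              mann_kendall, ols_trend, percent_area_by_category)


class TestOLS:
    def test_exact_line_recovered(self):
        y = 150.0 + 0.6 * np.arange(20)
        res = ols_trend(y)
        assert res.slope == pytest.approx(0.6, abs=1e-12)
        assert res.slope_per_decade == pytest.approx(6.0, abs=1e-10)
        assert res.p_ols < 1e-10

    def test_constant_series(self):
        res = ols_trend(np.full(10, 3.0))
        assert res.slope == 0.0 and res.p_ols == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            ols_trend([1.0, 2.0])

    def test_unbiased_under_noise(self):
        # Monte-Carlo: slope 1.0 + N(0, 5), n=32, 500 draws
        rng = np.random.default_rng(11)
        slopes = []
        for _ in range(500):
            y = 1.0 * np.arange(32) + rng.normal(0.0, 5.0, 32)
            slopes.append(ols_trend(y).slope)
        assert np.mean(slopes) == pytest.approx(1.0, abs=0.05)


class TestMannKendall:
    def test_strictly_monotone(self):
        res = mann_kendall(np.arange(20, dtype=float))
        assert res.mk_s == 190.0 and res.p_mk < 1e-3
        dec = mann_kendall(np.arange(20, dtype=float)[::-1])
        assert dec.mk_s == -190.0 and dec.p_mk == pytest.approx(res.p_mk)

    def test_all_tied(self):
        res = mann_kendall(np.full(10, 2.0))
        assert res.mk_s == 0.0 and res.p_mk == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=30).cumsum() + 10.0
        a = mann_kendall(y)
        b = mann_kendall(np.exp(y / 5.0))
        assert a.mk_s == b.mk_s and a.p_mk == pytest.approx(b.p_mk, rel=1e-12)

    def test_sign_agrees_with_ols_for_monotone(self):
        y = np.array([1.0, 2.5, 2.6, 4.0, 7.0, 9.5])
        res = mann_kendall(y)
        assert np.sign(res.mk_s) == np.sign(res.slope) == 1

    def test_p_close_to_scipy_kendalltau(self):
        # independent oracle: scipy's tau test (no continuity correction,
        # so allow a small gap)
        rng = np.random.default_rng(9)
        for _ in range(20):
            y = rng.normal(size=34)
            ours = mann_kendall(y).p_mk
            theirs = stats.kendalltau(np.arange(34), y).pvalue
            assert ours == pytest.approx(theirs, abs=0.02)

    def test_type_one_error_calibrated(self):
        # nominal alpha = 0.05 on iid series, n=34
        rng = np.random.default_rng(12345)
        rejections = sum(mann_kendall(rng.normal(size=34)).p_mk < 0.05
                         for _ in range(1000))
        assert 0.03 <= rejections / 1000 <= 0.07


HAND_TABLE = {}  # (n_sig_pos, n_sig_neg) -> category, ensemble of 8
for pos in range(9):
    for neg in range(9 - pos):
        if pos and neg:
            HAND_TABLE[(pos, neg)] = "uncertain"
        elif pos == neg == 0:
            HAND_TABLE[(pos, neg)] = "no_change"
        else:
            k, d = (pos, "increase") if pos else (neg, "decrease")
            tier = "very_likely" if k >= 6 else ("likely" if k >= 4 else "probably")
            HAND_TABLE[(pos, neg)] = f"{tier}_{d}"


class TestConsistency:
    def test_exhaustive_truth_table(self):
        for (pos, neg), expected in HAND_TABLE.items():
            label = classify_counts(pos, neg, n_total=8)
            assert label.category == expected, (pos, neg)
            assert label.n_sig_pos + label.n_sig_neg + label.n_nonsig == 8

    def test_classify_from_trend_pairs(self):
        assert consistency_classify([(1, True)] * 8).category == "very_likely_increase"
        assert consistency_classify([(1, True)] * 2 + [(1, False)] * 6
                                    ).category == "probably_increase"
        assert consistency_classify([(1, True), (-1, True)] + [(0, False)] * 6
                                    ).category == "uncertain"
        assert consistency_classify([(-1, False)] * 8).category == "no_change"

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            consistency_classify([])


class TestSpatialSummaries:
    def test_area_weighted_mean(self):
        assert area_weighted_mean([4.0, 4.0, 4.0], [0.0, 30.0, 60.0]) == 4.0
        assert area_weighted_mean([1.0, 2.0, 6.0], [0.0, 0.0, 0.0]) == pytest.approx(3.0)
        # cos(60) = 0.5 -> weight 1/3 on the second point
        assert area_weighted_mean([0.0, 1.0], [0.0, 60.0]) == pytest.approx(1.0 / 3.0)
        assert np.isnan(area_weighted_mean([np.nan], [10.0]))

    def test_climate_bins_match_brute_force(self):
        rng = np.random.default_rng(21)
        n = 200
        mat = rng.uniform(15.0, 30.0, n)
        map_ = rng.uniform(200.0, 3000.0, n)
        dsl = {"P_lt_Ep": rng.uniform(0, 300, n), "P_lt_Pbar": rng.uniform(0, 300, n)}
        mat_edges = [15, 20, 25, 30]
        map_edges = [0, 1000, 2000, 3000]
        out = climate_bin_summary(dsl, mat, map_, mat_edges, map_edges)
        col = "dsl_P_lt_Ep_minus_P_lt_Pbar"
        for _, row in out.iterrows():
            sel = np.array([row["mat_bin"].left < m <= row["mat_bin"].right and
                            row["map_bin"].left < q <= row["map_bin"].right
                            for m, q in zip(mat, map_)])
            assert row["count"] == sel.sum()
            if sel.any():
                brute = np.mean(dsl["P_lt_Ep"][sel] - dsl["P_lt_Pbar"][sel])
                assert row[col] == pytest.approx(brute)
            else:
                assert np.isnan(row[col])

    def test_percent_area(self):
        labels = np.array(["likely_increase"] * 4)
        assert percent_area_by_category(labels, [0, 5, 10, 15]) == {
            "likely_increase": pytest.approx(100.0)}
        # half the equal-latitude points excluded -> percentages over the rest
        labels = np.array(["a", "a", "b", "b"])
        out = percent_area_by_category(labels, [0, 0, 0, 0],
                                       exclusion_mask=[False, True, False, True])
        assert out == {"a": pytest.approx(50.0), "b": pytest.approx(50.0)}

    def test_percent_area_matches_weighted_tally(self):
        rng = np.random.default_rng(4)
        lats = rng.uniform(-23.5, 23.5, 60)
        labels = rng.choice(["up", "down", "none"], 60)
        excl = rng.random(60) < 0.2
        out = percent_area_by_category(labels, lats, excl)
        w = np.cos(np.deg2rad(lats))
        keep = ~excl
        for cat in set(labels[keep]):
            expected = 100.0 * w[keep & (labels == cat)].sum() / w[keep].sum()
            assert out[cat] == pytest.approx(expected)
        assert sum(out.values()) == pytest.approx(100.0)

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError):
            percent_area_by_category(["a"], [0.0], [True])
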