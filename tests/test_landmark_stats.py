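import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from artdose.landmark_stats import (correlations, delta_abs, ecdf,
                                    holm_adjust, order_statistic_percentile,
                                    percentile_summary, percentile_with_ci,
                                    rank_adaptation_fit, rank_sum_test,
                                    scale_test, signed_rank_test)


class TestDeltaAbs:
    def test_signed_combination(self):
        t = pd.DataFrame({"inter_mm": [8.0], "intra_mm": [-3.0], "parameter": [1]})
        assert delta_abs(t)["delta_mm"].iloc[0] == pytest.approx(5.0)

    def test_equal_zero(self):
        t = pd.DataFrame({"inter_mm": [4.0], "intra_mm": [4.0], "parameter": [1]})
        assert delta_abs(t)["delta_mm"].iloc[0] == 0.0

    def test_missing_pairs_dropped_and_counted(self):
        t = pd.DataFrame({"inter_mm": [1.0, np.nan, 2.0],
                          "intra_mm": [0.5, 1.0, np.nan], "parameter": [1, 1, 1]})
        out = delta_abs(t)
        assert len(out) == 1
        assert out.attrs["n_dropped"] == 2

    def test_sampler_direction(self):
        # inter spread > intra spread -> positive median delta per parameter
        from artdose.config import MotionConfig
        from artdose.synthetic_cohort import MotionModel

        model = MotionModel(MotionConfig())
        rng = np.random.default_rng(42)
        samples = model.sample(200, rng)
        for k in range(8):
            inter = np.array([s.landmark_inter[k] for s in samples])
            intra = np.array([s.landmark_intra[k] for s in samples])
            assert np.median(np.abs(inter) - np.abs(intra)) > 0


class TestPercentileSummary:
    def test_constant_column(self):
        t = pd.DataFrame({"parameter": [1] * 30, "inter_mm": [4.0] * 30,
                          "intra_mm": [2.0] * 30})
        out = percentile_summary(t)
        assert out.loc[1, "inter_mm_p95"] == 4.0

    def test_sort_oracle_1_to_100(self):
        t = pd.DataFrame({"parameter": [1] * 100,
                          "inter_mm": np.arange(1.0, 101.0),
                          "intra_mm": np.arange(1.0, 101.0)})
        out = percentile_summary(t)
        assert out.loc[1, "inter_mm_p95"] == 95.0

    def test_order_statistic_convention(self):
        assert order_statistic_percentile(np.arange(1.0, 101.0), 0.95) == 95.0
        assert order_statistic_percentile(np.arange(1.0, 101.0), 0.025) == 3.0
        assert order_statistic_percentile(np.array([7.0]), 1.0) == 7.0

    def test_sampler_calibration_bands(self):
        from artdose.config import MotionConfig
        from artdose.synthetic_cohort import MotionModel, deviation_table

        model = MotionModel(MotionConfig())
        rng = np.random.default_rng(5)
        samples = model.sample(2000, rng)
        rows = []
        for i, s in enumerate(samples):
            for k in range(8):
                rows.append({"parameter": k + 1, "inter_mm": s.landmark_inter[k],
                             "intra_mm": s.landmark_intra[k]})
        out = percentile_summary(pd.DataFrame(rows))
        inter = out["inter_mm_p95"].to_numpy()
        intra = out["intra_mm_p95"].to_numpy()
        assert np.all(inter >= 6.0) and np.all(inter <= 12.0)
        assert np.all(intra >= 4.0) and np.all(intra <= 10.0)


class TestSignedRank:
    def test_all_positive_n10_exact(self):
        d = np.arange(1.0, 11.0)
        res = signed_rank_test(d)
        assert res.p_value == pytest.approx(2.0 / 1024.0, abs=1e-6)

    def test_symmetric_high_p(self):
        d = np.array([-2.0, -1.0, 1.0, 2.0])
        res = signed_rank_test(d)
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_degenerate(self):
        res = signed_rank_test(np.zeros(8))
        assert res.note is not None and "degenerate" in res.note

    def test_oracle_equivalence_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(6, 20))
            d = rng.normal(0.3, 1.0, size=n)
            d = np.round(d, 3)
            d = d[d != 0]
            if d.size < 6 or np.unique(np.abs(d)).size < d.size:
                continue
            res = signed_rank_test(d)
            ref = sps.wilcoxon(d, method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_oracle_equivalence_normal_approx(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            d = rng.normal(0.2, 1.0, size=60)
            res = signed_rank_test(d)
            ref = sps.wilcoxon(d, method="approx", correction=True)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)

    def test_full_enumeration_oracle_tiny(self):
        # brute-force the 2^8 sign patterns and compare
        rng = np.random.default_rng(3)
        d = np.round(rng.normal(0.5, 1.0, size=8), 2)
        d = d[d != 0]
        n = d.size
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [ranks[np.array(sign) == 1].sum()
              for sign in itertools.product([0, 1], repeat=n)]
        ws = np.array(ws)
        p_oracle = min(1.0, 2 * min((ws <= w_obs).mean(), (ws >= w_obs).mean()))
        res = signed_rank_test(d)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)


class TestRankSum:
    def test_tiny_enumeration(self):
        res = rank_sum_test(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert res.p_value == pytest.approx(1.0 / 3.0, abs=1e-9)

    def test_identical_multisets_midpoint(self):
        a = np.array([1.0, 2.0, 3.0])
        res = rank_sum_test(a, a.copy())
        assert res.statistic == pytest.approx(3 * (6 + 1) / 2.0)

    def test_oracle_equivalence_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            na, nb = int(rng.integers(3, 9)), int(rng.integers(3, 9))
            a = rng.normal(0, 1, na)
            b = rng.normal(0.5, 1, nb)
            res = rank_sum_test(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_oracle_equivalence_normal(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(0, 1, 40)
            b = rng.normal(0.3, 1, 35)
            res = rank_sum_test(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-6)


class TestScaleTests:
    def test_identical_samples_high_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        res = scale_test(a, a.copy(), "ansari_bradley")
        assert res.p_value > 0.9

    def test_hand_enumeration_oracle(self):
        # A = {1, 9}, B = {4, 5, 6}: enumerate the C(5,2) label assignments
        a = np.array([1.0, 9.0])
        b = np.array([4.0, 5.0, 6.0])
        res = scale_test(a, b, "ansari_bradley", center=True)
        ac = a - np.median(a)
        bc = b - np.median(b)
        pooled = np.concatenate([ac, bc])
        ranks = sps.rankdata(pooled)
        scores = np.minimum(ranks, len(pooled) + 1 - ranks)
        obs = scores[:2].sum()
        stats = [scores[list(pair)].sum()
                 for pair in itertools.combinations(range(5), 2)]
        stats = np.array(stats)
        p_oracle = min(1.0, 2 * min((stats <= obs).mean(), (stats >= obs).mean()))
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_ansari_matches_scipy_exact(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            na, nb = int(rng.integers(4, 9)), int(rng.integers(4, 9))
            a = rng.normal(0, 1, na)
            b = rng.normal(0, 2, nb)
            res = scale_test(a, b, "ansari_bradley", center=False)
            ref = sps.ansari(a, b)
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    def test_ansari_matches_scipy_normal(self):
        # scipy only takes its normal path once one sample reaches 55
        rng = np.random.default_rng(7)
        a = rng.normal(0, 1, 60)
        b = rng.normal(0, 2, 58)
        res = scale_test(a, b, "ansari_bradley", center=False)
        ref = sps.ansari(a, b)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-3)

    def test_mood_matches_scipy(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 2, 28)
        res = scale_test(a, b, "mood", center=False)
        z, p = sps.mood(a, b)
        assert res.p_value == pytest.approx(p, rel=1e-6)

    def test_mood_exact_enumeration(self):
        a = np.array([1.0, 9.0])
        b = np.array([4.0, 5.0, 6.0])
        res = scale_test(a, b, "mood", center=False)
        pooled = np.concatenate([a, b])
        ranks = sps.rankdata(pooled)
        n = 5
        scores = (ranks - (n + 1) / 2) ** 2
        obs = scores[:2].sum()
        stats = np.array([scores[list(pair)].sum()
                          for pair in itertools.combinations(range(5), 2)])
        p_oracle = min(1.0, 2 * min((stats <= obs).mean(), (stats >= obs).mean()))
        assert res.p_value == pytest.approx(p_oracle, abs=1e-9)

    def test_power_against_triple_spread(self):
        rng = np.random.default_rng(9)
        rejected = 0
        n_sims = 500
        for _ in range(n_sims):
            a = rng.normal(0, 1, 50)
            b = rng.normal(0, 3, 50)
            if scale_test(a, b, "ansari_bradley").p_value < 0.05:
                rejected += 1
        assert rejected / n_sims > 0.8

    def test_type_i_error_band(self):
        # null calibration at the 23 + 23 split scale
        rng = np.random.default_rng(10)
        n_sims = 2000
        rejections = 0
        for _ in range(n_sims):
            a = rng.normal(0, 1, 23)
            b = rng.normal(0, 1, 23)
            if scale_test(a, b, "ansari_bradley").p_value < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_sims <= 0.07

    def test_tie_warning(self):
        a = np.array([1.0, 1.0, 1.0, 2.0])
        b = np.array([1.0, 1.0, 1.0, 3.0])
        res = scale_test(a, b, "ansari_bradley", center=False)
        assert res.note is not None


class TestCorrelations:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        res = correlations(x, x, "pearson")
        assert res.estimate == pytest.approx(1.0)

    def test_perfect_negative_spearman(self):
        x = np.arange(10.0)
        y = np.exp(-x)  # monotone decreasing, nonlinear
        res = correlations(x, y, "spearman")
        assert res.estimate == pytest.approx(-1.0)

    def test_oracle_equivalence(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(size=30)
            y = 0.5 * x + rng.normal(size=30)
            rp = correlations(x, y, "pearson")
            ref = sps.pearsonr(x, y)
            assert rp.estimate == pytest.approx(ref.statistic, abs=1e-9)
            assert rp.p_value == pytest.approx(ref.pvalue, abs=1e-9)
            rs = correlations(x, y, "spearman")
            ref_s = sps.spearmanr(x, y)
            assert rs.estimate == pytest.approx(ref_s.statistic, abs=1e-9)

    def test_fisher_ci_contains_estimate(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=50)
        y = 0.7 * x + rng.normal(size=50)
        res = correlations(x, y)
        assert res.ci[0] < res.estimate < res.ci[1]

    def test_min_n(self):
        with pytest.raises(ValueError):
            correlations(np.arange(4.0), np.arange(4.0))


class TestEcdf:
    def test_constant_single_step(self):
        xs, fs = ecdf(np.full(5, 3.0))
        assert xs.tolist() == [3.0]
        assert fs.tolist() == [1.0]

    def test_value_at_max_is_one(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=40)
        xs, fs = ecdf(v)
        assert fs[-1] == 1.0
        assert np.all(np.diff(fs) > 0)

    def test_kolmogorov_distance_uniform(self):
        rng = np.random.default_rng(14)
        n = 100
        bound = 1.36 / np.sqrt(n)
        within = 0
        n_sims = 200
        for _ in range(n_sims):
            v = rng.uniform(size=n)
            xs, fs = ecdf(v)
            ks = np.max(np.maximum(np.abs(fs - xs),
                                   np.abs(np.concatenate([[0.0], fs[:-1]]) - xs)))
            within += ks < bound
        assert 0.88 <= within / n_sims <= 1.0


class TestPercentileWithCI:
    def test_sort_oracle_1_to_100(self):
        est, ci, note = percentile_with_ci(np.arange(1.0, 101.0), q=0.025)
        assert est == 3.0
        assert "order-statistic" in note

    def test_constant_zero_width(self):
        est, ci, _ = percentile_with_ci(np.full(50, 7.0), q=0.025)
        assert est == 7.0
        assert ci == (7.0, 7.0)

    def test_coverage_monte_carlo(self):
        rng = np.random.default_rng(15)
        q, true_q = 0.1, sps.norm.ppf(0.1)  # regime where nominal coverage is attainable
        n_sims, n = 1000, 100
        covered = 0
        for _ in range(n_sims):
            v = rng.normal(size=n)
            _, (lo, hi), _ = percentile_with_ci(v, q=q)
            covered += lo <= true_q <= hi
        assert covered / n_sims >= 0.93

    def test_bootstrap_seeded_reproducible(self):
        rng = np.random.default_rng(16)
        v = rng.normal(size=60)
        r1 = percentile_with_ci(v, q=0.1, method="bootstrap", seed=3)
        r2 = percentile_with_ci(v, q=0.1, method="bootstrap", seed=3)
        assert r1 == r2

    def test_min_n(self):
        with pytest.raises(ValueError):
            percentile_with_ci(np.arange(10.0))


class TestRankAdaptationFit:
    def test_perfect_linear(self):
        d = np.linspace(-5, 5, 20)
        r = (d - d.min()) / (d.max() - d.min())
        fit = rank_adaptation_fit(r, d)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["p_value"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_slope(self):
        rng = np.random.default_rng(17)
        d = rng.normal(size=200)
        r = np.full(200, 0.5) + rng.uniform(-0.01, 0.01, 200)
        fit = rank_adaptation_fit(np.clip(r, 0, 1), d)
        assert fit["r_squared"] < 0.05

    def test_normal_equations_hand_example(self):
        # 5-point example solved by the closed-form normal equations
        d = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        r = np.array([0.1, 0.3, 0.35, 0.6, 0.9])
        n = 5
        sx, sy = d.sum(), r.sum()
        sxx, sxy = (d * d).sum(), (d * r).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        fit = rank_adaptation_fit(r, d)
        assert fit["slope"] == pytest.approx(slope, abs=1e-12)
        assert fit["intercept"] == pytest.approx(intercept, abs=1e-12)

    def test_quadratic_term(self):
        d = np.linspace(-3, 3, 30)
        r = (d ** 2) / 9.0
        fit_lin = rank_adaptation_fit(r, d)
        fit_quad = rank_adaptation_fit(r, d, quadratic=True)
        assert fit_quad["r_squared"] > 0.99 > fit_lin["r_squared"] + 0.5


class TestHolm:
    def test_monotone_and_bounded(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        assert np.all(adj <= 1.0)
        assert adj[0] == pytest.approx(0.04)
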