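import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from gutmr import (EstimationError, EstimatorConfig, egger, estimate_all, ivw,
                   mode_estimate, mr_presso, wald_ratio, weighted_median)

from conftest import make_harmonized, simulate_harmonized


class TestWaldRatio:
    def test_formula(self, harmonized_factory):
        (h,) = harmonized_factory([0.1], [0.02], [0.05], [0.01])
        est = wald_ratio(h)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_null_outcome_effect(self, harmonized_factory):
        (h,) = harmonized_factory([0.1], [0.02], [0.0], [0.01])
        est = wald_ratio(h)
        assert est.beta == 0.0
        assert est.pvalue == pytest.approx(1.0)

    def test_zero_exposure_effect_rejected(self, harmonized_factory):
        (h,) = harmonized_factory([0.0], [0.02], [0.05], [0.01])
        with pytest.raises(EstimationError):
            wald_ratio(h)

    def test_first_order_se_matches_monte_carlo(self, harmonized_factory):
        # the first-order delta method treats beta_exp as fixed
        (h,) = harmonized_factory([0.1], [1e-12], [0.05], [0.01])
        est = wald_ratio(h)
        rng = np.random.default_rng(31)
        draws = rng.normal(0.05, 0.01, 100_000) / 0.1
        assert est.se == pytest.approx(np.std(draws), rel=0.02)

    def test_binary_outcome_exponentiates(self, harmonized_factory):
        (h,) = harmonized_factory([0.1], [0.02], [0.05], [0.01])
        est = wald_ratio(h, binary=True)
        assert est.or_ == pytest.approx(np.exp(est.beta))


class TestIVW:
    def test_identical_ratios_give_zero_q(self, harmonized_factory):
        insts = harmonized_factory([0.1, 0.2], [0.02, 0.02], [0.07, 0.14],
                                   [0.01, 0.01])
        est, het = ivw(insts)
        assert est.beta == pytest.approx(0.7)
        assert het.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_duplicated_instrument_equals_wald(self, harmonized_factory):
        insts = harmonized_factory([0.1, 0.1], [0.02, 0.02], [0.05, 0.05],
                                   [0.01, 0.01])
        est, _ = ivw(insts, model="fixed")
        wald = wald_ratio(insts[0])
        assert est.beta == pytest.approx(wald.beta)

    def test_matches_bruteforce_weighted_mean_of_ratios(self, harmonized_sim):
        insts, _ = simulate_harmonized(n_snps=10, theta=0.1, seed=32)
        est, _ = ivw(insts)
        # independent route: inverse-variance-weighted mean of per-SNP Wald
        # ratios with first-order weights beta_x^2 / se_y^2
        num = den = 0.0
        for h in insts:
            ratio = h.beta_out / h.beta_exp
            w = h.beta_exp ** 2 / h.se_out ** 2
            num += w * ratio
            den += w
        assert est.beta == pytest.approx(num / den, abs=1e-10)

    def test_single_instrument_directed_to_wald(self, harmonized_factory):
        insts = harmonized_factory([0.1], [0.02], [0.05], [0.01])
        with pytest.raises(EstimationError):
            ivw(insts)

    def test_random_effects_never_tighter_than_fixed(self, harmonized_sim):
        insts, _ = simulate_harmonized(n_snps=20, theta=0.1, seed=33,
                                       pleiotropy_mode="balanced",
                                       pleiotropy_sd=0.01)
        fixed, _ = ivw(insts, model="fixed")
        random_, _ = ivw(insts, model="multiplicative_random")
        assert random_.se >= fixed.se
        assert random_.beta == pytest.approx(fixed.beta)

    def test_q_df_is_j_minus_one(self, harmonized_sim):
        insts, _ = simulate_harmonized(n_snps=8, theta=0.0, seed=34)
        _, het = ivw(insts)
        assert het.df == 7


class TestEgger:
    def test_exact_fit_recovers_slope_and_intercept(self, harmonized_factory):
        bx = np.array([0.1, 0.15, 0.2, 0.3])
        by = 0.1 * bx  # intercept 0, slope 0.1, no noise
        insts = make_harmonized(bx, [0.02] * 4, by, [0.01] * 4)
        est, het = egger(insts)
        assert est.beta == pytest.approx(0.1, abs=1e-12)
        assert est.intercept == pytest.approx(0.0, abs=1e-12)
        assert het.q_stat == pytest.approx(0.0, abs=1e-16)
        assert het.df == 2

    def test_constant_pleiotropy_lands_in_intercept(self, harmonized_factory):
        bx = np.array([0.1, 0.15, 0.2, 0.3, 0.25])
        by = 0.1 * bx + 0.02
        insts = make_harmonized(bx, [0.02] * 5, by, [0.01] * 5)
        est, _ = egger(insts)
        assert est.intercept == pytest.approx(0.02, abs=1e-12)
        assert est.beta == pytest.approx(0.1, abs=1e-12)

    def test_directional_pleiotropy_recovered_on_average(self):
        # pleiotropy is directional relative to the exposure-increasing
        # allele, so instruments are oriented before the shift is injected
        from gutmr import HarmonizedInstrument
        rng = np.random.default_rng(35)
        intercepts = slopes = 0.0
        n_rep = 500
        for s in range(n_rep):
            insts, _ = simulate_harmonized(n_snps=30, theta=0.1, rng=rng, seed=0)
            shifted = []
            for h in insts:
                sgn = -1.0 if h.beta_exp < 0 else 1.0
                shifted.append(HarmonizedInstrument(
                    h.variant_id, sgn * h.beta_exp, h.se_exp,
                    sgn * h.beta_out + 0.02, h.se_out))
            est, _ = egger(shifted)
            intercepts += est.intercept
            slopes += est.beta
        assert intercepts / n_rep == pytest.approx(0.02, abs=0.002)
        assert slopes / n_rep == pytest.approx(0.1, abs=0.01)

    def test_too_few_instruments_rejected(self, harmonized_factory):
        insts = harmonized_factory([0.1, 0.2], [0.02] * 2, [0.05, 0.1], [0.01] * 2)
        with pytest.raises(EstimationError):
            egger(insts)

    def test_invariant_to_allele_recoding(self, harmonized_sim):
        insts, _ = simulate_harmonized(n_snps=10, theta=0.1, seed=36)
        est1, _ = egger(insts)
        # recode half the instruments to the opposite allele
        from gutmr import HarmonizedInstrument
        flipped = [
            HarmonizedInstrument(h.variant_id, -h.beta_exp, h.se_exp,
                                 -h.beta_out, h.se_out) if i % 2 == 0 else h
            for i, h in enumerate(insts)]
        est2, _ = egger(flipped)
        assert est2.beta == pytest.approx(est1.beta, abs=1e-12)
        assert est2.intercept == pytest.approx(est1.intercept, abs=1e-12)


class TestWeightedMedian:
    def test_median_of_equal_weight_odd_set(self, harmonized_factory):
        insts = harmonized_factory([1.0, 1.0, 1.0], [0.02] * 3,
                                   [0.4, 0.5, 0.9], [0.1] * 3)
        est = weighted_median(insts, n_boot=200, seed=1)
        assert est.beta == pytest.approx(0.5)

    def test_dominant_weight_pulls_estimate(self, harmonized_factory):
        # one instrument carries ~98% of the weight
        insts = harmonized_factory([1.0, 0.1, 0.1], [0.02] * 3,
                                   [0.7, 0.02, 0.05], [0.1] * 3)
        est = weighted_median(insts, n_boot=200, seed=2)
        assert est.beta == pytest.approx(0.7, abs=0.05)

    def test_interpolation_convention(self, harmonized_factory):
        # independent brute-force implementation of the
        # p_j = (S_j - w_j/2) / S_J rule with linear interpolation
        rng = np.random.default_rng(37)
        bx = rng.uniform(0.1, 0.5, 7)
        by = rng.normal(0.1 * bx, 0.02)
        sy = rng.uniform(0.01, 0.05, 7)
        insts = make_harmonized(bx, [0.02] * 7, by, sy)
        est = weighted_median(insts, n_boot=200, seed=3)
        ratios = by / bx
        weights = bx ** 2 / sy ** 2
        order = np.argsort(ratios)
        r, w = ratios[order], weights[order]
        s = np.cumsum(w)
        p = (s - w / 2) / s[-1]
        k = np.searchsorted(p, 0.5, side="right") - 1
        expected = r[k] + (r[k + 1] - r[k]) * (0.5 - p[k]) / (p[k + 1] - p[k])
        assert est.beta == pytest.approx(expected, abs=1e-12)

    @given(st.lists(st.tuples(st.floats(0.05, 0.5), st.floats(-0.2, 0.2),
                              st.floats(0.005, 0.05)),
                    min_size=3, max_size=15))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_estimate_bounded_by_ratio_range(self, rows):
        bx = np.array([r[0] for r in rows])
        by = np.array([r[1] for r in rows])
        sy = np.array([r[2] for r in rows])
        insts = make_harmonized(bx, [0.02] * len(rows), by, sy)
        est = weighted_median(insts, n_boot=100, seed=0)
        ratios = by / bx
        assert ratios.min() - 1e-12 <= est.beta <= ratios.max() + 1e-12

    def test_breakdown_under_minority_pleiotropy(self):
        # pleiotropy on <50% of weight: the median stays near the truth
        from gutmr import HarmonizedInstrument
        rng = np.random.default_rng(38)
        ok = 0
        n_rep = 200
        for s in range(n_rep):
            insts, truth = simulate_harmonized(n_snps=20, theta=0.1, rng=rng, seed=0)
            w = np.array([h.beta_exp ** 2 / h.se_out ** 2 for h in insts])
            share = w / w.sum()
            # contaminate instruments carrying ~45% of the total weight
            order = np.argsort(share)
            cum = np.cumsum(share[order])
            bad = set(order[: int(np.searchsorted(cum, 0.45))].tolist())
            biased = [
                HarmonizedInstrument(h.variant_id, h.beta_exp, h.se_exp,
                                     h.beta_out + 0.5 * h.beta_exp, h.se_out)
                if i in bad else h
                for i, h in enumerate(insts)]
            est = weighted_median(biased, n_boot=200, seed=s)
            if abs(est.beta - 0.1) < 2 * est.se:
                ok += 1
        assert ok >= 0.6 * n_rep  # far above what the contaminated IVW attains


class TestModeEstimators:
    def test_degenerate_identical_ratios(self, harmonized_factory):
        insts = harmonized_factory([1.0, 1.0, 1.0], [0.02] * 3,
                                   [0.6, 0.6, 0.6], [0.1] * 3)
        est = mode_estimate(insts, weighted=False, n_boot=200, seed=4)
        assert est.beta == pytest.approx(0.6)

    def test_majority_cluster_wins(self, harmonized_factory):
        insts = harmonized_factory([1.0] * 4, [0.02] * 4,
                                   [0.1, 0.1, 0.1, 0.9], [0.1] * 4)
        est = mode_estimate(insts, weighted=False, n_boot=200, seed=5)
        assert est.beta == pytest.approx(0.1, abs=0.05)

    def test_argmax_matches_dense_grid_oracle(self, harmonized_factory):
        rng = np.random.default_rng(39)
        bx = rng.uniform(0.1, 0.5, 8)
        by = rng.normal(0.1 * bx, 0.05)
        sy = rng.uniform(0.01, 0.05, 8)
        insts = make_harmonized(bx, [0.02] * 8, by, sy)
        est = mode_estimate(insts, weighted=True, n_boot=200, seed=6,
                            grid_size=2001)
        ratios = by / bx
        w = (np.abs(bx) / sy) ** 2
        w = w / w.sum()
        sd = np.std(ratios, ddof=1)
        iqr = np.subtract(*np.percentile(ratios, [75, 25]))
        s = min(sd, iqr / 1.349) if iqr > 0 else sd
        h = 0.9 * s * 8 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, 20_001)
        dens = (w[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
        expected = grid[np.argmax(dens)]
        assert est.beta == pytest.approx(expected, abs=2 * (grid[1] - grid[0]) + 1e-3)


class TestMRPresso:
    def test_injected_outlier_flagged(self, harmonized_sim):
        insts, _ = simulate_harmonized(n_snps=20, theta=0.1, seed=40)
        from gutmr import HarmonizedInstrument
        h0 = insts[0]
        insts[0] = HarmonizedInstrument(h0.variant_id, h0.beta_exp, h0.se_exp,
                                        h0.beta_out + 10 * h0.se_out, h0.se_out)
        res = mr_presso(insts, n_sim=1000, seed=41)
        assert h0.variant_id in res.outlier_ids
        assert res.global_p <= 0.05
        assert res.corrected.nsnp == 20 - len(res.outlier_ids)
        assert res.distortion_p == res.distortion_p  # defined when outliers exist

    def test_clean_data_keeps_all_instruments(self, harmonized_sim):
        insts, _ = simulate_harmonized(n_snps=20, theta=0.1, seed=42)
        res = mr_presso(insts, n_sim=1000, seed=43)
        assert res.outlier_ids == []
        assert res.corrected.beta == pytest.approx(res.raw.beta)
        assert 1 / 1001 <= res.global_p <= 1.0

    def test_preconditions(self, harmonized_factory):
        insts = harmonized_factory([0.1] * 3, [0.02] * 3, [0.05] * 3, [0.01] * 3)
        with pytest.raises(EstimationError):
            mr_presso(insts, n_sim=1000)


class TestDispatchAndInvariance:
    @pytest.mark.parametrize("n_snps,methods", [
        (1, {"wald"}),
        (2, {"ivw"}),
        (3, {"ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"}),
        (10, {"ivw", "egger", "weighted_median", "simple_mode", "weighted_mode",
              "presso_corrected"}),
    ])
    def test_method_battery_dispatch(self, n_snps, methods):
        insts, _ = simulate_harmonized(n_snps=n_snps, theta=0.1, seed=44)
        cfg = EstimatorConfig(n_boot=200, n_sim=1000)
        ests = estimate_all(insts, config=cfg)
        assert {e.method for e in ests} == methods

    def test_exposure_rescaling_divides_estimates(self):
        from gutmr import HarmonizedInstrument
        insts, _ = simulate_harmonized(n_snps=10, theta=0.1, seed=45)
        c = 2.5
        scaled = [HarmonizedInstrument(h.variant_id, c * h.beta_exp, c * h.se_exp,
                                       h.beta_out, h.se_out) for h in insts]
        cfg = EstimatorConfig(n_boot=400, n_sim=1000)
        for e1, e2 in zip(estimate_all(insts, config=cfg),
                          estimate_all(scaled, config=cfg)):
            tol = 1e-10 if e1.method in ("ivw", "egger", "presso_corrected") \
                else max(4 * e1.se / c, 0.02)
            assert e2.beta == pytest.approx(e1.beta / c, abs=tol)

    def test_multi_snp_estimators_recover_truth(self):
        # theta in {0, 0.08, 0.14}: every estimator within 2 SE most of the time
        rng = np.random.default_rng(46)
        methods = ["ivw", "egger", "weighted_median", "weighted_mode"]
        hits = {m: 0 for m in methods}
        n_rep = 25
        thetas = [0.0, 0.08, 0.14]
        for theta in thetas:
            for _ in range(n_rep):
                insts, _ = simulate_harmonized(n_snps=30, theta=theta, rng=rng, seed=0)
                est_i, _ = ivw(insts)
                est_e, _ = egger(insts)
                est_m = weighted_median(insts, n_boot=200, seed=1)
                est_o = mode_estimate(insts, weighted=True, n_boot=200, seed=2)
                for m, e in zip(methods, (est_i, est_e, est_m, est_o)):
                    if abs(e.beta - theta) < 2 * e.se:
                        hits[m] += 1
        for m in methods:
            assert hits[m] / (n_rep * len(thetas)) >= 0.85

    def test_q_zero_iff_ratios_equal(self, harmonized_factory):
        insts = harmonized_factory([0.1, 0.2, 0.4], [0.02] * 3,
                                   [0.03, 0.06, 0.12], [0.01] * 3)
        _, het = ivw(insts)
        assert het.q_stat == pytest.approx(0.0, abs=1e-18)
        bumped = harmonized_factory([0.1, 0.2, 0.4], [0.02] * 3,
                                    [0.03, 0.06, 0.13], [0.01] * 3)
        _, het2 = ivw(bumped)
        assert het2.q_stat > 0
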