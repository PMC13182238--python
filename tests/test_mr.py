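"""MR estimator correctness against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from tests.conftest import make_instruments, make_pair
from tiermr import mr
from tiermr.mr import (
    MRError,
    cochran_q,
    ivw,
    mr_egger,
    outlier_screen,
    run_mr,
    wald_ratio,
    weighted_median,
)


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        est = wald_ratio(make_pair(beta_exp=0.5, beta_out=0.25, se_out=0.1))
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_null_effect(self):
        est = wald_ratio(make_pair(beta_exp=1.0, beta_out=0.0, se_out=0.1))
        assert est.beta == 0.0
        assert est.pval == pytest.approx(1.0)

    def test_zero_exposure_raises(self):
        with pytest.raises(MRError):
            wald_ratio(make_pair(beta_exp=0.0))

    def test_second_order_matches_numeric_delta_oracle(self):
        """Second-order se equals gradient-propagation with numeric gradients."""
        bx, by, sx, sy = 0.5, 0.25, 0.05, 0.1
        est = wald_ratio(make_pair(beta_exp=bx, se_exp=sx, beta_out=by, se_out=sy),
                         second_order=True)
        f = lambda x, y: y / x
        h = 1e-6
        gx = (f(bx + h, by) - f(bx - h, by)) / (2 * h)
        gy = (f(bx, by + h) - f(bx, by - h)) / (2 * h)
        se_oracle = np.sqrt(gx**2 * sx**2 + gy**2 * sy**2)
        assert est.se == pytest.approx(float(se_oracle), rel=1e-5)


class TestIVW:
    def test_equal_ratios_give_common_value(self):
        inst = make_instruments([0.5, 0.4], [0.01, 0.01], [0.25, 0.20], [0.1, 0.1])
        est = ivw(inst, "fixed")
        assert est.beta == pytest.approx(0.5, abs=1e-12)
        assert est.se == pytest.approx(np.sqrt(0.01 / 0.41))

    def test_matches_zero_intercept_wls_oracle(self, random_instruments):
        import statsmodels.api as sm

        bx, _, by, sy = random_instruments.beta_arrays()
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        est = ivw(random_instruments, "fixed")
        assert est.beta == pytest.approx(float(fit.params[0]), rel=1e-10)
        # fixed-effect IVW se is the unscaled WLS se
        unscaled = float(fit.bse[0] / np.sqrt(fit.scale))
        assert est.se == pytest.approx(unscaled, rel=1e-10)

    def test_single_pair_formula_equals_wald(self):
        pair = make_pair(beta_exp=0.4, beta_out=0.1, se_out=0.05)
        w = 1 / pair.se_out**2
        beta = (w * pair.beta_exp * pair.beta_out) / (w * pair.beta_exp**2)
        se = np.sqrt(1 / (w * pair.beta_exp**2))
        est = wald_ratio(pair)
        assert beta == pytest.approx(est.beta)
        assert se == pytest.approx(est.se)

    def test_random_se_never_below_fixed(self, rng):
        for seed in range(10):
            g = np.random.default_rng(seed)
            m = 8
            inst = make_instruments(g.uniform(0.05, 0.2, m), np.full(m, 0.01),
                                    g.normal(0.02, 0.05, m), g.uniform(0.01, 0.05, m))
            assert ivw(inst, "random").se >= ivw(inst, "fixed").se - 1e-15

    def test_requires_two_instruments(self):
        inst = make_instruments([0.5], [0.01], [0.25], [0.1])
        with pytest.raises(MRError):
            ivw(inst)

    def test_or_ci_formatting(self):
        """Log-odds 0.0907 (se 0.0340) maps to OR 1.095, 95% CI 1.024-1.170."""
        est = mr.MREstimate("ivw_fixed", 0.0907, 0.0340, 0.01, 10)
        assert est.or_ == pytest.approx(1.095, abs=5e-4)
        assert est.ci_low == pytest.approx(1.024, abs=5e-4)
        assert est.ci_high == pytest.approx(1.170, abs=5e-4)


class TestEgger:
    def test_line_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inst = make_instruments(bx, np.full(4, 0.01), 0.5 * bx, np.full(4, 0.02))
        slope, intercept = mr_egger(inst)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)
        assert intercept.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_appears_in_intercept(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        inst = make_instruments(bx, np.full(4, 0.01), 0.5 * bx + 0.05, np.full(4, 0.02))
        slope, intercept = mr_egger(inst)
        assert intercept.egger_intercept == pytest.approx(0.05, abs=1e-10)
        assert slope.beta == pytest.approx(0.5, abs=1e-10)

    def test_matches_normal_equations_oracle(self, random_instruments):
        bx, _, by, sy = random_instruments.beta_arrays()
        sign = np.where(bx < 0, -1.0, 1.0)
        bx, by = bx * sign, by * sign
        w = 1 / sy**2
        X = np.column_stack([np.ones_like(bx), bx])
        xtwx = X.T @ (w[:, None] * X)
        coef = np.linalg.solve(xtwx, X.T @ (w * by))
        resid = by - X @ coef
        df = len(bx) - 2
        sigma2 = float(resid @ (w * resid)) / df
        cov = sigma2 * np.linalg.inv(xtwx)
        slope, intercept = mr_egger(random_instruments)
        assert intercept.egger_intercept == pytest.approx(coef[0], rel=1e-8)
        assert slope.beta == pytest.approx(coef[1], rel=1e-8)
        assert intercept.intercept_se == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-6)
        assert slope.se == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-6)

    def test_requires_three(self):
        inst = make_instruments([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(MRError):
            mr_egger(inst)


def _wm_oracle(ratios, weights):
    """Cumulative-weight scan with interpolation, written independently."""
    order = np.argsort(ratios)
    r, w = np.asarray(ratios)[order], np.asarray(weights)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    for k in range(len(r) - 1):
        if s[k] <= 0.5 <= s[k + 1]:
            return r[k] + (0.5 - s[k]) / (s[k + 1] - s[k]) * (r[k + 1] - r[k])
    return r[0] if 0.5 < s[0] else r[-1]


class TestWeightedMedian:
    def test_equal_weight_middle_element(self):
        bx = np.array([1.0, 1.0, 1.0])
        by = np.array([0.2, 0.5, 0.9])
        inst = make_instruments(bx, np.full(3, 1e-9), by, np.full(3, 0.1))
        est = weighted_median(inst, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5, abs=1e-6)

    def test_identical_ratios_stable(self):
        bx = np.array([0.1, 0.2, 0.3])
        inst = make_instruments(bx, np.full(3, 1e-6), 0.4 * bx, np.full(3, 1e-6))
        est = weighted_median(inst, n_boot=200, seed=2)
        assert est.beta == pytest.approx(0.4, abs=1e-4)
        assert est.se < 1e-3

    def test_matches_cumulative_scan_oracle(self, rng):
        m = 5
        bx = rng.uniform(0.1, 0.3, m)
        by = rng.normal(0.2 * bx, 0.02)
        sx = np.full(m, 0.01)
        sy = rng.uniform(0.01, 0.03, m)
        inst = make_instruments(bx, sx, by, sy)
        est = weighted_median(inst, n_boot=10, seed=3)
        ratios = by / bx
        var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
        assert est.beta == pytest.approx(_wm_oracle(ratios, 1 / var), rel=1e-10)

    def test_majority_valid_recovers_truth(self):
        """A minority of invalid instruments cannot drag the estimate away."""
        g = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            m = 11
            lam = g.uniform(0.1, 0.2, m)
            sx = np.full(m, 0.002)
            sy = np.full(m, 0.004)
            offset = np.zeros(m)
            offset[:4] = 0.08  # 4 of 11 invalid
            bx = g.normal(lam, sx)
            by = g.normal(0.25 * lam + offset, sy)
            est = weighted_median(make_instruments(bx, sx, by, sy), n_boot=200, seed=5)
            if abs(est.beta - 0.25) < 1.96 * est.se + 0.02:
                hits += 1
        assert hits >= 17


class TestCochranQ:
    def test_equal_ratios_zero(self):
        bx = np.array([0.1, 0.2])
        inst = make_instruments(bx, np.full(2, 1e-9), 0.5 * bx, np.full(2, 0.1))
        het = cochran_q(inst, 0.5)
        assert het.Q == pytest.approx(0.0, abs=1e-10)
        assert het.pval == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # unit weights: ratios 0 and 1, reference 0.5 -> Q = 0.25 + 0.25
        inst = make_instruments([1.0, 1.0], [1e-9, 1e-9], [0.0, 1.0], [1.0, 1.0])
        het = cochran_q(inst, 0.5)
        assert het.Q == pytest.approx(0.5, rel=1e-6)
        assert het.df == 1

    def test_reorder_invariant(self, random_instruments):
        q1 = cochran_q(random_instruments, 0.3).Q
        rev = make_instruments(*[a[::-1] for a in random_instruments.beta_arrays()])
        assert cochran_q(rev, 0.3).Q == pytest.approx(q1)


class TestOutlierScreen:
    def test_planted_outlier_flagged(self):
        g = np.random.default_rng(5)
        m = 10
        lam = g.uniform(0.1, 0.2, m)
        sx = np.full(m, 0.002)
        sy = np.full(m, 0.01)
        bx = g.normal(lam, sx)
        by = g.normal(0.3 * lam, sy)
        by[4] += 10 * sy[4]
        inst = make_instruments(bx, sx, by, sy)
        res = outlier_screen(inst, n_sim=400, seed=9)
        assert "rs5" in res.outlier_ids
        assert res.global_pval < 0.05

    def test_homogeneous_usually_clean(self):
        g = np.random.default_rng(6)
        flagged = 0
        for _ in range(10):
            m = 8
            lam = g.uniform(0.1, 0.2, m)
            bx = g.normal(lam, 0.002)
            by = g.normal(0.3 * lam, 0.01)
            inst = make_instruments(bx, np.full(m, 0.002), by, np.full(m, 0.01))
            res = outlier_screen(inst, n_sim=200, seed=13)
            flagged += len(res.outlier_ids) > 0
        assert flagged <= 2

    def test_three_instruments_no_flagging(self):
        inst = make_instruments([0.1, 0.2, 0.3], [0.01] * 3, [0.05, 0.1, 0.15], [0.02] * 3)
        with pytest.warns(UserWarning, match="fewer than 4"):
            res = outlier_screen(inst, n_sim=100, seed=1)
        assert res.outlier_ids == []
        assert res.global_pval is not None


class TestRunMR:
    def test_single_instrument_uses_wald(self):
        inst = make_instruments([0.5], [0.01], [0.25], [0.1])
        report = run_mr(inst)
        assert report.primary.method == "wald_ratio"
        assert report.sensitivity == []

    def test_two_instruments_ivw_only(self):
        inst = make_instruments([0.5, 0.4], [0.01] * 2, [0.25, 0.2], [0.1] * 2)
        report = run_mr(inst)
        assert report.primary.method.startswith("ivw")
        assert report.sensitivity == []

    def test_many_instruments_full_report(self, random_instruments):
        report = run_mr(random_instruments, n_boot=50, n_sim=100, seed=2)
        assert report.primary.method.startswith("ivw")
        assert {e.method for e in report.sensitivity} == {"egger_slope", "weighted_median"}
        assert report.heterogeneity is not None
        assert report.pleiotropy.egger_intercept is not None
        frame = report.to_frame()
        assert len(frame) == 3
        assert set(frame["method"]) == {report.primary.method, "egger_slope", "weighted_median"}

    def test_empty_raises(self):
        from tiermr.sumstats import InstrumentSet

        with pytest.raises(MRError):
            run_mr(InstrumentSet("x", "y", []))
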