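"""MR estimators against independent oracles and algebraic identities."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from pqtlmr.instruments import Instrument
from pqtlmr.mr import (
    bonferroni_threshold,
    cochran_q,
    format_or_ci,
    ivw,
    mr_egger,
    smr_test,
    wald_ratio,
    weighted_median,
)

from conftest import make_instrument_set


def _inst(bx, by, sy, sx=0.005):
    return Instrument(snp_id="rs1", beta_x=bx, se_x=sx, eaf=0.3, n_x=5e4,
                      p_x=1e-12, beta_y=by, se_y=sy)


class TestWaldRatio:
    def test_arithmetic(self):
        r = wald_ratio(_inst(0.5, 0.1, 0.02))
        assert r.beta == pytest.approx(0.2)
        assert r.se == pytest.approx(0.04)

    def test_null_outcome(self):
        r = wald_ratio(_inst(0.5, 0.0, 0.02))
        assert r.beta == 0
        assert r.p == pytest.approx(1.0)

    def test_zero_exposure_errors(self):
        with pytest.raises(ValueError):
            wald_ratio(_inst(0.0, 0.1, 0.02))

    def test_or_ci_display(self):
        # independent exp-transform oracle for the display convention
        beta, se = 0.2070, 0.0427
        expect = (
            f"{np.exp(beta):.2f} ({np.exp(beta - 1.96 * se):.2f}"
            f"–{np.exp(beta + 1.96 * se):.2f})"
        )
        assert format_or_ci(beta, se) == expect
        assert expect.startswith("1.23 (1.13")


class TestIVW:
    def test_single_instrument_reduces_to_wald(self):
        s = make_instrument_set([0.4], [0.03], by=[0.09])
        w = wald_ratio(s.instruments[0])
        r = ivw(s)
        assert r.beta == pytest.approx(w.beta, rel=1e-15)
        assert r.se == pytest.approx(w.se, rel=1e-15)

    def test_equal_ratios_give_ratio_and_zero_q(self):
        s = make_instrument_set([0.2, 0.4, 0.6], [0.02, 0.02, 0.02], theta=0.2)
        assert ivw(s).beta == pytest.approx(0.2)
        assert cochran_q(s).q == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_through_origin(self):
        """IVW equals weighted least squares solved by explicit normal
        equations (and statsmodels WLS), to 1e-10 relative."""
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.1, 0.5, 8)
        sy = rng.uniform(0.01, 0.05, 8)
        by = 0.2 * bx + rng.normal(0, sy)
        s = make_instrument_set(bx, sy, by=by)
        r = ivw(s, model="fixed")
        beta_ne = np.sum(bx * by / sy**2) / np.sum(bx**2 / sy**2)
        assert r.beta == pytest.approx(beta_ne, rel=1e-12)
        fit = sm.WLS(by, bx[:, None], weights=1 / sy**2).fit()
        assert r.beta == pytest.approx(fit.params[0], rel=1e-10)

    def test_multiplicative_random_never_shrinks_se(self):
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.1, 0.5, 10)
        sy = np.full(10, 0.02)
        by = 0.2 * bx + rng.normal(0, 5 * sy)  # overdispersed
        s = make_instrument_set(bx, sy, by=by)
        assert ivw(s, model="multiplicative_random").se >= ivw(s, model="fixed").se

    def test_empty_set_errors(self):
        with pytest.raises(ValueError):
            ivw(make_instrument_set([], []))


class TestEgger:
    def test_exact_fit_through_origin(self):
        s = make_instrument_set([0.1, 0.3, 0.5], [0.02, 0.02, 0.02], theta=0.2)
        r = mr_egger(s)
        assert r.beta == pytest.approx(0.2, abs=1e-12)
        assert r.egger_intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_outcome_shift_moves_intercept_only(self):
        rng = np.random.default_rng(6)
        bx = rng.uniform(0.1, 0.5, 6)
        sy = rng.uniform(0.01, 0.03, 6)
        by = 0.2 * bx + rng.normal(0, sy)
        r0 = mr_egger(make_instrument_set(bx, sy, by=by))
        r1 = mr_egger(make_instrument_set(bx, sy, by=by + 0.05))
        assert r1.beta == pytest.approx(r0.beta, rel=1e-10)
        assert r1.egger_intercept == pytest.approx(r0.egger_intercept + 0.05, rel=1e-8)

    def test_matches_statsmodels_wls(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.1, 0.5, 9)
        sy = rng.uniform(0.01, 0.03, 9)
        by = 0.01 + 0.2 * bx + rng.normal(0, sy)
        r = mr_egger(make_instrument_set(bx, sy, by=by))
        fit = sm.WLS(by, sm.add_constant(bx), weights=1 / sy**2).fit()
        assert r.beta == pytest.approx(fit.params[1], rel=1e-10)
        assert r.egger_intercept == pytest.approx(fit.params[0], rel=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            mr_egger(make_instrument_set([0.1, 0.2], [0.02, 0.02]))

    def test_intercept_p_uniform_under_no_pleiotropy(self):
        """With a zero true intercept the intercept p-values are uniform
        (KS over 200 simulations, alpha 0.01)."""
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(200):
            bx = rng.uniform(0.1, 0.5, 25)
            sy = rng.uniform(0.01, 0.03, 25)
            by = 0.2 * bx + rng.normal(0, sy)
            pvals.append(mr_egger(make_instrument_set(bx, sy, by=by)).egger_intercept_p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestWeightedMedian:
    def test_equal_weight_median(self):
        s = make_instrument_set([1.0, 1.0, 1.0], [0.02, 0.02, 0.02],
                                by=[0.1, 0.2, 0.9])
        assert weighted_median(s, n_boot=10, seed=0).beta == pytest.approx(0.2)

    def test_duplication_invariance(self):
        bx, sy, by = [0.2, 0.3, 0.4], [0.02, 0.03, 0.01], [0.05, 0.04, 0.09]
        s1 = make_instrument_set(bx, sy, by=by)
        s2 = make_instrument_set(bx * 2, sy * 2, by=by * 2)
        assert (weighted_median(s1, n_boot=10, seed=0).beta
                == pytest.approx(weighted_median(s2, n_boot=10, seed=0).beta))

    def test_robust_to_minority_invalid_instruments(self):
        """7 valid instruments at theta 0.2 + 3 with large pleiotropic
        offsets: the weighted median stays near 0.2 while IVW is pulled
        away."""
        rng = np.random.default_rng(42)
        bx = rng.uniform(0.2, 0.5, 10)
        sy = np.full(10, 0.01)
        by = 0.2 * bx + rng.normal(0, sy)
        by[:3] += 0.15  # invalid: direct pleiotropic effects
        s = make_instrument_set(bx, sy, by=by)
        wm = weighted_median(s, n_boot=200, seed=1)
        assert abs(wm.beta - 0.2) < 0.05
        assert abs(ivw(s).beta - 0.2) > 0.05
        # brute-force oracle: scan the weighted CDF midpoints directly
        ratios = by / bx
        weights = (bx / sy) ** 2
        order = np.argsort(ratios)
        w = weights[order] / weights.sum()
        s_mid = np.cumsum(w) - w / 2
        oracle = np.interp(0.5, s_mid, ratios[order])
        assert wm.beta == pytest.approx(oracle, rel=1e-12)


class TestCochranQ:
    def test_two_instrument_closed_form(self):
        bx = np.array([0.3, 0.5])
        by = np.array([0.07, 0.09])
        sy = np.array([0.02, 0.03])
        s = make_instrument_set(bx, sy, by=by)
        theta = by / bx
        w = (bx / sy) ** 2
        # Q for two estimates equals the squared standardized difference
        expect = (theta[0] - theta[1]) ** 2 / (1 / w[0] + 1 / w[1])
        q = cochran_q(s)
        assert q.q == pytest.approx(expect, rel=1e-12)
        assert q.df == 1

    def test_reorder_invariance(self):
        bx, sy, by = [0.2, 0.3, 0.4], [0.02, 0.03, 0.01], [0.05, 0.04, 0.09]
        q1 = cochran_q(make_instrument_set(bx, sy, by=by)).q
        q2 = cochran_q(make_instrument_set(bx[::-1], sy[::-1], by=by[::-1])).q
        assert q1 == pytest.approx(q2, rel=1e-12)


class TestJointSignFlip:
    def test_wald_ivw_q_invariant(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.1, 0.5, 5)
        sy = rng.uniform(0.01, 0.03, 5)
        by = 0.2 * bx + rng.normal(0, sy)
        s = make_instrument_set(bx, sy, by=by)
        s_flip = make_instrument_set(-bx, sy, by=-by)
        assert ivw(s).beta == pytest.approx(ivw(s_flip).beta, rel=1e-12)
        assert cochran_q(s).q == pytest.approx(cochran_q(s_flip).q, rel=1e-12)
        w0 = wald_ratio(s.instruments[0]).beta
        w1 = wald_ratio(s_flip.instruments[0]).beta
        assert w0 == pytest.approx(w1, rel=1e-15)


class TestSMR:
    def test_null_outcome(self):
        r = smr_test(0.5, 0.05, 0.0, 0.02)
        assert r.p == pytest.approx(1.0)

    def test_chi_square_oracle(self):
        # z_x = 10, z_y = 3 -> T = 900/109
        r = smr_test(0.5, 0.05, 0.06, 0.02)
        t = 900 / 109
        assert r.p == pytest.approx(stats.chi2.sf(t, 1), rel=1e-12)
        assert r.p == pytest.approx(4.06e-3, rel=0.01)

    def test_t_bounded_by_min_z_squared(self):
        rng = np.random.default_rng(10)
        for _ in range(50):
            bx, by = rng.normal(0, 0.3, 2)
            sx, sy = rng.uniform(0.01, 0.1, 2)
            if bx == 0:
                continue
            p = smr_test(bx, sx, by, sy).p
            zmin2 = min((bx / sx) ** 2, (by / sy) ** 2)
            assert p >= stats.chi2.sf(zmin2, 1) - 1e-12


class TestBonferroni:
    def test_identity(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_zero_tests_errors(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
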