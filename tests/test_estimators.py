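"""The five MR estimators, their oracles, and the causal-call rules."""

import numpy as np
import pytest
from scipy import stats

from mrmediate.estimators import (IVW, EggerRegression, ModeEstimator,
                                  WeightedMedian, causal_call, egger, ivw,
                                  method_panel, mode_estimate, wald_ratios,
                                  weighted_median)

from conftest import make_harmonized


# --- independent oracles ---------------------------------------------------

def ivw_oracle(r, se):
    w = 1.0 / se**2
    b = np.sum(w * r) / np.sum(w)
    return b, np.sum(w) ** -0.5


def egger_oracle(bx, by, sy):
    """Weighted normal equations with orientation flip and SE inflation."""
    s = np.sign(bx)
    s[s == 0] = 1
    bx, by = bx * s, by * s
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    A = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(A, X.T @ (w * by))
    resid = by - X @ coef
    k = len(bx)
    sigma2 = np.sum(w * resid**2) / (k - 2)
    cov_unit = np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_unit) * max(1.0, sigma2))
    return coef, se


def weighted_median_oracle(r, w):
    """Brute-force cumulative-weight crossing with interpolation."""
    order = np.argsort(r)
    r, w = np.asarray(r)[order], np.asarray(w)[order]
    cum = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    below = np.where(cum < 0.5)[0]
    if len(below) == 0:
        return r[0]
    i = below[-1]
    if i == len(r) - 1:
        return r[-1]
    frac = (0.5 - cum[i]) / (cum[i + 1] - cum[i])
    return r[i] + frac * (r[i + 1] - r[i])


# --- wald ratios -----------------------------------------------------------

class TestWaldRatios:
    def test_closed_form(self):
        h = make_harmonized([0.2], 0.01, [0.1], 0.02)
        r, se = wald_ratios(h)
        assert r[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.1)

    def test_negative_exposure_flips_sign_only(self):
        h1 = make_harmonized([0.2], 0.01, [0.1], 0.02)
        h2 = make_harmonized([-0.2], 0.01, [0.1], 0.02)
        r1, s1 = wald_ratios(h1)
        r2, s2 = wald_ratios(h2)
        assert r2[0] == pytest.approx(-r1[0]) and s2[0] == pytest.approx(s1[0])

    def test_elementwise_oracle_and_zero_exclusion(self, rng):
        bx = rng.normal(0.1, 0.05, 10)
        bx[3] = 0.0
        by = rng.normal(0, 0.05, 10)
        sy = rng.uniform(0.01, 0.05, 10)
        h = make_harmonized(bx, 0.01, by, sy)
        r, se = wald_ratios(h)
        keep = bx != 0
        np.testing.assert_allclose(r, by[keep] / bx[keep])
        np.testing.assert_allclose(se, sy[keep] / np.abs(bx[keep]))


# --- IVW -------------------------------------------------------------------

class TestIVW:
    def test_identical_ratios_degenerate(self):
        h = make_harmonized([0.1, 0.2, 0.4], 0.01,
                            [0.05, 0.10, 0.20], [0.02, 0.04, 0.08])
        est = IVW(model="auto").fit(h)
        assert est.estimate_ == pytest.approx(0.5)
        assert est.q_ == pytest.approx(0.0, abs=1e-20)
        assert est.model_used_ == "fixed"

    def test_single_pair_rejected(self):
        h = make_harmonized([0.1], 0.01, [0.05], 0.02)
        with pytest.raises(ValueError):
            ivw(h)

    def test_three_pair_weighted_mean_oracle(self):
        # ratios (0.5, 0.3, 0.8) with ratio SEs (0.1, 0.2, 0.4)
        h = make_harmonized([1.0, 1.0, 1.0], 0.01,
                            [0.5, 0.3, 0.8], [0.1, 0.2, 0.4])
        r = np.array([0.5, 0.3, 0.8])
        se = np.array([0.1, 0.2, 0.4])
        b, sef = ivw_oracle(r, se)
        est = ivw(h, model="fixed")
        assert est.B == pytest.approx(b, abs=1e-14)
        assert est.SE == pytest.approx(sef, abs=1e-14)

    def test_fixed_equals_closed_form_on_random_tables(self, rng):
        for _ in range(5):
            k = 10
            h = make_harmonized(rng.uniform(0.05, 0.3, k),
                                rng.uniform(0.005, 0.02, k),
                                rng.normal(0.05, 0.05, k),
                                rng.uniform(0.01, 0.05, k))
            r, se = wald_ratios(h)
            b, sef = ivw_oracle(r, se)
            est = ivw(h, model="fixed")
            assert abs(est.B - b) < 1e-10 and abs(est.SE - sef) < 1e-10

    def test_random_effects_inflates_se_under_heterogeneity(self):
        h = make_harmonized(np.ones(6), 0.01,
                            [0.1, 0.9, 0.2, 0.8, 0.15, 0.85], 0.05)
        fixed = ivw(h, model="fixed")
        random = ivw(h, model="random")
        assert random.SE > fixed.SE
        assert random.B == pytest.approx(fixed.B)

    def test_auto_selects_random_when_q_significant(self):
        h = make_harmonized(np.ones(6), 0.01,
                            [0.1, 0.9, 0.2, 0.8, 0.15, 0.85], 0.05)
        est = IVW(model="auto").fit(h)
        assert est.q_pvalue_ < 0.05 and est.model_used_ == "random"


# --- Egger -----------------------------------------------------------------

class TestEgger:
    def test_line_through_origin(self, rng):
        bx = rng.uniform(0.05, 0.3, 8)
        h = make_harmonized(bx, 0.01, 0.4 * bx, rng.uniform(0.01, 0.03, 8))
        slope, intercept = egger(h)
        assert slope.B == pytest.approx(0.4, abs=1e-10)
        assert intercept["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_recovered_as_intercept(self, rng):
        bx = rng.uniform(0.05, 0.3, 50)
        c = 0.03
        by = 0.4 * bx + c + rng.normal(0, 0.005, 50)
        h = make_harmonized(bx, 0.01, by, 0.02)  # equal weights
        _, intercept = egger(h)
        assert intercept["intercept"] == pytest.approx(c, abs=0.01)

    def test_normal_equations_oracle(self, rng):
        for _ in range(5):
            k = 5
            bx = rng.normal(0.1, 0.1, k)
            by = rng.normal(0.05, 0.05, k)
            sy = rng.uniform(0.01, 0.05, k)
            h = make_harmonized(bx, 0.01, by, sy)
            coef, se = egger_oracle(bx.copy(), by.copy(), sy)
            slope, intercept = egger(h)
            assert abs(slope.B - coef[1]) < 1e-10
            assert abs(slope.SE - se[1]) < 1e-10
            assert abs(intercept["intercept"] - coef[0]) < 1e-10
            assert abs(intercept["se"] - se[0]) < 1e-10

    def test_too_few_pairs_rejected(self):
        h = make_harmonized([0.1, 0.2], 0.01, [0.05, 0.1], 0.02)
        with pytest.raises(ValueError):
            egger(h)


# --- weighted median -------------------------------------------------------

class TestWeightedMedian:
    def test_equal_weights_exact_median(self):
        h = make_harmonized([1, 1, 1], 0.01, [0.1, 0.5, 0.9], 0.05)
        est = weighted_median(h, n_boot=100, seed=1)
        assert est.B == pytest.approx(0.5)

    def test_dominant_weight_limit(self):
        h = make_harmonized([1, 1, 1], 0.01, [0.1, 0.5, 0.9],
                            [0.5, 0.5, 1e-4])
        est = weighted_median(h, n_boot=100, seed=1)
        assert est.B == pytest.approx(0.9, abs=1e-3)

    def test_brute_force_interpolation_oracle(self, rng):
        for _ in range(5):
            k = 7
            bx = rng.uniform(0.05, 0.3, k)
            by = rng.normal(0.05, 0.05, k)
            sy = rng.uniform(0.01, 0.05, k)
            h = make_harmonized(bx, 0.01, by, sy)
            r, se = wald_ratios(h)
            expected = weighted_median_oracle(r, 1.0 / se**2)
            est = weighted_median(h, n_boot=50, seed=1)
            assert abs(est.B - expected) < 1e-10

    def test_bootstrap_se_reproducible(self, random_pairs):
        a = weighted_median(random_pairs, n_boot=200, seed=42)
        b = weighted_median(random_pairs, n_boot=200, seed=42)
        assert a.SE == b.SE


# --- mode ------------------------------------------------------------------

class TestMode:
    def test_identical_ratios_return_common_value(self):
        h = make_harmonized([0.1, 0.2, 0.4], 0.01,
                            [0.05, 0.10, 0.20], [0.02, 0.04, 0.08])
        est = mode_estimate(h, n_boot=50, seed=1)
        assert est.B == pytest.approx(0.5)

    def test_heavier_cluster_wins(self, rng):
        # 7 ratios near 0.4, 3 near 1.2
        r = np.concatenate([rng.normal(0.4, 0.01, 7), rng.normal(1.2, 0.01, 3)])
        h = make_harmonized(np.ones(10), 0.01, r, 0.05)
        est = mode_estimate(h, weighted=False, n_boot=50, seed=1)
        assert 0.3 < est.B < 0.5

    def test_simple_equals_weighted_under_equal_weights(self, rng):
        r = rng.normal(0.3, 0.1, 8)
        h = make_harmonized(np.ones(8), 0.01, r, 0.05)
        simple = ModeEstimator(weighted=False, n_boot=10, seed=3).fit(h)
        weighted = ModeEstimator(weighted=True, n_boot=10, seed=3).fit(h)
        assert simple.estimate_ == pytest.approx(weighted.estimate_)


# --- cross-estimator properties --------------------------------------------

def test_dominant_weight_convergence(rng):
    """With one overwhelming weight, IVW, weighted median and weighted mode
    all converge to that pair's Wald ratio."""
    bx = np.array([0.2, 0.15, 0.1, 0.25])
    by = np.array([0.02, 0.09, 0.11, 0.175])
    sy = np.array([1e-5, 0.5, 0.5, 0.5])
    h = make_harmonized(bx, 0.01, by, sy)
    target = by[0] / bx[0]
    assert ivw(h, model="fixed").B == pytest.approx(target, abs=1e-4)
    assert weighted_median(h, n_boot=50, seed=1).B == pytest.approx(target, abs=1e-4)
    assert mode_estimate(h, weighted=True, n_boot=50, seed=1).B == \
        pytest.approx(target, abs=0.05)


@pytest.mark.parametrize("fit", [
    lambda h: ivw(h, model="fixed"),
    lambda h: egger(h)[0],
    lambda h: weighted_median(h, n_boot=100, seed=5),
    lambda h: mode_estimate(h, weighted=True, n_boot=100, seed=5),
    lambda h: mode_estimate(h, weighted=False, n_boot=100, seed=5),
])
def test_exposure_rescaling_equivariance(fit, random_pairs):
    """Multiplying (beta_x, se_x) by c divides every estimator's B by c."""
    c = 2.5
    scaled = random_pairs.df.copy()
    scaled["beta_x"] *= c
    scaled["se_x"] *= c
    base = fit(random_pairs)
    rescaled = fit(make_like(scaled))
    assert rescaled.B == pytest.approx(base.B / c, rel=1e-9)


def make_like(df):
    from mrmediate.sumstats import HarmonizedTable
    return HarmonizedTable("X", "Y", df)


def test_or_ci_log_round_trip(random_pairs):
    """exp/log round trip recovers B and SE from the OR columns exactly."""
    est = ivw(random_pairs, model="fixed")
    assert np.log(est.OR) == pytest.approx(est.B)
    assert (np.log(est.ci_high) - np.log(est.ci_low)) / (2 * 1.96) == \
        pytest.approx(est.SE)
    assert est.ci_low < est.OR < est.ci_high


def test_sklearn_params_round_trip():
    est = WeightedMedian(n_boot=77, seed=9)
    assert est.get_params() == {"n_boot": 77, "seed": 9}
    est.set_params(n_boot=11)
    assert est.n_boot == 11


# --- causal call -----------------------------------------------------------

def _panel(bs, p_ivw, or_ivw=None):
    from mrmediate.estimators import MethodPanel, MREstimate
    names = ["ivw", "egger", "weighted_median", "simple_mode", "weighted_mode"]
    ests = {}
    for name, b in zip(names, bs):
        ests[name] = MREstimate(method=name, B=b, SE=0.1,
                                pval=p_ivw if name == "ivw" else 0.5,
                                OR=float(np.exp(b)),
                                ci_low=float(np.exp(b - 0.196)),
                                ci_high=float(np.exp(b + 0.196)), n_snps=10)
    consistent = all(b > 0 for b in bs) or all(b < 0 for b in bs)
    return MethodPanel(estimates=ests, directionally_consistent=consistent,
                       p_ivw=p_ivw)


class TestCausalCall:
    def test_consistent_positive_significant_is_risk(self):
        # OR = 1.411 on the IVW row, all five betas positive, p < 0.0001
        b = float(np.log(1.411))
        call = causal_call(_panel([b, 0.3, 0.35, 0.2, 0.4], 1e-5))
        assert call.significant and call.direction == "risk"

    def test_sign_inconsistency_blocks_significance(self):
        call = causal_call(_panel([0.3, 0.2, 0.25, -0.05, 0.3], 0.001))
        assert not call.significant and call.direction == "null"

    def test_nonsignificant_ivw_is_null(self):
        call = causal_call(_panel([-0.3, -0.2, -0.25, -0.05, -0.3], 0.2))
        assert not call.significant and call.direction == "null"

    def test_consistent_negative_significant_is_protective(self):
        call = causal_call(_panel([-0.3, -0.2, -0.25, -0.05, -0.3], 0.01))
        assert call.significant and call.direction == "protective"


def test_method_panel_bundles_all_five(random_pairs):
    panel = method_panel(random_pairs, n_boot=50, seed=3)
    assert set(panel.estimates) == {"ivw", "egger", "weighted_median",
                                    "simple_mode", "weighted_mode"}
    assert panel.p_ivw == panel.estimates["ivw"].pval


def test_ivw_null_calibration_summary_level():
    """On clean null data the IVW test rejects at ~nominal 5%."""
    from mrmediate.experiments import ivw_null_rejection_rate
    rate = ivw_null_rejection_rate(n_reps=400, seed=3)
    assert 0.03 <= rate <= 0.07
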