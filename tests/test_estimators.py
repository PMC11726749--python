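import math

import numpy as np
import pytest

from mrpipe.estimators import (
    EggerRegressor,
    IVWEstimator,
    WeightedMedianEstimator,
    egger,
    ivw,
    to_odds_ratio,
    wald_ratios,
    weighted_median,
)
from mrpipe.instruments import HarmonizedSet

from conftest import random_harmonized


def make_h(beta_exp, beta_out, se_out, se_exp=None):
    beta_exp = np.asarray(beta_exp, float)
    k = beta_exp.size
    return HarmonizedSet(
        snp_ids=[f"rs{i}" for i in range(k)],
        beta_exp=beta_exp,
        se_exp=np.full(k, 0.01) if se_exp is None else np.asarray(se_exp, float),
        beta_out=np.asarray(beta_out, float),
        se_out=np.asarray(se_out, float),
        flipped=np.zeros(k, dtype=bool),
    )


class TestWaldRatios:
    def test_arithmetic_and_sign(self):
        h = make_h([0.1, -0.1], [0.05, 0.05], [0.01, 0.01])
        w = wald_ratios(h)
        assert w.theta[0] == pytest.approx(0.5)
        assert w.se_theta[0] == pytest.approx(0.1)
        assert w.weight[0] == pytest.approx(100.0)
        assert w.theta[1] == pytest.approx(-0.5)

    def test_matches_arithmetic_oracle(self, harmonized5):
        w = wald_ratios(harmonized5)
        for j in range(harmonized5.n_snp):
            t = harmonized5.beta_out[j] / harmonized5.beta_exp[j]
            s = harmonized5.se_out[j] / abs(harmonized5.beta_exp[j])
            assert w.theta[j] == pytest.approx(t, abs=1e-12)
            assert w.se_theta[j] == pytest.approx(s, abs=1e-12)
            assert w.weight[j] == pytest.approx(1 / s**2, rel=1e-12)

    def test_zero_exposure_dropped_all_zero_raises(self):
        h = make_h([0.0, 0.1], [0.01, 0.02], [0.01, 0.01])
        with pytest.warns(UserWarning):
            w = wald_ratios(h)
        assert w.dropped == ("rs0",)
        h0 = make_h([0.0], [0.01], [0.01])
        with pytest.raises(ValueError):
            wald_ratios(h0)


class TestIVW:
    def test_single_snp_equals_wald_ratio(self):
        h = make_h([0.1], [0.05], [0.01])
        with pytest.warns(UserWarning):
            r = ivw(h)
        assert r.method == "WaldRatio"
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)

    def test_homogeneous_ratios_fixed_equals_random(self):
        h = make_h([0.1, 0.2, 0.4], [0.03, 0.06, 0.12], [0.01, 0.02, 0.01])
        rf = ivw(h, model="fixed")
        rr = ivw(h, model="random")
        assert rf.beta == pytest.approx(0.3)
        assert rf.se == pytest.approx(rr.se)  # Q = 0 -> multiplier floored at 1

    def test_equals_weighted_regression_through_origin(self, rng):
        for _ in range(5):
            h = random_harmonized(rng, k=7)
            est = IVWEstimator(model="fixed").fit(
                h.beta_exp[:, None], h.beta_out, 1 / h.se_out**2)
            # closed-form weighted regression through the origin
            w = 1 / h.se_out**2
            beta = np.sum(w * h.beta_exp * h.beta_out) / np.sum(w * h.beta_exp**2)
            se = 1 / np.sqrt(np.sum(w * h.beta_exp**2))
            assert est.beta_ == pytest.approx(beta, abs=1e-12)
            assert est.se_fixed_ == pytest.approx(se, abs=1e-12)

    def test_fixed_se_never_exceeds_random_se(self, rng):
        for _ in range(10):
            h = random_harmonized(rng, k=6)
            rf = ivw(h, model="fixed")
            rr = ivw(h, model="random")
            assert rf.se <= rr.se + 1e-15

    def test_auto_model_follows_heterogeneity(self, rng):
        # wildly heterogeneous ratios -> random; identical ratios -> fixed
        h_het = make_h([0.1, 0.1, 0.1, 0.1], [0.5, -0.5, 0.3, -0.4],
                       [0.01, 0.01, 0.01, 0.01])
        est = IVWEstimator(model="auto").fit(
            h_het.beta_exp[:, None], h_het.beta_out, 1 / h_het.se_out**2)
        assert est.model_used_ == "random"
        h_hom = make_h([0.1, 0.2], [0.05, 0.10], [0.01, 0.01])
        est2 = IVWEstimator(model="auto").fit(
            h_hom.beta_exp[:, None], h_hom.beta_out, 1 / h_hom.se_out**2)
        assert est2.model_used_ == "fixed"


class TestEgger:
    def test_line_through_origin_recovered(self):
        x = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_h(x, 0.4 * x, np.full(4, 0.01))
        res, pleio = egger(h)
        assert pleio.intercept == pytest.approx(0.0, abs=1e-10)
        assert res.beta == pytest.approx(0.4, abs=1e-10)

    def test_constant_offset_moves_intercept_not_slope(self):
        x = np.array([0.05, 0.1, 0.2, 0.3])
        y = 0.4 * x
        c = 0.02
        h0 = make_h(x, y, np.full(4, 0.01))
        h1 = make_h(x, y + c, np.full(4, 0.01))
        r0, p0 = egger(h0)
        r1, p1 = egger(h1)
        assert p1.intercept - p0.intercept == pytest.approx(c, abs=1e-10)
        assert r1.beta == pytest.approx(r0.beta, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(5):
            h = random_harmonized(rng, k=8)
            est = EggerRegressor(overdispersion=False).fit(
                h.beta_exp[:, None], h.beta_out, 1 / h.se_out**2)
            # solve the weighted normal equations independently, after
            # orienting exposure effects non-negative
            sign = np.where(h.beta_exp < 0, -1.0, 1.0)
            x, y = h.beta_exp * sign, h.beta_out * sign
            w = 1 / h.se_out**2
            A = np.array([[np.sum(w), np.sum(w * x)],
                          [np.sum(w * x), np.sum(w * x * x)]])
            b = np.array([np.sum(w * y), np.sum(w * x * y)])
            c0, c1 = np.linalg.solve(A, b)
            assert est.intercept_ == pytest.approx(c0, abs=1e-10)
            assert est.beta_ == pytest.approx(c1, abs=1e-10)
            resid = y - c0 - c1 * x
            phi = np.sum(w * resid**2) / (len(x) - 2)
            cov = np.linalg.inv(A) * phi
            assert est.se_ == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-8)

    def test_requires_three_instruments(self):
        h = make_h([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(ValueError, match=">= 3"):
            egger(h)


class TestWeightedMedian:
    def test_equal_weights_reduce_to_median(self):
        h = make_h([1.0, 1.0, 1.0], [1.0, 2.0, 9.0], [1.0, 1.0, 1.0])
        r = weighted_median(h, n_boot=50, seed=0)
        assert r.beta == pytest.approx(2.0)

    def test_majority_weight_snp_dominates(self):
        # middle SNP carries >50% of the weight
        h = make_h([1.0, 1.0, 1.0], [1.0, 5.0, 9.0], [1.0, 0.05, 1.0])
        r = weighted_median(h, n_boot=50, seed=0)
        assert r.beta == pytest.approx(5.0, abs=0.1)

    def test_matches_brute_force_cumulative_scan(self, rng):
        for _ in range(5):
            h = random_harmonized(rng, k=5)
            r = weighted_median(h, n_boot=10, seed=1)
            theta = h.beta_out / h.beta_exp
            w = (h.beta_exp / h.se_out) ** 2
            order = np.argsort(theta)
            th, ww = theta[order], w[order]
            s = (np.cumsum(ww) - ww / 2) / ww.sum()
            # brute-force scan for the interpolation bracket at s = 0.5
            if s[0] >= 0.5:
                expected = th[0]
            else:
                j = max(i for i in range(len(s)) if s[i] < 0.5)
                expected = th[j] + (th[j + 1] - th[j]) * (0.5 - s[j]) / (s[j + 1] - s[j])
            assert r.beta == pytest.approx(expected, abs=1e-12)

    def test_estimate_within_theta_range(self, rng):
        for _ in range(10):
            h = random_harmonized(rng, k=6)
            theta = h.beta_out / h.beta_exp
            r = weighted_median(h, n_boot=10, seed=2)
            assert theta.min() - 1e-12 <= r.beta <= theta.max() + 1e-12

    def test_bootstrap_se_deterministic_under_seed(self, harmonized5):
        a = weighted_median(harmonized5, n_boot=200, seed=9)
        b = weighted_median(harmonized5, n_boot=200, seed=9)
        assert a.se == b.se


class TestOddsRatio:
    def test_null_beta_gives_symmetric_ci(self):
        or_, lo, hi = to_odds_ratio(0.0, 0.1, 0.95)
        assert or_ == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-12)

    def test_round_trip_of_reported_or(self):
        beta = math.log(0.9886)
        or_, _, _ = to_odds_ratio(beta, 0.005)
        assert or_ == pytest.approx(0.9886, rel=1e-12)

    def test_ci_product_identity(self, rng):
        for _ in range(10):
            beta, se = rng.normal(), rng.uniform(0.01, 0.5)
            or_, lo, hi = to_odds_ratio(float(beta), float(se))
            assert lo * hi == pytest.approx(or_**2, rel=1e-12)


def test_sign_equivariance_of_all_estimators(rng):
    h = random_harmonized(rng, k=6)
    neg = HarmonizedSet(
        snp_ids=h.snp_ids, beta_exp=h.beta_exp, se_exp=h.se_exp,
        beta_out=-h.beta_out, se_out=h.se_out, flipped=h.flipped)
    r, rn = ivw(h), ivw(neg)
    assert rn.beta == pytest.approx(-r.beta, abs=1e-12)
    assert rn.se == pytest.approx(r.se, rel=1e-9)
    # weighted-median point estimate is exactly equivariant; its bootstrap
    # SE only in distribution, so compare within Monte-Carlo slack
    rw, rwn = (weighted_median(h, n_boot=4000, seed=4),
               weighted_median(neg, n_boot=4000, seed=4))
    assert rwn.beta == pytest.approx(-rw.beta, abs=1e-12)
    assert rwn.se == pytest.approx(rw.se, rel=0.1)
    re_, _ = egger(h)
    rne, _ = egger(neg)
    assert rne.beta == pytest.approx(-re_.beta, abs=1e-12)
    assert rne.se == pytest.approx(re_.se, rel=1e-9)


def test_no_pleiotropy_cis_cover_truth():
    """All three estimators' 95% CIs cover the true effect ~95% of the time."""
    from scipy.stats import binom
    from mrpipe.simulate import SimulationConfig, simulate_triplet
    from mrpipe.instruments import select_by_pvalue, clump, harmonize, InstrumentConfig
    from mrpipe.gwas_io import attach_positions
    cfgI = InstrumentConfig()
    n_rep, truth = 150, 0.1
    cover = {"ivw": 0, "egger": 0, "wm": 0}
    for s in range(n_rep):
        t = simulate_triplet(SimulationConfig(
            beta_exp_out_direct=truth, seed=20_000 + s))
        sel = select_by_pvalue(t.exposure, cfgI)
        h = harmonize(clump(sel, attach_positions(t.ld, sel), cfgI), t.outcome, cfgI)
        for key, r in (("ivw", ivw(h)),
                       ("egger", egger(h)[0]),
                       ("wm", weighted_median(h, n_boot=200, seed=s))):
            cover[key] += r.ci_low <= math.exp(truth) <= r.ci_high
    lo, hi = binom.interval(0.999, n_rep, 0.95)
    for key, c in cover.items():
        assert lo <= c <= hi, f"{key} coverage {c}/{n_rep}"
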