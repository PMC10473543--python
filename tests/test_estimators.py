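"""Estimator correctness against independent weighted-regression oracles."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from mrmediate.estimators import (
    ivw,
    ivw_q_statistic,
    mr_egger,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)

from conftest import make_instruments, random_instruments


class TestWaldRatio:
    def test_basic_arithmetic(self):
        h = make_instruments([0.1], [0.02], [0.01])[0]
        est = wald_ratio(h)
        assert est.beta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        h = make_instruments([0.1], [0.0], [0.01])[0]
        assert wald_ratio(h).beta == 0.0

    def test_negative_exposure_beta_absolute_se(self):
        h = make_instruments([-0.1], [0.02], [0.01])[0]
        est = wald_ratio(h)
        assert est.beta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)  # |beta_exp| in the denominator

    def test_zero_exposure_beta_fatal(self):
        h = make_instruments([0.0], [0.02], [0.01])[0]
        with pytest.raises(ValueError):
            wald_ratio(h)


class TestIVW:
    def test_homogeneous_ratios(self):
        hs = make_instruments([0.1, 0.2], [0.01, 0.02], [0.01, 0.01])
        est = ivw(hs, effects_model="auto")
        assert est.beta == pytest.approx(0.1)
        q, _ = ivw_q_statistic(hs)
        assert q == pytest.approx(0.0, abs=1e-20)
        assert est.effects_model == "fixed"

    def test_meta_analysis_se_scaling(self):
        one = make_instruments([0.1], [0.02], [0.01])
        est1 = wald_ratio(one[0])
        for j in (4, 9):
            hs = make_instruments([0.1] * j, [0.02] * j, [0.01] * j)
            est = ivw(hs, effects_model="fixed")
            assert est.beta == pytest.approx(est1.beta)
            assert est.se == pytest.approx(est1.se / math.sqrt(j), rel=1e-12)

    def test_matches_wls_through_origin_oracle(self, rng):
        for _ in range(100):
            hs = random_instruments(rng, j=10)
            bx = np.array([h.beta_exp for h in hs])
            by = np.array([h.beta_out for h in hs])
            sy = np.array([h.se_out for h in hs])
            fit = sm.WLS(by, bx[:, None], weights=sy**-2.0).fit()
            est = ivw(hs, effects_model="fixed")
            assert est.beta == pytest.approx(fit.params[0], rel=1e-10)
            # statsmodels scales by the residual MSE; undo to get the fixed SE
            se_fixed = fit.bse[0] / np.sqrt(fit.mse_resid)
            assert est.se == pytest.approx(se_fixed, rel=1e-10)

    def test_equal_weights_reduce_to_mean(self):
        ratios = np.array([0.5, 1.5, -0.3, 0.9])
        hs = make_instruments([0.1] * 4, 0.1 * ratios, [0.01] * 4)
        est = ivw(hs, effects_model="fixed")
        assert est.beta == pytest.approx(ratios.mean(), rel=1e-12)

    def test_random_effects_never_smaller_se(self, rng):
        for _ in range(20):
            hs = random_instruments(rng, j=8)
            assert ivw(hs, "random").se >= ivw(hs, "fixed").se - 1e-15

    def test_requires_two_instruments(self):
        with pytest.raises(ValueError, match="wald"):
            ivw(make_instruments([0.1], [0.02], [0.01]))


class TestEgger:
    def test_exact_line_through_origin(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        hs = make_instruments(bx, 0.1 * bx, rng.uniform(0.005, 0.02, 10))
        est, pleio = mr_egger(hs)
        assert est.beta == pytest.approx(0.1, abs=1e-12)
        assert pleio.intercept == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)
        hs = make_instruments(bx, 0.05 + 0.1 * bx, rng.uniform(0.005, 0.02, 10))
        est, pleio = mr_egger(hs)
        assert est.beta == pytest.approx(0.1, abs=1e-12)
        assert pleio.intercept == pytest.approx(0.05, abs=1e-12)

    def test_matches_wls_oracle_with_orientation(self, rng):
        for _ in range(100):
            hs = random_instruments(rng, j=20)
            bx = np.array([h.beta_exp for h in hs])
            by = np.array([h.beta_out for h in hs])
            sy = np.array([h.se_out for h in hs])
            sign = np.where(bx < 0, -1.0, 1.0)
            bxo, byo = bx * sign, by * sign
            X = sm.add_constant(bxo)
            fit = sm.WLS(byo, X, weights=sy**-2.0).fit()
            est, pleio = mr_egger(hs)
            assert est.beta == pytest.approx(fit.params[1], rel=1e-10)
            assert pleio.intercept == pytest.approx(fit.params[0], rel=1e-10, abs=1e-14)
            scale = max(1.0, np.sqrt(fit.mse_resid))
            assert est.se == pytest.approx(fit.bse[1] / np.sqrt(fit.mse_resid) * scale, rel=1e-10)

    def test_orientation_noop_when_all_positive(self, rng):
        # with every beta_exp > 0 the orientation step must change nothing:
        # the slope equals the unoriented weighted regression exactly
        bx = rng.uniform(0.05, 0.3, 12)
        sy = rng.uniform(0.005, 0.02, 12)
        by = 0.1 * bx + rng.normal(0, sy)
        est, _ = mr_egger(make_instruments(bx, by, sy))
        fit = sm.WLS(by, sm.add_constant(bx), weights=sy**-2.0).fit()
        assert est.beta == pytest.approx(fit.params[1], rel=1e-12)

    def test_requires_three_instruments(self):
        with pytest.raises(ValueError):
            mr_egger(make_instruments([0.1, 0.2], [0.01, 0.02], [0.01, 0.01]))


class TestWeightedMedian:
    def _equal_weight(self, ratios, seed=1):
        bx = np.full(len(ratios), 0.1)
        by = 0.1 * np.asarray(ratios)
        sy = np.full(len(ratios), 0.01)
        return weighted_median(make_instruments(bx, by, sy), n_boot=100, seed=seed)

    def test_symmetric_median(self):
        assert self._equal_weight([1.0, 2.0, 3.0]).beta == pytest.approx(2.0)

    def test_robust_to_one_outlier(self):
        assert self._equal_weight([1.0, 2.0, 100.0]).beta == pytest.approx(2.0)

    def test_equal_weights_give_interpolated_median(self, rng):
        ratios = rng.normal(0.2, 0.5, 8)
        est = self._equal_weight(ratios)
        # interpolated (weighted, equal weights) median oracle
        r = np.sort(ratios)
        s = (np.arange(1, 9) - 0.5) / 8.0
        assert est.beta == pytest.approx(float(np.interp(0.5, s, r)), rel=1e-12)

    def test_matches_grid_search_oracle(self, rng):
        for _ in range(30):
            hs = random_instruments(rng, j=15)
            ratios = np.array([h.wald_ratio for h in hs])
            weights = np.array([h.weight for h in hs])
            est = weighted_median(hs, n_boot=100, seed=7)
            # oracle: scan a fine grid for the point where the cumulative
            # weight of midpoint-corrected mass crosses one half
            order = np.argsort(ratios)
            r, w = ratios[order], weights[order]
            s = (np.cumsum(w) - 0.5 * w) / w.sum()
            grid = np.linspace(r[0], r[-1], 200001)
            crossing = grid[np.searchsorted(np.interp(grid, r, s), 0.5)]
            assert est.beta == pytest.approx(crossing, abs=(r[-1] - r[0]) / 1e4)

    def test_bit_reproducible_for_fixed_seed(self, rng):
        hs = random_instruments(rng, j=10)
        a = weighted_median(hs, n_boot=200, seed=42)
        b = weighted_median(hs, n_boot=200, seed=42)
        assert a.beta == b.beta and a.se == b.se

    def test_seed_required(self, rng):
        with pytest.raises(ValueError, match="seed"):
            weighted_median(random_instruments(rng), n_boot=100, seed=None)


class TestOddsRatioScale:
    def test_null_effect_is_or_one(self):
        hs = make_instruments([0.1, 0.2], [0.0, 0.0], [0.01, 0.01])
        est = to_odds_ratio(ivw(hs, "fixed"))
        assert est.or_scale[0] == pytest.approx(1.0)

    def test_printed_or_example(self):
        hs = make_instruments([0.1, 0.2], [0.1 * math.log(1.06), 0.2 * math.log(1.06)],
                              [0.01, 0.01])
        est = to_odds_ratio(ivw(hs, "fixed"))
        assert est.or_scale[0] == pytest.approx(1.06)

    def test_reciprocal_symmetry(self, rng):
        hs = random_instruments(rng, j=6, causal=0.25)
        est = to_odds_ratio(ivw(hs, "fixed"))
        neg = make_instruments(
            [h.beta_exp for h in hs], [-h.beta_out for h in hs], [h.se_out for h in hs]
        )
        est_neg = to_odds_ratio(ivw(neg, "fixed"))
        assert est_neg.or_scale[0] == pytest.approx(1.0 / est.or_scale[0], rel=1e-12)

    def test_ci_consistency(self, rng):
        est = to_odds_ratio(ivw(random_instruments(rng), "fixed"))
        assert est.or_scale[1] == pytest.approx(math.exp(est.ci_low), rel=1e-12)
        assert est.or_scale[2] == pytest.approx(math.exp(est.ci_high), rel=1e-12)
        assert est.ci_low < est.beta < est.ci_high


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_estimators_permutation_invariant(seed):
    rng = np.random.default_rng(seed)
    hs = random_instruments(rng, j=8)
    perm = [hs[i] for i in rng.permutation(8)]
    assert ivw(perm, "fixed").beta == pytest.approx(ivw(hs, "fixed").beta, rel=1e-12)
    ea, pa = mr_egger(hs)
    eb, pb = mr_egger(perm)
    assert eb.beta == pytest.approx(ea.beta, rel=1e-10)
    assert pb.intercept == pytest.approx(pa.intercept, rel=1e-10, abs=1e-14)
    wa = weighted_median(hs, n_boot=100, seed=3)
    wb = weighted_median(perm, n_boot=100, seed=3)
    assert wb.beta == pytest.approx(wa.beta, rel=1e-12)
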