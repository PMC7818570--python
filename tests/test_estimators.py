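import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, strategies as st
from scipy import optimize

import tsmr.estimators as est
from tsmr.estimators import EstimatorError

from conftest import make_instruments


def arrays(instruments):
    return (np.array([i.gamma for i in instruments]),
            np.array([i.se_gamma for i in instruments]),
            np.array([i.alpha for i in instruments]),
            np.array([i.se_alpha for i in instruments]))


class TestWaldRatios:
    def test_closed_form(self):
        inst = make_instruments([0.1], [0.005], [0.02], [0.01])
        [(rsid, ratio, se)] = est.wald_ratios(inst)
        assert ratio == pytest.approx(0.2)
        assert se == pytest.approx(0.1)

    def test_zero_alpha_zero_ratio(self):
        inst = make_instruments([0.1], [0.005], [0.0], [0.01])
        assert est.wald_ratios(inst)[0][1] == 0.0

    def test_zero_gamma_excluded(self):
        inst = make_instruments([0.1, 0.0], [0.005] * 2, [0.02, 0.01], [0.01] * 2)
        assert len(est.wald_ratios(inst)) == 1

    def test_elementwise_division_oracle(self):
        rng = np.random.default_rng(1)
        g, a = rng.normal(0.1, 0.02, 5), rng.normal(0, 0.05, 5)
        sa = rng.uniform(0.005, 0.02, 5)
        inst = make_instruments(g, [0.003] * 5, a, sa)
        for (_, ratio, se), gj, aj, saj in zip(est.wald_ratios(inst), g, a, sa):
            assert ratio == pytest.approx(aj / gj, rel=1e-14)
            assert se == pytest.approx(saj / abs(gj), rel=1e-14)


class TestIVW:
    def test_single_instrument_is_wald_ratio(self):
        inst = make_instruments([0.1], [0.005], [0.02], [0.01])
        e = est.ivw(inst)
        assert e.beta == pytest.approx(0.2)
        assert e.method == "Wald ratio"

    def test_identical_snps_give_common_ratio(self):
        inst = make_instruments([0.1, 0.1], [0.005] * 2, [0.02, 0.02], [0.01] * 2)
        assert est.ivw(inst).beta == pytest.approx(0.2, rel=1e-14)

    def test_collinear_fixture_exact(self, collinear_instruments):
        e = est.ivw(collinear_instruments)
        assert e.beta == pytest.approx(-0.28, rel=1e-13)
        q = est.cochrans_q(collinear_instruments, e.beta)
        assert q.q == pytest.approx(0.0, abs=1e-20)

    def test_matches_wls_through_origin_oracle(self, random_instruments):
        g, sg, a, sa = arrays(random_instruments)
        fit = sm.WLS(a, g[:, None], weights=1.0 / sa**2).fit()
        mine_fixed = est.ivw(random_instruments, effects_model="fixed")
        mine_rand = est.ivw(random_instruments)
        assert mine_fixed.beta == pytest.approx(fit.params[0], rel=1e-10)
        assert mine_rand.beta == pytest.approx(fit.params[0], rel=1e-10)
        # statsmodels bse carries the multiplicative scale; fixed se divides it out
        scale_free_se = fit.bse[0] / np.sqrt(fit.scale)
        assert mine_fixed.se == pytest.approx(scale_free_se, rel=1e-10)
        assert mine_rand.se == pytest.approx(max(fit.bse[0], scale_free_se), rel=1e-10)

    def test_or_fields_are_exponentiated(self, random_instruments):
        e = est.ivw(random_instruments)
        assert e.or_ == pytest.approx(math.exp(e.beta), rel=1e-14)
        assert e.or_ci_low == pytest.approx(math.exp(e.ci_low), rel=1e-14)
        assert e.ci_low <= e.beta <= e.ci_high

    def test_all_zero_gamma_fatal(self):
        inst = make_instruments([0.0, 0.0], [0.005] * 2, [0.01, 0.0], [0.01] * 2)
        with pytest.raises(EstimatorError):
            est.ivw(inst)


class TestMREgger:
    def test_exact_line_recovered(self):
        g = np.array([0.05, 0.08, 0.11, 0.15, 0.2])
        a = 0.1 + 0.5 * g
        inst = make_instruments(g, [0.004] * 5, a, [0.01] * 5)
        slope, intercept = est.mr_egger(inst)
        assert slope.beta == pytest.approx(0.5, rel=1e-12)
        assert intercept.intercept == pytest.approx(0.1, rel=1e-12)
        q = est.cochrans_q(inst, slope.beta, n_params=2, intercept=intercept.intercept)
        assert q.q == pytest.approx(0.0, abs=1e-18)
        assert q.q_df == 3

    def test_matches_weighted_regression_oracle(self):
        rng = np.random.default_rng(7)
        J = 12
        g = np.abs(rng.normal(0.1, 0.04, J))
        sa = rng.uniform(0.005, 0.02, J)
        a = 0.02 - 0.3 * g + rng.normal(0, sa)
        inst = make_instruments(g, [0.003] * J, a, sa)
        X = sm.add_constant(g)
        fit = sm.WLS(a, X, weights=1.0 / sa**2).fit()
        slope, intercept = est.mr_egger(inst)
        assert intercept.intercept == pytest.approx(fit.params[0], rel=1e-10)
        assert slope.beta == pytest.approx(fit.params[1], rel=1e-10)
        # my residual scale is floored at 1
        scale = max(1.0, np.sqrt(fit.scale))
        assert intercept.se == pytest.approx(fit.bse[0] / np.sqrt(fit.scale) * scale, rel=1e-10)
        assert slope.se == pytest.approx(fit.bse[1] / np.sqrt(fit.scale) * scale, rel=1e-10)

    def test_orientation_invariance(self):
        """Flipping any (gamma, alpha) pair jointly leaves Egger unchanged."""
        rng = np.random.default_rng(3)
        g = rng.normal(0.1, 0.03, 8)
        a = 0.05 + 0.4 * g + rng.normal(0, 0.01, 8)
        inst = make_instruments(g, [0.003] * 8, a, [0.01] * 8)
        flipped = make_instruments(-g, [0.003] * 8, -a, [0.01] * 8)
        s1, i1 = est.mr_egger(inst)
        s2, i2 = est.mr_egger(flipped)
        assert s1.beta == pytest.approx(s2.beta, rel=1e-12)
        assert i1.intercept == pytest.approx(i2.intercept, rel=1e-12)

    def test_too_few_instruments(self):
        inst = make_instruments([0.1, 0.2], [0.003] * 2, [0.01, 0.02], [0.01] * 2)
        with pytest.raises(EstimatorError, match=">= 3"):
            est.mr_egger(inst)


class TestCochransQ:
    def test_equal_ratios_give_zero_q(self):
        g = np.array([0.05, 0.1, 0.2])
        inst = make_instruments(g, [0.003] * 3, 0.3 * g, [0.01] * 3)
        r = est.cochrans_q(inst, 0.3)
        assert r.q == pytest.approx(0.0, abs=1e-20)
        assert r.q_pval == pytest.approx(1.0)
        assert r.q_df == 2

    def test_df_insufficient_fatal(self):
        inst = make_instruments([0.1], [0.003], [0.02], [0.01])
        with pytest.raises(EstimatorError):
            est.cochrans_q(inst, 0.2, n_params=1)


class TestChi2UpperTail:
    def test_df2_closed_form(self):
        for q in [0.0, 0.301, 1.462, 5.0, 20.0]:
            assert est.chi2_upper_tail(q, 2) == pytest.approx(math.exp(-q / 2), rel=1e-12)

    def test_zero_q_gives_one(self):
        for df in [1, 2, 5, 30]:
            assert est.chi2_upper_tail(0.0, df) == 1.0

    @given(st.floats(0, 100), st.floats(0.001, 100), st.integers(1, 30))
    def test_monotone_decreasing_in_q(self, q, dq, df):
        assert est.chi2_upper_tail(q + dq, df) <= est.chi2_upper_tail(q, df) + 1e-15

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            est.chi2_upper_tail(-1.0, 2)
        with pytest.raises(ValueError):
            est.chi2_upper_tail(1.0, 0)


class TestMaximumLikelihood:
    def test_small_sigma_gamma_limit_is_ivw(self, random_instruments):
        inst = [i.__class__(**{**_fields(i), "se_gamma": 1e-8}) for i in random_instruments]
        ml = est.maximum_likelihood(inst)
        fixed = est.ivw(inst, effects_model="fixed")
        assert ml.beta == pytest.approx(fixed.beta, abs=1e-4)
        assert ml.se == pytest.approx(fixed.se, rel=1e-2)

    def test_collinear_exact(self, collinear_instruments):
        assert est.maximum_likelihood(collinear_instruments).beta == pytest.approx(-0.28, abs=1e-9)

    def test_grid_search_oracle(self, random_instruments):
        """Independent oracle: joint likelihood with per-SNP nuisance means
        minimized numerically, profiled over a beta grid of step 1e-4."""
        g, sg, a, sa = arrays(random_instruments)
        ml = est.maximum_likelihood(random_instruments)

        def joint_neg2ll(beta):
            total = 0.0
            for gj, sgj, aj, saj in zip(g, sg, a, sa):
                obj = lambda gi: (gj - gi) ** 2 / sgj**2 + (aj - beta * gi) ** 2 / saj**2
                total += optimize.minimize_scalar(obj).fun
            return total

        grid = np.arange(ml.beta - 0.005, ml.beta + 0.005, 1e-4)
        values = [joint_neg2ll(b) for b in grid]
        assert abs(ml.beta - grid[int(np.argmin(values))]) <= 1e-4


def _fields(inst):
    return {k: getattr(inst, k) for k in (
        "rsid", "effect_allele", "other_allele", "gamma", "se_gamma",
        "alpha", "se_alpha", "eaf_exposure", "eaf_outcome",
        "pval_exposure", "pval_outcome", "flipped", "palindromic")}


class TestWeightedMedian:
    def test_equal_weight_middle_element(self):
        inst = make_instruments([0.1, 0.1, 0.1], [0.003] * 3,
                                [0.01, 0.02, 0.09], [0.01] * 3)
        e = est.weighted_median(inst, n_boot=0)
        assert e.beta == pytest.approx(0.2, rel=1e-12)

    def test_all_equal_ratios(self):
        g = np.array([0.05, 0.1, 0.2, 0.15])
        inst = make_instruments(g, [0.003] * 4, 0.7 * g, [0.01] * 4)
        e = est.weighted_median(inst, n_boot=200, seed=5)
        assert e.beta == pytest.approx(0.7, rel=1e-10)
        assert e.se < 0.2

    def test_interpolation_oracle_unequal_weights(self):
        rng = np.random.default_rng(11)
        J = 7
        g = rng.normal(0.1, 0.02, J)
        sa = rng.uniform(0.004, 0.02, J)
        a = 0.25 * g + rng.normal(0, sa)
        inst = make_instruments(g, [0.003] * J, a, sa)
        ratios = a / g
        w = (np.abs(g) / sa) ** 2
        # hand implementation of the cumulative-weight interpolation
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], w[order] / w.sum()
        cum = np.cumsum(w_s) - 0.5 * w_s
        k = np.searchsorted(cum, 0.5)
        expected = r_s[k - 1] + (r_s[k] - r_s[k - 1]) * (0.5 - cum[k - 1]) / (cum[k] - cum[k - 1])
        e = est.weighted_median(inst, n_boot=0)
        assert e.beta == pytest.approx(expected, rel=1e-12)

    def test_dominant_weight_converges_to_its_ratio(self):
        # one instrument carries ~all the weight -> its Wald ratio wins
        inst = make_instruments([0.1, 0.1, 0.1], [0.003] * 3,
                                [0.01, 0.05, 0.09], [1e-6, 1.0, 1.0])
        e = est.weighted_median(inst, n_boot=0)
        assert e.beta == pytest.approx(0.1, abs=1e-3)

    def test_penalized_downweights_outlier(self):
        g = np.full(9, 0.1)
        a = 0.1 * g  # ratios all 0.1
        a[0] = 0.5 * g[0] * 10  # one wild outlier ratio
        inst = make_instruments(g, [0.003] * 9, a, [0.005] * 9)
        plain = est.weighted_median(inst, n_boot=0)
        pen = est.weighted_median(inst, penalized=True, n_boot=0)
        assert abs(pen.beta - 0.1) <= abs(plain.beta - 0.1) + 1e-12

    def test_seed_required_for_bootstrap(self):
        inst = make_instruments([0.1] * 3, [0.003] * 3, [0.02] * 3, [0.01] * 3)
        with pytest.raises(ValueError, match="seed"):
            est.weighted_median(inst, n_boot=100)


class TestModeEstimator:
    def test_all_equal_ratios(self):
        g = np.array([0.05, 0.1, 0.2])
        inst = make_instruments(g, [0.003] * 3, 0.4 * g, [0.01] * 3)
        e = est.mode_estimator(inst, n_boot=0)
        assert e.beta == pytest.approx(0.4, abs=1e-9)

    def test_majority_cluster_wins(self):
        ratios = np.array([0.199, 0.2, 0.201, 0.2005, 0.1995, 0.9, 0.91])
        g = np.full(7, 0.1)
        inst = make_instruments(g, [0.003] * 7, ratios * g, [0.01] * 7)
        e = est.mode_estimator(inst, n_boot=0)
        assert e.beta == pytest.approx(0.2, abs=0.01)

    def test_dense_grid_oracle(self):
        rng = np.random.default_rng(23)
        J = 9
        g = rng.normal(0.1, 0.02, J)
        sa = rng.uniform(0.005, 0.015, J)
        a = 0.3 * g + rng.normal(0, sa)
        inst = make_instruments(g, [0.003] * J, a, sa)
        ratios = a / g
        for weighted in (False, True):
            w = (np.abs(g) / sa) ** 2 if weighted else np.ones(J)
            wn = w / w.sum()
            s = float(np.std(ratios, ddof=1))
            from scipy.stats import median_abs_deviation
            mad = float(median_abs_deviation(ratios, scale="normal"))
            h = 0.9 * min(s, mad) * J ** (-1 / 5)
            grid = np.arange(ratios.min() - 3 * h, ratios.max() + 3 * h, 1e-4)
            dens = np.zeros_like(grid)
            for rj, wj in zip(ratios, wn):  # independent kernel-sum evaluation
                dens += wj * np.exp(-0.5 * ((grid - rj) / h) ** 2)
            expected = grid[int(np.argmax(dens))]
            e = est.mode_estimator(inst, weighted=weighted, n_boot=0)
            assert e.beta == pytest.approx(expected, abs=1.5e-4)

    def test_bootstrap_se_positive_and_seeded(self):
        rng = np.random.default_rng(2)
        g = rng.normal(0.1, 0.02, 8)
        a = 0.2 * g + rng.normal(0, 0.01, 8)
        inst = make_instruments(g, [0.003] * 8, a, [0.01] * 8)
        e1 = est.mode_estimator(inst, n_boot=100, seed=4)
        e2 = est.mode_estimator(inst, n_boot=100, seed=4)
        assert e1.se > 0 and e1.se == e2.se


class TestRAPS:
    def test_small_sigma_gamma_limit_is_ivw(self, random_instruments):
        inst = [i.__class__(**{**_fields(i), "se_gamma": 1e-9}) for i in random_instruments]
        r = est.raps(inst)
        fixed = est.ivw(inst, effects_model="fixed")
        assert r.beta == pytest.approx(fixed.beta, abs=1e-4)

    def test_collinear_exact(self, collinear_instruments):
        assert est.raps(collinear_instruments).beta == pytest.approx(-0.28, abs=1e-10)

    def test_bisection_oracle(self):
        rng = np.random.default_rng(31)
        J = 20
        g = rng.normal(0.1, 0.04, J)
        sg = rng.uniform(0.002, 0.01, J)
        sa = rng.uniform(0.004, 0.02, J)
        a = -0.15 * g + rng.normal(0, sa)
        inst = make_instruments(g, sg, a, sa)
        r = est.raps(inst)

        def score(beta):  # independent coding of the adjusted profile score
            return sum(
                (aj - beta * gj) * gj / (saj**2 + beta**2 * sgj**2)
                for gj, sgj, aj, saj in zip(g, sg, a, sa))

        root = optimize.bisect(score, r.beta - 0.5, r.beta + 0.5, xtol=1e-12)
        assert r.beta == pytest.approx(root, abs=1e-8)

    def test_overdispersion_reweights_and_recovers(self):
        rng = np.random.default_rng(13)
        J = 30
        g = rng.normal(0.1, 0.03, J)
        sa = rng.uniform(0.003, 0.02, J)  # heteroskedastic outcome SEs
        # extra pleiotropic noise far above sa: strong overdispersion
        a = 0.2 * g + rng.normal(0, 0.05, J)
        inst = make_instruments(g, [0.001] * J, a, sa)
        plain = est.raps(inst)
        over = est.raps(inst, overdispersion=True)
        # the fitted tau2 flattens the weights, so the roots must differ,
        # while both stay in the neighbourhood of the true slope
        assert over.beta != plain.beta
        assert over.beta == pytest.approx(0.2, abs=0.3)

    def test_overdispersion_noop_when_no_excess_spread(self, collinear_instruments):
        plain = est.raps(collinear_instruments)
        over = est.raps(collinear_instruments, overdispersion=True)
        assert over.beta == pytest.approx(plain.beta, abs=1e-10)


class TestLeaveOneOut:
    def test_length_and_homogeneous_within_ci(self):
        g = np.linspace(0.08, 0.2, 4)
        inst = make_instruments(g, [0.003] * 4, 0.3 * g, [0.01] * 4)
        loo = est.leave_one_out(inst)
        assert len(loo.estimates) == 4
        for _, e in loo.estimates:
            assert e.n_snps == 3
            assert loo.full.ci_low <= e.beta <= loo.full.ci_high

    def test_planted_outlier_moves_farthest(self):
        rng = np.random.default_rng(17)
        J = 8
        g = rng.normal(0.12, 0.02, J)
        a = 0.25 * g + rng.normal(0, 0.002, J)
        a[3] += 0.2  # analytically planted outlier
        inst = make_instruments(g, [0.003] * J, a, [0.01] * J)
        loo = est.leave_one_out(inst)
        shifts = {rsid: abs(e.beta - loo.full.beta) for rsid, e in loo.estimates}
        assert max(shifts, key=shifts.get) == inst[3].rsid


def test_weighted_median_more_robust_than_ivw_to_invalid_instruments():
    """With 40% of instruments carrying directional pleiotropy, the weighted
    median (majority-valid consistent) should beat IVW on absolute error."""
    rng = np.random.default_rng(8)
    J = 30
    beta = -0.28
    g = np.abs(rng.normal(0.1, 0.03, J))
    sa = rng.uniform(0.004, 0.01, J)
    a = beta * g + rng.normal(0, sa)
    a[: int(0.4 * J)] += 0.05  # invalid instruments: direct outcome effects
    inst = make_instruments(g, [0.003] * J, a, sa)
    ivw_err = abs(est.ivw(inst).beta - beta)
    wm_err = abs(est.weighted_median(inst, n_boot=0).beta - beta)
    assert wm_err < ivw_err


class TestEquivariance:
    @pytest.mark.parametrize("estimator", [
        lambda i: est.ivw(i),
        lambda i: est.mr_egger(i)[0],
        est.maximum_likelihood,
        est.raps,
        lambda i: est.weighted_median(i, n_boot=0),
        lambda i: est.mode_estimator(i, n_boot=0),
    ])
    def test_negating_alpha_negates_estimate(self, random_instruments, estimator):
        neg = [i.__class__(**{**_fields(i), "alpha": -i.alpha}) for i in random_instruments]
        e_pos = estimator(random_instruments)
        e_neg = estimator(neg)
        assert e_neg.beta == pytest.approx(-e_pos.beta, rel=1e-6, abs=1e-10)
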