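import numpy as np
import pytest
from scipy import stats

import croptail as ct
from croptail.dependence import _profile_nll, fit_conditional
from croptail.marginal import laplace_quantile


def brute_force_feasible(a, b, z_lo, z_hi, v_max, n_grid=2000):
    """Direct numeric evaluation of the envelope conditions on a huge v-grid."""
    if not (-1.0 <= a <= 1.0 and b < 1.0):
        return False
    v = np.geomspace(v_max, v_max * 1e8, n_grid)
    upper_ok = np.all(a * v + v**b * z_hi <= v * (1 + 1e-12))
    lower_ok = np.all(a * v + v**b * z_lo >= -v * (1 + 1e-12))
    return bool(upper_ok and lower_ok)


class TestConstraints:
    def test_box_violations_infeasible(self):
        assert not ct.constraints_feasible(1.2, 0.0, -1.0, 1.0, 5.0)
        assert not ct.constraints_feasible(-1.2, 0.0, -1.0, 1.0, 5.0)
        assert not ct.constraints_feasible(0.5, 1.0, -1.0, 1.0, 5.0)

    def test_agrees_with_brute_force(self, rng):
        """Predicate matches direct numeric evaluation on 100 random candidates."""
        for _ in range(100):
            a = rng.uniform(-1.05, 1.05)
            b = rng.uniform(-2.0, 1.05)
            z_lo = rng.uniform(-3.0, 0.5)
            z_hi = z_lo + rng.uniform(0.0, 4.0)
            v_max = rng.uniform(1.5, 10.0)
            assert ct.constraints_feasible(a, b, z_lo, z_hi, v_max) == \
                brute_force_feasible(a, b, z_lo, z_hi, v_max)

    def test_perfect_positive_dependence_edge(self):
        # a=1 feasible only when the upper residual quantile is non-positive
        assert ct.constraints_feasible(1.0, 0.0, -0.5, 0.0, 5.0)
        assert not ct.constraints_feasible(1.0, 0.0, -0.5, 0.1, 5.0)


class TestFitConditional:
    def test_reconstruction_exact(self, laplace_gaussian_pair):
        pair, _ = laplace_gaussian_pair
        fit = ct.fit_conditional(pair.response, pair.conditioning)
        recon = fit.a * fit.cond_exceedances + fit.cond_exceedances**fit.b * fit.residuals
        np.testing.assert_allclose(recon, fit.resp_exceedances, atol=1e-10)

    def test_gaussian_sign_and_slope(self, laplace_gaussian_pair):
        pair, _ = laplace_gaussian_pair
        fit = ct.fit_conditional(pair.response, pair.conditioning)
        assert fit.a == pytest.approx(0.49, abs=0.10)
        assert 0.0 < fit.b < 1.0

    def test_perfect_dependence(self):
        spec = ct.SyntheticSpec(family="perfect", n=5000, marginal="laplace", seed=2)
        pair, _ = ct.gen_pair(spec)
        fit = ct.fit_conditional(pair.response, pair.conditioning)
        assert fit.a == pytest.approx(1.0, abs=0.02)
        assert np.std(fit.residuals) < 1e-6
        assert fit.b_unidentified

    def test_independence_limit(self):
        spec = ct.SyntheticSpec(family="independent", n=50000, marginal="laplace", seed=0)
        pair, _ = ct.gen_pair(spec)
        fit = ct.fit_conditional(pair.response, pair.conditioning)
        assert abs(fit.a) < 0.1
        ks = stats.kstest(fit.residuals, stats.laplace.cdf).statistic
        assert ks < 0.05

    @pytest.mark.parametrize("rho,sign", [(0.6, 1), (-0.6, -1)])
    def test_sign_consistency(self, rho, sign):
        """Positive (negative) monotone tail dependence gives a-hat of matching sign."""
        hits = 0
        for rep in range(20):
            spec = ct.SyntheticSpec(family="gaussian", rho=rho, n=5000,
                                    marginal="laplace", seed=1000 + rep)
            pair, _ = ct.gen_pair(spec)
            fit = ct.fit_conditional(pair.response, pair.conditioning)
            hits += (np.sign(fit.a) == sign)
        assert hits >= 19

    def test_too_few_exceedances(self, rng):
        y = laplace_quantile(rng.random(50))
        with pytest.raises(ValueError, match="exceedances"):
            ct.fit_conditional(y, y, q_dep=0.9)

    def test_multistart_stability(self, rng):
        """Best feasible objective is insensitive to the starting point."""
        spec = ct.SyntheticSpec(family="gaussian", rho=0.5, n=20000, marginal="laplace", seed=9)
        pair, _ = ct.gen_pair(spec)
        nlls = []
        for _ in range(10):
            start = ((rng.uniform(-0.9, 0.9), rng.uniform(-1.0, 0.9)),)
            fit = fit_conditional(pair.response, pair.conditioning, starts=start)
            nlls.append(fit.negloglik)
        assert max(nlls) - min(nlls) < 1e-4


class TestProfileSurface:
    def test_fit_attains_grid_optimum(self, laplace_gaussian_pair):
        pair, _ = laplace_gaussian_pair
        fit = ct.fit_conditional(pair.response, pair.conditioning)
        surf = ct.profile_surface(pair.response, pair.conditioning,
                                  a_grid=np.linspace(0.2, 0.8, 25),
                                  b_grid=np.linspace(-0.2, 0.8, 25))
        feas = surf[surf["feasible"]]
        best = feas.loc[feas["nll"].idxmin()]
        da = np.diff(np.unique(surf["a"]))[0]
        db = np.diff(np.unique(surf["b"]))[0]
        assert abs(best["a"] - fit.a) <= da + 1e-9
        assert abs(best["b"] - fit.b) <= db + 1e-9

    def test_fitted_value_beats_random_feasible_nodes(self, laplace_gaussian_pair, rng):
        pair, _ = laplace_gaussian_pair
        fit = ct.fit_conditional(pair.response, pair.conditioning)
        u = fit.dep_threshold
        mask = pair.conditioning > u
        y, yr = pair.conditioning[mask], pair.response[mask]
        for _ in range(50):
            a, b = rng.uniform(-0.99, 0.99), rng.uniform(-1.5, 0.95)
            nll, _, _ = _profile_nll(a, b, y, yr)
            assert fit.negloglik <= nll + 1e-9

    def test_perfect_dependence_on_a_edge(self):
        spec = ct.SyntheticSpec(family="perfect", n=2000, marginal="laplace", seed=5)
        pair, _ = ct.gen_pair(spec)
        surf = ct.profile_surface(pair.response, pair.conditioning, constrain=False)
        best = surf.loc[surf["nll"].idxmin()]
        assert best["a"] == surf["a"].max()


class TestThresholdStability:
    def test_entry_per_candidate_and_guards(self):
        spec = ct.SyntheticSpec(family="gaussian", rho=0.5, n=500, marginal="laplace", seed=7)
        pair, _ = ct.gen_pair(spec)
        grid = list(np.arange(0.50, 0.901, 0.05)) + [0.999]
        trace = ct.threshold_stability(pair.response, pair.conditioning,
                                       quantile_grid=grid, n_boot=5, seed=1)
        assert len(trace) == len(grid)
        assert not trace.iloc[-1]["fitted"]  # q=0.999 leaves < 10 of 500

    def test_stable_under_exact_model(self):
        """Data from the conditional model itself: a-hat drifts less than the bootstrap bands."""
        spec = ct.SyntheticSpec(family="ht-exact", a=0.5, b=0.2, resid_sd=0.5,
                                n=4000, marginal="laplace", seed=11)
        pair, _ = ct.gen_pair(spec)
        trace = ct.threshold_stability(pair.response, pair.conditioning,
                                       quantile_grid=np.arange(0.6, 0.901, 0.1),
                                       n_boot=15, seed=2)
        fitted = trace[trace["fitted"]]
        widest = (fitted["a_hi"] - fitted["a_lo"]).max()
        assert fitted["a"].max() - fitted["a"].min() < widest


class TestResidualDiagnostics:
    def test_independent_under_exact_model(self):
        pvals = []
        for rep in range(30):
            spec = ct.SyntheticSpec(family="ht-exact", a=0.4, b=0.3, n=2000,
                                    marginal="laplace", seed=500 + rep)
            pair, _ = ct.gen_pair(spec)
            fit = ct.fit_conditional(pair.response, pair.conditioning)
            diag = ct.residual_independence_diag(fit)
            pvals.append(diag["p_value"])
        assert np.mean(np.array(pvals) > 0.01) >= 0.9

    def test_constructed_failure_detected(self, laplace_gaussian_pair):
        pair, _ = laplace_gaussian_pair
        fit = ct.fit_conditional(pair.response, pair.conditioning)
        fit.residuals = fit.cond_exceedances.copy()
        diag = ct.residual_independence_diag(fit)
        assert diag["spearman_rho"] == pytest.approx(1.0)

    def test_guard_small_sample(self, laplace_gaussian_pair):
        pair, _ = laplace_gaussian_pair
        fit = ct.fit_conditional(pair.response, pair.conditioning)
        fit.residuals = fit.residuals[:5]
        fit.cond_exceedances = fit.cond_exceedances[:5]
        with pytest.raises(ValueError, match="residuals"):
            ct.residual_independence_diag(fit)
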