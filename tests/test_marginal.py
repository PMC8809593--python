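import numpy as np
import pytest
from scipy import stats

import croptail as ct
from croptail.marginal import GPDParams, MarginalModel, gpd_negloglik


def constructed_model(beta=1.0, xi=0.0):
    """Marginal model with known splice: body 1..9 (pp i/10), threshold 8, F(u)=0.8."""
    body = np.arange(1.0, 10.0)
    gpd = GPDParams(beta=beta, xi=xi, se_beta=0.1, se_xi=0.1, n_exceedances=2, loglik=0.0)
    return MarginalModel(threshold=8.0, q_threshold=0.8, tail_fraction=0.2,
                         gpd=gpd, body_sample=body)


class TestMeanResidualLife:
    def test_hand_computed(self):
        mrl = ct.mean_residual_life([1.0, 2.0, 3.0, 4.0], [2.0])
        assert mrl.loc[0, "mean_excess"] == pytest.approx(1.5)
        assert mrl.loc[0, "n_exceedances"] == 2

    def test_exponential_memorylessness(self, rng):
        x = rng.exponential(size=20000)
        mrl = ct.mean_residual_life(x, [0.0, 0.5, 1.0, 2.0])
        ok = mrl[mrl["defined"]]
        # mean excess of Exp(1) is 1 at every threshold
        assert np.all(np.abs(ok["mean_excess"] - 1.0) < 3 * ok["se"] + 0.01)

    def test_grid_above_max_flagged(self):
        mrl = ct.mean_residual_life([1.0, 2.0, 3.0], [3.0, 5.0])
        assert not mrl["defined"].any()


class TestGPDFit:
    def test_exponential_limit(self, rng):
        exc = rng.exponential(scale=2.0, size=4000)
        fit = ct.fit_gpd_mle(exc, 0.0)
        assert abs(fit.xi) < 3 * fit.se_xi + 0.02
        assert fit.beta == pytest.approx(np.mean(exc), rel=0.05)

    def test_too_few_exceedances(self):
        with pytest.raises(ValueError, match="exceedances"):
            ct.fit_gpd_mle(np.arange(1.0, 6.0), 0.0, min_exceedances=10)

    def test_negative_shape_support_constraint(self, rng):
        exc = rng.uniform(0, 1, size=2000)  # bounded: xi < 0 expected
        fit = ct.fit_gpd_mle(exc, 0.0)
        assert fit.xi < 0
        # fitted upper endpoint beyond the largest exceedance
        assert -fit.beta / fit.xi > exc.max()

    def test_matches_grid_search_oracle(self, rng):
        """MLE log-likelihood agrees with an independent grid-refinement maximizer."""
        for _ in range(5):
            exc = stats.genpareto.rvs(c=rng.uniform(-0.2, 0.4), scale=rng.uniform(0.5, 2),
                                      size=60, random_state=rng)
            fit = ct.fit_gpd_mle(exc, 0.0)
            nll_grid = grid_search_nll(exc)
            assert -fit.loglik <= nll_grid + 1e-6


class TestSemiparametricCDF:
    def test_continuity_at_threshold(self):
        m = constructed_model()
        assert m.cdf(8.0)[0] == pytest.approx(0.8)

    def test_closed_form_exponential_tail(self):
        m = constructed_model(beta=1.0, xi=0.0)
        # F(u+1) = 1 - 0.2 * exp(-1)
        assert m.cdf(9.0)[0] == pytest.approx(1 - 0.2 * np.exp(-1), abs=1e-12)

    def test_closed_form_quantile(self):
        m = constructed_model(beta=1.0, xi=0.0)
        # p=0.99: u + log(0.2/0.01)
        assert m.quantile(0.99)[0] == pytest.approx(8.0 + np.log(20.0), abs=1e-12)
        assert m.quantile(0.8)[0] == pytest.approx(8.0)

    def test_monotone_and_limits(self):
        m = constructed_model(beta=0.7, xi=0.15)
        xs = np.linspace(0.0, 60.0, 500)
        ps = m.cdf(xs)
        assert np.all(np.diff(ps) >= 0)
        assert m.cdf(1e9)[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("xi", [-0.2, 0.0, 0.3])
    def test_quantile_cdf_roundtrip(self, xi, rng):
        x = stats.t.rvs(df=4, size=800, random_state=rng)
        m = MarginalModel.fit(x, q_threshold=0.8)
        p = rng.uniform(0.81, 0.9999, size=100)  # above the splice
        np.testing.assert_allclose(m.cdf(m.quantile(p)), p, atol=1e-9)

    def test_invalid_levels_rejected(self):
        m = constructed_model()
        with pytest.raises(ValueError):
            m.quantile(0.0)
        with pytest.raises(ValueError):
            m.quantile(1.0)


class TestTailDiagnostics:
    def test_pp_qq_near_diagonal_for_good_fit(self, rng):
        x = stats.genpareto.rvs(c=0.1, scale=1.0, size=4000, random_state=rng)
        m = MarginalModel.fit(x, q_threshold=0.8)
        d = ct.tail_fit_diagnostics(m)
        assert len(d) == m.gpd.n_exceedances
        assert np.max(np.abs(d["prob_fitted"] - d["prob_empirical"])) < 0.08
        # QQ points track the observed exceedances except deep in the tail
        bulk = d.iloc[: int(0.95 * len(d))]
        assert np.corrcoef(bulk["value"], bulk["quantile_fitted"])[0, 1] > 0.99


class TestLaplaceTransform:
    def test_pointwise_values(self):
        m = constructed_model()
        # F(2.5)=0.25 by body interpolation -> log(0.5)
        assert m.to_laplace(2.5)[0] == pytest.approx(np.log(0.5), abs=1e-12)
        # median maps to zero
        assert m.to_laplace(m.quantile(0.5))[0] == pytest.approx(0.0, abs=1e-12)
        # F = 1 - 0.5 e^{-2} maps to exactly 2
        x = m.quantile(1 - 0.5 * np.exp(-2))
        assert m.to_laplace(x)[0] == pytest.approx(2.0, abs=1e-9)

    def test_from_laplace_inverse(self):
        m = constructed_model(beta=1.3, xi=0.1)
        assert m.from_laplace(0.0)[0] == pytest.approx(m.quantile(0.5)[0])
        p = 1 - 0.5 * np.exp(-2)
        assert m.from_laplace(2.0)[0] == pytest.approx(m.quantile(p)[0], abs=1e-12)

    def test_roundtrip_above_splice(self, rng):
        x = stats.t.rvs(df=4, size=1000, random_state=rng)
        m = MarginalModel.fit(x)
        y = rng.uniform(1.7, 6.0, size=100)  # above the Laplace splice of q=0.8
        np.testing.assert_allclose(m.to_laplace(m.from_laplace(y)), y, atol=1e-9)

    def test_probability_integral_transform(self, rng):
        x = rng.gamma(3.0, 2.0, size=2000)
        m = MarginalModel.fit(x)
        y = m.to_laplace(x)
        ks = stats.kstest(y, stats.laplace.cdf).statistic
        assert ks < 1.63 / np.sqrt(2000)


def grid_search_nll(exc, rounds=4, width=41):
    """Independent brute-force GPD maximizer: iterative grid refinement."""
    b_lo, b_hi = 0.05 * np.mean(exc), 5.0 * np.mean(exc)
    x_lo, x_hi = -0.9, 1.5
    best = (np.inf, None, None)
    for _ in range(rounds):
        betas = np.linspace(b_lo, b_hi, width)
        xis = np.linspace(x_lo, x_hi, width)
        for b in betas:
            for x in xis:
                v = gpd_negloglik((b, x), exc)
                if v < best[0]:
                    best = (v, b, x)
        db, dx = betas[1] - betas[0], xis[1] - xis[0]
        b_lo, b_hi = max(best[1] - 2 * db, 1e-6), best[1] + 2 * db
        x_lo, x_hi = best[2] - 2 * dx, best[2] + 2 * dx
    return best[0]
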