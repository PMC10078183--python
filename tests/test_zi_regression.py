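import numpy as np
import pytest
from scipy import stats

from biastree.zi_regression import (
    fit_zi,
    predict_zi,
    vuong_test,
    zi_loglik,
    zi_loglik_obs,
    zi_score,
)


def brute_force_zi_loglik(params, Xc, Xz, y, family):
    """Mixture pmf summed term by term in plain arithmetic via scipy pmfs."""
    pc, pz = Xc.shape[1], Xz.shape[1]
    beta = params[:pc]
    gamma = params[pc:pc + pz]
    total = 0.0
    for i in range(len(y)):
        mu = np.exp(Xc[i] @ beta)
        pi = 1 / (1 + np.exp(-(Xz[i] @ gamma)))
        if family == "poisson":
            f = stats.poisson.pmf(y[i], mu)
        else:
            theta = np.exp(params[-1])
            f = stats.nbinom.pmf(y[i], theta, theta / (theta + mu))
        total += np.log(pi * (y[i] == 0) + (1 - pi) * f)
    return total


def random_instance(rng, family):
    n = int(rng.integers(5, 30))
    pc = int(rng.integers(1, 3))
    pz = int(rng.integers(1, 3))
    Xc = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(pc - 1)])
    Xz = np.column_stack([np.ones(n)] + [rng.standard_normal(n) for _ in range(pz - 1)])
    y = rng.poisson(2.0, n)
    y[rng.random(n) < 0.3] = 0
    k = pc + pz + (1 if family == "negbin" else 0)
    params = rng.standard_normal(k) * 0.5
    return params, Xc, Xz, y


class TestLoglik:
    @pytest.mark.parametrize("family", ["poisson", "negbin"])
    def test_matches_brute_force_oracle(self, rng, family):
        for _ in range(50):
            params, Xc, Xz, y = random_instance(rng, family)
            ours = zi_loglik(params, Xc, Xz, y, family)
            oracle = brute_force_zi_loglik(params, Xc, Xz, y, family)
            assert ours == pytest.approx(oracle, rel=1e-10)

    def test_degenerate_mixture_equals_plain_poisson(self, rng):
        # gamma -> -inf means pi = 0: plain Poisson likelihood
        n = 50
        Xc = np.ones((n, 1))
        y = rng.poisson(3.0, n)
        params = np.array([np.log(3.0), -500.0])
        plain = stats.poisson.logpmf(y, 3.0).sum()
        assert zi_loglik(params, Xc, Xc, y, "poisson") == pytest.approx(plain)

    def test_single_zero_closed_form(self):
        # y=0, pi=0.5, mu=2: log(0.5 + 0.5 e^-2)
        Xc = np.ones((1, 1))
        params = np.array([np.log(2.0), 0.0])
        expected = np.log(0.5 + 0.5 * np.exp(-2.0))
        assert zi_loglik(params, Xc, Xc, np.array([0]), "poisson") == pytest.approx(expected)

    def test_rejects_invalid_counts(self):
        Xc = np.ones((2, 1))
        with pytest.raises(ValueError):
            zi_loglik(np.zeros(2), Xc, Xc, np.array([-1, 2]), "poisson")
        with pytest.raises(ValueError):
            zi_loglik(np.zeros(2), Xc, Xc, np.array([0.5, 2.0]), "poisson")

    @pytest.mark.parametrize("family", ["poisson", "negbin"])
    def test_gradient_matches_finite_differences(self, rng, family):
        for _ in range(10):
            params, Xc, Xz, y = random_instance(rng, family)
            g = zi_score(params, Xc, Xz, y, family)
            fd = np.zeros_like(g)
            for j in range(len(params)):
                e = np.zeros_like(params)
                e[j] = 1e-6
                fd[j] = (
                    zi_loglik(params + e, Xc, Xz, y, family)
                    - zi_loglik(params - e, Xc, Xz, y, family)
                ) / 2e-6
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-7)


def simulate_zip(rng, n, mu, pi):
    N = rng.poisson(mu, n)
    excess = rng.random(n) < pi
    return np.where(excess, 0, N)


class TestFit:
    def test_intercept_only_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        y = simulate_zip(rng, 5000, mu=5.0, pi=0.5)
        X = np.ones((5000, 1))
        fit = fit_zi(X, X, y, family="poisson")
        assert fit.converged
        mu_hat = float(np.exp(fit.beta[0]))
        pi_hat = float(1 / (1 + np.exp(-fit.gamma[0])))
        assert mu_hat == pytest.approx(5.0, abs=0.2)
        assert pi_hat == pytest.approx(0.5, abs=0.03)

    def test_no_excess_zeros_matches_plain_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 3000
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        fit = fit_zi(X, X, y, family="poisson")
        assert fit.gamma[0] < -2  # pi pushed toward 0
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(fit.beta, glm.params, atol=0.05)

    def test_negbin_poisson_limit(self):
        rng = np.random.default_rng(6)
        y = simulate_zip(rng, 2000, mu=4.0, pi=0.4)
        X = np.ones((2000, 1))
        fp = fit_zi(X, X, y, family="poisson")
        fnb = fit_zi(X, X, y, family="negbin")
        # with no overdispersion, NB converges to the Poisson likelihood
        assert abs(fnb.loglik - fp.loglik) < 1e-3 * len(y)

    def test_matches_statsmodels_zip(self):
        # independent implementation cross-check
        import statsmodels.api as sm

        rng = np.random.default_rng(7)
        n = 2000
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        mu = np.exp(0.8 + 0.4 * x)
        pi = 1 / (1 + np.exp(-(-0.5 + 0.7 * x)))
        y = np.where(rng.random(n) < pi, 0, rng.poisson(mu))
        ours = fit_zi(X, X, y, family="poisson")
        sm_fit = sm.ZeroInflatedPoisson(y, X, exog_infl=X).fit(disp=0, maxiter=200)
        assert ours.loglik == pytest.approx(sm_fit.llf, abs=1e-3)
        np.testing.assert_allclose(ours.beta, sm_fit.params[2:], atol=1e-3)
        np.testing.assert_allclose(ours.gamma, sm_fit.params[:2], atol=1e-3)

    def test_degenerate_responses_rejected(self):
        X = np.ones((50, 1))
        with pytest.raises(ValueError):
            fit_zi(X, X, np.zeros(50, dtype=int))
        with pytest.raises(ValueError):
            fit_zi(X, X, np.ones(50, dtype=int))

    def test_bias_shrinks_with_sample_size(self):
        mu, pi = 5.0, 0.5
        errs = {}
        for n in (500, 8000):
            e = []
            for rep in range(5):
                rng = np.random.default_rng(100 + rep)
                y = simulate_zip(rng, n, mu, pi)
                X = np.ones((n, 1))
                fit = fit_zi(X, X, y, family="poisson")
                e.append(abs(np.exp(fit.beta[0]) - mu) + abs(fit.gamma[0]))
            errs[n] = np.mean(e)
        assert errs[8000] < errs[500]

    def test_loglik_improves_over_initialization(self):
        rng = np.random.default_rng(8)
        y = simulate_zip(rng, 1000, 3.0, 0.4)
        X = np.ones((1000, 1))
        init = np.array([0.1, 0.1])
        fit = fit_zi(X, X, y, family="poisson", init=init)
        assert fit.loglik >= zi_loglik(init, X, X, y, "poisson")

    def test_fitted_mean_matches_sample_mean(self):
        # score equation for intercepts: average E[Y] equals mean(y)
        rng = np.random.default_rng(9)
        y = simulate_zip(rng, 2000, 4.0, 0.3)
        X = np.ones((2000, 1))
        fit = fit_zi(X, X, y, family="poisson")
        preds = predict_zi(fit, (X, X), type="whole")
        assert preds.mean() == pytest.approx(y.mean(), rel=1e-4)


class TestPredict:
    def test_closed_form_intercepts(self):
        rng = np.random.default_rng(10)
        y = simulate_zip(rng, 200, 3.0, 0.4)
        X = np.ones((200, 1))
        fit = fit_zi(X, X, y, family="poisson")
        fit.beta[0], fit.gamma[0] = 1.0, 0.0
        p = predict_zi(fit, (X, X), type="all")
        assert p.count[0] == pytest.approx(np.e)
        assert p.zero[0] == pytest.approx(0.5)
        assert p.whole[0] == pytest.approx(np.e / 2)

    def test_whole_never_exceeds_count(self, small_landscape, observed_world):
        _, Y, _, _ = observed_world
        X, names = small_landscape.design_matrix()
        fit = fit_zi(X, X, Y, family="poisson", names_count=names, names_zero=names)
        p = predict_zi(fit, small_landscape, type="all")
        assert (p.whole <= p.count + 1e-12).all()
        assert ((p.zero > 0) & (p.zero < 1)).all()

    def test_design_mismatch_raises(self, small_landscape, observed_world):
        _, Y, _, _ = observed_world
        X, names = small_landscape.design_matrix()
        fit = fit_zi(X, X, Y, family="poisson", names_count=names, names_zero=names)
        import copy

        other = copy.deepcopy(small_landscape)
        other.cells["landclass"] = other.cells["landclass"].cat.rename_categories(
            {"landclass_2": "landclass_9"})
        with pytest.raises(ValueError, match="landclass"):
            predict_zi(fit, other, type="count")


class TestVuong:
    def _two_fits(self, seed=11):
        rng = np.random.default_rng(seed)
        n = 2000
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x])
        lam = rng.gamma(0.5, np.exp(0.5 + 0.3 * x) / 0.5)
        N = rng.poisson(lam)
        y = np.where(rng.random(n) < 0.3, 0, N)
        f1 = fit_zi(X, X, y, family="negbin")
        f2 = fit_zi(X, X, y, family="poisson")
        return f1, f2

    def test_identical_fits_give_zero(self):
        f1, _ = self._two_fits()
        res = vuong_test(f1, f1, correction="none")
        assert res.z == 0.0

    def test_aic_correction_arithmetic(self):
        f1, f2 = self._two_fits()
        f1.k, f2.k, f1.n, f2.n = 81, 80, 10_000, 10_000
        res = vuong_test(f1, f2, correction="aic")
        assert res.c == pytest.approx(1.0)
        res_aicc = vuong_test(f1, f2, correction="aicc")
        expected = (81 + 81 * 82 / (10_000 - 82)) - (80 + 80 * 81 / (10_000 - 81))
        assert res_aicc.c == pytest.approx(expected)

    def test_nb_favored_on_overdispersed_data(self):
        f_nb, f_pois = self._two_fits(seed=12)
        res = vuong_test(f_pois, f_nb, correction="aicc")
        assert res.z < 0  # negative favors the NB model (fit2)
        assert res.favored == "fit2"

    def test_mismatched_n_rejected(self):
        f1, _ = self._two_fits()
        import copy

        f3 = copy.deepcopy(f1)
        f3.n = f1.n - 1
        f3.llobs = f1.llobs[:-1]
        with pytest.raises(ValueError):
            vuong_test(f1, f3)
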