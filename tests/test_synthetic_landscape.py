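import numpy as np
import pandas as pd
import pytest
from scipy import stats

from biastree.synthetic_landscape import (
    LandscapeConfig,
    TruthConfig,
    generate_landscape,
    place_points,
    simulate_field_survey,
    simulate_recorders,
    simulate_sampling,
    simulate_true_abundance,
)


def morans_i_lag1(field2d):
    """Brute-force Moran's I with rook (lag-1) neighbours."""
    z = field2d - field2d.mean()
    num = 0.0
    wsum = 0
    nr, nc = z.shape
    for i in range(nr):
        for j in range(nc):
            for di, dj in ((0, 1), (1, 0), (0, -1), (-1, 0)):
                a, b = i + di, j + dj
                if 0 <= a < nr and 0 <= b < nc:
                    num += z[i, j] * z[a, b]
                    wsum += 1
    return (z.size / wsum) * num / (z**2).sum()


class TestGenerateLandscape:
    def test_minimal_single_cell(self):
        cfg = LandscapeConfig(n_rows=1, n_cols=1, n_numeric_covariates=2,
                              categorical_levels={"lc": 2}, seed=0)
        lsc = generate_landscape(cfg)
        assert lsc.n_cells == 1
        assert np.isfinite(lsc.cells[["cov1", "cov2"]].to_numpy()).all()
        assert lsc.cells["lc"].iloc[0] in {"lc_0", "lc_1"}

    def test_deterministic_given_seed(self):
        cfg = LandscapeConfig(n_rows=6, n_cols=7, n_numeric_covariates=3,
                              categorical_levels={"lc": 3}, seed=5)
        a = generate_landscape(cfg)
        b = generate_landscape(cfg)
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_correlation_length_raises_spatial_autocorrelation(self):
        smooth = generate_landscape(LandscapeConfig(
            n_rows=30, n_cols=30, n_numeric_covariates=1,
            covariate_correlation_length=10_000.0, seed=3))
        rough = generate_landscape(LandscapeConfig(
            n_rows=30, n_cols=30, n_numeric_covariates=1,
            covariate_correlation_length=100.0, seed=3))
        i_smooth = morans_i_lag1(smooth.cells["cov1"].to_numpy().reshape(30, 30))
        i_rough = morans_i_lag1(rough.cells["cov1"].to_numpy().reshape(30, 30))
        assert i_smooth > i_rough

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            LandscapeConfig(n_rows=0, n_cols=5)
        with pytest.raises(ValueError):
            LandscapeConfig(n_rows=2, n_cols=2, categorical_levels={"lc": 1})

    def test_numeric_covariates_standardized(self, small_landscape):
        v = small_landscape.cells["cov1"].to_numpy()
        assert abs(v.mean()) < 1e-10
        assert abs(v.std() - 1) < 1e-10


class TestTrueAbundance:
    def test_poisson_limit_mean(self):
        lsc = generate_landscape(LandscapeConfig(n_rows=100, n_cols=100,
                                                 n_numeric_covariates=0, seed=0))
        truth = TruthConfig(beta_count=(np.log(5.0),), theta=1e6,
                            gamma_zero=(0.0,), seed=1)
        N = simulate_true_abundance(lsc, truth)
        se = np.sqrt(5.0 / N.size)
        assert abs(N.mean() - 5.0) < 3 * se

    def test_vanishing_mean_all_zero(self):
        lsc = generate_landscape(LandscapeConfig(n_rows=20, n_cols=20,
                                                 n_numeric_covariates=0, seed=0))
        truth = TruthConfig(beta_count=(-20.0,), theta=1.0, gamma_zero=(0.0,), seed=1)
        assert simulate_true_abundance(lsc, truth).sum() == 0

    def test_nb_variance_identity(self):
        # var = mu + mu^2/theta = 5 + 25/0.2 = 130
        lsc = generate_landscape(LandscapeConfig(n_rows=100, n_cols=200,
                                                 n_numeric_covariates=0, seed=0))
        truth = TruthConfig(beta_count=(np.log(5.0),), theta=0.2,
                            gamma_zero=(0.0,), seed=2)
        N = simulate_true_abundance(lsc, truth)
        assert 105 < N.var(ddof=1) < 160

    def test_nonconformable_beta_raises(self, small_landscape):
        truth = TruthConfig(beta_count=(0.0, 0.0), theta=1.0, gamma_zero=(0.0,))
        with pytest.raises(ValueError, match="beta_count"):
            simulate_true_abundance(small_landscape, truth)


class TestSampling:
    def _flat(self, n=100):
        return generate_landscape(LandscapeConfig(n_rows=n, n_cols=n,
                                                  n_numeric_covariates=0, seed=0))

    def test_no_bias_limit(self):
        lsc = self._flat(30)
        truth = TruthConfig(beta_count=(1.0,), theta=2.0,
                            gamma_zero=(-40.0,), detection_prob=1.0, seed=3)
        N = simulate_true_abundance(lsc, truth)
        Y, excess = simulate_sampling(lsc, N, truth)
        assert np.array_equal(Y, N)
        assert not excess.any()

    def test_total_censoring(self):
        lsc = self._flat(20)
        truth = TruthConfig(beta_count=(1.0,), theta=2.0, gamma_zero=(40.0,), seed=3)
        N = simulate_true_abundance(lsc, truth)
        Y, excess = simulate_sampling(lsc, N, truth)
        assert Y.sum() == 0 and excess.all()

    def test_half_censoring_fraction(self):
        lsc = self._flat(100)
        truth = TruthConfig(beta_count=(1.0,), theta=2.0, gamma_zero=(0.0,), seed=4)
        N = simulate_true_abundance(lsc, truth)
        _, excess = simulate_sampling(lsc, N, truth)
        se = 0.5 / np.sqrt(excess.size)
        assert abs(excess.mean() - 0.5) < 3 * se

    def test_flag_consistency(self, small_landscape, small_truth, observed_world):
        _, Y, excess, _ = observed_world
        assert (Y[excess] == 0).all()

    def test_invalid_detection_prob(self):
        with pytest.raises(ValueError):
            TruthConfig(beta_count=(0.0,), theta=1.0, gamma_zero=(0.0,),
                        detection_prob=1.5)

    def test_zi_marginal_zero_probability(self):
        # homogeneous case: P(Y=0) = pi + (1-pi) * NB(0; mu, theta)
        lsc = self._flat(100)
        mu, theta, pi = 2.0, 0.5, 0.4
        gamma0 = np.log(pi / (1 - pi))
        truth = TruthConfig(beta_count=(np.log(mu),), theta=theta,
                            gamma_zero=(gamma0,), seed=5)
        N = simulate_true_abundance(lsc, truth)
        Y, _ = simulate_sampling(lsc, N, truth)
        p0 = pi + (1 - pi) * (theta / (theta + mu)) ** theta
        se = np.sqrt(p0 * (1 - p0) / Y.size)
        assert abs((Y == 0).mean() - p0) < 4 * se


class TestPlacePoints:
    def test_empty(self, small_landscape):
        recs = place_points(small_landscape, np.zeros(100, dtype=int), seed=0)
        assert len(recs) == 0

    def test_containment_and_conservation(self, small_landscape):
        Y = np.zeros(100, dtype=int)
        Y[37] = 3
        Y[5] = 2
        recs = place_points(small_landscape, Y, seed=1)
        assert len(recs) == 5
        for _, r in recs.iterrows():
            cell = small_landscape.cells.loc[r["cell_id"]]
            assert cell["x_min"] <= r["x"] < cell["x_min"] + 1000
            assert cell["y_min"] <= r["y"] < cell["y_min"] + 1000
        assert (recs["cell_id"].value_counts().sort_index().to_numpy() == [2, 3]).all()


class TestRecorders:
    def test_single_recorder_takes_all(self, small_landscape, observed_world):
        _, _, _, records = observed_world
        _, assigned = simulate_recorders(small_landscape, records, 1, 5000.0, seed=0)
        assert (assigned["recorder_id"] == 0).all()

    def test_deterministic(self, small_landscape, observed_world):
        _, _, _, records = observed_world
        _, a = simulate_recorders(small_landscape, records, 5, 3000.0, seed=9)
        _, b = simulate_recorders(small_landscape, records, 5, 3000.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_infinite_decay_uniform_assignment(self, small_landscape, observed_world):
        _, _, _, records = observed_world
        _, assigned = simulate_recorders(small_landscape, records, 4, 1e12, seed=2)
        counts = assigned["recorder_id"].value_counts().reindex(range(4), fill_value=0)
        p = stats.chisquare(counts.to_numpy()).pvalue
        assert p > 0.01


class TestFieldSurvey:
    def test_census(self):
        out = simulate_field_survey([0, 1], [7, 3], coverage=1.0,
                                    detection_prob=1.0, seed=0)
        assert (out["observed_count"].to_numpy() == [7, 3]).all()
        assert (out["surveyed_area"] == 1e6).all()

    def test_binomial_mean_half_coverage(self):
        n_rep = 10_000
        out = simulate_field_survey(np.arange(n_rep), np.full(n_rep, 100),
                                    coverage=0.5, seed=1)
        se = np.sqrt(100 * 0.5 * 0.5 / n_rep)
        assert abs(out["observed_count"].mean() - 50) < 4 * se

    def test_density_estimator_unbiased(self):
        n_rep = 20_000
        out = simulate_field_survey(
            np.arange(n_rep), np.full(n_rep, 40),
            coverage=lambda r, n: 0.2 + 0.8 * r.random(n), seed=2)
        true_density = 40 / 1e6
        assert abs(out["density"].mean() / true_density - 1) < 0.02

    def test_bad_coverage_rejected(self):
        with pytest.raises(ValueError):
            simulate_field_survey([0], [5], coverage=0.0, seed=0)
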