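import numpy as np
import pytest

from biastree.synthetic_landscape import (
    LandscapeConfig,
    TruthConfig,
    generate_landscape,
    place_points,
    simulate_sampling,
    simulate_true_abundance,
)


@pytest.fixture(scope="session")
def small_landscape():
    """10x10 grid, 2 smooth numeric covariates, one 3-level class."""
    cfg = LandscapeConfig(
        n_rows=10,
        n_cols=10,
        cell_size=1000.0,
        n_numeric_covariates=2,
        categorical_levels={"landclass": 3},
        covariate_correlation_length=2000.0,
        seed=42,
    )
    return generate_landscape(cfg)


@pytest.fixture(scope="session")
def small_truth():
    # intercept, cov1, cov2, landclass_1, landclass_2
    return TruthConfig(
        beta_count=(0.5, 0.7, -0.4, 0.2, -0.2),
        theta=0.8,
        gamma_zero=(-0.3, 0.9, 0.0, 0.0, 0.0),
        seed=7,
    )


@pytest.fixture(scope="session")
def observed_world(small_landscape, small_truth):
    """Full synthetic observation set: (N, Y, excess flags, records)."""
    N = simulate_true_abundance(small_landscape, small_truth)
    Y, excess = simulate_sampling(small_landscape, N, small_truth)
    records = place_points(small_landscape, Y, seed=11)
    return N, Y, excess, records


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
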