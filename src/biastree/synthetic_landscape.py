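"""Synthetic landscapes, true abundances and biased observation processes.

Generates everything the downstream bias-correction stages need, with the
statistical structure real gridded citizen-science data are assumed to
have: a regular grid of square cells (1 km by default) carrying spatially
autocorrelated numeric covariates and spatially coherent categorical
classes; a true per-cell abundance drawn from a log-linear negative
binomial model; an excess-zero (non-sampling) process that is logistic in
the same covariates; point records scattered within sampled cells;
recorder home bases with distance-decaying activity; and partial-coverage
field surveys of selected squares.

True abundances and excess-zero flags are returned separately from the
observed data so that model-fitting code can never see them; tests use
them as oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass(frozen=True)
class LandscapeConfig:
    """Geometry and covariate structure of a synthetic landscape.

    Parameters
    ----------
    n_rows, n_cols
        Grid dimensions; the landscape has ``n_rows * n_cols`` cells.
    cell_size
        Cell edge length in metres (1 km squares by default).
    n_numeric_covariates
        Number of spatially autocorrelated numeric covariates
        (centred and scaled to mean 0, sd 1 over the landscape).
    categorical_levels
        Mapping of categorical covariate name to its number of levels
        (each must have at least 2 levels). Classes are spatially
        coherent, mimicking land-class maps.
    covariate_correlation_length
        Smoothness scale in metres: white noise is smoothed with a
        Gaussian kernel of this spatial scale (a cheap stand-in for a
        Gaussian process with that correlation length).
    seed
        Seed for covariate generation.
    """

    n_rows: int
    n_cols: int
    cell_size: float = 1000.0
    n_numeric_covariates: int = 3
    categorical_levels: dict = field(default_factory=dict)
    covariate_correlation_length: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_numeric_covariates < 0:
            raise ValueError("n_numeric_covariates must be >= 0")
        for name, k in self.categorical_levels.items():
            if k < 2:
                raise ValueError(f"categorical covariate {name!r} needs >= 2 levels")


@dataclass(frozen=True)
class TruthConfig:
    """Generative parameters for true abundance and the sampling process.

    ``beta_count`` (log link) and ``gamma_zero`` (logit link) must conform
    to the design matrix implied by the landscape (intercept, numeric
    covariates, then one-hot dummies for each categorical covariate with
    the first level as reference). ``theta`` is the negative-binomial
    dispersion (variance mu + mu^2/theta); ``detection_prob`` binomially
    thins counts inside sampled cells and defaults to 1 because the
    emulated bias is zero-generating, not detection-driven.
    """

    beta_count: tuple
    theta: float
    gamma_zero: tuple
    detection_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be > 0")
        if not (0 < self.detection_prob <= 1):
            raise ValueError("detection_prob must be in (0, 1]")


@dataclass
class Landscape:
    """A grid landscape: cell table plus geometry metadata.

    ``cells`` has one row per cell with columns ``cell_id, row, col,
    x_min, y_min``, the numeric covariates and the categorical covariates.
    Cell (row, col) covers the half-open square
    [x_min, x_min + s) x [y_min, y_min + s).
    """

    cells: pd.DataFrame
    n_rows: int
    n_cols: int
    cell_size: float
    numeric_names: list
    categorical_names: list

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def extent(self) -> tuple:
        """(x_min, y_min, x_max, y_max) of the landscape."""
        return (0.0, 0.0, self.n_cols * self.cell_size, self.n_rows * self.cell_size)

    def design_matrix(self) -> tuple:
        """Full design matrix (intercept, numeric, one-hot categorical).

        Returns ``(X, names)``; the reference level of each categorical
        covariate is its first level and is omitted, matching the
        convention model coefficient tables use for baselines.
        """
        from biastree.grid_records import build_design

        return build_design(self.cells, self.numeric_names, self.categorical_names)

    def cell_id_at(self, x, y):
        """Half-open point-in-cell lookup; -1 for out-of-extent points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor(x / self.cell_size).astype(int)
        row = np.floor(y / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        out = np.where(inside, row * self.n_cols + col, -1)
        return out


def _smooth_field(rng: np.random.Generator, n_rows: int, n_cols: int, sigma_cells: float) -> np.ndarray:
    """White noise smoothed with a Gaussian kernel, re-standardized."""
    z = rng.standard_normal((n_rows, n_cols))
    if sigma_cells > 0:
        z = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="nearest")
    sd = z.std()
    if sd > 0:
        z = (z - z.mean()) / sd
    return z


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate a landscape of cells with spatially structured covariates.

    Numeric covariates are smoothed white noise, centred and scaled over
    the landscape. Categorical covariates are produced by quantile-
    thresholding an independent smoothed latent field, which yields
    spatially coherent patches of each class. Deterministic given the
    config seed.
    """
    rng = np.random.default_rng(config.seed)
    nr, nc = config.n_rows, config.n_cols
    sigma = config.covariate_correlation_length / config.cell_size

    rows, cols = np.divmod(np.arange(nr * nc), nc)
    data = {
        "cell_id": np.arange(nr * nc),
        "row": rows,
        "col": cols,
        "x_min": cols * config.cell_size,
        "y_min": rows * config.cell_size,
    }

    numeric_names = [f"cov{i + 1}" for i in range(config.n_numeric_covariates)]
    for name in numeric_names:
        data[name] = _smooth_field(rng, nr, nc, sigma).ravel()

    categorical_names = list(config.categorical_levels)
    for name in categorical_names:
        k = config.categorical_levels[name]
        latent = _smooth_field(rng, nr, nc, sigma).ravel()
        # quantile thresholds give roughly equal-area classes
        edges = np.quantile(latent, np.linspace(0, 1, k + 1)[1:-1])
        codes = np.searchsorted(edges, latent, side="right")
        data[name] = pd.Categorical.from_codes(
            codes, categories=[f"{name}_{j}" for j in range(k)]
        )

    cells = pd.DataFrame(data)
    return Landscape(
        cells=cells,
        n_rows=nr,
        n_cols=nc,
        cell_size=config.cell_size,
        numeric_names=numeric_names,
        categorical_names=categorical_names,
    )


def simulate_true_abundance(landscape: Landscape, truth: TruthConfig) -> np.ndarray:
    """Draw true per-cell abundances N_i ~ NB(mu_i = exp(x_i . beta), theta).

    Uses the gamma-Poisson mixture representation of the negative
    binomial, so variance is mu + mu^2/theta.
    """
    X, names = landscape.design_matrix()
    beta = np.asarray(truth.beta_count, dtype=float)
    if beta.shape[0] != X.shape[1]:
        raise ValueError(
            f"beta_count has {beta.shape[0]} coefficients but the design "
            f"matrix has {X.shape[1]} columns ({names})"
        )
    mu = np.exp(X @ beta)
    rng = np.random.default_rng(truth.seed)
    lam = rng.gamma(shape=truth.theta, scale=mu / truth.theta)
    return rng.poisson(lam)


def simulate_sampling(landscape: Landscape, N: np.ndarray, truth: TruthConfig):
    """Apply the excess-zero (non-sampling) process and optional thinning.

    With probability pi_i = logistic(x_i . gamma) cell i is never visited:
    its observed count is 0 and it is flagged as an excess zero. Otherwise
    the observed count is Binomial(N_i, detection_prob). Returns
    ``(Y, excess_flags)``; the flags exist only so oracle tests can
    distinguish censored cells — fitting code must never see them.
    """
    N = np.asarray(N)
    if N.shape[0] != landscape.n_cells:
        raise ValueError("N must have one entry per cell")
    X, names = landscape.design_matrix()
    gamma = np.asarray(truth.gamma_zero, dtype=float)
    if gamma.shape[0] != X.shape[1]:
        raise ValueError(
            f"gamma_zero has {gamma.shape[0]} coefficients but the design "
            f"matrix has {X.shape[1]} columns ({names})"
        )
    eta = X @ gamma
    pi = 1.0 / (1.0 + np.exp(-eta))
    rng = np.random.default_rng(truth.seed + 1)
    excess = rng.random(landscape.n_cells) < pi
    Y = rng.binomial(N, truth.detection_prob)
    Y[excess] = 0
    return Y, excess


def place_points(landscape: Landscape, Y: np.ndarray, seed: int) -> pd.DataFrame:
    """Scatter exactly Y_i uniform points inside cell i's square.

    Returns a records table (record_id, x, y, cell_id, status); every
    point carries its generating cell id, and the total number of rows is
    sum(Y).
    """
    Y = np.asarray(Y, dtype=int)
    if np.any(Y < 0):
        raise ValueError("Y must be nonnegative")
    rng = np.random.default_rng(seed)
    cell_ids = np.repeat(landscape.cells["cell_id"].to_numpy(), Y)
    x0 = np.repeat(landscape.cells["x_min"].to_numpy(), Y)
    y0 = np.repeat(landscape.cells["y_min"].to_numpy(), Y)
    n = cell_ids.shape[0]
    x = x0 + rng.random(n) * landscape.cell_size
    y = y0 + rng.random(n) * landscape.cell_size
    status = rng.choice(["ancient", "veteran"], size=n, p=[0.2, 0.8])
    return pd.DataFrame(
        {
            "record_id": np.arange(n),
            "x": x,
            "y": y,
            "cell_id": cell_ids,
            "status": status,
        }
    )


def simulate_recorders(
    landscape: Landscape,
    records: pd.DataFrame,
    n_recorders: int,
    activity_decay: float,
    seed: int,
):
    """Place recorder home bases and assign each record to a recorder.

    Homes are uniform over the landscape. A record at distance d from
    recorder j's home is assigned to j with probability proportional to
    exp(-d / activity_decay); as activity_decay -> infinity the
    assignment becomes uniform over recorders. Returns ``(homes,
    records_with_recorder)`` where homes is a table (recorder_id, x, y).
    """
    if n_recorders < 1:
        raise ValueError("n_recorders must be >= 1")
    if activity_decay <= 0:
        raise ValueError("activity_decay must be > 0")
    rng = np.random.default_rng(seed)
    x_max = landscape.n_cols * landscape.cell_size
    y_max = landscape.n_rows * landscape.cell_size
    homes = pd.DataFrame(
        {
            "recorder_id": np.arange(n_recorders),
            "x": rng.random(n_recorders) * x_max,
            "y": rng.random(n_recorders) * y_max,
        }
    )
    rx = records["x"].to_numpy()[:, None]
    ry = records["y"].to_numpy()[:, None]
    d = np.hypot(rx - homes["x"].to_numpy()[None, :], ry - homes["y"].to_numpy()[None, :])
    logw = -d / activity_decay
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    w /= w.sum(axis=1, keepdims=True)
    u = rng.random(len(records))
    assignment = (w.cumsum(axis=1) < u[:, None]).sum(axis=1)
    out = records.copy()
    out["recorder_id"] = assignment
    return homes, out


def simulate_field_survey(
    cell_ids,
    N_true,
    coverage,
    detection_prob: float = 1.0,
    seed: int = 0,
    cell_area: float = 1_000_000.0,
) -> pd.DataFrame:
    """Simulate partial-coverage surveys of the given squares.

    For each square a coverage fraction c is taken from ``coverage``
    (either a sequence of fractions, one per square, or a callable
    ``coverage(rng, n)`` returning fractions in (0, 1]); the observed
    count is Binomial(N_true, c * detection_prob). Returns a table with
    cell_id, observed_count, coverage_fraction, surveyed_area (c times
    cell area) and density (observed / surveyed area, trees per m^2).
    """
    cell_ids = np.asarray(cell_ids)
    N_true = np.asarray(N_true, dtype=int)
    if cell_ids.shape[0] != N_true.shape[0]:
        raise ValueError("cell_ids and N_true must align")
    rng = np.random.default_rng(seed)
    n = cell_ids.shape[0]
    if callable(coverage):
        c = np.asarray(coverage(rng, n), dtype=float)
    else:
        c = np.broadcast_to(np.asarray(coverage, dtype=float), (n,)).copy()
    if np.any((c <= 0) | (c > 1)):
        raise ValueError("coverage fractions must be in (0, 1]")
    if not (0 < detection_prob <= 1):
        raise ValueError("detection_prob must be in (0, 1]")
    observed = rng.binomial(N_true, c * detection_prob)
    surveyed_area = c * cell_area
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "observed_count": observed,
            "coverage_fraction": c,
            "surveyed_area": surveyed_area,
            "density": observed / surveyed_area,
        }
    )
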