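"""Penalized presence-background suitability model with AICc tuning.

Presence points (label 1) are contrasted against pseudo-absence
background points (label 0) through a logistic regression on per-point
covariates, with an optional ridge penalty on non-intercept terms and an
optional quadratic expansion of numeric covariates. The fitted linear
predictor mapped through the logistic function is a relative habitat-
suitability index — the standard infinitely-weighted-points equivalence
makes this an explicit, inspectable stand-in for presence-only machine
learning suitability models. Candidate fits over a penalty/feature grid
are compared by AICc.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass(frozen=True)
class DesignSpec:
    """Feature expansion for the suitability model.

    ``features`` is 'linear' (numeric terms + one-hot categoricals) or
    'linear+quadratic' (adds squared numeric terms).
    """

    numeric: tuple
    categorical: tuple = ()
    features: str = "linear"

    def __post_init__(self):
        if self.features not in ("linear", "linear+quadratic"):
            raise ValueError("features must be 'linear' or 'linear+quadratic'")


@dataclass
class PBModelFit:
    coef: np.ndarray
    names: list
    lam: float
    loglik: float
    k: int
    n: int
    converged: bool
    spec: DesignSpec
    levels: dict


def _expand(df: pd.DataFrame, spec: DesignSpec, levels: dict | None = None):
    """Build the point-level design matrix; returns (X, names, levels)."""
    blocks = [np.ones((len(df), 1))]
    names = ["intercept"]
    for nm in spec.numeric:
        v = df[nm].to_numpy(dtype=float)
        blocks.append(v[:, None])
        names.append(nm)
        if spec.features == "linear+quadratic":
            blocks.append((v**2)[:, None])
            names.append(f"{nm}^2")
    out_levels = {}
    for nm in spec.categorical:
        col = df[nm]
        if levels is None:
            levs = (
                list(col.cat.categories)
                if isinstance(col.dtype, pd.CategoricalDtype)
                else sorted(col.unique())
            )
        else:
            levs = levels[nm]
            unseen = set(col.unique()) - set(levs)
            if unseen:
                raise ValueError(f"unseen level(s) {sorted(unseen)} in covariate {nm!r}")
        out_levels[nm] = list(levs)
        for lev in levs[1:]:
            blocks.append((col == lev).to_numpy(dtype=float)[:, None])
            names.append(f"{nm}[{lev}]")
    return np.hstack(blocks), names, out_levels


def fit_presence_background(
    presences: pd.DataFrame,
    background: pd.DataFrame,
    design_spec: DesignSpec,
    lam: float = 0.0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> PBModelFit:
    """Fit presence (1) vs background (0) by penalized logistic regression.

    Maximizes the Bernoulli log-likelihood minus (lam/2) * ||coef||^2
    over the non-intercept terms. ``loglik`` stored on the fit is the
    unpenalized log-likelihood at the penalized optimum, which feeds the
    AICc comparison. Complete separation with lam = 0 is reported as a
    non-convergence error suggesting a positive penalty.
    """
    if len(presences) == 0 or len(background) == 0:
        raise ValueError("need at least one presence and one background point")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    df = pd.concat([presences, background], ignore_index=True)
    ylab = np.concatenate([np.ones(len(presences)), np.zeros(len(background))])
    X, names, levels = _expand(df, design_spec)
    n, p = X.shape
    mask = np.ones(p)
    mask[0] = 0.0  # intercept unpenalized

    def nll(b):
        eta = X @ b
        ll = ylab @ eta - np.logaddexp(0.0, eta).sum()
        return -(ll - 0.5 * lam * np.sum(mask * b**2))

    def grad(b):
        mu = 1.0 / (1.0 + np.exp(-(X @ b)))
        return -(X.T @ (ylab - mu) - lam * mask * b)

    b0 = np.zeros(p)
    res = optimize.minimize(
        nll, b0, jac=grad, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-12},
    )
    g = grad(res.x)
    converged = bool(np.max(np.abs(g)) < tol * (1 + abs(res.fun)) * n)
    if lam == 0.0 and np.max(np.abs(res.x[1:])) > 30:
        # the unpenalized MLE does not exist under complete separation;
        # coefficients diverge along the separating direction
        raise RuntimeError(
            "presence-background fit did not converge (likely complete "
            "separation); refit with a ridge penalty lam > 0"
        )
    eta = X @ res.x
    loglik = float(ylab @ eta - np.logaddexp(0.0, eta).sum())
    return PBModelFit(
        coef=res.x,
        names=names,
        lam=lam,
        loglik=loglik,
        k=int(np.sum(res.x != 0.0)),
        n=n,
        converged=converged,
        spec=design_spec,
        levels=levels,
    )


def predict_suitability(fit: PBModelFit, cells: pd.DataFrame) -> np.ndarray:
    """Per-cell suitability in [0, 1]: logistic of the linear predictor.

    ``cells`` must carry the covariates used in training; an unseen
    categorical level raises an error naming the level.
    """
    X, names, _ = _expand(cells, fit.spec, levels=fit.levels)
    if names != fit.names:
        raise ValueError(f"design mismatch: expected {fit.names}, got {names}")
    return 1.0 / (1.0 + np.exp(-(X @ fit.coef)))


def select_model_by_aicc(candidates) -> PBModelFit:
    """Return the candidate minimizing AICc; ties go to the smaller k.

    AICc = -2 ll + 2k + 2k(k+1)/(n-k-1); candidates with n <= k + 1 are
    skipped (AICc undefined), and if none remain an error is raised.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates")
    scored = []
    for c in candidates:
        if c.n <= c.k + 1:
            continue
        a = -2 * c.loglik + 2 * c.k + 2 * c.k * (c.k + 1) / (c.n - c.k - 1)
        scored.append((a, c.k, c))
    if not scored:
        raise ValueError("AICc undefined for every candidate (n <= k + 1)")
    scored.sort(key=lambda t: (t[0], t[1]))
    return scored[0][2]


def covariates_at_points(landscape, points: pd.DataFrame) -> pd.DataFrame:
    """Attach cell covariates to points by half-open point-in-cell lookup."""
    ids = landscape.cell_id_at(points["x"].to_numpy(), points["y"].to_numpy())
    if np.any(ids < 0):
        raise ValueError("points outside landscape extent")
    covs = landscape.cells.loc[
        ids, landscape.numeric_names + landscape.categorical_names
    ].reset_index(drop=True)
    out = points.reset_index(drop=True).copy()
    for c in covs.columns:
        out[c] = covs[c].to_numpy()
    return out
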