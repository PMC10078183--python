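"""Field-survey design, effort-adjusted density, calibration, totals.

Stratified selection of survey squares (a random tranche plus four
strata crossing record presence with predicted excess-zero
probability), the trees-per-square-metre density that divides observed
counts by surveyed area, ordinary-least-squares calibration of model
predictions against field outcomes, and the landscape-wide total
obtained by applying the calibration to every cell and summing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from biastree.model_evaluation import auc as _auc

STRATA = ("noATI_low", "noATI_high", "ATI_low", "ATI_high")


def select_squares(
    cells: pd.DataFrame,
    zero_pred,
    n_random: int = 50,
    n_per_stratum: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Select survey squares: random tranche plus four model-based strata.

    ``cells`` must carry ``cell_id`` and the observed count ``Y``;
    ``zero_pred`` is the fitted per-cell excess-zero probability. First
    ``n_random`` cells are drawn uniformly without replacement; then,
    from each stratum of (has records?) x (zero prediction above/below
    its landscape mean), ``n_per_stratum`` further cells are drawn
    uniformly among cells not already selected. Low predicted abundance
    corresponds to a high zero prediction.

    Returns a table (cell_id, stratum) of length
    ``n_random + 4 * n_per_stratum``.
    """
    zero_pred = np.asarray(zero_pred, dtype=float)
    if len(cells) != zero_pred.shape[0]:
        raise ValueError("zero_pred must align with cells")
    rng = np.random.default_rng(seed)
    ids = cells["cell_id"].to_numpy()
    Y = cells["Y"].to_numpy()
    if n_random > len(cells):
        raise ValueError("n_random exceeds the number of cells")
    random_ids = rng.choice(ids, size=n_random, replace=False)
    chosen = set(random_ids.tolist())
    # high zero prediction = low predicted abundance
    thresh = zero_pred.mean()
    low_abund = zero_pred > thresh
    has_rec = Y > 0
    strata_masks = {
        "noATI_low": (~has_rec) & low_abund,
        "noATI_high": (~has_rec) & ~low_abund,
        "ATI_low": has_rec & low_abund,
        "ATI_high": has_rec & ~low_abund,
    }
    rows = [{"cell_id": int(c), "stratum": "random"} for c in random_ids]
    for name in STRATA if n_per_stratum > 0 else ():
        pool = ids[strata_masks[name]]
        pool = pool[~np.isin(pool, list(chosen))]
        if pool.shape[0] < n_per_stratum:
            raise ValueError(
                f"stratum {name!r} has only {pool.shape[0]} available cells "
                f"(need {n_per_stratum})"
            )
        take = rng.choice(pool, size=n_per_stratum, replace=False)
        chosen.update(take.tolist())
        rows += [{"cell_id": int(c), "stratum": name} for c in take]
    return pd.DataFrame(rows)


def tree_density(observed_count, coverage_fraction, cell_area: float = 1_000_000.0):
    """Survey-effort-adjusted density: count / (coverage * cell area).

    Units are trees per square metre for the default 1-km cell.
    """
    observed_count = np.asarray(observed_count, dtype=float)
    coverage_fraction = np.asarray(coverage_fraction, dtype=float)
    if np.any((coverage_fraction <= 0) | (coverage_fraction > 1)):
        raise ValueError("coverage_fraction must be in (0, 1]")
    return observed_count / (coverage_fraction * cell_area)


@dataclass
class CalibrationResult:
    """OLS calibration of model predictions against field outcomes."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    metric: str
    n: int
    estimates: np.ndarray | None = None
    total: float | None = None


def calibrate(predictions_surveyed, field_values, metric: str = "density") -> CalibrationResult:
    """OLS of the field metric on the model prediction (identity link).

    ``metric`` records whether the field values are raw abundance or
    effort-adjusted density; the fitted intercept/slope later convert
    every cell's prediction into a calibrated estimate.
    """
    import statsmodels.api as sm

    p = np.asarray(predictions_surveyed, dtype=float)
    v = np.asarray(field_values, dtype=float)
    if p.shape[0] < 3:
        raise ValueError("need at least 3 surveyed squares")
    if np.std(p) == 0:
        raise ValueError("predictions are constant; calibration undefined")
    if metric not in ("abundance", "density"):
        raise ValueError("metric must be 'abundance' or 'density'")
    X = sm.add_constant(p)
    res = sm.OLS(v, X).fit()
    return CalibrationResult(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        metric=metric,
        n=p.shape[0],
    )


def national_total(
    calibration: CalibrationResult,
    predictions_all_cells,
    cell_area: float = 1_000_000.0,
    clip_negative: bool = False,
) -> CalibrationResult:
    """Apply the calibration to every cell and sum to a total T.

    Per-cell estimate = a + b * prediction. Under the abundance metric
    T is the plain sum of estimates; under the density metric each
    estimate is trees/m^2, so T = sum(estimates) * cell_area. Negative
    per-cell estimates are kept by default (set ``clip_negative`` to
    floor them at 0 before summation). Returns a copy of the
    calibration carrying ``estimates`` and ``total``.
    """
    p = np.asarray(predictions_all_cells, dtype=float)
    est = calibration.intercept + calibration.slope * p
    if clip_negative:
        est = np.maximum(est, 0.0)
    total = est.sum() * (cell_area if calibration.metric == "density" else 1.0)
    return CalibrationResult(
        intercept=calibration.intercept,
        slope=calibration.slope,
        se_intercept=calibration.se_intercept,
        se_slope=calibration.se_slope,
        metric=calibration.metric,
        n=calibration.n,
        estimates=est,
        total=float(total),
    )


def field_auc(
    model_predictions,
    surveyed_pa,
    threshold_reference=None,
    kind: str = "abundance",
) -> float:
    """AUC of model predictions against field presence-absence.

    Abundance-type predictions are first binarized at the median of the
    ``threshold_reference`` set (typically the predictions over every
    selected square, even if only a subset was surveyed) and the binary
    values are used as scores; suitability-type predictions are used
    directly as scores.
    """
    preds = np.asarray(model_predictions, dtype=float)
    pa = np.asarray(surveyed_pa).astype(int)
    if kind == "abundance":
        from biastree.model_evaluation import threshold_to_pa

        scores, _ = threshold_to_pa(preds, method="median", reference_set=threshold_reference)
    elif kind == "suitability":
        scores = preds
    else:
        raise ValueError("kind must be 'abundance' or 'suitability'")
    return _auc(pa, scores)
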