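"""Internal model validation: cross-validation and evaluation metrics.

Ten-fold cross-validation with cell-level random folds, rank-based AUC,
AICc, root-mean-square log error, Pearson/Spearman correlations, and
the mean/median thresholding that converts abundance predictions to
presence-absence for ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


def aicc(loglik: float, k: int, n: int) -> float:
    """Corrected Akaike information criterion.

    AICc = -2 ll + 2k + 2k(k+1)/(n-k-1); undefined for n <= k + 1.
    """
    if n <= k + 1:
        raise ValueError("AICc undefined for n <= k + 1")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute 1/2.

    Requires both classes present.
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined with a single class")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def rmsle(predicted, observed) -> float:
    """Root-mean-square log error: sqrt(mean((ln(1+p) - ln(1+o))^2))."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if np.any(p < 0) or np.any(o < 0):
        raise ValueError("RMSLE requires nonnegative inputs")
    return float(np.sqrt(np.mean((np.log1p(p) - np.log1p(o)) ** 2)))


def correlate(predicted, observed) -> tuple:
    """Pearson r and Spearman r_s (average ranks for ties).

    Both vectors must have length >= 3 and be non-constant.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape[0] < 3:
        raise ValueError("need at least 3 observations")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("correlation undefined for constant vectors")
    r = float(stats.pearsonr(p, o).statistic)
    rs = float(stats.spearmanr(p, o).statistic)
    return r, rs


def threshold_to_pa(predictions, method: str = "mean", reference_set=None):
    """Binarize abundance predictions at a mean or median threshold.

    The threshold is computed on ``reference_set`` (default: the
    predictions themselves); a cell is classed present iff its
    prediction is strictly greater than the threshold. Returns
    ``(binary, threshold)``.
    """
    predictions = np.asarray(predictions, dtype=float)
    ref = predictions if reference_set is None else np.asarray(reference_set, dtype=float)
    if ref.size == 0:
        raise ValueError("reference set must be nonempty")
    if method == "mean":
        t = float(ref.mean())
    elif method == "median":
        t = float(np.median(ref))
    else:
        raise ValueError("method must be 'mean' or 'median'")
    return (predictions > t).astype(int), t


def fold_assignments(n: int, k: int, seed: int) -> np.ndarray:
    """Random near-equal fold labels in {0..k-1}; sizes differ by <= 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k observations")
    rng = np.random.default_rng(seed)
    labels = np.arange(n) % k
    rng.shuffle(labels)
    return labels


@dataclass
class CVResult:
    predictions: np.ndarray
    folds: np.ndarray
    fits: list
    failed_folds: list = field(default_factory=list)


def kfold_cv(data, k: int, seed: int, fit_fn, predict_fn) -> CVResult:
    """k-fold cross-validation over the rows of ``data``.

    ``fit_fn(train)`` returns a fitted object; ``predict_fn(fit, test)``
    returns one prediction per test row. Every row is predicted exactly
    once by a model not trained on it. A fold whose fit fails is flagged
    (NaN predictions) and reported, not silently dropped.
    """
    n = len(data)
    folds = fold_assignments(n, k, seed)
    preds = np.full(n, np.nan)
    fits = []
    failed = []
    idx = np.arange(n)
    for f in range(k):
        test = folds == f
        train_rows = data.iloc[idx[~test]] if hasattr(data, "iloc") else data[~test]
        test_rows = data.iloc[idx[test]] if hasattr(data, "iloc") else data[test]
        try:
            fit = fit_fn(train_rows)
            preds[test] = np.asarray(predict_fn(fit, test_rows), dtype=float)
            fits.append(fit)
        except Exception as exc:  # surfaced via failed_folds
            fits.append(None)
            failed.append((f, repr(exc)))
    return CVResult(predictions=preds, folds=folds, fits=fits, failed_folds=failed)


@dataclass
class EvaluationReport:
    """One model's internal-validation summary."""

    model: str
    aicc: float
    auc_train: float
    auc_test: float
    rmsle: float
    pearson_r: float
    spearman_rs: float
    threshold: float
    fold_variance: float
    fold_sd: float
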