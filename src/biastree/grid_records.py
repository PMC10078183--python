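"""Grid/record data model: aggregation, screening and diagnostics.

Point records live in projected metres; cell (row, col) covers the
half-open square [x_min, x_min + s) x [y_min, y_min + s), so a point on
an interior boundary belongs to exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def build_design(
    cells: pd.DataFrame,
    numeric: list,
    categorical: list,
    reference: dict | None = None,
    add_intercept: bool = True,
):
    """Design matrix from a cell table: intercept, numeric, one-hot dummies.

    Each categorical covariate is one-hot encoded against a reference
    level that is omitted from the design (the first level
    lexicographically unless ``reference`` names another), mirroring the
    baseline convention of regression coefficient tables.

    Returns ``(X, names)`` with X a dense float array.
    """
    reference = reference or {}
    blocks = []
    names = []
    n = len(cells)
    if add_intercept:
        blocks.append(np.ones((n, 1)))
        names.append("intercept")
    for name in numeric:
        blocks.append(cells[name].to_numpy(dtype=float)[:, None])
        names.append(name)
    for name in categorical:
        col = cells[name]
        levels = (
            list(col.cat.categories)
            if isinstance(col.dtype, pd.CategoricalDtype)
            else sorted(col.unique())
        )
        ref = reference.get(name, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not a level of {name!r}")
        for lev in levels:
            if lev == ref:
                continue
            blocks.append((col == lev).to_numpy(dtype=float)[:, None])
            names.append(f"{name}[{lev}]")
    X = np.hstack(blocks) if blocks else np.empty((n, 0))
    return X, names


def pool_rare_levels(col: pd.Series, min_count: int, other_label: str = "other") -> pd.Series:
    """Pool levels with fewer than ``min_count`` cells into one class.

    Mirrors the common practice of combining rare categories to aid model
    fitting.
    """
    counts = col.value_counts()
    rare = set(counts.index[counts < min_count])
    if not rare:
        return col
    out = col.astype(object).where(~col.isin(rare), other_label)
    return pd.Series(pd.Categorical(out), index=col.index, name=col.name)


def aggregate_to_counts(
    records: pd.DataFrame,
    landscape,
    on_outside: str = "error",
) -> np.ndarray:
    """Aggregate point records to a per-cell pseudo-abundance count Y.

    Y_i is the number of records whose (x, y) falls in cell i under the
    half-open convention; cells without records get 0 and the total is
    conserved. Records outside the landscape extent are reported by id
    and either raise (``on_outside='error'``) or are dropped
    (``'drop'``).
    """
    if on_outside not in ("error", "drop"):
        raise ValueError("on_outside must be 'error' or 'drop'")
    Y = np.zeros(landscape.n_cells, dtype=int)
    if len(records) == 0:
        return Y
    ids = landscape.cell_id_at(records["x"].to_numpy(), records["y"].to_numpy())
    outside = ids < 0
    if outside.any():
        bad = records.loc[outside, "record_id"].tolist()
        if on_outside == "error":
            raise ValueError(f"records outside landscape extent: {bad}")
        ids = ids[~outside]
    np.add.at(Y, ids, 1)
    return Y


def overdispersion_ratio(Y) -> float:
    """Sample variance : mean ratio of a count vector.

    Computed with the n-1 variance denominator. A ratio well above 1
    indicates overdispersion relative to the Poisson. Undefined
    (ValueError) when the mean is 0.
    """
    Y = np.asarray(Y, dtype=float)
    m = Y.mean()
    if m == 0:
        raise ValueError("overdispersion ratio undefined for all-zero counts")
    return float(Y.var(ddof=1) / m)


@dataclass
class CollinearityReport:
    correlation: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list
    flagged_vif: list

    @property
    def ok(self) -> bool:
        return not self.flagged_pairs and not self.flagged_vif


def screen_collinearity(
    numeric: pd.DataFrame,
    r_threshold: float = 0.6,
    vif_threshold: float = 5.0,
) -> CollinearityReport:
    """Pairwise Pearson correlations and variance inflation factors.

    VIF_j = 1 / (1 - R^2_j) from regressing covariate j on the other
    covariates (with intercept). Flags any pair with |r| above
    ``r_threshold`` and any covariate with VIF at or above
    ``vif_threshold``; a constant covariate gets infinite VIF and is
    flagged.
    """
    cols = list(numeric.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 numeric covariates")
    X = numeric.to_numpy(dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than covariates")
    corr = numeric.corr(method="pearson")
    flagged_pairs = [
        (cols[i], cols[j], float(corr.iloc[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(corr.iloc[i, j]) > r_threshold
    ]
    vifs = {}
    flagged_vif = []
    for j, name in enumerate(cols):
        yj = X[:, j]
        if np.var(yj) == 0:
            vifs[name] = np.inf
            flagged_vif.append(name)
            continue
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        v = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
        vifs[name] = float(v)
        if v >= vif_threshold:
            flagged_vif.append(name)
    return CollinearityReport(
        correlation=corr,
        vif=pd.Series(vifs),
        flagged_pairs=flagged_pairs,
        flagged_vif=flagged_vif,
    )


def residual_spatial_check(residuals, x, y) -> tuple:
    """Pearson correlation of model residuals with easting and northing.

    Weak correlations (near 0) indicate no strong residual spatial trend.
    Returns ``(r_x, r_y)``.
    """
    residuals = np.asarray(residuals, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def _r(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])

    return _r(residuals, x), _r(residuals, y)
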