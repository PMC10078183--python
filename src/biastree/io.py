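"""CSV exchange formats for records, cell tables and bias surfaces."""

from __future__ import annotations

import pandas as pd

from biastree.synthetic_landscape import Landscape

GEOMETRY_COLS = ["cell_id", "row", "col", "x_min", "y_min"]


def write_records_csv(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_cells_csv(landscape: Landscape, path, Y=None) -> None:
    """Cell table: geometry, covariates, and (optionally) the count Y."""
    out = landscape.cells.copy()
    if Y is not None:
        out["Y"] = Y
    out.to_csv(path, index=False)


def read_cells_csv(path) -> tuple:
    """Rebuild a Landscape (and Y if present) from a cell-table CSV.

    Geometry is inferred from the row/col/x_min/y_min columns; remaining
    numeric columns are treated as numeric covariates and object columns
    as categorical covariates.
    """
    cells = pd.read_csv(path)
    n_rows = int(cells["row"].max()) + 1
    n_cols = int(cells["col"].max()) + 1
    if n_cols > 1:
        cell_size = float(cells.loc[cells["col"] == 1, "x_min"].iloc[0])
    elif n_rows > 1:
        cell_size = float(cells.loc[cells["row"] == 1, "y_min"].iloc[0])
    else:
        cell_size = 1000.0
    Y = cells.pop("Y").to_numpy() if "Y" in cells.columns else None
    numeric, categorical = [], []
    for c in cells.columns:
        if c in GEOMETRY_COLS:
            continue
        if pd.api.types.is_numeric_dtype(cells[c]):
            numeric.append(c)
        else:
            cells[c] = pd.Series(pd.Categorical(cells[c]), index=cells.index)
            categorical.append(c)
    landscape = Landscape(
        cells=cells,
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=cell_size,
        numeric_names=numeric,
        categorical_names=categorical,
    )
    return landscape, Y


def write_surface_csv(landscape: Landscape, weights, path) -> None:
    pd.DataFrame(
        {"cell_id": landscape.cells["cell_id"], "weight": weights}
    ).to_csv(path, index=False)
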