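"""Pseudo-absence (background) generation and bias surfaces.

Presence-only models contrast presences against background points. The
paper-grade corrections implemented here manipulate where those
background points fall: uniformly at random, restricted to buffers
around the presences, or weighted by a nonnegative per-cell bias surface
derived from point kernel densities (e.g. recorder home bases), rescaled
rasters (e.g. altitude), or the record density itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class BiasSurface:
    """Nonnegative per-cell weights steering pseudo-absence placement."""

    weights: np.ndarray
    provenance: str
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("bias surface weights must be nonnegative")
        if not np.any(self.weights > 0):
            raise ValueError("bias surface must have at least one positive weight")


def _points_frame(landscape, x, y) -> pd.DataFrame:
    return pd.DataFrame({"x": x, "y": y, "cell_id": landscape.cell_id_at(x, y)})


def random_background(landscape, n: int, seed: int) -> pd.DataFrame:
    """n pseudo-absence points uniform over the landscape extent."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = landscape.extent
    x = x0 + rng.random(n) * (x1 - x0)
    y = y0 + rng.random(n) * (y1 - y0)
    return _points_frame(landscape, x, y)


def buffer_restricted_background(
    records: pd.DataFrame,
    radius: float,
    landscape,
    n: int,
    seed: int,
    max_tries: int = 1000,
) -> pd.DataFrame:
    """n points uniform over the union of disks around the presences.

    Points are drawn by rejection from the bounding box of the buffer
    union intersected with the landscape; each accepted point lies
    within ``radius`` of at least one record. Raises if the acceptance
    rate is so low that the union is effectively empty.
    """
    if len(records) == 0:
        raise ValueError("records must be nonempty")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    xy = records[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(xy)
    ex0, ey0, ex1, ey1 = landscape.extent
    bx0 = max(ex0, xy[:, 0].min() - radius)
    bx1 = min(ex1, xy[:, 0].max() + radius)
    by0 = max(ey0, xy[:, 1].min() - radius)
    by1 = min(ey1, xy[:, 1].max() + radius)
    if bx1 <= bx0 or by1 <= by0:
        raise ValueError("buffer union does not intersect the landscape")
    out_x, out_y = [], []
    remaining = n
    for _ in range(max_tries):
        m = max(4 * remaining, 256)
        cx = bx0 + rng.random(m) * (bx1 - bx0)
        cy = by0 + rng.random(m) * (by1 - by0)
        d, _ = tree.query(np.column_stack([cx, cy]), k=1)
        ok = d <= radius
        out_x.append(cx[ok][:remaining])
        out_y.append(cy[ok][:remaining])
        remaining -= len(out_x[-1])
        if remaining == 0:
            break
    else:
        raise RuntimeError("buffer rejection sampling failed to terminate")
    x = np.concatenate(out_x)
    y = np.concatenate(out_y)
    return _points_frame(landscape, x, y)


def kernel_density_surface(points: pd.DataFrame, bandwidth: float, landscape) -> BiasSurface:
    """Gaussian kernel density of a point set evaluated at cell centroids.

    Weight of cell i is sum_j exp(-d_ij^2 / (2 h^2)) over points j, with
    d_ij the distance from the cell centroid to the point and h the
    bandwidth in metres. Linear in the point set.
    """
    if len(points) == 0:
        raise ValueError("points must be nonempty")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    cx = landscape.cells["x_min"].to_numpy() + landscape.cell_size / 2
    cy = landscape.cells["y_min"].to_numpy() + landscape.cell_size / 2
    px = points["x"].to_numpy(dtype=float)
    py = points["y"].to_numpy(dtype=float)
    w = np.zeros(landscape.n_cells)
    # chunk over cells to bound the pairwise matrix
    step = max(1, int(2_000_000 / max(1, len(px))))
    for s in range(0, landscape.n_cells, step):
        e = min(s + step, landscape.n_cells)
        d2 = (cx[s:e, None] - px[None, :]) ** 2 + (cy[s:e, None] - py[None, :]) ** 2
        w[s:e] = np.exp(-d2 / (2 * bandwidth**2)).sum(axis=1)
    return BiasSurface(weights=w, provenance="point_kernel_density", bandwidth=bandwidth)


def raster_bias_surface(values, direction: str = "ascending", provenance: str = "raster_rescale") -> BiasSurface:
    """Min-max rescale a per-cell raster into bias weights in [0, 1].

    ``direction='ascending'`` gives higher weight to higher values;
    ``'descending'`` inverts (for distance-type sources where nearness
    should attract sampling). A constant raster yields a uniform surface
    (with a warning via provenance note, since it carries no signal).
    """
    values = np.asarray(values, dtype=float)
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    span = values.max() - values.min()
    if span == 0:
        import warnings

        warnings.warn("constant raster: bias surface is uniform")
        w = np.ones_like(values)
    else:
        w = (values - values.min()) / span
        if direction == "descending":
            w = 1.0 - w
    return BiasSurface(weights=w, provenance=provenance)


def record_density_surface(Y) -> BiasSurface:
    """Bias surface proportional to the per-cell record count itself."""
    return raster_bias_surface(np.asarray(Y, dtype=float), "ascending", provenance="record_density")


def weighted_background(surface: BiasSurface, landscape, n: int, seed: int) -> pd.DataFrame:
    """n points drawn cell-first with probability proportional to weight.

    Cells are drawn with replacement proportional to the surface weight,
    then a uniform point is placed inside each drawn cell. Presence
    cells are not excluded, matching standard bias-file practice.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    w = surface.weights
    if w.shape[0] != landscape.n_cells:
        raise ValueError("surface does not match landscape")
    rng = np.random.default_rng(seed)
    p = w / w.sum()
    cells = rng.choice(landscape.n_cells, size=n, replace=True, p=p)
    x0 = landscape.cells["x_min"].to_numpy()[cells]
    y0 = landscape.cells["y_min"].to_numpy()[cells]
    x = x0 + rng.random(n) * landscape.cell_size
    y = y0 + rng.random(n) * landscape.cell_size
    return pd.DataFrame({"x": x, "y": y, "cell_id": cells})
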