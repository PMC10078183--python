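"""Spatial filtering (thinning) of occurrence records.

Three bias corrections applied to presence points before
presence-background modelling: systematic sampling on a coarse grid,
single-linkage cluster thinning, and distance-weighted subsampling that
favours isolated records. Every filter returns a subset of the input
rows with identities preserved and is deterministic under a fixed seed.

Neighbour queries go through a k-d tree; correctness is defined by the
brute-force pairwise oracles in the test suite, not by the index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


def _coords(records: pd.DataFrame) -> np.ndarray:
    return records[["x", "y"]].to_numpy(dtype=float)


def systematic_sample(
    records: pd.DataFrame,
    resolution: float,
    seed: int,
    origin: tuple = (0.0, 0.0),
) -> pd.DataFrame:
    """Keep one uniformly chosen record per occupied coarse grid cell.

    A coarse grid of the given resolution, anchored at ``origin``, is
    overlaid on the records; the output has exactly one record per
    occupied coarse cell (so no two retained records share a coarse
    cell).
    """
    if len(records) == 0:
        raise ValueError("records must be nonempty")
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    xy = _coords(records)
    cx = np.floor((xy[:, 0] - origin[0]) / resolution).astype(np.int64)
    cy = np.floor((xy[:, 1] - origin[1]) / resolution).astype(np.int64)
    key = pd.Series(list(zip(cx, cy)), index=records.index)
    rng = np.random.default_rng(seed)
    # random tie-break per record, then take the max key holder per cell
    u = pd.Series(rng.random(len(records)), index=records.index)
    keep = u.groupby(key, sort=False).idxmax()
    return records.loc[sorted(keep)].copy()


def cluster_filter(records: pd.DataFrame, link_distance: float, seed: int) -> pd.DataFrame:
    """Keep one record per single-linkage cluster at ``link_distance``.

    Records strictly closer than ``link_distance`` are linked; clusters
    are the connected components of that graph (members can therefore be
    farther than ``link_distance`` apart as long as a chain connects
    them). One uniformly chosen record is retained per component;
    singletons are their own component and always retained.
    """
    if link_distance <= 0:
        raise ValueError("link_distance must be > 0")
    n = len(records)
    if n == 0:
        raise ValueError("records must be nonempty")
    xy = _coords(records)
    tree = cKDTree(xy)
    pairs = tree.query_pairs(r=link_distance, output_type="ndarray")
    if len(pairs):
        d = np.hypot(
            xy[pairs[:, 0], 0] - xy[pairs[:, 1], 0],
            xy[pairs[:, 0], 1] - xy[pairs[:, 1], 1],
        )
        pairs = pairs[d < link_distance]  # strict inequality
    if len(pairs):
        g = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        _, labels = connected_components(g, directed=False)
    else:
        labels = np.arange(n)
    rng = np.random.default_rng(seed)
    u = pd.Series(rng.random(n), index=records.index)
    keep = u.groupby(pd.Series(labels, index=records.index), sort=False).idxmax()
    return records.loc[sorted(keep)].copy()


def nearest_neighbor_distances(records: pd.DataFrame) -> np.ndarray:
    """Distance from each record to its nearest other record."""
    xy = _coords(records)
    if len(xy) < 2:
        raise ValueError("need at least 2 records")
    tree = cKDTree(xy)
    d, _ = tree.query(xy, k=2)
    return d[:, 1]


def weighted_distance_sample(records: pd.DataFrame, n_keep: int, seed: int) -> pd.DataFrame:
    """Subsample records with probability increasing in isolation.

    Each record's nearest-neighbour distance is min-max rescaled to a
    weight in [0, 1]; ``n_keep`` distinct records are then drawn
    sequentially without replacement with probability proportional to
    weight (isolated records are favoured). Zero-weight records become
    eligible only after every positive-weight record is exhausted.

    Implemented with exponential sort keys (Efraimidis-Spirakis), which
    reproduces the sequential weighted draw exactly.
    """
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records")
    if not (1 <= n_keep <= n):
        raise ValueError("n_keep must be in [1, n_records]")
    d = nearest_neighbor_distances(records)
    span = d.max() - d.min()
    w = np.ones(n) if span == 0 else (d - d.min()) / span
    rng = np.random.default_rng(seed)
    # key = Exp(1)/w; smallest keys win; w=0 -> inf, only drawn after all
    # positive weights, in random order (exponential ties are continuous)
    e = rng.exponential(size=n)
    with np.errstate(divide="ignore"):
        key = np.where(w > 0, e / np.where(w > 0, w, 1.0), np.inf)
    order = np.lexsort((e, key))  # e breaks ties among zero-weight records
    keep_pos = np.sort(order[:n_keep])
    return records.iloc[keep_pos].copy()
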