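"""Measurements on simulated spheroids.

Three read-outs mirror what is quantified on microscopy z-slices of real
spheroids:

* **rasterized area** — the domain is divided into an ``n x n`` grid, a disk
  of value 1 is drawn at each cell centre with the cell's radius, overlaps
  count once, and the covered-element count is rescaled to um^2;
* **relative growth** — area at time t divided by the area at t=0;
* **Delaunay mean distance** — mean edge length of the Delaunay
  triangulation of the cell centres, a compactness statistic (lower means a
  denser spheroid).

All functions are pure: they read point/radius snapshots and never touch
simulation state.  Replicate series are aggregated as mean and 25th/75th
percentile per timepoint.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay
from scipy.spatial._qhull import QhullError

__all__ = [
    "raster_area",
    "relative_growth",
    "delaunay_mean_distance",
    "aggregate",
    "snapshot_metrics",
]


def raster_area(positions: np.ndarray, radii: np.ndarray,
                domain_half_width: float, n: int = 5000) -> float:
    """Union-of-disks area, um^2, via an ``n x n`` occupancy raster.

    A grid element counts as covered when its centre lies inside or on the
    boundary of at least one cell disk; elements covered by several cells
    count once.  The count is rescaled by the element area
    ``(2*half_width / n)^2``.
    """
    if n < 1:
        raise ValueError("raster resolution n must be >= 1")
    positions = np.asarray(positions, dtype=float).reshape(-1, 2)
    radii = np.asarray(radii, dtype=float).reshape(-1)
    if positions.shape[0] == 0:
        return 0.0
    h = 2.0 * domain_half_width / n
    # element k has centre -half_width + (k + 0.5) * h
    covered = np.zeros((n, n), dtype=bool)
    for (cx, cy), r in zip(positions, radii):
        if r <= 0:
            continue
        i0 = max(int(math.floor((cx - r + domain_half_width) / h - 0.5)), 0)
        i1 = min(int(math.ceil((cx + r + domain_half_width) / h - 0.5)), n - 1)
        j0 = max(int(math.floor((cy - r + domain_half_width) / h - 0.5)), 0)
        j1 = min(int(math.ceil((cy + r + domain_half_width) / h - 0.5)), n - 1)
        if i1 < i0 or j1 < j0:
            continue
        xs = -domain_half_width + (np.arange(i0, i1 + 1) + 0.5) * h - cx
        ys = -domain_half_width + (np.arange(j0, j1 + 1) + 0.5) * h - cy
        covered[j0:j1 + 1, i0:i1 + 1] |= \
            (xs[None, :] ** 2 + ys[:, None] ** 2) <= r * r
    return float(covered.sum()) * h * h


def relative_growth(areas) -> np.ndarray:
    """Series of areas divided by the initial area; the first entry is 1."""
    areas = np.asarray(areas, dtype=float)
    if areas.size == 0:
        raise ValueError("empty area series")
    if areas[0] <= 0:
        raise ValueError("initial area must be > 0")
    return areas / areas[0]


def delaunay_mean_distance(points: np.ndarray) -> float:
    """Mean edge length of the Delaunay triangulation of the points, um.

    Degenerate inputs (fewer than 3 points, or all collinear) have no
    triangulation; NaN is returned and recorded as a missing value.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    if points.shape[0] < 3:
        return float("nan")
    try:
        tri = Delaunay(points)
    except QhullError:
        return float("nan")
    edges = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = simplex[a], simplex[(a + 1) % 3]
            edges.add((min(i, j), max(i, j)))
    idx = np.array(sorted(edges))
    lengths = np.linalg.norm(points[idx[:, 0]] - points[idx[:, 1]], axis=1)
    return float(lengths.mean())


def aggregate(df: pd.DataFrame, value_columns=("cell_count", "area_um2",
                                               "relative_growth",
                                               "delaunay_mean_um")) -> pd.DataFrame:
    """Mean and 25th/75th percentile per timepoint across replicates.

    Expects a tidy table with ``time_min`` and ``replicate`` columns; every
    replicate must cover the same time grid.  Percentiles use linear
    interpolation between order statistics.
    """
    counts = df.groupby("time_min")["replicate"].nunique()
    if counts.nunique() > 1:
        raise ValueError("replicate series have ragged time grids")
    value_columns = [c for c in value_columns if c in df.columns]
    grouped = df.groupby("time_min")
    out = {}
    for col in value_columns:
        out[f"{col}_mean"] = grouped[col].mean()
        out[f"{col}_p25"] = grouped[col].quantile(0.25)
        out[f"{col}_p75"] = grouped[col].quantile(0.75)
    return pd.DataFrame(out).reset_index()


def snapshot_metrics(times, snapshots, domain_half_width: float,
                     raster_n: int = 5000) -> pd.DataFrame:
    """Per-snapshot metrics table for one replicate.

    ``snapshots`` is a sequence of ``(positions, radii)`` pairs aligned with
    ``times`` (minutes).
    """
    rows = []
    for t, (pos, rad) in zip(times, snapshots):
        rows.append({
            "time_min": t,
            "cell_count": pos.shape[0],
            "area_um2": raster_area(pos, rad, domain_half_width, raster_n),
            "delaunay_mean_um": delaunay_mean_distance(pos),
        })
    df = pd.DataFrame(rows)
    df["relative_growth"] = relative_growth(df["area_um2"].to_numpy())
    return df[["time_min", "cell_count", "area_um2", "relative_growth",
               "delaunay_mean_um"]]
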