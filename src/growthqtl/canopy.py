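"""Point-cloud reduction to per-plot percentile canopy heights.

Chain: classify ground points (grid-minimum seeding + iterative robust
plane refit), interpolate a digital elevation model (DEM), subtract it to
get a canopy height model (CHM), and extract plot-level height
percentiles (P95 by default) inside rectangular plot footprints.

The ground classifier is a deliberately transparent two-step procedure:
per-cell minima seed a least-squares plane, then the surface is refit a
few times keeping only points within ``z_tolerance`` above it (points
below are always kept), which pulls the surface down onto the true ground
even when some cells contain only canopy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GroundModel",
    "classify_ground",
    "canopy_height_model",
    "extract_plot_percentile",
    "extract_plot_metrics",
    "read_xyz",
    "write_xyz",
]


@dataclass
class GroundModel:
    """Planar DEM z = a*x + b*y + c with per-point ground labels."""

    coef: tuple[float, float, float]
    ground_mask: np.ndarray  # True where the point was classified ground

    def dem(self, x, y):
        a, b, c = self.coef
        return a * np.asarray(x, float) + b * np.asarray(y, float) + c


def _fit_plane(pts: np.ndarray) -> tuple[float, float, float]:
    A = np.column_stack([pts[:, 0], pts[:, 1], np.ones(len(pts))])
    coef, *_ = np.linalg.lstsq(A, pts[:, 2], rcond=None)
    return tuple(float(v) for v in coef)


def classify_ground(
    points: np.ndarray,
    cell_size: float = 1.0,
    robust_iterations: int = 5,
    z_tolerance: float = 0.10,
) -> GroundModel:
    """Label each point ground/canopy and return the fitted ground plane.

    Raises on degenerate geometry (fewer than 3 seeds, or all candidate
    ground points collinear in xy).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) == 0:
        raise ValueError("points must be a non-empty (n, 3) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in point cloud")
    # grid-minimum seeding
    ix = np.floor(pts[:, 0] / cell_size).astype(np.int64)
    iy = np.floor(pts[:, 1] / cell_size).astype(np.int64)
    cells = {}
    for i, key in enumerate(zip(ix, iy)):
        j = cells.get(key)
        if j is None or pts[i, 2] < pts[j, 2]:
            cells[key] = i
    seeds = pts[list(cells.values())]
    _check_noncollinear(seeds)
    coef = _fit_plane(seeds)
    ground = None
    for _ in range(max(robust_iterations, 1)):
        resid = pts[:, 2] - (coef[0] * pts[:, 0] + coef[1] * pts[:, 1] + coef[2])
        new_ground = resid <= z_tolerance
        if not new_ground.any():
            break
        cand = pts[new_ground]
        try:
            _check_noncollinear(cand)
        except ValueError:
            break
        coef = _fit_plane(cand)
        if ground is not None and np.array_equal(ground, new_ground):
            ground = new_ground
            break
        ground = new_ground
    if ground is None or not ground.any():
        raise ValueError("ground classification found no ground points")
    return GroundModel(coef=coef, ground_mask=ground)


def _check_noncollinear(pts: np.ndarray) -> None:
    if len(pts) < 3:
        raise ValueError("need >= 3 candidate ground points")
    xy = pts[:, :2] - pts[:, :2].mean(axis=0)
    s = np.linalg.svd(xy, compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("candidate ground points are collinear in xy")


def canopy_height_model(points: np.ndarray, ground: GroundModel) -> np.ndarray:
    """Normalized height per point: z minus the DEM at (x, y)."""
    pts = np.asarray(points, dtype=float)
    return pts[:, 2] - ground.dem(pts[:, 0], pts[:, 1])


def extract_plot_percentile(
    points: np.ndarray,
    chm: np.ndarray,
    rectangle,
    percentile: float = 95.0,
) -> float:
    """Percentile of normalized heights inside one plot rectangle.

    Membership is boundary-inclusive on the min edges and exclusive on the
    max edges; percentiles interpolate linearly between order statistics.
    An empty plot returns NaN (a missing-value sentinel, never zero).
    """
    if not (0 < percentile <= 100):
        raise ValueError("percentile must lie in (0, 100]")
    pts = np.asarray(points, dtype=float)
    r = rectangle
    inside = (
        (pts[:, 0] >= r["x_min"]) & (pts[:, 0] < r["x_max"])
        & (pts[:, 1] >= r["y_min"]) & (pts[:, 1] < r["y_max"])
    )
    if not inside.any():
        return float("nan")
    return float(np.percentile(chm[inside], percentile))


def extract_plot_metrics(
    points: np.ndarray,
    rectangles: pd.DataFrame,
    percentiles=(95, 99, 100),
    cell_size: float = 1.0,
    z_tolerance: float = 0.10,
    min_points: int = 1,
) -> pd.DataFrame:
    """Full chain for one cloud: classify, normalize, extract per plot.

    Plots with fewer than ``min_points`` member points get NaN metrics
    and ``n_points`` reported for filtering.
    """
    ground = classify_ground(points, cell_size=cell_size, z_tolerance=z_tolerance)
    chm = canopy_height_model(points, ground)
    pts = np.asarray(points, dtype=float)
    rows = []
    for _, rec in rectangles.iterrows():
        inside = (
            (pts[:, 0] >= rec["x_min"]) & (pts[:, 0] < rec["x_max"])
            & (pts[:, 1] >= rec["y_min"]) & (pts[:, 1] < rec["y_max"])
        )
        n = int(inside.sum())
        row = {"plot_id": rec["plot_id"], "n_points": n}
        for p in percentiles:
            row[f"p{int(p)}_m"] = (
                float(np.percentile(chm[inside], p)) if n >= min_points else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def read_xyz(path) -> np.ndarray:
    """Read a whitespace-separated XYZ text file."""
    return np.loadtxt(path, dtype=float, ndmin=2)[:, :3]


def write_xyz(points: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(points, dtype=float), fmt="%.6f")
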