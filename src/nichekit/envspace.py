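"""PCA environmental envelopes, convex-hull overlap, bootstrap comparisons."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon
from shapely.geometry.polygon import orient

from nichekit.errors import GeometryError, InputError


@dataclass
class PCAResult:
    """Standardized (correlation-matrix) PCA.

    ``scores = (X - center) / scale @ loadings``. Sign convention: the
    largest-magnitude entry of each loading vector is positive.
    """

    loadings: np.ndarray          # variables x components
    scores: np.ndarray            # records x components
    explained_var_fraction: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    names: list[str]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        return (X - self.center) / self.scale @ self.loadings


@dataclass
class HullOverlap:
    """Pairwise convex-hull overlap summary in PC1-PC2 space."""

    area_a: float
    area_b: float
    area_intersection: float
    frac_a: float                 # intersection / area_a
    frac_b: float                 # intersection / area_b
    frac_union: float             # intersection / union
    points_in_overlap_a: float    # proportion of a's points inside the intersection
    points_in_overlap_b: float


@dataclass
class CIResult:
    statistic: str
    estimate: float
    ci_low: float
    ci_high: float
    n_boot: int


def run_pca(env_table: pd.DataFrame | np.ndarray, names: list[str] | None = None) -> PCAResult:
    """PCA on the correlation matrix of a records x variables table.

    Variables are z-scored first (heterogeneous units); components are
    the correlation-matrix eigenvectors, ordered by decreasing eigenvalue.
    """
    if isinstance(env_table, pd.DataFrame):
        names = list(env_table.columns)
        X = env_table.to_numpy(float)
    else:
        X = np.asarray(env_table, float)
        if names is None:
            names = [f"v{j}" for j in range(X.shape[1])]
    n, p = X.shape
    if n < p + 1:
        raise InputError(f"need >= {p + 1} records for {p} variables")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    if np.any(scale == 0):
        bad = [names[j] for j in range(p) if scale[j] == 0]
        raise InputError(f"constant variables: {bad}")
    Z = (X - center) / scale
    corr = (Z.T @ Z) / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|.| loading entry positive
    for k in range(p):
        j = np.argmax(np.abs(eigvecs[:, k]))
        if eigvecs[j, k] < 0:
            eigvecs[:, k] = -eigvecs[:, k]
    explained = eigvals / eigvals.sum()
    scores = Z @ eigvecs
    return PCAResult(eigvecs, scores, explained, center, scale, list(names))


def convex_hull(points2d: np.ndarray) -> Polygon:
    """Convex hull polygon of 2-D points, vertices counter-clockwise."""
    pts = np.asarray(points2d, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError("points2d must be (n, 2)")
    if pts.shape[0] < 3:
        raise GeometryError("need >= 3 points")
    hull = MultiPoint([tuple(p) for p in pts]).convex_hull
    if hull.geom_type != "Polygon":
        raise GeometryError("points are collinear; hull is degenerate")
    return orient(hull, sign=1.0)


def hull_overlap(
    hull_a: Polygon,
    hull_b: Polygon,
    points_a: np.ndarray | None = None,
    points_b: np.ndarray | None = None,
) -> HullOverlap:
    """Intersection-based overlap of two convex hulls.

    Point-in-overlap proportions count boundary points as inside.
    Disjoint hulls give zeros, not an error.
    """
    inter = hull_a.intersection(hull_b)
    area_a, area_b = hull_a.area, hull_b.area
    area_i = inter.area
    union_area = area_a + area_b - area_i

    def _points_frac(points: np.ndarray | None) -> float:
        if points is None or len(points) == 0 or area_i == 0:
            return 0.0
        pts = np.asarray(points, float)
        inside = shapely.intersects_xy(inter, pts[:, 0], pts[:, 1])
        return float(np.mean(inside))

    return HullOverlap(
        area_a=area_a,
        area_b=area_b,
        area_intersection=area_i,
        frac_a=area_i / area_a if area_a > 0 else 0.0,
        frac_b=area_i / area_b if area_b > 0 else 0.0,
        frac_union=area_i / union_area if union_area > 0 else 0.0,
        points_in_overlap_a=_points_frac(points_a),
        points_in_overlap_b=_points_frac(points_b),
    )


_STATS = {"mean": np.mean, "median": np.median}


def bootstrap_ci(values: np.ndarray, statistic: str = "mean", n_boot: int = 1000, seed: int = 0) -> CIResult:
    """Percentile bootstrap 95% CI (2.5/97.5 percentiles) of mean or median."""
    values = np.asarray(values, float)
    if len(values) < 2:
        raise InputError("need >= 2 values")
    if statistic not in _STATS:
        raise InputError(f"statistic must be one of {sorted(_STATS)}")
    fn = _STATS[statistic]
    rng = np.random.default_rng(seed)
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = fn(values[idx], axis=1)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return CIResult(statistic, float(fn(values)), float(lo), float(hi), n_boot)


def ci_letter_groups(cis: dict[str, CIResult]) -> dict[str, str]:
    """Compact letter display from CI overlap.

    Classes whose CIs overlap share at least one letter; classes with
    disjoint CIs share none. Letters are assigned in ascending order of
    point estimate: maximal runs of mutually overlapping intervals
    (intervals have the Helly property, so maximal cliques of the
    overlap graph are contiguous in sorted order) each get one letter.
    """
    if len(cis) < 2:
        raise InputError("need >= 2 classes")
    keys = sorted(cis, key=lambda k: cis[k].estimate)
    intervals = [(cis[k].ci_low, cis[k].ci_high) for k in keys]
    n = len(keys)

    def overlaps(i: int, j: int) -> bool:
        return intervals[i][0] <= intervals[j][1] and intervals[j][0] <= intervals[i][1]

    # maximal cliques = maximal runs [i, j] with min(hi over run) >= max(lo over run)
    cliques: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and all(overlaps(k, j + 1) for k in range(i, j + 1)):
            j += 1
        if not cliques or cliques[-1][1] < j or cliques[-1][0] > i:
            if not any(ci <= i and j <= cj for ci, cj in cliques):
                cliques.append((i, j))
    letters = "abcdefghijklmnopqrstuvwxyz"
    out = {k: "" for k in keys}
    for c_idx, (i, j) in enumerate(cliques):
        for k in range(i, j + 1):
            out[keys[k]] += letters[c_idx % len(letters)]
    return out
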