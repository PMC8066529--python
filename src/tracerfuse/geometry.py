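"""Data-space geometry of region point clouds.

Three diagnostics link classifier performance to the geometry of the
class-conditional point clouds:

* the **between-region variance fraction** — the share of total sum of
  squares attributable to differences between region centroids (the classic
  one-way ANOVA decomposition, here on a tracer subset);
* **centroid distances** — Euclidean distances between per-region mean
  vectors;
* the **hull overlap fraction** — per region, the 90% of points closest to
  their own centroid are kept (outlier trimming), their convex hulls are
  built in 2-D or 3-D, and the summed measure of the pairwise hull
  intersections is divided by the summed measure of the hulls. Low overlap
  means well-separated fingerprints.

A saturating regression of performance against any of these metrics
(:func:`performance_geometry_regression`) quantifies how much of the
performance variation the geometry explains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.optimize import curve_fit, linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError
from shapely.geometry import MultiPoint

from .data import BioTracerTable

__all__ = [
    "GeometrySummary",
    "between_variance_fraction",
    "centroid_distances",
    "hull_overlap_fraction",
    "hull_overlap_from_points",
    "monte_carlo_overlap",
    "performance_geometry_regression",
    "geometry_summary",
]


@dataclass
class GeometrySummary:
    """Geometry diagnostics for one tracer subset."""

    subset: list
    between_variance_fraction: float
    centroid_distances: dict[tuple[str, str], float]
    mean_centroid_distance: float
    hull_overlap_fraction: float | None = None


def _points_by_region(table: BioTracerTable, subset) -> dict[str, np.ndarray]:
    sub = table.select_tracers(subset) if subset is not None else table
    reg = sub.region.to_numpy()
    return {r: sub.matrix[reg == r] for r in sub.regions}


def between_variance_fraction(table: BioTracerTable, subset=None) -> float:
    """Share of the total sum of squares carried by region-mean differences.

    ``Σ_r n_r·‖centroid_r − grand‖² / Σ_i ‖x_i − grand‖²`` on the subset
    columns — the multivariate one-way ANOVA between/total ratio.
    """
    groups = _points_by_region(table, subset)
    allx = np.vstack(list(groups.values()))
    grand = allx.mean(axis=0)
    total_ss = float(np.sum((allx - grand) ** 2))
    if total_ss == 0:
        return 0.0
    between_ss = sum(len(g) * float(np.sum((g.mean(axis=0) - grand) ** 2))
                     for g in groups.values())
    return between_ss / total_ss


def centroid_distances(table: BioTracerTable, subset=None) -> dict[tuple[str, str], float]:
    """Euclidean distances between per-region centroids on the subset columns."""
    groups = _points_by_region(table, subset)
    cents = {r: g.mean(axis=0) for r, g in groups.items()}
    return {
        (a, b): float(np.linalg.norm(cents[a] - cents[b]))
        for a, b in combinations(cents, 2)
    }


# ---- convex-hull overlap -----------------------------------------------------


def _retain_closest(points: np.ndarray, retain_fraction: float) -> np.ndarray:
    """Keep the ⌈f·n⌉ points nearest their own centroid (outlier trimming)."""
    n_keep = math.ceil(retain_fraction * len(points))
    dist = np.linalg.norm(points - points.mean(axis=0), axis=1)
    order = np.argsort(dist, kind="stable")
    return points[order[:n_keep]]


def _hull_measure(points: np.ndarray) -> tuple[ConvexHull, float]:
    try:
        hull = ConvexHull(points)
    except QhullError as err:
        raise ValueError(f"degenerate convex hull (collinear/coplanar points): {err}")
    return hull, float(hull.volume)  # qhull "volume" is area in 2-D


def _pair_intersection_2d(pa: np.ndarray, pb: np.ndarray) -> float:
    inter = MultiPoint(pa).convex_hull.intersection(MultiPoint(pb).convex_hull)
    return float(inter.area)


def _pair_intersection_3d(ha: ConvexHull, hb: ConvexHull) -> float:
    # joint halfspace system A x <= -b from both hulls' facet inequalities
    eqs = np.vstack([ha.equations, hb.equations])
    A, b = eqs[:, :-1], eqs[:, -1]
    # Chebyshev centre: maximise r s.t. A x + r·‖A_i‖ ≤ −b
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    res = linprog(
        c=np.r_[np.zeros(A.shape[1]), -1.0],
        A_ub=np.hstack([A, norms]),
        b_ub=-b,
        bounds=[(None, None)] * A.shape[1] + [(0, None)],
        method="highs",
    )
    if not res.success or res.x[-1] <= 1e-12:
        return 0.0  # empty or measure-zero intersection
    interior = res.x[:-1]
    hs = HalfspaceIntersection(eqs, interior)
    return float(ConvexHull(hs.intersections).volume)


def hull_overlap_from_points(
    points_by_region: dict[str, np.ndarray],
    retain_fraction: float = 0.9,
    triple_rule: str = "pairwise-sum",
) -> float:
    """Overlap fraction of per-region convex hulls from raw point clouds.

    Per region, the ``⌈retain_fraction·n⌉`` points nearest their centroid are
    retained; the result is (sum of pairwise hull-intersection measures) /
    (sum of hull measures). ``triple_rule="inclusion-exclusion"`` additionally
    subtracts twice the triple intersection so the union-overlap region is
    counted once (3-region case only).
    """
    dims = {p.shape[1] for p in points_by_region.values()}
    if len(dims) != 1 or dims.pop() not in (2, 3):
        raise ValueError("hull overlap is defined for 2-D or 3-D subsets")
    d = next(iter(points_by_region.values())).shape[1]
    kept = {r: _retain_closest(p, retain_fraction) for r, p in points_by_region.items()}
    for r, p in kept.items():
        if len(p) < d + 1:
            raise ValueError(f"region {r!r} retains {len(p)} points; need ≥ {d + 1}")
    hulls = {r: _hull_measure(p) for r, p in kept.items()}
    total = sum(m for _, m in hulls.values())
    pair_sum = 0.0
    for a, b in combinations(kept, 2):
        if d == 2:
            pair_sum += _pair_intersection_2d(kept[a], kept[b])
        else:
            pair_sum += _pair_intersection_3d(hulls[a][0], hulls[b][0])
    overlap = pair_sum
    if triple_rule == "inclusion-exclusion":
        if len(kept) == 3 and d == 2:
            names = list(kept)
            h = [MultiPoint(kept[r]).convex_hull for r in names]
            triple = h[0].intersection(h[1]).intersection(h[2]).area
            overlap -= 2.0 * float(triple)
        elif len(kept) == 3:
            raise NotImplementedError("inclusion-exclusion triple rule is 2-D only")
    elif triple_rule != "pairwise-sum":
        raise ValueError(f"unknown triple rule {triple_rule!r}")
    return overlap / total


def hull_overlap_fraction(
    table: BioTracerTable,
    subset,
    retain_fraction: float = 0.9,
    triple_rule: str = "pairwise-sum",
) -> float:
    """Hull overlap fraction on a 2- or 3-tracer subset of a table."""
    names = table._subset_names(subset)
    if len(names) not in (2, 3):
        raise ValueError(f"hull overlap needs a subset of size 2 or 3; got {names}")
    try:
        return hull_overlap_from_points(
            _points_by_region(table, subset), retain_fraction, triple_rule
        )
    except ValueError as err:
        raise ValueError(f"subset {names}: {err}") from err


def monte_carlo_overlap(
    points_by_region: dict[str, np.ndarray],
    retain_fraction: float = 0.9,
    n_points: int = 200_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo rejection estimate of the hull overlap fraction.

    Uniform points in the joint bounding box are tested for membership in each
    hull via its facet inequalities; each pairwise intersection measure is the
    box measure times the joint-hit rate. Returns ``(overlap, se)``; intended
    as an independent cross-check of :func:`hull_overlap_from_points`.
    """
    kept = {r: _retain_closest(p, retain_fraction) for r, p in points_by_region.items()}
    hulls = {r: _hull_measure(p) for r, p in kept.items()}
    total = sum(m for _, m in hulls.values())
    allp = np.vstack(list(kept.values()))
    lo, hi = allp.min(axis=0), allp.max(axis=0)
    box = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_points, allp.shape[1]))
    inside = {}
    for r, (hull, _) in hulls.items():
        A, b = hull.equations[:, :-1], hull.equations[:, -1]
        inside[r] = np.all(pts @ A.T + b <= 1e-12, axis=1)
    est, var = 0.0, 0.0
    for a, b_ in combinations(kept, 2):
        p_hit = float((inside[a] & inside[b_]).mean())
        est += box * p_hit
        var += (box**2) * p_hit * (1 - p_hit) / n_points
    return est / total, float(np.sqrt(var)) / total


# ---- regression of performance on geometry ----------------------------------


@dataclass
class SaturatingFit:
    """y = c + (a − c)·(1 − exp(−b·x)) least-squares fit."""

    a: float
    b: float
    c: float
    r_squared: float
    degenerate: bool = False

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.c + (self.a - self.c) * (1.0 - np.exp(-self.b * x))


def performance_geometry_regression(
    x: np.ndarray, y: np.ndarray, c_min: float = 0.0
) -> SaturatingFit:
    """Non-linear least squares of performance against a geometry metric.

    Fits the bounded, monotone saturating form ``y = c + (a−c)(1−exp(−b·x))``
    (c = intercept at x=0, a = asymptote, b = rate ≥ 0), with the intercept
    floored at ``c_min`` (e.g. chance level 1/R). R² = 1 − SSres/SStot;
    a constant response is reported as a degenerate fit with R² = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points to fit the saturating curve")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("metric and performance values must be finite")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 1e-12 * max(1.0, float(np.max(np.abs(y))) ** 2) * y.size:
        return SaturatingFit(a=float(y[0]), b=0.0, c=float(y[0]),
                             r_squared=0.0, degenerate=True)

    def f(xx, a, b, c):
        return c + (a - c) * (1.0 - np.exp(-b * xx))

    xspan = x.max() - x.min() if x.max() > x.min() else 1.0
    p0 = [float(y.max()), 1.0 / xspan, max(float(y.min()), c_min)]
    try:
        popt, _ = curve_fit(
            f, x, y, p0=p0,
            bounds=([0.0, 0.0, c_min], [1.5, np.inf, 1.5]),
            maxfev=20_000,
        )
    except RuntimeError as err:
        resid = float(np.sum((f(x, *p0) - y) ** 2))
        raise RuntimeError(f"regression did not converge (residual {resid:.4g})") from err
    ss_res = float(np.sum((y - f(x, *popt)) ** 2))
    return SaturatingFit(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                         r_squared=1.0 - ss_res / ss_tot)


def geometry_summary(
    table: BioTracerTable,
    subset,
    retain_fraction: float = 0.9,
    triple_rule: str = "pairwise-sum",
) -> GeometrySummary:
    """All geometry diagnostics for one subset (hull overlap only for 2-D/3-D)."""
    names = table._subset_names(subset)
    dists = centroid_distances(table, subset)
    overlap = None
    if len(names) in (2, 3):
        overlap = hull_overlap_fraction(table, subset, retain_fraction, triple_rule)
    return GeometrySummary(
        subset=names,
        between_variance_fraction=between_variance_fraction(table, subset),
        centroid_distances=dists,
        mean_centroid_distance=float(np.mean(list(dists.values()))),
        hull_overlap_fraction=overlap,
    )
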