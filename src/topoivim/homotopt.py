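"""Derivative-free simplicial-homology global optimization.

The optimizer samples a compact box with a low-discrepancy sequence,
triangulates the samples into a simplicial complex, and reads the
objective's topology off the complex: a vertex whose value is no greater
than all of its neighbors' values is a *minimizer vertex*, and the star
of that vertex (the simplices containing it) bounds a locally convex
sub-domain that is guaranteed to contain a stationary point of any
continuous objective. Each minimizer vertex is refined by a bounded
derivative-free local search inside its star's bounding box, giving the
*minimizer pool*. For a Lipschitz objective that is adequately sampled,
growing the sampling set further does not grow the pool, which yields
the stopping rule: double the samples until the (deduplicated) pool
cardinality is stable and the best value has stopped improving.

Only box constraints are supported; additional structure (e.g. penalty
terms) is folded into the objective by the caller.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.stats import qmc

from .ivim import ConfigurationError

__all__ = [
    "TriangulatedComplex",
    "MinimizerPool",
    "ShgoResult",
    "sample_domain",
    "build_complex",
    "star",
    "minimizer_pool",
    "local_refine",
    "shgo_minimize",
    "pool_invariance_check",
]

#: two refined minima merge when within this relative distance per dimension
DEDUP_RTOL = 1e-3
#: local refinement tolerance on the function value
REFINE_FATOL = 1e-8
#: simplex diameter tolerance, relative to the box width per dimension
REFINE_XTOL_REL = 1e-7
REFINE_MAXITER = 500
#: stop doubling when the best value improved by less than this
VALUE_ATOL = 1e-10


@dataclass
class TriangulatedComplex:
    """Sampled vertices, their objective values, and the simplices gluing them."""

    vertices: np.ndarray  # (N, n)
    values: np.ndarray  # (N,)
    simplices: np.ndarray  # (S, n+1) int
    adjacency: list  # per-vertex sorted array of neighbor indices
    n_evaluations: int = 0

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def ndim(self) -> int:
        return self.vertices.shape[1]


@dataclass
class MinimizerPool:
    """Vertices no worse than any neighbor, with their star-derived boxes and refinements."""

    minimizers: list  # vertex indices
    star_boxes: list  # per minimizer: list of (lo, hi) per dimension
    refined: list = field(default_factory=list)  # (point, value) after local refinement


@dataclass
class ShgoResult:
    x: np.ndarray
    fun: float
    minima: list  # all deduplicated refined (point, value), sorted by value
    nfev: int
    n_iterations: int
    pool_sizes: list  # |M| per sampling iteration
    success: bool = True


def _as_bounds(bounds):
    lo = np.array([float(b[0]) for b in bounds])
    hi = np.array([float(b[1]) for b in bounds])
    if np.any(lo >= hi) or not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ConfigurationError(f"bounds must be finite with lo < hi, got {bounds!r}")
    return lo, hi


def sample_domain(bounds, n_points: int, seed: int) -> np.ndarray:
    """Sobol low-discrepancy sample of the box, plus its 2**n corners.

    The Sobol sequence is seeded (scrambled) so runs are reproducible,
    and prefixes are nested: the first N points of a 2N draw with the
    same seed equal the N-point draw, so sample doubling reuses earlier
    evaluations of the same locations. The corners guarantee that the
    convex hull of the sample covers the whole box.
    """
    lo, hi = _as_bounds(bounds)
    n = lo.size
    if n_points < n + 1:
        raise ConfigurationError(f"need at least n+1={n + 1} points, got {n_points}")
    sob = qmc.Sobol(d=n, scramble=True, seed=int(seed))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # non-power-of-two draw
        u = sob.random(n_points)
    pts = lo + u * (hi - lo)
    corners = np.array(list(itertools.product(*zip(lo, hi))))
    return np.vstack([pts, corners])


def _chain_simplices_1d(vertices: np.ndarray) -> np.ndarray:
    order = np.argsort(vertices[:, 0], kind="stable")
    return np.column_stack([order[:-1], order[1:]])


def build_complex(vertices: np.ndarray, objective, batch=None) -> TriangulatedComplex:
    """Triangulate the samples (Delaunay) and evaluate the objective once per vertex.

    ``batch``, if given, evaluates an (N, n) array of points in one call.
    Degenerate (collinear/coplanar) vertex sets are jittered once and
    retried before raising.
    """
    vertices = np.asarray(vertices, dtype=float)
    n = vertices.shape[1]
    if vertices.shape[0] < n + 1:
        raise ConfigurationError("need at least n+1 vertices to triangulate")
    if n == 1:
        simplices = _chain_simplices_1d(vertices)
    else:
        try:
            simplices = Delaunay(vertices).simplices
        except QhullError:
            scale = np.ptp(vertices, axis=0)
            rng = np.random.default_rng(0)
            jittered = vertices + rng.normal(scale=1e-9 * np.maximum(scale, 1.0), size=vertices.shape)
            try:
                simplices = Delaunay(jittered).simplices
            except QhullError as err:  # pragma: no cover - requires pathological input
                raise ConfigurationError("degenerate vertex set cannot be triangulated") from err

    if batch is not None:
        values = np.asarray(batch(vertices), dtype=float)
        nfev = vertices.shape[0]
    else:
        values = np.array([float(objective(v)) for v in vertices])
        nfev = vertices.shape[0]

    # symmetric adjacency from all vertex pairs within each simplex
    simplices = np.asarray(simplices)
    k = simplices.shape[1]
    pairs = [(a, b) for a in range(k) for b in range(k) if a != b]
    src = np.concatenate([simplices[:, a] for a, _ in pairs])
    dst = np.concatenate([simplices[:, b] for _, b in pairs])
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    adjacency = []
    bounds_idx = np.searchsorted(src, np.arange(vertices.shape[0] + 1))
    for i in range(vertices.shape[0]):
        adjacency.append(np.unique(dst[bounds_idx[i]:bounds_idx[i + 1]]))
    return TriangulatedComplex(
        vertices=vertices, values=values, simplices=np.asarray(simplices),
        adjacency=adjacency, n_evaluations=nfev,
    )


def star(complex_: TriangulatedComplex, v_i: int) -> np.ndarray:
    """Indices of the simplices incident to vertex ``v_i`` (the star of the vertex)."""
    if not 0 <= v_i < complex_.n_vertices:
        raise IndexError(f"vertex index {v_i} out of range")
    return np.flatnonzero(np.any(complex_.simplices == v_i, axis=1))


def _star_box(complex_: TriangulatedComplex, v_i: int):
    """Axis-aligned bounding box of a vertex's star (the vertex plus its neighbors)."""
    idx = np.concatenate([[v_i], complex_.adjacency[v_i]]).astype(int)
    pts = complex_.vertices[idx]
    return list(zip(pts.min(axis=0), pts.max(axis=0)))


def minimizer_pool(complex_: TriangulatedComplex) -> MinimizerPool:
    """Extract vertices whose value is <= every adjacent vertex's value.

    On flat plateaus, equal-valued adjacent candidates form connected
    components; one representative (lowest index) per component enters
    the pool, which keeps flat valleys from flooding it.
    """
    values = complex_.values
    candidates = [
        i for i in range(complex_.n_vertices)
        if complex_.adjacency[i].size == 0
        or values[i] <= values[complex_.adjacency[i]].min()
    ]
    cand_set = set(candidates)
    seen: set = set()
    reps = []
    for i in candidates:  # ascending index order -> lowest-index representative
        if i in seen:
            continue
        comp = {i}
        frontier = [i]
        while frontier:
            k = frontier.pop()
            for j in complex_.adjacency[k]:
                j = int(j)
                if j in cand_set and j not in comp and values[j] == values[k]:
                    comp.add(j)
                    frontier.append(j)
        seen |= comp
        reps.append(i)
    return MinimizerPool(
        minimizers=reps,
        star_boxes=[_star_box(complex_, i) for i in reps],
    )


def _nelder_mead_bounded(objective, start, lo, hi, fatol, maxiter):
    """Minimal Nelder-Mead with bound clipping (standard 1/2/0.5/0.5 coefficients)."""
    n = start.size
    span = hi - lo
    simplex = np.tile(start, (n + 1, 1))
    for i in range(n):
        step = 0.05 * span[i] if span[i] > 0 else 1e-8
        simplex[i + 1, i] = np.clip(simplex[i + 1, i] + step, lo[i], hi[i])
        if simplex[i + 1, i] == simplex[0, i]:
            simplex[i + 1, i] = np.clip(simplex[i + 1, i] - step, lo[i], hi[i])
    fvals = np.array([objective(x) for x in simplex])
    xatol = REFINE_XTOL_REL * np.maximum(span, 1e-30)
    nit = 0
    while nit < maxiter:
        order = np.argsort(fvals, kind="stable")
        simplex, fvals = simplex[order], fvals[order]
        if (fvals[-1] - fvals[0] <= fatol
                and np.all(np.abs(simplex[1:] - simplex[0]).max(axis=0) <= xatol)):
            return simplex[0], fvals[0], True
        nit += 1
        centroid = simplex[:-1].mean(axis=0)
        xr = np.clip(centroid + (centroid - simplex[-1]), lo, hi)
        fr = objective(xr)
        if fr < fvals[0]:
            xe = np.clip(centroid + 2.0 * (centroid - simplex[-1]), lo, hi)
            fe = objective(xe)
            simplex[-1], fvals[-1] = (xe, fe) if fe < fr else (xr, fr)
        elif fr < fvals[-2]:
            simplex[-1], fvals[-1] = xr, fr
        else:
            xc = np.clip(centroid + 0.5 * (simplex[-1] - centroid), lo, hi)
            fc = objective(xc)
            if fc < fvals[-1]:
                simplex[-1], fvals[-1] = xc, fc
            else:  # shrink toward the best vertex
                simplex[1:] = simplex[0] + 0.5 * (simplex[1:] - simplex[0])
                fvals[1:] = [objective(x) for x in simplex[1:]]
    order = np.argsort(fvals, kind="stable")
    return simplex[order[0]], fvals[order[0]], False


def local_refine(objective, start, box_bounds, maxiter: int = REFINE_MAXITER):
    """Bounded Nelder-Mead descent from ``start`` inside ``box_bounds``.

    Returns (point, value, converged). The returned value never exceeds
    the value at ``start``; the point stays inside the box.
    """
    start = np.asarray(start, dtype=float)
    lo = np.array([b[0] for b in box_bounds], dtype=float)
    hi = np.array([b[1] for b in box_bounds], dtype=float)
    start = np.clip(start, lo, hi)
    f0 = float(objective(start))
    x, fv, converged = _nelder_mead_bounded(objective, start, lo, hi,
                                            REFINE_FATOL, maxiter)
    if fv > f0:  # never leave worse than we started
        return start, f0, converged
    return np.clip(x, lo, hi), float(fv), converged


def _interior(x, box, lo, hi, rtol=1e-6):
    """True when x sits strictly inside its star box (away from every face
    that is not also a face of the global box)."""
    for xi, (b_lo, b_hi), g_lo, g_hi in zip(x, box, lo, hi):
        tol = rtol * max(b_hi - b_lo, 1e-30)
        if xi - b_lo <= tol and b_lo - g_lo > tol:
            return False
        if b_hi - xi <= tol and g_hi - b_hi > tol:
            return False
    return True


def _dedup_minima(minima, bounds):
    """Merge refined minima that coincide within DEDUP_RTOL per bounds-scaled dimension."""
    lo, hi = _as_bounds(bounds)
    width = hi - lo
    kept = []
    for x, v in sorted(minima, key=lambda t: t[1]):
        if not any(np.all(np.abs(x - xk) <= DEDUP_RTOL * width) for xk, _ in kept):
            kept.append((x, v))
    return kept


def shgo_minimize(objective, bounds, n_points: int = 64, max_iters: int = 4,
                  seed: int = 0, batch=None) -> ShgoResult:
    """Full pipeline: sample -> triangulate -> minimizer pool -> refine, with doubling.

    Sampling is doubled until the deduplicated pool cardinality is
    unchanged across one doubling *and* the best value stopped improving
    (the invariance stopping rule), or ``max_iters`` rounds are reached.
    Returns every refined minimum sorted by value; deterministic for a
    fixed (objective, bounds, n_points, seed).
    """
    lo, hi = _as_bounds(bounds)
    nfev = 0
    prev_count = None
    prev_best = np.inf
    minima = []
    pool_sizes = []
    it = 0
    N = int(n_points)
    for it in range(1, max_iters + 1):
        pts = sample_domain(bounds, N, seed)
        comp = build_complex(pts, objective, batch=batch)
        nfev += comp.n_evaluations
        bad = ~np.isfinite(comp.values)
        if bad.mean() > 0.5:
            raise ConfigurationError(
                "objective non-finite at more than half the samples; check bounds"
            )
        comp.values[bad] = np.inf
        pool = minimizer_pool(comp)
        refined = []
        for v_i, box in zip(pool.minimizers, pool.star_boxes):
            x, val, _ = local_refine(objective, comp.vertices[v_i], box)
            refined.append((x, val))
        pool.refined = refined
        # polish within the global box: star-box artifacts of sparse sampling
        # (pool vertices on tilted valley floors) slide to the true minimum
        # of their basin instead of sticking to a star-box face; points that
        # finished strictly inside their star box are already local minima
        polished = []
        for (x, val), box in zip(refined, pool.star_boxes):
            if _interior(x, box, lo, hi):
                polished.append((x, val))
                continue
            xg, vg, _ = local_refine(objective, x, list(zip(lo, hi)))
            polished.append((xg, vg) if vg <= val else (x, val))
        minima = _dedup_minima(polished, bounds)
        pool_sizes.append(len(minima))
        best = minima[0][1]
        if prev_count == len(minima) and prev_best - best < VALUE_ATOL:
            break
        prev_count, prev_best = len(minima), best
        N *= 2
    x_best, f_best = minima[0]
    return ShgoResult(
        x=np.asarray(x_best), fun=float(f_best), minima=minima,
        nfev=nfev, n_iterations=it, pool_sizes=pool_sizes,
    )


def pool_invariance_check(objective, bounds, n_sequence, seed: int = 0, batch=None):
    """Pool cardinality (after refinement and deduplication) for each sampling size.

    For adequately sampled Lipschitz objectives the sequence plateaus at
    the true number of distinct minima and does not grow thereafter.
    """
    lo, hi = _as_bounds(bounds)
    sizes = []
    for n in n_sequence:
        pts = sample_domain(bounds, int(n), seed)
        comp = build_complex(pts, objective, batch=batch)
        pool = minimizer_pool(comp)
        polished = []
        for v_i, box in zip(pool.minimizers, pool.star_boxes):
            x, val, _ = local_refine(objective, comp.vertices[v_i], box)
            if not _interior(x, box, lo, hi):
                xg, vg, _ = local_refine(objective, x, list(zip(lo, hi)))
                if vg <= val:
                    x, val = xg, vg
            polished.append((x, val))
        sizes.append(len(_dedup_minima(polished, bounds)))
    return sizes
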