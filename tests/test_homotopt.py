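"""Simplicial-homology optimizer: sampling, complex, star domains, pool, refinement."""

import numpy as np
import pytest
from scipy.optimize import shgo as scipy_shgo
from scipy.spatial import ConvexHull
from scipy.stats import qmc

from topoivim import homotopt as ho
from topoivim.ivim import ConfigurationError


def double_well(x):
    return (x[0] ** 2 - 1) ** 2 + x[1] ** 2


def bowl(x):
    return (x[0] - 0.3) ** 2 + (x[1] - 0.7) ** 2


class TestSampleDomain:
    def test_deterministic_and_contained(self):
        b = [(0.0, 1.0), (0.0, 1.0)]
        p1 = ho.sample_domain(b, 16, seed=0)
        p2 = ho.sample_domain(b, 16, seed=0)
        np.testing.assert_array_equal(p1, p2)
        assert np.all(p1 >= 0.0) and np.all(p1 <= 1.0)
        # includes the 4 box corners
        corners = {(0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0)}
        assert corners <= set(map(tuple, p1))

    def test_prefix_nesting_under_doubling(self):
        b = [(0.0, 2.0), (-1.0, 1.0)]
        p1 = ho.sample_domain(b, 32, seed=5)[:32]
        p2 = ho.sample_domain(b, 64, seed=5)[:32]
        np.testing.assert_array_equal(p1, p2)

    def test_lower_discrepancy_than_random(self):
        b = [(0.0, 1.0), (0.0, 1.0)]
        pts = ho.sample_domain(b, 128, seed=1)
        d_sobol = qmc.discrepancy(pts)
        rng = np.random.default_rng(0)
        d_rand = np.mean([
            qmc.discrepancy(rng.uniform(size=pts.shape)) for _ in range(20)
        ])
        assert d_sobol < d_rand

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            ho.sample_domain([(1.0, 0.0)], 8, seed=0)


class TestBuildComplex:
    def test_unit_square_two_triangles(self):
        verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        comp = ho.build_complex(verts, lambda x: 0.0)
        assert comp.simplices.shape == (2, 3)
        # the two triangles share the diagonal: exactly 2 shared vertices
        shared = set(comp.simplices[0]) & set(comp.simplices[1])
        assert len(shared) == 2

    def test_objective_evaluated_once_per_vertex(self):
        calls = []

        def obj(x):
            calls.append(tuple(x))
            return float(np.sum(np.asarray(x) ** 2))

        verts = ho.sample_domain([(0, 1), (0, 1)], 16, seed=2)
        comp = ho.build_complex(verts, obj)
        assert len(calls) == comp.n_vertices == verts.shape[0]

    def test_simplex_volumes_sum_to_hull_volume(self):
        verts = ho.sample_domain([(0, 2), (0, 3)], 64, seed=3)
        comp = ho.build_complex(verts, lambda x: 0.0)
        total = 0.0
        for s in comp.simplices:
            p = comp.vertices[s]
            total += abs(np.linalg.det(p[1:] - p[0])) / 2.0
        hull = ConvexHull(verts)
        assert total == pytest.approx(hull.volume, rel=1e-9)

    def test_adjacency_symmetric(self):
        verts = ho.sample_domain([(0, 1), (0, 1)], 32, seed=4)
        comp = ho.build_complex(verts, lambda x: 0.0)
        for i, nbrs in enumerate(comp.adjacency):
            for j in nbrs:
                assert i in comp.adjacency[int(j)]


class TestStar:
    def test_star_covers_all_simplices(self):
        verts = ho.sample_domain([(0, 1), (0, 1)], 32, seed=6)
        comp = ho.build_complex(verts, lambda x: 0.0)
        union = set()
        for i in range(comp.n_vertices):
            union |= set(ho.star(comp, i).tolist())
        assert union == set(range(comp.simplices.shape[0]))

    def test_star_is_incident_simplices(self):
        verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        comp = ho.build_complex(verts, lambda x: 0.0)
        for i in range(4):
            for s_idx in ho.star(comp, i):
                assert i in comp.simplices[s_idx]
        with pytest.raises(IndexError):
            ho.star(comp, 99)


class TestMinimizerPool:
    def test_convex_1d_chain_single_minimum(self):
        verts = np.array([[-1.0], [-0.5], [0.0], [0.5], [1.0]])
        comp = ho.build_complex(verts, lambda x: x[0] ** 2)
        pool = ho.minimizer_pool(comp)
        assert [tuple(comp.vertices[i]) for i in pool.minimizers] == [(0.0,)]

    def test_double_well_two_minima_on_grid(self):
        g = np.linspace(-2, 2, 16)
        X, Y = np.meshgrid(g, g)
        verts = np.column_stack([X.ravel(), Y.ravel()])
        comp = ho.build_complex(verts, double_well)
        pool = ho.minimizer_pool(comp)
        pts = comp.vertices[pool.minimizers]
        assert len(pool.minimizers) == 2
        assert sorted(np.sign(pts[:, 0])) == [-1, 1]

    def test_constant_objective_deduplicates_to_one(self):
        verts = ho.sample_domain([(0, 1), (0, 1)], 32, seed=8)
        comp = ho.build_complex(verts, lambda x: 1.0)
        pool = ho.minimizer_pool(comp)
        # flat surface: all vertices tie; one representative per connected component
        assert len(pool.minimizers) == 1

    def test_refined_point_inside_star_box(self):
        verts = ho.sample_domain([(-2, 2), (-2, 2)], 64, seed=9)
        comp = ho.build_complex(verts, double_well)
        pool = ho.minimizer_pool(comp)
        for v_i, box in zip(pool.minimizers, pool.star_boxes):
            x, val, _ = ho.local_refine(double_well, comp.vertices[v_i], box)
            for xi, (lo, hi) in zip(x, box):
                assert lo - 1e-12 <= xi <= hi + 1e-12
            assert val <= comp.values[v_i] + 1e-15


class TestLocalRefine:
    def test_quadratic_bowl_converges(self):
        x, v, ok = ho.local_refine(bowl, [0.0, 0.0], [(0, 1), (0, 1)])
        np.testing.assert_allclose(x, [0.3, 0.7], atol=1e-6)
        assert ok

    def test_idempotent_at_minimum(self):
        x, v, _ = ho.local_refine(bowl, [0.3, 0.7], [(0, 1), (0, 1)])
        assert v <= bowl([0.3, 0.7])


class TestShgoMinimize:
    def test_double_well_finds_both_minima(self):
        res = ho.shgo_minimize(double_well, [(-2, 2), (-2, 2)], n_points=32, seed=0)
        assert res.fun == pytest.approx(0.0, abs=1e-8)
        assert len(res.minima) == 2
        xs = sorted(m[0][0] for m in res.minima)
        np.testing.assert_allclose(xs, [-1.0, 1.0], atol=1e-4)

    def test_deterministic(self):
        r1 = ho.shgo_minimize(double_well, [(-2, 2), (-2, 2)], n_points=32, seed=3)
        r2 = ho.shgo_minimize(double_well, [(-2, 2), (-2, 2)], n_points=32, seed=3)
        np.testing.assert_array_equal(r1.x, r2.x)
        assert r1.fun == r2.fun
        assert [tuple(m[0]) for m in r1.minima] == [tuple(m[0]) for m in r2.minima]

    def test_matches_dense_grid_oracle(self):
        """Best value no worse than a 400x400 grid search, on random smooth objectives."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            a, b = rng.uniform(0.5, 2, 2)
            cx, cy = rng.uniform(-0.5, 0.5, 2)

            def obj(x, a=a, b=b, cx=cx, cy=cy):
                return (a * (x[0] - cx) ** 2 + b * (x[1] - cy) ** 2
                        + 0.3 * np.sin(3 * x[0]) * np.sin(3 * x[1]))

            res = ho.shgo_minimize(obj, [(-1, 1), (-1, 1)], n_points=64, seed=1)
            g = np.linspace(-1, 1, 400)
            X, Y = np.meshgrid(g, g)
            Z = (a * (X - cx) ** 2 + b * (Y - cy) ** 2
                 + 0.3 * np.sin(3 * X) * np.sin(3 * Y))
            assert res.fun <= Z.min() + 1e-9

    def test_agrees_with_scipy_shgo_oracle(self):
        """Independent cross-check against the reference SHGO implementation."""
        ours = ho.shgo_minimize(double_well, [(-2, 2), (-2, 2)], n_points=32, seed=0)
        ref = scipy_shgo(double_well, [(-2, 2), (-2, 2)], n=64)
        assert ours.fun == pytest.approx(ref.fun, abs=1e-6)

    def test_nonfinite_objective_raises(self):
        with pytest.raises(ConfigurationError):
            ho.shgo_minimize(lambda x: np.nan, [(0, 1), (0, 1)], n_points=16, seed=0)


class TestPoolInvariance:
    def test_double_well_plateau_at_two(self):
        sizes = ho.pool_invariance_check(double_well, [(-2, 2), (-2, 2)],
                                         (16, 64, 256), seed=0)
        assert sizes[-1] == 2
        assert sizes[-2] == 2

    def test_convex_bowl_plateau_at_one(self):
        sizes = ho.pool_invariance_check(bowl, [(0, 1), (0, 1)],
                                         (16, 64, 256), seed=0)
        assert all(s == 1 for s in sizes)

    def test_six_minima_polynomial_matches_grid_enumeration(self):
        """Camel-back-style surface: plateau count equals brute-force minima count."""

        def camel(x):
            return ((4 - 2.1 * x[0] ** 2 + x[0] ** 4 / 3) * x[0] ** 2
                    + x[0] * x[1] + (-4 + 4 * x[1] ** 2) * x[1] ** 2)

        bounds = [(-2.0, 2.0), (-1.0, 1.0)]
        # brute-force enumeration of strict local minima on a fine grid
        g1 = np.linspace(*bounds[0], 201)
        g2 = np.linspace(*bounds[1], 201)
        X, Y = np.meshgrid(g1, g2, indexing="ij")
        Z = (4 - 2.1 * X ** 2 + X ** 4 / 3) * X ** 2 + X * Y + (-4 + 4 * Y ** 2) * Y ** 2
        interior_minima = 0
        for i in range(1, 200):
            for j in range(1, 200):
                if Z[i, j] < Z[i - 1:i + 2, j - 1:j + 2].min() + 1e-15 \
                        and np.argmin(Z[i - 1:i + 2, j - 1:j + 2]) == 4:
                    interior_minima += 1
        sizes = ho.pool_invariance_check(camel, bounds, (64, 256, 1024), seed=2)
        assert sizes[-1] == interior_minima
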