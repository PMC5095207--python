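import numpy as np
import pytest

from varfit.polysys import DataPoint, PolySystem, bezout_number, evaluate
from varfit.geometry import (
    CodimensionError,
    build_critical_system,
    critical_family_solve,
    critical_transport,
    ed_degree,
    intersect_varieties,
    min_distance,
    min_from_solutions,
    numerical_dimension,
)
from varfit.tracker import TrackConfig, total_degree_solve
from varfit.synthdata import ellipsoid_model

from _oracles import lagrange_critical_count, set_distance


class TestBuildCriticalSystem:
    def test_augmented_system_is_square(self, sphere_xy):
        cs = build_critical_system(sphere_xy, DataPoint([0.5, 0.2], [1.0, 1.0]))
        assert cs.system.is_square()
        # (x,y,z) + 2 z-vars + (1 + r+m = 4) multipliers
        assert cs.system.n_vars == 3 + 2 + 4

    def test_partially_observed_sphere_has_four_critical_points(self, sphere_xy):
        """z·λ = 0 splits into the z = 0 circle pair plus a tangency pair."""
        cs = build_critical_system(sphere_xy, DataPoint([0.53, 0.21], [1.0, 1.0]))
        sols = total_degree_solve(cs.system)
        iso = [
            p
            for p, s, mu in zip(sols.points, sols.is_singular, sols.multiplicities)
            if not s and mu == 1
        ]
        assert len(iso) == 4

    def test_fully_observed_sphere_has_antipodal_pair(self, sphere_full):
        y = np.array([0.3, -0.4, 0.5])
        cs = build_critical_system(sphere_full, DataPoint(y.tolist(), [1.0] * 3))
        sols = total_degree_solve(cs.system)
        npoint = len(cs.point_vars)
        reals = [
            np.real(p[:3])
            for p in sols.points
            if np.abs(p[:npoint].imag).max() < 1e-6 * (1 + np.abs(p[:npoint].real).max())
        ]
        expect = y / np.linalg.norm(y)
        assert set_distance(reals, [expect, -expect]) < 1e-6

    def test_critical_points_satisfy_base_constraints(self, sphere_xy):
        cs = build_critical_system(sphere_xy, DataPoint([0.9, 0.1], [0.5, 0.5]))
        sols = total_degree_solve(cs.system)
        base = PolySystem(
            cs.system.variables, [cs.system.polynomials[i] for i in cs.base_indices]
        )
        for p in sols.points:
            assert np.abs(evaluate(base, p)).max() < 1e-8

    def test_overdetermined_constraints_raise(self):
        # 3 steady-state rows but only 2 free unknowns (no parameters)
        f = PolySystem.from_strings(
            ["x**2 - y", "y**2 - x", "x*y - 1"], ["x", "y"]
        )
        g = PolySystem.from_strings(["x"], ["x", "y"])
        from varfit.polysys import ModelSpec

        m = ModelSpec((), ("x", "y"), ("o",), f, g, {})
        with pytest.raises(CodimensionError):
            build_critical_system(m, DataPoint([1.0], [1.0]))


class TestMinDistance:
    def test_nearest_point_pair_on_sphere(self, sphere_xy):
        """Data (1.7, 0) projects to (1, 0, 0); plain d² = 0.49."""
        res = min_distance(sphere_xy, DataPoint([1.7, 0.0], [0.1, 0.1]))
        assert res.d2 == pytest.approx(0.49, abs=1e-8)
        est = res.argmins[0]
        assert est["states"]["x"] == pytest.approx(1.0, abs=1e-8)
        assert est["states"]["y"] == pytest.approx(0.0, abs=1e-8)
        assert est["outputs"]["o_x"] == pytest.approx(1.0, abs=1e-8)

    def test_small_distance(self, sphere_xy):
        res = min_distance(sphere_xy, DataPoint([1.01, 0.0], [0.1, 0.1]))
        assert res.d2 == pytest.approx(1e-4, abs=1e-10)

    def test_on_variety_distance_is_zero(self, sphere_full):
        pt = np.array([0.6, 0.8, 0.0])
        res = min_distance(sphere_full, DataPoint(pt.tolist(), [1.0] * 3))
        assert res.d2 <= 1e-10

    def test_weighted_objective(self, sphere_xy):
        """Heterogeneous variances tilt the argmin toward the precise output."""
        res = min_distance(sphere_xy, DataPoint([1.7, 0.0], [0.1, 0.001]))
        # with y' pinned tightly, the argmin stays near (1, 0, 0)
        assert res.argmins[0]["states"]["y"] == pytest.approx(0.0, abs=1e-6)
        assert res.sigma_ref2 == 1.0  # heterogeneous: weighted units

    def test_local_minimum_not_improved_by_descent(self, sphere_xy):
        """Projected-descent refinement cannot improve the returned argmin."""
        data = DataPoint([1.3, 0.45], [0.1, 0.1])
        res = min_distance(sphere_xy, data)
        x = np.array(
            [res.argmins[0]["states"][v] for v in ("x", "y", "z")], dtype=float
        )
        y = np.array([1.3, 0.45])
        best = res.d2_weighted

        def obj(v):
            return ((v[0] - y[0]) ** 2 + (v[1] - y[1]) ** 2) / 0.1

        for step in [1e-3, 1e-4]:
            for _ in range(50):
                grad = np.array([2 * (x[0] - y[0]) / 0.1, 2 * (x[1] - y[1]) / 0.1, 0.0])
                cand = x - step * grad
                cand = cand / np.linalg.norm(cand)  # project back to the sphere
                if obj(cand) < obj(x):
                    x = cand
        assert obj(x) >= best - 1e-6


class TestIntersectVarieties:
    def test_two_real_points(self, sphere_xy):
        res = intersect_varieties(sphere_xy, DataPoint([0.0, 0.0], [0.1, 0.1]))
        assert res.kind == "zero_dimensional"
        assert set_distance(res.real_points, [(0, 0, 1), (0, 0, -1)]) < 1e-8

    def test_positive_dimensional_circle(self, sphere_xy):
        res = intersect_varieties(sphere_xy, DataPoint([0.0, None], [0.1, 0.1]))
        assert res.kind == "positive_dimensional"
        assert res.dimension == 1
        assert len(res.witness_points) > 0

    def test_complex_only_intersection(self, sphere_xy):
        res = intersect_varieties(sphere_xy, DataPoint([1.7, 0.0], [0.1, 0.1]))
        assert res.kind == "zero_dimensional"
        assert res.real_points == []
        assert res.complex_count == 2


class TestNumericalDimension:
    @pytest.mark.parametrize(
        "exprs,vars_,dim",
        [
            (["x**2 + y**2 + z**2 - 1"], ["x", "y", "z"], 2),
            (["x - 1", "y - 2"], ["x", "y"], 0),
            (["x + 2*y - z - 3"], ["x", "y", "z"], 2),
        ],
    )
    def test_known_dimensions(self, exprs, vars_, dim):
        s = PolySystem.from_strings(exprs, vars_)
        assert numerical_dimension(s) == dim


class TestEDDegree:
    def test_sphere_fully_observed(self, sphere_full):
        assert ed_degree(sphere_full, trials=2) == 2

    def test_generic_ellipsoid(self, generic_ellipsoid):
        assert ed_degree(generic_ellipsoid, trials=2) == 6

    def test_sphere_partially_observed(self, sphere_xy):
        assert ed_degree(sphere_xy, trials=2) == 4

    def test_matches_lagrange_oracle_on_ellipsoid(self, generic_ellipsoid):
        """Symbolic Lagrange elimination agrees with the homotopy count."""
        a, b, c = 1.3, 0.8, 1.9
        f = (
            f"{b**2 * c**2}*x**2 + {a**2 * c**2}*y**2 + {a**2 * b**2}*z**2"
            f" - {a**2 * b**2 * c**2}"
        )
        count = lagrange_critical_count(f, ["x", "y", "z"], [0.31, -0.77, 0.52])
        assert count == ed_degree(generic_ellipsoid, trials=2)

    def test_seed_stability(self, sphere_full):
        degs = {
            ed_degree(sphere_full, trials=1, config=TrackConfig(seed=s))
            for s in range(3)
        }
        assert degs == {2}


class TestParameterTransport:
    def test_transport_matches_fresh_solves(self, sphere_xy):
        """Critical solutions moved by parameter homotopy = fresh solves."""
        template = DataPoint([1.0, 1.0], [1.0, 1.0])
        cfg = TrackConfig(seed=0)
        cs, y_gen, sols = critical_family_solve(sphere_xy, template, cfg)
        rng = np.random.default_rng(11)
        for _ in range(3):
            y = rng.normal(size=2) * 1.5
            data = DataPoint(y.tolist(), [1.0, 1.0])
            moved = critical_transport(cs, y_gen, sols, data, cfg)
            fresh_cs = build_critical_system(sphere_xy, data, seed=cfg.seed)
            fresh = total_degree_solve(fresh_cs.system, cfg)
            d_moved, _ = min_from_solutions(cs, moved, data, cfg)
            d_fresh = min_distance(sphere_xy, data, cfg).d2_weighted
            assert d_moved == pytest.approx(d_fresh, rel=1e-6, abs=1e-9)
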