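import itertools

import numpy as np
import pytest

from varfit.polysys import PolySystem, ShapeError, bezout_number
from varfit.tracker import (
    SolutionSet,
    StartPointError,
    TrackConfig,
    classify_real,
    parameter_homotopy,
    total_degree_solve,
    track_path,
)

from _oracles import set_distance, solve_symbolic


def _sorted_real(points):
    return sorted(tuple(np.round(np.real(p), 6)) for p in points)


class TestTrackPath:
    def test_path_continuity_picks_the_connected_root(self):
        start = PolySystem.from_strings(["x**2 - 1"], ["x"])
        target = PolySystem.from_strings(["x**2 - 4"], ["x"])
        r_plus = track_path(start, target, [1.0])
        r_minus = track_path(start, target, [-1.0])
        assert r_plus.status == "converged"
        assert r_plus.endpoint[0] == pytest.approx(2.0, abs=1e-8)
        assert r_minus.endpoint[0] == pytest.approx(-2.0, abs=1e-8)

    def test_double_root_detected_as_singular(self):
        start = PolySystem.from_strings(["x**2 - 1"], ["x"])
        target = PolySystem.from_strings(["x**2"], ["x"])
        r = track_path(start, target, [1.0])
        assert abs(r.endpoint[0]) < 1e-4
        assert r.status in ("singular", "converged")
        if r.status == "converged":
            assert r.condition > 1e6

    def test_bad_start_point_rejected(self):
        start = PolySystem.from_strings(["x**2 - 1"], ["x"])
        target = PolySystem.from_strings(["x**2 - 4"], ["x"])
        with pytest.raises(StartPointError):
            track_path(start, target, [0.5])


class TestTotalDegreeSolve:
    def test_two_by_two_product_system(self):
        s = PolySystem.from_strings(["x**2 - 1", "y**2 - 4"], ["x", "y"])
        sols = total_degree_solve(s)
        assert _sorted_real(sols.points) == [
            (-1.0, -2.0),
            (-1.0, 2.0),
            (1.0, -2.0),
            (1.0, 2.0),
        ]
        assert all(sols.is_real)

    def test_circle_line_intersection(self):
        s = PolySystem.from_strings(["x**2 + y**2 - 5", "x - y - 1"], ["x", "y"])
        sols = total_degree_solve(s)
        assert _sorted_real(sols.points) == [(-1.0, -2.0), (2.0, 1.0)]

    def test_sphere_slice_count_matches_bezout(self):
        s = PolySystem.from_strings(
            ["x**2 + y**2 + z**2 - 1", "x - 0.3", "y - 0.2"], ["x", "y", "z"]
        )
        sols = total_degree_solve(s)
        assert len(sols) == bezout_number(s) == 2
        assert all(sols.is_real)
        z = np.sqrt(1 - 0.09 - 0.04)
        assert sorted(np.real(p[2]) for p in sols.points) == pytest.approx([-z, z])

    def test_non_square_rejected(self):
        with pytest.raises(ShapeError):
            total_degree_solve(
                PolySystem.from_strings(["x**2 + y**2 - 1"], ["x", "y"])
            )

    def test_residual_contract(self):
        s = PolySystem.from_strings(
            ["x**3 - 2*x*y + 1", "y**2 - x - 1"], ["x", "y"]
        )
        sols = total_degree_solve(s)
        from varfit.polysys import evaluate

        for p in sols.points:
            assert np.abs(evaluate(s, p)).max() < 1e-8

    def test_gamma_invariance(self):
        """Different seeds (hence gammas) give the same solution set."""
        s = PolySystem.from_strings(
            ["x**2*y - x + 1", "x*y**2 + y - 2"], ["x", "y"]
        )
        a = total_degree_solve(s, TrackConfig(seed=0))
        b = total_degree_solve(s, TrackConfig(seed=123))
        assert set_distance(a.points, b.points) < 1e-6

    def test_path_accounting_small_suite(self):
        """converged + diverged + failed = Bézout number on random systems."""
        rng = np.random.default_rng(42)
        for _ in range(10):
            nv = int(rng.integers(1, 3))
            names = ["x", "y"][:nv]
            polys = []
            for _ in range(nv):
                p = {}
                for e in itertools.product(range(3), repeat=nv):
                    if sum(e) <= 2:
                        p[e] = complex(int(rng.integers(-3, 4)))
                polys.append(p)
            try:
                s = PolySystem(names, polys)
                nb = bezout_number(s)
            except Exception:
                continue
            if nb == 0:
                continue
            sols = total_degree_solve(s)
            assert sols.n_converged_paths + sols.n_diverged + sols.n_failed == nb

    def test_matches_symbolic_oracle(self):
        exprs = ["x**2 + y**2 - 5", "x*y - 2"]
        s = PolySystem.from_strings(exprs, ["x", "y"])
        sols = total_degree_solve(s)
        oracle = solve_symbolic(exprs, ["x", "y"])
        assert len(sols) == len(oracle)
        assert set_distance(sols.points, oracle) < 1e-6


class TestParameterHomotopy:
    def test_square_root_family(self):
        fam = PolySystem.from_strings(["x**2 - p"], ["x", "p"])
        q0 = [1 + 0.37j]
        roots = np.sqrt(complex(q0[0]))
        starts = [[roots], [-roots]]
        sols = parameter_homotopy(fam, ["p"], q0, starts, [4.0])
        assert _sorted_real(sols.points) == [(-2.0,), (2.0,)]

    def test_collapse_to_double_root(self):
        fam = PolySystem.from_strings(["x**2 - p"], ["x", "p"])
        q0 = [1 + 0.37j]
        r = np.sqrt(complex(q0[0]))
        sols = parameter_homotopy(fam, ["p"], q0, [[r], [-r]], [0.0])
        # both paths collapse onto x = 0: one clustered/singular endpoint
        assert len(sols.points) <= 1
        if sols.points:
            assert abs(sols.points[0][0]) < 1e-3
            assert sols.is_singular[0] or sols.multiplicities[0] == 2

    def test_bad_generic_solution_rejected(self):
        fam = PolySystem.from_strings(["x**2 - p"], ["x", "p"])
        with pytest.raises(StartPointError):
            parameter_homotopy(fam, ["p"], [1.0], [[5.0]], [4.0])


class TestClassifyReal:
    def test_filters_and_zeroes_imaginary_parts(self):
        sols = SolutionSet(
            points=[np.array([1 + 1e-12j]), np.array([1j])],
            multiplicities=[1, 1],
            is_real=[True, False],
            is_singular=[False, False],
            residuals=[0.0, 0.0],
            n_paths=2,
            n_diverged=0,
            n_failed=0,
        )
        real = classify_real(sols, 1e-6)
        assert len(real) == 1
        assert real.points[0].imag.max() == 0.0

    def test_empty_set(self):
        empty = SolutionSet([], [], [], [], [], 0, 0, 0)
        assert len(classify_real(empty, 1e-6)) == 0

    def test_conjugate_pairing_of_discarded_points(self):
        """Non-real solutions of real systems occur in conjugate pairs."""
        rng = np.random.default_rng(3)
        for _ in range(5):
            c = [int(rng.integers(-3, 4)) for _ in range(3)]
            s = PolySystem.from_strings(
                [
                    f"x**2 + ({c[0]})*y + ({c[1]})",
                    f"y**2 + ({c[2]})*x - 1",
                ],
                ["x", "y"],
            )
            sols = total_degree_solve(s)
            nonreal = [p for p, r in zip(sols.points, sols.is_real) if not r]
            for p in nonreal:
                conj_present = any(
                    np.abs(np.conj(p) - q).max() < 1e-6 * (1 + np.abs(q).max())
                    for q in nonreal
                )
                assert conj_present
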