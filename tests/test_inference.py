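import numpy as np
import pytest
from scipy import stats

from varfit.polysys import DataPoint, ModelSpec, PolySystem
from varfit.inference import (
    chi2_threshold,
    estimate,
    joint_distance,
    select,
    validate,
)
from varfit.synthdata import ellipsoid_model
from varfit.tracker import TrackConfig

from _oracles import grid_min_distance


class TestChi2Threshold:
    def test_against_numerical_cdf_inversion(self):
        """Independent oracle: bisect the chi-squared CDF computed by
        direct numerical integration of the density."""
        import math

        from scipy.integrate import quad

        def cdf2(x, m=2):
            v, _ = quad(lambda t: t ** (m / 2 - 1) * math.exp(-t / 2), 0, x)
            return v / (2 ** (m / 2) * math.gamma(m / 2))

        lo, hi = 0.0, 50.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if cdf2(mid) < 0.9:
                lo = mid
            else:
                hi = mid
        assert chi2_threshold(2, 0.1, 1.0) == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_printed_value_with_sigma2(self):
        assert chi2_threshold(2, 0.1, 0.1) == pytest.approx(0.4605, abs=5e-5)

    def test_monotonicity(self):
        assert chi2_threshold(2, 0.05) > chi2_threshold(2, 0.1)
        assert chi2_threshold(3, 0.1) > chi2_threshold(2, 0.1)

    def test_alpha_to_one_limit(self):
        assert chi2_threshold(2, 1 - 1e-12) < 1e-9

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.3])
    def test_domain_errors(self, alpha):
        with pytest.raises(ValueError):
            chi2_threshold(2, alpha)


class TestValidate:
    def test_decision_matrix_on_worked_examples(self, fig2_cases):
        """The four observation scenarios give compatible / possibly /
        incompatible / compatible, exactly as the validation algorithm
        prescribes."""
        expected = {
            "fig2b": "compatible",
            "fig2c": "possibly",
            "fig2d": "incompatible",
            "fig2e": "compatible",
        }
        for name, want in expected.items():
            case = fig2_cases[name]
            r = validate(case.model, case.data, alpha=0.1)
            assert r.decision == want, name

    def test_exact_intersection_reports_points(self, fig2_cases):
        r = validate(fig2_cases["fig2b"].model, fig2_cases["fig2b"].data, 0.1)
        assert r.d2 == 0.0
        zs = sorted(e["states"]["z"] for e in r.estimates)
        assert zs == pytest.approx([-1.0, 1.0], abs=1e-8)

    def test_rejection_values(self, fig2_cases):
        r = validate(fig2_cases["fig2d"].model, fig2_cases["fig2d"].data, 0.1)
        assert r.d2 == pytest.approx(0.49, abs=1e-8)
        assert r.p_alpha == pytest.approx(0.4605, abs=5e-5)
        assert r.d2 > r.p_alpha

    def test_incompatible_iff_empty_and_large(self, fig2_cases):
        for name in ("fig2b", "fig2c", "fig2d", "fig2e"):
            case = fig2_cases[name]
            r = validate(case.model, case.data, alpha=0.1)
            inter_real = r.intersection is not None and bool(r.intersection.real_points)
            if r.decision == "incompatible":
                assert not inter_real and r.d2_weighted > stats.chi2.isf(0.1, r.dof)
            if inter_real:
                assert r.d2 == 0.0

    def test_output_permutation_invariance(self):
        """Reordering the declared outputs does not change d² or decision."""
        m1 = ellipsoid_model(outputs=("x", "y"))
        m2 = ellipsoid_model(outputs=("y", "x"))
        d1 = DataPoint([1.7, 0.0], [0.1, 0.1])
        d2 = DataPoint([0.0, 1.7], [0.1, 0.1])
        r1 = validate(m1, d1, 0.1)
        r2 = validate(m2, d2, 0.1)
        assert r1.d2 == pytest.approx(r2.d2, rel=1e-9)
        assert r1.decision == r2.decision

    def test_variance_rescaling_consistency(self):
        """σ² → cσ² rescales p_α by c, leaves plain d² fixed, and the
        weighted statistic/decision pair transforms consistently."""
        m = ellipsoid_model()
        r1 = validate(m, DataPoint([1.7, 0.0], [0.1, 0.1]), 0.1)
        r2 = validate(m, DataPoint([1.7, 0.0], [0.5, 0.5]), 0.1)
        assert r1.d2 == pytest.approx(r2.d2, rel=1e-9)  # plain units
        assert r2.p_alpha == pytest.approx(5 * r1.p_alpha, rel=1e-9)
        assert r1.d2_weighted == pytest.approx(5 * r2.d2_weighted, rel=1e-9)
        # with the larger error bars the same misfit becomes acceptable
        assert r1.decision == "incompatible" and r2.decision == "compatible"


class TestLikelihoodLink:
    def test_argmin_maximizes_gaussian_loglikelihood(self, sphere_xy):
        """The returned argmin beats every other critical point in exact
        Gaussian log-likelihood, not just in d²."""
        from varfit.geometry import build_critical_system, _real_critical_candidates
        from varfit.tracker import total_degree_solve

        data = DataPoint([1.42, 0.37], [0.1, 0.1])
        cfg = TrackConfig()
        cs = build_critical_system(sphere_xy, data, seed=0)
        sols = total_degree_solve(cs.system, cfg)
        cands, _ = _real_critical_candidates(cs, sols, cfg)
        assert len(cands) >= 2
        y = np.array([1.42, 0.37])

        def loglik(point):
            z = np.real(point[3:5])
            return float(
                np.sum(stats.norm.logpdf(y, loc=z, scale=np.sqrt(0.1)))
            )

        r = estimate(sphere_xy, data)
        zhat = np.array([r.estimates[0]["outputs"]["o_x"], r.estimates[0]["outputs"]["o_y"]])
        best = float(np.sum(stats.norm.logpdf(y, loc=zhat, scale=np.sqrt(0.1))))
        for p, _ in cands:
            assert best >= loglik(p) - 1e-9


class TestSelect:
    def test_ordering_by_distance(self):
        """Of two compatible spheres, the one nearer the data is chosen."""
        near = ellipsoid_model()  # unit sphere
        far = ellipsoid_model(known={"a": 0.2, "b": 0.2, "c": 0.2})
        data = DataPoint([1.01, 0.0], [0.1, 0.1])
        rep = select({"near": near, "far": far}, data, alpha=0.1)
        assert rep.selected == "near"
        assert rep.ranking[0] == "near"

    def test_indeterminate_when_both_intersect(self):
        m1 = ellipsoid_model()
        m2 = ellipsoid_model(outputs=("x", "y"), known={"a": 2.0, "b": 1.0, "c": 1.0})
        # x' = 0 only: both model varieties meet the data variety in curves
        data = DataPoint([0.0, None], [0.1, 0.1])
        rep = select({"s": m1, "e": m2}, data, alpha=0.1)
        assert rep.indeterminate
        assert rep.selected is None
        assert "measuring more variables" in rep.message

    def test_all_rejected(self):
        m1 = ellipsoid_model()
        m2 = ellipsoid_model(known={"a": 0.5, "b": 0.5, "c": 0.5})
        data = DataPoint([3.0, 0.0], [0.01, 0.01])
        rep = select({"m1": m1, "m2": m2}, data, alpha=0.1)
        assert rep.selected is None and not rep.indeterminate
        assert "no model" in rep.message


class TestEstimate:
    def test_exact_fit_recovers_axis_length(self):
        """Data on the variety forces â = 2 through the intersection."""
        m = ellipsoid_model(
            known={"b": 1.0, "c": 1.0}, outputs=("x", "y", "z")
        )
        data = DataPoint([2.0, 0.0, 0.0], [0.1, 0.1, 0.1])
        r = estimate(m, data, nonneg=True)
        assert r.d2 == 0.0
        a_hats = [e["params"]["a"] for e in r.estimates]
        assert any(a == pytest.approx(2.0, abs=1e-6) for a in a_hats)
        assert all(a >= 0 for a in a_hats)

    def test_non_identifiable_flagged(self):
        m = ellipsoid_model(known={"b": 1.0, "c": 1.0}, outputs=("x", "y"))
        # (x, y) data inside the disc: a is free along an intersection curve
        r = estimate(m, DataPoint([0.5, 0.1], [0.1, 0.1]))
        assert r.decision == "possibly"
        assert r.diagnostics.get("non_identifiable")


class TestJointDistance:
    def test_two_copies_decouple(self, sphere_xy):
        """Parameter-free model: the joint d² is the sum of the singles."""
        dp = DataPoint([1.7, 0.0], [0.1, 0.1])
        r = joint_distance(sphere_xy, [dp, dp])
        assert r.d2 == pytest.approx(0.98, abs=1e-6)
        assert r.dof == 4

    def test_on_variety_points_give_zero(self):
        fvars = ("R", "x")
        f = PolySystem.from_strings(["x**2 - R"], fvars)
        g = PolySystem.from_strings(["x"], fvars)
        model = ModelSpec(("R",), ("x",), ("o",), f, g, {"R": 2.25})
        dp = DataPoint([1.5], [0.1])  # x = √R exactly on the variety
        r = joint_distance(model, [dp, dp, dp])
        assert r.d2 <= 1e-10

    def test_shared_parameter_matches_grid_oracle(self):
        """Joint estimation of a shared parameter vs a dense 1-D grid."""
        fvars = ("R", "x")
        f = PolySystem.from_strings(["x**2 - R"], fvars)
        g = PolySystem.from_strings(["x"], fvars)
        model = ModelSpec(("R",), ("x",), ("o",), f, g, {})
        y1, y2 = 1.21, 0.84
        d1 = DataPoint([y1], [1.0])
        d2 = DataPoint([y2], [1.0])
        r = joint_distance(model, [d1, d2])
        R_hat = r.estimates[0]["params"]["R"]

        def obj(R):
            if R < 0:
                return np.inf
            s = np.sqrt(R)
            return min((y1 - s) ** 2, (y1 + s) ** 2) + min(
                (y2 - s) ** 2, (y2 + s) ** 2
            )

        R_grid, val = grid_min_distance(obj, np.linspace(0.0, 4.0, 400001))
        assert R_hat == pytest.approx(R_grid, abs=1e-3)
        assert r.d2 == pytest.approx(val, abs=1e-6)

    def test_needs_two_points(self, sphere_xy):
        with pytest.raises(ValueError):
            joint_distance(sphere_xy, [DataPoint([1.0, 0.0], [0.1, 0.1])])
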