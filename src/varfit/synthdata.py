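"""Synthetic fixtures and data simulation.

Every stage of the pipeline is testable offline: this module exposes the
worked ellipsoid example (four observation scenarios with their expected
validation outcomes), a set of small mass-action networks, steady-state
simulation by stiff ODE integration with a terminal Newton polish, and
Gaussian observation noise.  Parameter and initial-condition draws follow
the lognormal(0, 1) convention common for rate constants.

The bundled reaction networks are synthetic study systems built for this
package: they reproduce the *shape* of published case studies (a two-state
conversion with conservation; a trio of interaction circuits that differ in
one coupling reaction; a three-species within-host viral-dynamics model
with an unknown clearance rate) at sizes where every critical system is
solvable by a dense total-degree homotopy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from ._batcheval import BatchEvaluator
from .crn import ReactionNetwork, network_to_model, parse_network
from .polysys import DataPoint, ModelSpec, PolySystem, bind_known

__all__ = [
    "SyntheticCase",
    "simulate_steady_state",
    "simulate_network_steady_state",
    "draw_parameters",
    "make_observation",
    "builtin_examples",
    "ellipsoid_model",
    "two_species_network",
    "interaction_trio",
    "viral_model_network",
]


class ConvergenceError(RuntimeError):
    """ODE integration did not settle onto a steady state."""


@dataclass
class SyntheticCase:
    name: str
    model: ModelSpec
    data: DataPoint
    expected: dict = field(default_factory=dict)
    true_params: dict = field(default_factory=dict)
    steady_state: np.ndarray | None = None
    clean_outputs: np.ndarray | None = None
    seed: int | None = None


# ---------------------------------------------------------------------------
# fixture models
# ---------------------------------------------------------------------------

def ellipsoid_model(
    known: Mapping[str, float] | None = None,
    outputs: Sequence[str] = ("x", "y"),
) -> ModelSpec:
    """Axis-aligned ellipsoid x²/a² + y²/b² + z²/c² = 1, denominators cleared.

    With a = b = c = 1 (the default ``known``) the variety is the unit
    sphere; ``outputs`` selects which coordinates are measurable.
    """
    params = ("a", "b", "c")
    states = ("x", "y", "z")
    fvars = params + states
    f = PolySystem.from_strings(
        ["b**2*c**2*x**2 + a**2*c**2*y**2 + a**2*b**2*z**2 - a**2*b**2*c**2"], fvars
    )
    g = PolySystem.from_strings(list(outputs), fvars)
    out_names = tuple(f"o_{o}" for o in outputs)
    if known is None:
        known = {"a": 1.0, "b": 1.0, "c": 1.0}
    return ModelSpec(params, states, out_names, f, g, dict(known))


TWO_SPECIES_TEXT = "A <-> B, k1, k2\n"


def two_species_network() -> ReactionNetwork:
    """Reversible isomerisation A ⇌ B with conserved total A + B."""
    return parse_network(TWO_SPECIES_TEXT)


_TRIO_TEXTS = {
    "annihilation": (
        "0 -> P1, k1\nP1 -> 0, d1\n0 -> P2, k2\nP2 -> 0, d2\nP1 + P2 -> 0, gma\n"
    ),
    "p2_degrades_p1": (
        "0 -> P1, k1\nP1 -> 0, d1\n0 -> P2, k2\nP2 -> 0, d2\nP1 + P2 -> P2, gma\n"
    ),
    "p1_degrades_p2": (
        "0 -> P1, k1\nP1 -> 0, d1\n0 -> P2, k2\nP2 -> 0, d2\nP1 + P2 -> P1, gma\n"
    ),
}

TRIO_BASAL_RATES = {"k1": 2.0, "d1": 1.0, "k2": 3.0, "d2": 1.0}
TRIO_TRUE_GAMMA = 1.0


def interaction_trio(measured: Sequence[str] = ("P1", "P2")) -> dict[str, ModelSpec]:
    """Three candidate circuits differing only in the coupling reaction.

    All share basal synthesis/degradation of proteins P1 and P2 (rates k1,
    d1, k2, d2, treated as measured and bound); they differ in how the
    proteins interact: mutual annihilation, P2-catalysed removal of P1, or
    P1-catalysed removal of P2 (rate ``gma``, unknown).  Data are simulated
    from the second circuit.
    """
    out = {}
    for name, text in _TRIO_TEXTS.items():
        net = parse_network(text)
        out[name] = network_to_model(net, measured, known=dict(TRIO_BASAL_RATES))
    return out


VIRAL_TEXT = (
    "0 -> T, s\n"
    "T -> 0, d1\n"
    "T + V -> I + V, k\n"
    "I -> 0, d2\n"
    "I -> I + V, p\n"
    "V -> 0, dV\n"
)

VIRAL_TRUE_PARAMS = {"s": 10.0, "d1": 0.1, "k": 0.1, "d2": 0.5, "p": 5.0, "dV": 3.0}


def viral_model_network() -> ReactionNetwork:
    """Within-host viral dynamics: target cells T, infected cells I, virus V.

    Infection converts T to I at rate k·T·V, infected cells produce free
    virus at rate p, and virus is cleared at rate dV — the clearance rate
    is the canonical single unknown to recover from steady-state data
    (true value 3 in the bundled parameterisation).
    """
    return parse_network(VIRAL_TEXT)


def viral_model(unknown: Sequence[str] = ("dV",)) -> ModelSpec:
    net = viral_model_network()
    known = {k: v for k, v in VIRAL_TRUE_PARAMS.items() if k not in unknown}
    return network_to_model(net, measured=("T", "I", "V"), known=known)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def simulate_network_steady_state(
    network: ReactionNetwork,
    rates: Mapping[str, float],
    x0: Sequence[float],
    horizon: float = 1e6,
    tol: float = 1e-8,
) -> np.ndarray:
    """Integrate the mass-action ODEs to steady state, then Newton-polish.

    Uses a stiff integrator (BDF) until the right-hand side is below
    ``tol``; the returned state exactly zeroes the steady-state polynomials
    (to tolerance) and lies on the stoichiometric compatibility class of
    ``x0``.  Refuses to return silently if the run does not converge.
    """
    from .crn import conservation_laws, steady_state_system

    full = steady_state_system(network)
    from .polysys import substitute

    rhs_sys = substitute(full, dict(rates))
    if tuple(rhs_sys.variables) != tuple(network.species):
        raise ValueError("rates must bind every rate symbol")
    ev = BatchEvaluator(rhs_sys)
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative")

    def rhs(t, x):
        return np.real(ev.values(x.astype(complex)[None, :])[0])

    def jac(t, x):
        return np.real(ev.jacobians(x.astype(complex)[None, :])[0])

    t_end, x = 0.0, x0.copy()
    span = 100.0
    while t_end < horizon:
        sol = solve_ivp(
            rhs, (0.0, span), x, method="BDF", jac=jac, rtol=1e-10, atol=1e-12
        )
        x = sol.y[:, -1]
        t_end += span
        span = min(span * 10.0, horizon - t_end) if horizon > t_end else span
        if np.abs(rhs(0.0, x)).max() < max(tol, 1e-10):
            break
    # Newton polish on the full-rank square system (pivot rows + conservation)
    laws = conservation_laws(network)
    import sympy as sp

    S = sp.Matrix(network.stoichiometric_matrix())
    pivot_rows = list(S.T.rref()[1])
    idx = {s: i for i, s in enumerate(network.species)}
    for _ in range(50):
        F = np.real(ev.values(x.astype(complex)[None, :])[0])[pivot_rows]
        C = np.array(
            [sum(c * x[idx[s]] for s, c in coeffs.items()) - sum(c * x0[idx[s]] for s, c in coeffs.items())
             for coeffs, _ in laws]
        )
        r = np.concatenate([F, C])
        if np.abs(r).max() < 1e-12:
            break
        J_f = np.real(ev.jacobians(x.astype(complex)[None, :])[0])[pivot_rows]
        J_c = np.zeros((len(laws), len(x)))
        for jrow, (coeffs, _) in enumerate(laws):
            for s, c in coeffs.items():
                J_c[jrow, idx[s]] = c
        J = np.vstack([J_f, J_c])
        x = x - np.linalg.solve(J, r)
    resid = np.abs(rhs(0.0, x)).max()
    if resid > tol:
        raise ConvergenceError(
            f"steady state not reached: residual {resid:.2e} after t={t_end:g}"
        )
    return x


def simulate_steady_state(
    model: ModelSpec,
    params: Mapping[str, float],
    x0: Sequence[float],
    horizon: float = 1e6,
    tol: float = 1e-8,
) -> np.ndarray:
    """Steady state of ``dx/dt = f(a, x)`` for a model whose f is the ODE RHS.

    Requires one f-polynomial per state (CRN-derived reduced models carry
    conservation rows instead — simulate those from their network).
    """
    bound = bind_known(model)
    from .polysys import substitute

    rhs_sys = substitute(bound.f, dict(params))
    if tuple(rhs_sys.variables) != tuple(bound.states):
        raise ValueError("params must bind every free parameter")
    if rhs_sys.n_polys != len(bound.states):
        raise ValueError(
            "f is not a square ODE right-hand side; simulate from the "
            "reaction network instead"
        )
    ev = BatchEvaluator(rhs_sys)
    x = np.asarray(x0, dtype=float)
    if np.any(x < 0):
        raise ValueError("initial state must be nonnegative")

    def rhs(t, xx):
        return np.real(ev.values(xx.astype(complex)[None, :])[0])

    sol = solve_ivp(rhs, (0.0, horizon), x, method="BDF", rtol=1e-10, atol=1e-12)
    x = sol.y[:, -1]
    for _ in range(50):
        F = np.real(ev.values(x.astype(complex)[None, :])[0])
        if np.abs(F).max() < 1e-13:
            break
        J = np.real(ev.jacobians(x.astype(complex)[None, :])[0])
        try:
            x = x - np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            break
    resid = np.abs(rhs(0.0, x)).max()
    if resid > tol:
        raise ConvergenceError(f"steady state not reached: residual {resid:.2e}")
    return x


# ---------------------------------------------------------------------------
# randomness
# ---------------------------------------------------------------------------

def outputs_from_state(
    network: ReactionNetwork, x: Sequence[float], measured: Sequence[str]
) -> np.ndarray:
    """Reorder a state vector (species order) into clean outputs (measured order)."""
    idx = {s: i for i, s in enumerate(network.species)}
    return np.array([x[idx[s]] for s in measured], dtype=float)


def draw_parameters(count: int, seed: int = 0) -> np.ndarray:
    """i.i.d. lognormal(μ=0, σ=1) rate-constant draws."""
    if count < 1:
        raise ValueError("count must be at least 1")
    return np.random.default_rng(seed).lognormal(mean=0.0, sigma=1.0, size=count)


def make_observation(
    clean: Sequence[float], sigma: float | Sequence[float], seed: int = 0
) -> DataPoint:
    """Corrupt clean outputs with Gaussian noise of standard deviation σ.

    ``sigma`` may be a scalar or per-output; variances σ² are recorded in
    the returned :class:`DataPoint`.  σ = 0 returns the clean outputs (with
    a tiny positive variance floor so the data point stays well-formed).
    """
    clean = np.asarray(clean, dtype=float)
    sig = np.broadcast_to(np.asarray(sigma, dtype=float), clean.shape).copy()
    if np.any(sig < 0):
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    noise = np.where(sig > 0, rng.normal(size=clean.shape) * sig, 0.0)
    var = np.where(sig > 0, sig**2, 1e-12)
    return DataPoint((clean + noise).tolist(), var.tolist())


# ---------------------------------------------------------------------------
# built-in worked examples
# ---------------------------------------------------------------------------

FIG_SIGMA2 = 0.1  # common error variance of the ellipsoid scenarios


def builtin_examples(sigma2: float = FIG_SIGMA2) -> dict[str, SyntheticCase]:
    """Named worked examples with their expected validation outcomes.

    The four ellipsoid scenarios observe (x, y) of the unit sphere at
    α = 0.1 with common error variance σ² = 0.1:

    - ``fig2b`` — y = (0, 0): compatible, two real intersection points (0, 0, ±1)
    - ``fig2c`` — only x' = 0 observed: a positive-dimensional intersection,
      decision "possibly"
    - ``fig2d`` — y = (1.7, 0): d² = 0.49 > p_α = 0.4605, rejected
    - ``fig2e`` — y = (1.01, 0): compatible

    plus small reaction-network cases used by the recovery experiments.
    """
    sphere = ellipsoid_model()
    cases = {
        "fig2b": SyntheticCase(
            "fig2b",
            sphere,
            DataPoint([0.0, 0.0], [sigma2, sigma2]),
            expected={
                "decision": "compatible",
                "d2": 0.0,
                "n_real_intersection": 2,
                "intersection_points": [(0.0, 0.0, 1.0), (0.0, 0.0, -1.0)],
            },
        ),
        "fig2c": SyntheticCase(
            "fig2c",
            sphere,
            DataPoint([0.0, None], [sigma2, sigma2]),
            expected={"decision": "possibly", "intersection_dimension": 1},
        ),
        "fig2d": SyntheticCase(
            "fig2d",
            sphere,
            DataPoint([1.7, 0.0], [sigma2, sigma2]),
            expected={
                "decision": "incompatible",
                "d2": 0.49,
                "p_alpha": 0.4605,
                "nearest_model_point": (1.0, 0.0, 0.0),
                "nearest_data_point": (1.7, 0.0, 0.0),
            },
        ),
        "fig2e": SyntheticCase(
            "fig2e",
            sphere,
            DataPoint([1.01, 0.0], [sigma2, sigma2]),
            expected={"decision": "compatible", "d2": 1e-4},
        ),
    }

    # two-species conversion at its exact steady state (σ = 0)
    net = two_species_network()
    rates = {"k1": 1.0, "k2": 2.0}
    x0 = np.array([2.0, 1.0])
    xss = simulate_network_steady_state(net, rates, x0)
    model = network_to_model(net, measured=("A", "B"), known={**rates, "T1": float(x0.sum())})
    cases["two_species_exact"] = SyntheticCase(
        "two_species_exact",
        model,
        DataPoint(xss.tolist(), [0.01, 0.01]),
        expected={"decision": "compatible", "d2": 0.0},
        true_params=rates,
        steady_state=xss,
        clean_outputs=xss,
    )
    return cases
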