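"""Probability-one polynomial homotopy continuation.

Finds all isolated complex solutions of square polynomial systems by
deforming a solved start system into the target along ``H(x, t) =
(1 - t)·γ·S(x) + t·T(x)`` and tracking every start root from ``t = 0`` to
``t = 1`` with an adaptive RK4 predictor / Newton corrector.  The random
complex unit ``γ`` (the "gamma trick") keeps paths off the discriminant
with probability one over the seed.

All paths of a solve advance in lockstep: the predictor/corrector linear
algebra is batched across paths with per-path adaptive step sizes, which is
what makes pure-NumPy tracking fast enough for critical systems with
hundreds of start paths.

Parameter homotopies reuse the solutions of one generic member of a family
to solve the same family at many other parameter values, tracking only as
many paths as there are generic solutions (for a critical system, the
Euclidean distance degree).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._batcheval import BatchEvaluator
from .polysys import PolySystem, ShapeError

__all__ = [
    "TrackConfig",
    "PathResult",
    "SolutionSet",
    "track_path",
    "total_degree_solve",
    "parameter_homotopy",
    "classify_real",
]

# path status codes
CONVERGED = "converged"
DIVERGED = "diverged_to_infinity"
FAILED = "failed"
SINGULAR = "singular"

_ACTIVE, _DONE_OK, _DONE_SING, _DONE_DIV, _DONE_FAIL = 0, 1, 2, 3, 4
_STATUS_NAMES = {
    _DONE_OK: CONVERGED,
    _DONE_SING: SINGULAR,
    _DONE_DIV: DIVERGED,
    _DONE_FAIL: FAILED,
}


class SolverFailure(RuntimeError):
    """Every tracked path failed; diagnostics attached."""


class StartPointError(ValueError):
    """Supplied start point is not a root of the start system."""


@dataclass
class TrackConfig:
    """Tunable knobs of the path tracker.

    Defaults follow common practice for double-precision tracking; the
    underlying theory does not prescribe them.  ``gamma`` defaults to a
    random unit complex number drawn from ``seed``.
    """

    initial_step: float = 0.05
    min_step: float = 1e-12
    max_step: float = 0.1
    corrector_tol: float = 1e-10
    max_corrector_iters: int = 3
    max_steps: int = 20_000
    max_consecutive_failures: int = 10
    divergence_cutoff: float = 1e8
    dedup_tol: float = 1e-6
    real_tol: float = 1e-6
    seed: int = 0
    gamma: complex | None = None

    def __post_init__(self) -> None:
        for name in (
            "initial_step",
            "min_step",
            "max_step",
            "corrector_tol",
            "dedup_tol",
            "real_tol",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.gamma is not None:
            g = complex(self.gamma)
            if abs(abs(g) - 1.0) > 1e-9:
                raise ValueError("gamma must lie on the complex unit circle")
            self.gamma = g

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def resolve_gamma(self, rng: np.random.Generator | None = None) -> complex:
        if self.gamma is not None:
            return self.gamma
        rng = rng or self.rng()
        theta = rng.uniform(0.05, 2 * np.pi - 0.05)
        return complex(np.cos(theta), np.sin(theta))


@dataclass
class PathResult:
    endpoint: np.ndarray
    status: str
    residual: float
    condition: float
    steps: int


@dataclass
class SolutionSet:
    """Deduplicated endpoints of a homotopy run.

    ``multiplicities[i]`` is the size of the endpoint cluster that collapsed
    onto ``points[i]``; clusters of size > 1 (or near-singular Jacobians)
    signal non-reduced or non-isolated solutions.
    """

    points: list[np.ndarray]
    multiplicities: list[int]
    is_real: list[bool]
    is_singular: list[bool]
    residuals: list[float]
    n_paths: int
    n_diverged: int
    n_failed: int
    path_results: list[PathResult] = field(default_factory=list, repr=False)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def n_converged_paths(self) -> int:
        return sum(self.multiplicities)

    def real_points(self, tol: float = 1e-6) -> list[np.ndarray]:
        return [np.real(p) for p, r in zip(self.points, self.is_real) if r]

    def nonsingular_count(self) -> int:
        return sum(
            1
            for m, s in zip(self.multiplicities, self.is_singular)
            if m == 1 and not s
        )


# ---------------------------------------------------------------------------
# homotopies
# ---------------------------------------------------------------------------

class _LinearHomotopy:
    """H(x, t) = (1 - t)·γ·S(x) + t·T(x)."""

    def __init__(self, start: PolySystem, target: PolySystem, gamma: complex):
        if start.variables != target.variables or start.n_polys != target.n_polys:
            raise ShapeError("start and target systems must share shape and variables")
        self.n = start.n_vars
        self.start = BatchEvaluator(start)
        self.target = BatchEvaluator(target)
        self.gamma = gamma

    def eval(self, X: np.ndarray, t: np.ndarray):
        vs, js = self.start.values_and_jacobians(X)
        vt, jt = self.target.values_and_jacobians(X)
        w = (self.gamma * (1.0 - t))[:, None]
        H = w * vs + t[:, None] * vt
        J = w[:, :, None] * js + t[:, None, None] * jt
        Ht = vt - self.gamma * vs
        return H, J, Ht

    def target_values_and_jacobians(self, X: np.ndarray):
        return self.target.values_and_jacobians(X)


class _TotalDegreeHomotopy:
    """H(x, t) = (1 - t)·γ·(x_i^{d_i} - 1) + t·T(x).

    The start system is diagonal, so its values and Jacobian are formed
    directly from per-variable powers — no second monomial table, and the
    Jacobian combination touches only the diagonal.
    """

    def __init__(self, target: PolySystem, gamma: complex):
        if not target.is_square():
            raise ShapeError("total-degree homotopy needs a square target")
        self.n = target.n_vars
        self.target = BatchEvaluator(target)
        self.gamma = gamma
        self.degs = np.array([max(d, 1) for d in target.degrees], dtype=np.int64)
        self._diag = np.arange(self.n)

    def _start_parts(self, X: np.ndarray):
        powm1 = X ** (self.degs - 1)[None, :]
        vs = X * powm1 - 1.0
        dvs = self.degs[None, :] * powm1
        return vs, dvs

    def eval(self, X: np.ndarray, t: np.ndarray):
        vt, jt = self.target.values_and_jacobians(X)
        vs, dvs = self._start_parts(X)
        w = (self.gamma * (1.0 - t))[:, None]
        H = w * vs + t[:, None] * vt
        J = jt * t[:, None, None]
        J[:, self._diag, self._diag] += w * dvs
        Ht = vt - self.gamma * vs
        return H, J, Ht

    def target_values_and_jacobians(self, X: np.ndarray):
        return self.target.values_and_jacobians(X)


class _ParameterHomotopy:
    """H(x, t) = F(x, (1 - t)·q0 + t·q1) for a parametrized family F."""

    def __init__(
        self,
        family: PolySystem,
        param_names: Sequence[str],
        q0: np.ndarray,
        q1: np.ndarray,
    ):
        pset = set(param_names)
        var_names = [v for v in family.variables if v not in pset]
        order = list(var_names) + list(param_names)
        from .polysys import poly_embed

        reordered = PolySystem(
            tuple(order),
            [poly_embed(p, family.variables, order) for p in family.polynomials],
        )
        self.n = len(var_names)
        if family.n_polys != self.n:
            raise ShapeError(
                f"family has {family.n_polys} polynomials in {self.n} tracked variables"
            )
        self.n_params = len(param_names)
        self.ev = BatchEvaluator(reordered)
        self.q0 = np.asarray(q0, dtype=complex)
        self.q1 = np.asarray(q1, dtype=complex)
        self.dq = self.q1 - self.q0

    def _augment(self, X: np.ndarray, t: np.ndarray) -> np.ndarray:
        q = (1.0 - t)[:, None] * self.q0 + t[:, None] * self.q1
        return np.concatenate([X, q], axis=1)

    def eval(self, X: np.ndarray, t: np.ndarray):
        V, Jfull = self.ev.values_and_jacobians(self._augment(X, t))
        J = Jfull[:, :, : self.n]
        Ht = Jfull[:, :, self.n :] @ self.dq
        return V, J, Ht

    def target_values_and_jacobians(self, X: np.ndarray):
        t1 = np.ones(X.shape[0])
        V, Jfull = self.ev.values_and_jacobians(self._augment(X, t1))
        return V, Jfull[:, :, : self.n]

    def values_at(self, X: np.ndarray, q: np.ndarray):
        A = np.concatenate([X, np.broadcast_to(q, (X.shape[0], self.n_params))], axis=1)
        return self.ev.values(A)


# ---------------------------------------------------------------------------
# batched linear solves
# ---------------------------------------------------------------------------

def _bsolve(A: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Solve A[i] x[i] = b[i] for a batch; flag paths whose solve failed."""
    P = A.shape[0]
    ok = np.ones(P, dtype=bool)
    try:
        x = np.linalg.solve(A, b[..., None])[..., 0]
    except np.linalg.LinAlgError:
        x = np.zeros_like(b)
        for i in range(P):
            try:
                x[i] = np.linalg.solve(A[i], b[i])
            except np.linalg.LinAlgError:
                ok[i] = False
    bad = ~np.isfinite(x).all(axis=1)
    ok &= ~bad
    x[bad] = 0.0
    return x, ok


def _maxabs(X: np.ndarray) -> np.ndarray:
    return np.abs(X).max(axis=1) if X.size else np.zeros(X.shape[0])


# ---------------------------------------------------------------------------
# the tracker
# ---------------------------------------------------------------------------

def _newton(hom, X, t, tol, max_iters):
    """Batched Newton correction of X at fixed t; returns (X, ok, residual)."""
    P = X.shape[0]
    ok = np.zeros(P, dtype=bool)
    res = np.full(P, np.inf)
    X = X.copy()
    live = np.ones(P, dtype=bool)
    for _ in range(max_iters):
        idx = np.nonzero(live)[0]
        if idx.size == 0:
            break
        H, J, _ = hom.eval(X[idx], t[idx])
        dx, solved = _bsolve(J, -H)
        Xn = X[idx] + dx
        step = _maxabs(dx)
        scale = 1.0 + _maxabs(Xn)
        X[idx[solved]] = Xn[solved]
        conv = solved & (step < tol * scale)
        ok[idx[conv]] = True
        live[idx[conv]] = False
        live[idx[~solved]] = False
        res[idx] = _maxabs(H)
    return X, ok, res


def _rk4(hom, X, t, h):
    """One batched RK4 predictor step along the Davidenko equation."""
    ok = np.ones(X.shape[0], dtype=bool)

    def v(Xc, tc):
        nonlocal ok
        H, J, Ht = hom.eval(Xc, tc)
        dx, solved = _bsolve(J, -Ht)
        ok &= solved
        return dx

    h2 = (h / 2.0)[:, None]
    hh = h[:, None]
    k1 = v(X, t)
    k2 = v(X + h2 * k1, t + h / 2.0)
    k3 = v(X + h2 * k2, t + h / 2.0)
    k4 = v(X + hh * k3, t + h)
    Xp = X + hh / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    ok &= np.isfinite(Xp).all(axis=1)
    return Xp, ok


def _run_paths(hom, X0: np.ndarray, config: TrackConfig) -> list[PathResult]:
    P, N = X0.shape
    X = X0.astype(complex).copy()
    t = np.zeros(P)
    h = np.full(P, min(config.initial_step, config.max_step))
    state = np.full(P, _ACTIVE, dtype=np.int8)
    steps = np.zeros(P, dtype=np.int64)
    streak = np.zeros(P, dtype=np.int64)
    fails = np.zeros(P, dtype=np.int64)
    residual = np.full(P, np.inf)
    condition = np.full(P, np.nan)
    eps = 1e-14

    guard = 0
    while True:
        act = np.nonzero(state == _ACTIVE)[0]
        if act.size == 0:
            break
        guard += 1
        if guard > config.max_steps:
            state[act] = _DONE_FAIL
            break

        ha = np.minimum(h[act], 1.0 - t[act])
        Xp, ok_pred = _rk4(hom, X[act], t[act], ha)
        tn = t[act] + ha
        Xc, ok_corr, _ = _newton(
            hom, Xp, tn, config.corrector_tol, config.max_corrector_iters
        )
        ok = ok_pred & ok_corr
        diverged = _maxabs(Xc) > config.divergence_cutoff
        accept = ok & ~diverged

        # diverged paths stop immediately
        div_idx = act[ok & diverged]
        state[div_idx] = _DONE_DIV
        X[div_idx] = Xc[ok & diverged]

        # accepted steps
        acc_idx = act[accept]
        X[acc_idx] = Xc[accept]
        t[acc_idx] = tn[accept]
        streak[acc_idx] += 1
        fails[acc_idx] = 0
        grow = acc_idx[streak[acc_idx] >= 5]
        h[grow] = np.minimum(h[grow] * 2.0, config.max_step)
        streak[grow] = 0

        # rejected steps: halve, abandon at the step floor or after too many
        # consecutive halvings (the endpoint polish rescues near-misses)
        rej_idx = act[~ok]
        h[rej_idx] *= 0.5
        streak[rej_idx] = 0
        fails[rej_idx] += 1
        dead = rej_idx[
            (h[rej_idx] < config.min_step)
            | (fails[rej_idx] >= config.max_consecutive_failures)
        ]
        state[dead] = _DONE_FAIL

        steps[act] += 1
        too_long = act[steps[act] >= config.max_steps]
        state[too_long] = _DONE_FAIL

        # paths that reached t = 1
        arrived = np.nonzero((state == _ACTIVE) & (t >= 1.0 - eps))[0]
        state[arrived] = _DONE_OK

    # --- endpoint classification -------------------------------------
    results: list[PathResult] = []
    done_ok = np.nonzero(state == _DONE_OK)[0]
    # near-miss paths: failed close to t=1 may sit on singular endpoints
    near = np.nonzero((state == _DONE_FAIL) & (t > 0.99) & (_maxabs(X) < 1e6))[0]
    polish_idx = np.concatenate([done_ok, near])
    if polish_idx.size:
        Xbefore = X[polish_idx].copy()
        Xp, okp, _ = _newton(hom, X[polish_idx], np.ones(polish_idx.size), 1e-13, 12)
        V, J = hom.target_values_and_jacobians(Xp)
        res = _maxabs(V)
        moved = _maxabs(Xp - Xbefore) / (1.0 + _maxabs(Xbefore))
        svals = [np.linalg.svd(J[i], compute_uv=False) for i in range(len(polish_idx))]
        conds = np.array([s[0] / max(s[-1], 1e-300) for s in svals])
        near_sing = np.array([s[-1] < 1e-8 * (1.0 + s[0]) for s in svals])
        rescued = np.isin(polish_idx, near)
        for j, i in enumerate(polish_idx):
            if rescued[j] and moved[j] > 0.05:
                # the polish jumped to an unrelated solution: the path itself
                # never arrived, keep it failed (or diverged if it blew up)
                state[i] = _DONE_DIV if _maxabs(Xbefore[j : j + 1])[0] > 1e4 else _DONE_FAIL
                continue
            X[i] = Xp[j]
            residual[i] = res[j]
            condition[i] = conds[j]
            if res[j] < 1e-8:
                state[i] = _DONE_SING if near_sing[j] else _DONE_OK
            elif res[j] < 1e-6:
                state[i] = _DONE_SING
            elif _maxabs(Xp[j : j + 1])[0] > 1e4:
                state[i] = _DONE_DIV
            else:
                state[i] = _DONE_FAIL
    # remaining failures with huge coordinates were really divergences
    big = np.nonzero((state == _DONE_FAIL) & (_maxabs(X) > 1e4))[0]
    state[big] = _DONE_DIV

    for i in range(P):
        results.append(
            PathResult(
                endpoint=X[i].copy(),
                status=_STATUS_NAMES[int(state[i])],
                residual=float(residual[i]),
                condition=float(condition[i]) if np.isfinite(condition[i]) else np.inf,
                steps=int(steps[i]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# deduplication and the public operations
# ---------------------------------------------------------------------------

def _cluster(points: list[np.ndarray], tol: float) -> tuple[list[np.ndarray], list[list[int]]]:
    reps: list[np.ndarray] = []
    members: list[list[int]] = []
    for i, p in enumerate(points):
        placed = False
        for k, r in enumerate(reps):
            if np.abs(p - r).max() <= tol * (1.0 + np.abs(r).max()):
                members[k].append(i)
                placed = True
                break
        if not placed:
            reps.append(p)
            members.append([i])
    return reps, members


def _is_real_point(p: np.ndarray, tol: float) -> bool:
    return bool(np.all(np.abs(p.imag) < tol * (1.0 + np.abs(p.real))))


def _collect(results: list[PathResult], config: TrackConfig) -> SolutionSet:
    good = [r for r in results if r.status in (CONVERGED, SINGULAR)]
    n_div = sum(r.status == DIVERGED for r in results)
    n_fail = sum(r.status == FAILED for r in results)
    reps, members = _cluster([r.endpoint for r in good], config.dedup_tol)
    points, mult, singular, residuals = [], [], [], []
    for r, mem in zip(reps, members):
        points.append(r)
        mult.append(len(mem))
        singular.append(
            len(mem) > 1 or any(good[i].status == SINGULAR for i in mem)
        )
        residuals.append(min(good[i].residual for i in mem))
    is_real = [_is_real_point(p, config.real_tol) for p in points]
    return SolutionSet(
        points=points,
        multiplicities=mult,
        is_real=is_real,
        is_singular=singular,
        residuals=residuals,
        n_paths=len(results),
        n_diverged=n_div,
        n_failed=n_fail,
        path_results=results,
    )


def track_path(
    start: PolySystem,
    target: PolySystem,
    start_point: Sequence[complex],
    config: TrackConfig | None = None,
) -> PathResult:
    """Track a single root of *start* to the corresponding root of *target*."""
    config = config or TrackConfig()
    x0 = np.asarray(start_point, dtype=complex)
    from .polysys import evaluate

    r0 = np.abs(evaluate(start, x0)).max()
    if r0 > 1e-8 * (1.0 + np.abs(x0).max()):
        raise StartPointError(f"start point residual {r0:.2e} too large")
    gamma = config.resolve_gamma()
    hom = _LinearHomotopy(start, target, gamma)
    return _run_paths(hom, x0[None, :], config)[0]


def _total_degree_start(system: PolySystem) -> tuple[PolySystem, np.ndarray]:
    degs = [max(d, 1) for d in system.degrees]
    n = system.n_vars
    polys = []
    for i, d in enumerate(degs):
        e = [0] * n
        e[i] = d
        polys.append({tuple(e): 1.0 + 0.0j, tuple([0] * n): -1.0 + 0.0j})
    start = PolySystem(system.variables, polys)
    roots_1d = [np.exp(2j * np.pi * np.arange(d) / d) for d in degs]
    pts = np.array(list(itertools.product(*roots_1d)), dtype=complex)
    return start, pts


def total_degree_solve(system: PolySystem, config: TrackConfig | None = None) -> SolutionSet:
    """All isolated complex solutions of a square system, with probability one.

    Builds the total-degree start system ``x_i^{d_i} - 1`` with its known
    roots-of-unity solutions and tracks every one of the ``∏ d_i`` paths.
    """
    if not system.is_square():
        raise ShapeError(
            f"total-degree solve needs a square system, got {system.n_polys} "
            f"equations in {system.n_vars} unknowns"
        )
    config = config or TrackConfig()
    _, pts = _total_degree_start(system)
    gamma = config.resolve_gamma()
    hom = _TotalDegreeHomotopy(system, gamma)
    results = _run_paths(hom, pts, config)
    sols = _collect(results, config)
    if len(sols) == 0 and sols.n_failed == sols.n_paths and sols.n_paths > 0:
        # probability-one contract: retry once with a fresh gamma
        warnings.warn("all paths failed; retrying with a fresh gamma")
        retry = TrackConfig(**{**config.__dict__, "seed": config.seed + 104729, "gamma": None})
        hom = _TotalDegreeHomotopy(system, retry.resolve_gamma())
        results = _run_paths(hom, pts, retry)
        sols = _collect(results, retry)
        if len(sols) == 0 and sols.n_failed == sols.n_paths:
            raise SolverFailure(
                f"all {sols.n_paths} paths failed on both gamma draws"
            )
    return sols


def parameter_homotopy(
    family: PolySystem,
    param_names: Sequence[str],
    generic_params: Sequence[complex],
    generic_solutions: SolutionSet | Sequence[Sequence[complex]],
    target_params: Sequence[complex],
    config: TrackConfig | None = None,
) -> SolutionSet:
    """Transport the solutions at one generic parameter value to another.

    Tracks one path per generic solution along the straight segment in
    parameter space; for a critical-system family parametrized by the data
    point this is the ED-degree-many-paths shortcut.
    """
    config = config or TrackConfig()
    q0 = np.asarray(generic_params, dtype=complex)
    q1 = np.asarray(target_params, dtype=complex)
    hom = _ParameterHomotopy(family, param_names, q0, q1)
    if isinstance(generic_solutions, SolutionSet):
        pts = np.array(generic_solutions.points, dtype=complex)
    else:
        pts = np.asarray(generic_solutions, dtype=complex)
    if pts.ndim != 2 or pts.shape[1] != hom.n:
        raise ShapeError("generic solutions have wrong dimension for the family")
    res0 = _maxabs(hom.values_at(pts, q0))
    scale = 1.0 + _maxabs(pts)
    if np.any(res0 > 1e-6 * scale):
        raise StartPointError(
            f"generic solutions do not solve the family at the generic parameters "
            f"(max residual {res0.max():.2e})"
        )
    results = _run_paths(hom, pts, config)
    return _collect(results, config)


def classify_real(solutions: SolutionSet, tol: float | None = None) -> SolutionSet:
    """Real subset of a solution set, with imaginary parts zeroed exactly."""
    if tol is not None and not tol > 0:
        raise ValueError("tolerance must be positive")
    tol = tol if tol is not None else 1e-6
    keep = [i for i, p in enumerate(solutions.points) if _is_real_point(p, tol)]
    return SolutionSet(
        points=[np.real(solutions.points[i]) + 0.0 for i in keep],
        multiplicities=[solutions.multiplicities[i] for i in keep],
        is_real=[True] * len(keep),
        is_singular=[solutions.is_singular[i] for i in keep],
        residuals=[solutions.residuals[i] for i in keep],
        n_paths=solutions.n_paths,
        n_diverged=solutions.n_diverged,
        n_failed=solutions.n_failed,
    )
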