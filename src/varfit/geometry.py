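"""Variety-level geometry: critical systems, intersections, dimensions.

The model variety lives in the joint (a, x, z) space and is cut out by the
steady-state equations ``f(a, x) = 0`` together with ``z - g(x) = 0``; the
data variety fixes the observed outputs to the measured values ``y``.  This
module builds the Fritz John first-order optimality system for the weighted
squared distance between the two — with the multiplier vector λ treated
projectively via a random affine chart, so extrema with a vanishing
objective multiplier λ₀ are not lost — and solves it by homotopy
continuation.  All critical points of the distance are found at once, so
the global minimum d² is certified with probability one over the random
choices (gamma, chart, slices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._batcheval import BatchEvaluator
from .polysys import (
    DataPoint,
    ModelSpec,
    PolySystem,
    ShapeError,
    bind_known,
    constant,
    monomial,
    poly_add,
    poly_diff,
    poly_embed,
    poly_scale,
    substitute,
)
from .tracker import SolutionSet, TrackConfig, parameter_homotopy, total_degree_solve

__all__ = [
    "CriticalSystem",
    "IntersectionResult",
    "build_critical_system",
    "min_distance",
    "DistanceResult",
    "intersect_varieties",
    "numerical_dimension",
    "ed_degree",
    "critical_family_solve",
    "critical_transport",
    "min_from_solutions",
]


class CodimensionError(ValueError):
    """More constraints than free unknowns in the Fritz John construction."""


class EmptinessError(RuntimeError):
    """System has no complex solutions at any slicing codimension."""


def _unique_name(base: str, taken: set[str]) -> str:
    name = base
    while name in taken:
        name = "_" + name
    taken.add(name)
    return name


# ---------------------------------------------------------------------------
# Fritz John critical system
# ---------------------------------------------------------------------------

@dataclass
class CriticalSystem:
    """Square Fritz John system for the weighted distance to a data point.

    Unknowns are ordered (free params a, states x, outputs z, multipliers λ).
    ``family`` is the same system with the observed data values replaced by
    parameter symbols ``data_params``, ready for parameter homotopies over
    the data point.
    """

    system: PolySystem
    family: PolySystem
    data_params: tuple[str, ...]
    avars: tuple[str, ...]
    xvars: tuple[str, ...]
    zvars: tuple[str, ...]
    lamvars: tuple[str, ...]
    outputs: tuple[str, ...]
    weights: np.ndarray
    y: np.ndarray
    base_indices: list[int]
    chart: np.ndarray
    model: ModelSpec
    data: DataPoint | list[DataPoint]
    blocks: list[tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)

    @property
    def point_vars(self) -> tuple[str, ...]:
        """The non-multiplier unknowns (a, x, z)."""
        return self.avars + self.xvars + self.zvars

    def split_point(self, point: np.ndarray) -> dict:
        """Decode a solution vector into parameter/state/output estimates."""
        na, nx = len(self.avars), len(self.xvars)
        a = point[:na]
        x = point[na : na + nx]
        z = point[na + nx : na + nx + len(self.zvars)]
        lam = point[na + nx + len(self.zvars) :]
        out_names = self.outputs if len(self.outputs) == len(self.zvars) else self.zvars
        if len(set(out_names)) != len(self.zvars):  # joint fits repeat outputs
            out_names = self.zvars
        return {
            "params": dict(zip(self.avars, a)),
            "states": dict(zip(self.xvars, x)),
            "outputs": dict(zip(out_names, z)),
            "multipliers": lam,
        }

    def objective(self, point: np.ndarray, y: np.ndarray | None = None) -> float:
        """Weighted squared distance Σ wᵢ(zᵢ - yᵢ)² at a (real) solution."""
        na, nx = len(self.avars), len(self.xvars)
        z = np.real(point[na + nx : na + nx + len(self.zvars)])
        yy = self.y if y is None else np.asarray(y, dtype=float)
        return float(np.sum(self.weights * (z - yy) ** 2))


def build_critical_system(
    model: ModelSpec,
    data: DataPoint,
    constraints: Sequence[str] | None = None,
    seed: int = 0,
) -> CriticalSystem:
    """Assemble the square Fritz John system for ``model`` against ``data``.

    ``constraints`` names free parameters/states to pin to zero before the
    augmentation (the boundary subsystems of orthant-constrained fits).
    Unobserved outputs get weight zero; their ``z`` stays a constrained free
    variable so partial observation shares the code path of full
    observation.
    """
    return _build_critical(
        model, [data], constraints=constraints, seed=seed, joint=False
    )


def build_joint_critical_system(
    model: ModelSpec,
    data_points: Sequence[DataPoint],
    constraints: Sequence[str] | None = None,
    seed: int = 0,
) -> CriticalSystem:
    """Fritz John system for the *joint* distance over several data points.

    Parameters ``a`` are shared; states and outputs get one copy per data
    point; the objective is the sum of the per-point weighted distances.
    """
    return _build_critical(
        model, list(data_points), constraints=constraints, seed=seed, joint=True
    )


def _build_critical(
    model: ModelSpec,
    data_points: list[DataPoint],
    constraints: Sequence[str] | None,
    seed: int,
    joint: bool,
) -> CriticalSystem:
    bound = bind_known(model)
    if constraints:
        zero = {v: 0.0 for v in constraints}
        f = substitute(bound.f, {k: v for k, v in zero.items() if k in bound.f.variables})
        g = substitute(bound.g, {k: v for k, v in zero.items() if k in bound.g.variables})
        params = tuple(a for a in bound.params if a not in zero)
        states = tuple(x for x in bound.states if x not in zero)
        bound = ModelSpec(params, states, bound.outputs, f, g, {})

    J = len(data_points)
    m = bound.n_outputs
    for dp in data_points:
        if len(dp.values) != m:
            raise ShapeError("data point length does not match model outputs")

    avars = tuple(bound.params)
    taken = set(avars)
    xvars_j, zvars_j = [], []
    for j in range(J):
        sfx = "" if J == 1 else f"_{j + 1}"
        xvars_j.append(tuple(_unique_name(x + sfx, taken) for x in bound.states))
        zvars_j.append(
            tuple(_unique_name(f"z_{o}{sfx}", taken) for o in bound.outputs)
        )
    r = bound.f.n_polys
    n_con = J * (r + m)
    if r > len(avars) + len(bound.states):
        raise CodimensionError(
            f"{r}+{m} constraints exceed the {len(avars) + len(bound.states)}+{m} "
            "free unknowns; use the reduced formulation (drop dependent "
            "steady-state rows, e.g. via conservation laws) before building "
            "the critical system"
        )
    lamvars = tuple(_unique_name(f"lam{i}", taken) for i in range(n_con + 1))
    yvars: list[str] = []

    flat_x = tuple(v for xs in xvars_j for v in xs)
    flat_z = tuple(v for zs in zvars_j for v in zs)
    U = avars + flat_x + flat_z + lamvars

    weights_list, y_list = [], []
    F_polys: list[dict] = []
    obj_grad: dict[str, dict] = {}  # var name -> d(obj)/d var as PolyMap over U+yvars
    Uy: list[str] = list(U)  # extended universe with data symbols (built below)

    # first pass: collect y symbols for observed outputs
    y_syms: list[list[str | None]] = []
    taken_y = set(U)
    for j, dp in enumerate(data_points):
        row = []
        for i in range(m):
            if dp.values[i] is not None:
                sfx = "" if J == 1 else f"_{j + 1}"
                s = _unique_name(f"y_{bound.outputs[i]}{sfx}", taken_y)
                row.append(s)
                yvars.append(s)
            else:
                row.append(None)
        y_syms.append(row)
    Uy = list(U) + yvars

    # the multiplier vector is projective, so the objective may be scaled
    # freely inside the critical system: normalizing the largest weight to 1
    # keeps the coefficients well conditioned for small error variances
    w_all = [
        0.0 if dp.values[i] is None else 1.0 / dp.variances[i]
        for dp in data_points
        for i in range(m)
    ]
    w_scale = max(w_all) if any(w_all) else 1.0

    for j, dp in enumerate(data_points):
        fvars = bound.params + bound.states
        remap = dict(zip(bound.states, xvars_j[j]))
        local = [remap.get(v, v) for v in fvars]
        for p in bound.f.polynomials:
            F_polys.append(poly_embed(p, local, Uy))
        for i, gp in enumerate(bound.g.polynomials):
            zi = monomial(Uy, zvars_j[j][i])
            F_polys.append(poly_add(zi, poly_scale(poly_embed(gp, local, Uy), -1.0)))
        for i in range(m):
            w = 0.0 if dp.values[i] is None else 1.0 / dp.variances[i]
            weights_list.append(w)
            y_list.append(0.0 if dp.values[i] is None else dp.values[i])
            if w != 0.0:
                # d(obj)/dz_i = 2 (w/w_scale) (z_i - y_i)
                wn = w / w_scale
                term = poly_add(
                    monomial(Uy, zvars_j[j][i], 2.0 * wn),
                    monomial(Uy, y_syms[j][i], -2.0 * wn),
                )
                obj_grad[zvars_j[j][i]] = term

    # gradient equations: lam0 * d(obj)/dv + sum_k lam_{k+1} * dF_k/dv = 0
    pos = {v: i for i, v in enumerate(Uy)}
    grad_polys = []
    for v in avars + flat_x + flat_z:
        acc: dict = {}
        if v in obj_grad:
            acc = _poly_times_var(obj_grad[v], pos[lamvars[0]], len(Uy))
        for k, Fp in enumerate(F_polys):
            d = poly_diff(Fp, pos[v])
            if d:
                acc = poly_add(acc, _poly_times_var(d, pos[lamvars[k + 1]], len(Uy)))
        grad_polys.append(acc)

    rng = np.random.default_rng(seed + 2_000_003)
    theta = rng.uniform(0, 2 * np.pi, size=len(lamvars))
    chart = np.exp(1j * theta)
    chart_poly: dict = constant(Uy, -1.0)
    for c, lv in zip(chart, lamvars):
        chart_poly = poly_add(chart_poly, monomial(Uy, lv, c))

    all_polys = F_polys + grad_polys + [chart_poly]
    family = PolySystem(tuple(Uy), all_polys)
    y_values = {s: v for row, dp in zip(y_syms, data_points) for s, v in
                [(row[i], dp.values[i]) for i in range(m) if row[i] is not None]}
    system = substitute(family, y_values)
    if tuple(system.variables) != U:
        raise AssertionError("unexpected variable ordering after data substitution")

    return CriticalSystem(
        system=system,
        family=family,
        data_params=tuple(yvars),
        avars=avars,
        xvars=flat_x,
        zvars=flat_z,
        lamvars=lamvars,
        outputs=tuple(bound.outputs) * J,
        weights=np.array(weights_list),
        y=np.array(y_list),
        base_indices=list(range(len(F_polys))),
        chart=chart,
        model=bound,
        data=data_points[0] if not joint else list(data_points),
        blocks=[(xvars_j[j], zvars_j[j]) for j in range(J)],
    )


def _poly_times_var(p: dict, var_index: int, n: int) -> dict:
    out = {}
    for e, c in p.items():
        ne = list(e)
        ne[var_index] += 1
        out[tuple(ne)] = c
    return out


# ---------------------------------------------------------------------------
# intersection of the model and data varieties
# ---------------------------------------------------------------------------

@dataclass
class IntersectionResult:
    kind: str  # "empty" | "zero_dimensional" | "positive_dimensional"
    variables: tuple[str, ...]
    real_points: list[np.ndarray]
    complex_count: int
    dimension: int
    witness_points: list[np.ndarray] = field(default_factory=list)
    dim_model: int | None = None
    dim_data: int | None = None
    ambient_dim: int | None = None


def _intersection_system(model: ModelSpec, data: DataPoint) -> PolySystem:
    bound = bind_known(model)
    U = bound.params + bound.states
    polys = [poly_embed(p, U, U) for p in bound.f.polynomials]
    for i in bound_observed(bound, data):
        gp = poly_embed(bound.g.polynomials[i], U, U)
        polys.append(poly_add(gp, constant(U, -data.values[i])))
    return PolySystem(U, polys)


def bound_observed(bound: ModelSpec, data: DataPoint) -> list[int]:
    if len(data.values) != bound.n_outputs:
        raise ShapeError("data point length does not match model outputs")
    return data.observed


def _square_up(system: PolySystem, rng: np.random.Generator) -> PolySystem:
    """Replace an overdetermined system by #vars random complex combinations.

    Solutions of the original are solutions of the squared-up system;
    extraneous solutions are filtered afterwards by residual.
    """
    U, E = system.n_vars, system.n_polys
    A = rng.normal(size=(U, E)) + 1j * rng.normal(size=(U, E))
    polys = []
    for i in range(U):
        acc: dict = {}
        for j, p in enumerate(system.polynomials):
            acc = poly_add(acc, poly_scale(p, A[i, j]))
        polys.append(acc)
    return PolySystem(system.variables, polys)


def _random_slices(system: PolySystem, d: int, rng: np.random.Generator) -> PolySystem:
    """Append d generic affine hyperplanes with real coefficients."""
    U = system.variables
    polys = list(system.polynomials)
    for _ in range(d):
        coeffs = rng.normal(size=len(U))
        p: dict = constant(U, rng.normal())
        for v, c in zip(U, coeffs):
            p = poly_add(p, monomial(U, v, c))
        polys.append(p)
    return PolySystem(U, polys)


def _solve_possibly_overdetermined(
    system: PolySystem, config: TrackConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Solutions of a (possibly overdetermined) system, residual-filtered."""
    if system.n_polys == system.n_vars:
        square = system
    elif system.n_polys > system.n_vars:
        square = _square_up(system, rng)
    else:
        raise ShapeError("underdetermined system passed to zero-dimensional solve")
    sols = total_degree_solve(square, config)
    ev = BatchEvaluator(system)
    out = []
    for p in sols.points:
        res = np.abs(ev.values(p[None, :])).max()
        if res < 1e-6 * (1.0 + np.abs(p).max()):
            out.append(p)
    return out


def numerical_dimension(system: PolySystem, config: TrackConfig | None = None) -> int:
    """Dimension of the solution set by random-slice probing.

    Returns the largest ``d ≥ 0`` such that the system plus ``d`` generic
    affine hyperplanes still has a finite nonempty solution set; raises
    :class:`EmptinessError` when no slicing codimension yields solutions.
    """
    config = config or TrackConfig()
    rng = np.random.default_rng(config.seed + 7_919)
    U, E = system.n_vars, system.n_polys

    def probe(d: int) -> bool:
        sliced = _random_slices(system, d, rng)
        if sliced.n_polys < U:
            return False  # still underdetermined: infinite or empty, not finite
        try:
            pts = _solve_possibly_overdetermined(sliced, config, rng)
        except Exception:
            return False
        return len(pts) > 0

    d0 = max(U - E, 0)
    if probe(d0):
        d = d0
        while d + 1 <= U and probe(d + 1):
            d += 1
        return d
    d = d0 - 1
    while d >= 0:
        if probe(d):
            return d
        d -= 1
    raise EmptinessError("no complex solutions found at any slicing codimension")


def intersect_varieties(
    model: ModelSpec, data: DataPoint, config: TrackConfig | None = None
) -> IntersectionResult:
    """Intersection of the model variety with the data variety.

    Works in the (free parameter, state) chart: substituting the observed
    values into the outputs reduces the intersection to the system
    ``{f = 0, g_obs(x) - y_obs = 0}``.  Zero-dimensional intersections are
    solved outright; under-determined ones are probed with generic slices
    for their dimension and witness points.
    """
    config = config or TrackConfig()
    rng = np.random.default_rng(config.seed + 104_651)
    system = _intersection_system(model, data)
    U, E = system.n_vars, system.n_polys
    bound = bind_known(model)

    # dimension audit in the joint (a, x, z) ambient space
    n_free = len(bound.params) + bound.n_states
    m_obs = data.n_observed
    ambient = n_free + bound.n_outputs
    dim_data = ambient - m_obs

    def _result(kind, reals, count, dim, witness=()):
        return IntersectionResult(
            kind=kind,
            variables=system.variables,
            real_points=list(reals),
            complex_count=count,
            dimension=dim,
            witness_points=list(witness),
            dim_model=None,
            dim_data=dim_data,
            ambient_dim=ambient,
        )

    if E >= U:
        pts = _solve_possibly_overdetermined(system, config, rng)
        reals = [np.real(p) for p in pts if _real_vec(p, config.real_tol)]
        if not pts:
            return _result("empty", [], 0, -1)
        return _result("zero_dimensional", reals, len(pts), 0)

    # under-determined: probe dimension
    try:
        dim = numerical_dimension(system, config)
    except EmptinessError:
        return _result("empty", [], 0, -1)
    if dim == 0:
        sq = _square_up(system, rng) if E != U else system
        pts = _solve_possibly_overdetermined(system if E == U else sq, config, rng)
        reals = [np.real(p) for p in pts if _real_vec(p, config.real_tol)]
        return _result("zero_dimensional", reals, len(pts), 0)
    sliced = _random_slices(system, dim, rng)
    witness = _solve_possibly_overdetermined(sliced, config, rng)
    return _result("positive_dimensional", [], len(witness), dim, witness)


def _real_vec(p: np.ndarray, tol: float) -> bool:
    return bool(np.all(np.abs(p.imag) < tol * (1.0 + np.abs(p.real))))


# ---------------------------------------------------------------------------
# minimum distance
# ---------------------------------------------------------------------------

@dataclass
class DistanceResult:
    d2: float | None  # display scale (common σ² units when uniform)
    d2_weighted: float | None
    sigma_ref2: float
    argmins: list[dict]
    solutions: SolutionSet | None
    critical: CriticalSystem | None
    n_real_criticals: int
    possibly_degenerate: bool
    boundary_hit: bool = False
    warning: str | None = None
    best_complex: np.ndarray | None = None


def _real_critical_candidates(
    cs: CriticalSystem, sols: SolutionSet, config: TrackConfig
) -> tuple[list[tuple[np.ndarray, float]], bool]:
    """Real critical points with their weighted objective values.

    Reality is judged on the (a, x, z) block only: the multiplier vector is
    normalized by a complex chart and is generally non-real even at real
    critical points.  Also reports whether degenerate (clustered/singular)
    endpoints were seen among candidates.
    """
    npoint = len(cs.point_vars)
    base = PolySystem(
        cs.system.variables, [cs.system.polynomials[i] for i in cs.base_indices]
    )
    base_ev = BatchEvaluator(base)
    cands = []
    degenerate = False
    for p, sing, mult in zip(sols.points, sols.is_singular, sols.multiplicities):
        block = p[:npoint]
        if not _real_vec(block, config.real_tol):
            continue
        res = np.abs(base_ev.values(p[None, :])).max()
        if res > 1e-6 * (1.0 + np.abs(p).max()):
            continue
        if sing or mult > 1:
            degenerate = True
        q = p.copy()
        q[:npoint] = np.real(block)
        cands.append((q, cs.objective(q)))
    return cands, degenerate


def min_distance(
    model: ModelSpec,
    data: DataPoint,
    config: TrackConfig | None = None,
    nonneg: bool = False,
    boundary_cap: int = 2,
) -> DistanceResult:
    """Global minimum of the weighted squared distance model ↔ data.

    Solves the Fritz John critical system, filters to real critical points
    (and to the closed non-negative orthant in (a, x) when ``nonneg``), and
    returns the minimum with every attaining point.  With ``nonneg`` the
    boundary of the orthant is swept by re-solving with up to
    ``boundary_cap`` free variables pinned to zero.
    """
    config = config or TrackConfig()
    cs = build_critical_system(model, data, seed=config.seed)
    sols = total_degree_solve(cs.system, config)
    cands, degenerate = _real_critical_candidates(cs, sols, config)

    ntol = 1e-7
    boundary_hit = False
    if nonneg:
        na, nx = len(cs.avars), len(cs.xvars)
        cands = [
            (p, v)
            for (p, v) in cands
            if np.all(np.real(p[: na + nx]) >= -ntol)
        ]
        free_vars = list(cs.avars + cs.xvars)
        import itertools as _it

        for k in range(1, min(boundary_cap, len(free_vars)) + 1):
            for subset in _it.combinations(free_vars, k):
                try:
                    cs_b = build_critical_system(
                        model, data, constraints=subset, seed=config.seed
                    )
                    sols_b = total_degree_solve(cs_b.system, config)
                except Exception:
                    continue
                sub, deg_b = _real_critical_candidates(cs_b, sols_b, config)
                degenerate = degenerate or deg_b
                nab, nxb = len(cs_b.avars), len(cs_b.xvars)
                for p, v in sub:
                    if np.all(np.real(p[: nab + nxb]) >= -ntol):
                        full = _lift_boundary_point(cs, cs_b, p)
                        cands.append((full, v))
                        boundary_hit = True

    sigma_ref2 = data.common_variance() if isinstance(data, DataPoint) else None
    sigma_ref2 = sigma_ref2 if sigma_ref2 is not None else 1.0

    if not cands:
        best = None
        if len(sols):
            objs = [cs.objective(p) for p in sols.points]
            best = sols.points[int(np.argmin(objs))]
        return DistanceResult(
            d2=None,
            d2_weighted=None,
            sigma_ref2=sigma_ref2,
            argmins=[],
            solutions=sols,
            critical=cs,
            n_real_criticals=0,
            possibly_degenerate=degenerate,
            warning="no real critical point found",
            best_complex=best,
        )

    vals = np.array([v for _, v in cands])
    vmin = float(vals.min())
    att = [cands[i][0] for i in np.nonzero(vals <= vmin + 1e-8 * (1 + vmin))[0]]
    argmins = [_point_estimates(cs, p) for p in att]
    return DistanceResult(
        d2=vmin * sigma_ref2,
        d2_weighted=vmin,
        sigma_ref2=sigma_ref2,
        argmins=argmins,
        solutions=sols,
        critical=cs,
        n_real_criticals=len(cands),
        possibly_degenerate=degenerate,
        boundary_hit=boundary_hit,
    )


def _point_estimates(cs: CriticalSystem, p: np.ndarray) -> dict:
    d = cs.split_point(p)
    return {
        "params": {k: float(np.real(v)) for k, v in d["params"].items()},
        "states": {k: float(np.real(v)) for k, v in d["states"].items()},
        "outputs": {k: float(np.real(v)) for k, v in d["outputs"].items()},
    }


def _lift_boundary_point(
    cs: CriticalSystem, cs_b: CriticalSystem, p: np.ndarray
) -> np.ndarray:
    """Embed a boundary-subsystem solution into the full system's chart."""
    vals = dict(zip(cs_b.avars + cs_b.xvars + cs_b.zvars, p))
    out = np.zeros(len(cs.point_vars) + len(cs.lamvars), dtype=complex)
    for i, v in enumerate(cs.point_vars):
        out[i] = vals.get(v, 0.0)
    return out


# ---------------------------------------------------------------------------
# parameter homotopy over the data point
# ---------------------------------------------------------------------------

def critical_family_solve(
    model: ModelSpec,
    data_template: DataPoint,
    config: TrackConfig | None = None,
) -> tuple[CriticalSystem, np.ndarray, SolutionSet]:
    """Solve the critical system once at a generic complex data point.

    Returns the critical system (whose ``family`` carries the data values as
    parameter symbols), the generic data vector used, and the solution set
    — the reusable start data for :func:`critical_transport`, which tracks
    only ED-degree-many paths per new data point instead of a full
    total-degree solve.
    """
    config = config or TrackConfig()
    rng = np.random.default_rng(config.seed + 32_452_843)
    m = len(data_template.values)
    vals = [
        None if data_template.values[i] is None
        else complex(rng.normal(), rng.normal())
        for i in range(m)
    ]
    cs = build_critical_system(
        model, _complex_datapoint(vals, data_template), seed=config.seed
    )
    sols = total_degree_solve(cs.system, config)
    keep = [
        p
        for p, s, mu in zip(sols.points, sols.is_singular, sols.multiplicities)
        if not s and mu == 1
    ]
    y_gen = np.array([v for v in vals if v is not None], dtype=complex)
    kept = SolutionSet(
        points=keep,
        multiplicities=[1] * len(keep),
        is_real=[False] * len(keep),
        is_singular=[False] * len(keep),
        residuals=[0.0] * len(keep),
        n_paths=sols.n_paths,
        n_diverged=sols.n_diverged,
        n_failed=sols.n_failed,
    )
    return cs, y_gen, kept


def critical_transport(
    cs: CriticalSystem,
    y_generic: np.ndarray,
    generic_solutions: SolutionSet,
    data: DataPoint,
    config: TrackConfig | None = None,
) -> SolutionSet:
    """Track generic critical solutions to the critical system of ``data``."""
    y_target = np.array(
        [data.values[i] for i in range(len(data.values)) if data.values[i] is not None],
        dtype=complex,
    )
    return parameter_homotopy(
        cs.family, cs.data_params, y_generic, generic_solutions, y_target, config
    )


def min_from_solutions(
    cs: CriticalSystem,
    sols: SolutionSet,
    data: DataPoint,
    config: TrackConfig | None = None,
    nonneg: bool = False,
) -> tuple[float | None, list[dict]]:
    """Minimum weighted distance over an (e.g. transported) solution set."""
    config = config or TrackConfig()
    y = np.array(
        [0.0 if v is None else v for v in data.values], dtype=float
    )
    npoint = len(cs.point_vars)
    na, nx = len(cs.avars), len(cs.xvars)
    cands = []
    for p in sols.points:
        if not _real_vec(p[:npoint], config.real_tol):
            continue
        if nonneg and not np.all(np.real(p[: na + nx]) >= -1e-7):
            continue
        cands.append((p, cs.objective(p, y=y)))
    if not cands:
        return None, []
    vals = np.array([v for _, v in cands])
    vmin = float(vals.min())
    att = [cands[i][0] for i in np.nonzero(vals <= vmin + 1e-8 * (1 + vmin))[0]]
    return vmin, [_point_estimates(cs, p) for p in att]


# ---------------------------------------------------------------------------
# Euclidean distance degree
# ---------------------------------------------------------------------------

def ed_degree(
    model: ModelSpec,
    trials: int = 3,
    config: TrackConfig | None = None,
    data_template: DataPoint | None = None,
) -> int:
    """ED degree of the model variety for the given observation pattern.

    For each trial a generic *complex* data point is drawn and the Fritz
    John system solved; the count of isolated nonsingular solutions with a
    nonzero objective multiplier λ₀ is the number of critical points of the
    squared distance.  The maximum over trials is returned (path failures
    can only undercount); disagreement between trials triggers a warning.
    """
    if trials < 1:
        raise ValueError("trials must be at least 1")
    config = config or TrackConfig()
    bound = bind_known(model)
    m = bound.n_outputs
    if data_template is None:
        data_template = DataPoint([1.0] * m, [1.0] * m)
    rng = np.random.default_rng(config.seed + 15_485_863)
    counts = []
    for trial in range(trials):
        y = rng.normal(size=m) + 1j * rng.normal(size=m)
        dp_vals = [
            complex(y[i]) if data_template.values[i] is not None else None
            for i in range(m)
        ]
        cs = build_critical_system(
            model, _complex_datapoint(dp_vals, data_template),
            seed=config.seed + trial,
        )
        cfg = TrackConfig(**{**config.__dict__, "seed": config.seed + trial})
        sols = total_degree_solve(cs.system, cfg)
        counts.append(_count_ed_solutions(cs, sols))
    if len(set(counts)) > 1:
        warnings.warn(f"ED-degree trials disagree: {counts}; reporting the maximum")
    return max(counts)


class _ComplexDataPoint(DataPoint):
    """Internal: data point allowed to carry complex generic values."""

    def __post_init__(self):  # relax the real/positive checks
        self.values = [None if v is None else complex(v) for v in self.values]
        self.variances = [float(s) for s in self.variances]


def _complex_datapoint(values, template: DataPoint) -> DataPoint:
    return _ComplexDataPoint(values, list(template.variances))


def _count_ed_solutions(cs: CriticalSystem, sols: SolutionSet) -> int:
    nlam = len(cs.lamvars)
    npoint = len(cs.point_vars)
    count = 0
    for p, sing, mult in zip(sols.points, sols.is_singular, sols.multiplicities):
        if sing or mult > 1:
            continue
        lam = p[npoint:]
        lam0 = lam[0]
        if np.abs(lam0) <= 1e-6 * max(np.abs(lam).max(), 1e-300):
            continue
        count += 1
    return count
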