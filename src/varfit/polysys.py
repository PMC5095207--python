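"""Sparse multivariate polynomial systems with named variables.

A polynomial is stored as a map from exponent tuples (one entry per declared
variable) to complex coefficients; a :class:`PolySystem` is an ordered list of
such polynomials over a shared, ordered variable universe.  This sparse
representation suits mass-action steady-state systems, which are sparse in
both monomials and variables.

The module also defines the two domain containers used throughout the
package: :class:`ModelSpec` (steady-state equations ``f(a, x) = 0`` with
output polynomials ``z = g(x)``) and :class:`DataPoint` (noisy observed
outputs ``y`` with per-output error variances).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import sympy as sp

__all__ = [
    "PolySystem",
    "ModelSpec",
    "DataPoint",
    "evaluate",
    "jacobian",
    "bezout_number",
    "bind_known",
    "parse_polynomial",
    "poly_to_string",
]

Exponent = tuple[int, ...]
PolyMap = dict[Exponent, complex]

_ZERO_TOL = 0.0  # coefficients exactly equal to zero are dropped


class DimensionError(ValueError):
    """Point or system shape does not match the declared variables."""


class NamingError(KeyError):
    """A symbol name is not part of the declared variable universe."""


class ShapeError(ValueError):
    """Operation requires a square system (``#polynomials == #variables``)."""


# ---------------------------------------------------------------------------
# low-level polynomial arithmetic on exponent maps
# ---------------------------------------------------------------------------

def poly_add(p: PolyMap, q: PolyMap) -> PolyMap:
    out = dict(p)
    for e, c in q.items():
        nc = out.get(e, 0.0) + c
        if nc == 0:
            out.pop(e, None)
        else:
            out[e] = nc
    return out


def poly_scale(p: PolyMap, s: complex) -> PolyMap:
    if s == 0:
        return {}
    return {e: c * s for e, c in p.items()}


def poly_mul(p: PolyMap, q: PolyMap) -> PolyMap:
    out: PolyMap = {}
    for e1, c1 in p.items():
        for e2, c2 in q.items():
            e = tuple(a + b for a, b in zip(e1, e2))
            nc = out.get(e, 0.0) + c1 * c2
            if nc == 0:
                out.pop(e, None)
            else:
                out[e] = nc
    return out


def poly_diff(p: PolyMap, var_index: int) -> PolyMap:
    out: PolyMap = {}
    for e, c in p.items():
        k = e[var_index]
        if k == 0:
            continue
        ne = list(e)
        ne[var_index] = k - 1
        out[tuple(ne)] = c * k
    return out


def poly_degree(p: PolyMap) -> int:
    if not p:
        return 0
    return max(sum(e) for e in p)


def poly_embed(p: PolyMap, old_vars: Sequence[str], new_vars: Sequence[str]) -> PolyMap:
    """Re-index a polynomial from one variable universe into a superset."""
    idx = []
    pos = {v: i for i, v in enumerate(new_vars)}
    for v in old_vars:
        if v not in pos:
            raise NamingError(f"variable {v!r} missing from target universe")
        idx.append(pos[v])
    n = len(new_vars)
    out: PolyMap = {}
    for e, c in p.items():
        ne = [0] * n
        for j, k in enumerate(e):
            if k:
                ne[idx[j]] = k
        out[tuple(ne)] = out.get(tuple(ne), 0.0) + c
    return {e: c for e, c in out.items() if c != 0}


def monomial(new_vars: Sequence[str], name: str, coeff: complex = 1.0) -> PolyMap:
    """Single-variable monomial ``coeff * name`` in the given universe."""
    e = [0] * len(new_vars)
    try:
        e[list(new_vars).index(name)] = 1
    except ValueError as exc:
        raise NamingError(f"unknown variable {name!r}") from exc
    return {tuple(e): coeff}


def constant(new_vars: Sequence[str], value: complex) -> PolyMap:
    if value == 0:
        return {}
    return {tuple([0] * len(new_vars)): value}


# ---------------------------------------------------------------------------
# PolySystem
# ---------------------------------------------------------------------------

@dataclass
class PolySystem:
    """Ordered list of sparse polynomials over named variables."""

    variables: tuple[str, ...]
    polynomials: list[PolyMap]

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        cleaned = []
        nv = len(self.variables)
        for p in self.polynomials:
            for e in p:
                if len(e) != nv:
                    raise DimensionError(
                        f"exponent tuple {e} has length {len(e)}, expected {nv}"
                    )
            cleaned.append({tuple(e): complex(c) for e, c in p.items() if c != 0})
        self.polynomials = cleaned

    # -- basic queries ----------------------------------------------------
    @property
    def n_polys(self) -> int:
        return len(self.polynomials)

    @property
    def n_vars(self) -> int:
        return len(self.variables)

    @property
    def degrees(self) -> tuple[int, ...]:
        return tuple(poly_degree(p) for p in self.polynomials)

    def is_square(self) -> bool:
        return self.n_polys == self.n_vars

    # -- construction helpers --------------------------------------------
    @classmethod
    def from_strings(cls, exprs: Iterable[str], variables: Sequence[str]) -> "PolySystem":
        return cls(tuple(variables), [parse_polynomial(s, variables) for s in exprs])

    def to_strings(self) -> list[str]:
        return [poly_to_string(p, self.variables) for p in self.polynomials]

    def subsystem(self, indices: Sequence[int]) -> "PolySystem":
        return PolySystem(self.variables, [self.polynomials[i] for i in indices])

    def concat(self, other: "PolySystem") -> "PolySystem":
        if other.variables != self.variables:
            raise DimensionError("concatenated systems must share the variable universe")
        return PolySystem(self.variables, self.polynomials + other.polynomials)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PolySystem({self.n_polys} polys in {list(self.variables)})"


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def evaluate(system: PolySystem, point: Sequence[complex]) -> np.ndarray:
    """Evaluate every polynomial of *system* at *point*."""
    point = np.asarray(point, dtype=complex)
    if point.shape != (system.n_vars,):
        raise DimensionError(
            f"point has shape {point.shape}, expected ({system.n_vars},)"
        )
    out = np.zeros(system.n_polys, dtype=complex)
    for i, p in enumerate(system.polynomials):
        acc = 0.0 + 0.0j
        for e, c in p.items():
            term = c
            for x, k in zip(point, e):
                if k:
                    term = term * x**k
            acc += term
        out[i] = acc
    return out


def jacobian(system: PolySystem, wrt: Sequence[str] | None = None) -> list[list[PolyMap]]:
    """Matrix of partial derivatives ``∂p_i/∂v_j`` as polynomials.

    ``wrt`` defaults to all declared variables; a name outside the universe
    raises :class:`NamingError`.
    """
    if wrt is None:
        wrt = system.variables
    pos = {v: i for i, v in enumerate(system.variables)}
    cols = []
    for v in wrt:
        if v not in pos:
            raise NamingError(f"unknown variable {v!r}")
        cols.append(pos[v])
    return [[poly_diff(p, j) for j in cols] for p in system.polynomials]


def bezout_number(system: PolySystem) -> int:
    """Product of total degrees — the number of total-degree start paths."""
    if not system.is_square():
        raise ShapeError(
            f"Bézout number requires a square system, got {system.n_polys} "
            f"polynomials in {system.n_vars} variables"
        )
    n = 1
    for d in system.degrees:
        n *= max(d, 1)
    return n


def substitute(system: PolySystem, values: Mapping[str, complex]) -> PolySystem:
    """Substitute numeric values for a subset of variables.

    The returned system lives in the remaining free variables, in declared
    order.  Unknown names raise :class:`NamingError`.
    """
    for name in values:
        if name not in system.variables:
            raise NamingError(f"cannot bind undeclared symbol {name!r}")
    keep = [i for i, v in enumerate(system.variables) if v not in values]
    vals = [values.get(v, None) for v in system.variables]
    new_vars = tuple(system.variables[i] for i in keep)
    new_polys: list[PolyMap] = []
    for p in system.polynomials:
        out: PolyMap = {}
        for e, c in p.items():
            coef = c
            for j, k in enumerate(e):
                if vals[j] is not None and k:
                    coef *= vals[j] ** k
            ne = tuple(e[i] for i in keep)
            nc = out.get(ne, 0.0) + coef
            if nc == 0:
                out.pop(ne, None)
            else:
                out[ne] = nc
        new_polys.append(out)
    return PolySystem(new_vars, new_polys)


# ---------------------------------------------------------------------------
# parsing / printing (sympy-backed)
# ---------------------------------------------------------------------------

def parse_polynomial(text: str, variables: Sequence[str]) -> PolyMap:
    """Parse plain infix polynomial text (``k1*A*B - k2*C``) to a sparse map.

    Both ``**`` and ``^`` are accepted for powers.
    """
    syms = sp.symbols(list(variables))
    expr = sp.sympify(text.replace("^", "**"), locals=dict(zip(variables, syms)))
    extra = expr.free_symbols - set(syms)
    if extra:
        raise NamingError(
            f"undeclared symbol(s) {sorted(str(s) for s in extra)} in {text!r}"
        )
    poly = sp.Poly(expr, *syms) if syms else sp.Poly(expr, sp.Symbol("_dummy"))
    out: PolyMap = {}
    if not syms:
        c = complex(expr)
        return {(): c} if c != 0 else {}
    for e, c in poly.terms():
        out[tuple(int(k) for k in e)] = complex(c)
    return {e: c for e, c in out.items() if c != 0}


def poly_to_string(p: PolyMap, variables: Sequence[str]) -> str:
    if not p:
        return "0"
    parts = []
    for e, c in sorted(p.items(), key=lambda t: (-sum(t[0]), t[0])):
        factors = []
        if c.imag == 0:
            cre = c.real
            coef = str(int(cre)) if cre == int(cre) else repr(cre)
        else:
            coef = f"({c})"
        factors.append(coef)
        for v, k in zip(variables, e):
            if k == 1:
                factors.append(v)
            elif k > 1:
                factors.append(f"{v}**{k}")
        parts.append("*".join(factors))
    return " + ".join(parts).replace("+ -", "- ")


# ---------------------------------------------------------------------------
# ModelSpec / DataPoint
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Polynomial steady-state model ``f(a, x) = 0`` with outputs ``z = g(x)``.

    ``params`` are the rate-constant-like symbols ``a``, ``states`` the
    dynamic variables ``x``, ``outputs`` the names of the measurable
    quantities ``z`` (one polynomial of ``g`` each).  ``known`` binds a
    subset of params/states to fixed real values.
    """

    params: tuple[str, ...]
    states: tuple[str, ...]
    outputs: tuple[str, ...]
    f: PolySystem
    g: PolySystem
    known: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = tuple(self.params)
        self.states = tuple(self.states)
        self.outputs = tuple(self.outputs)
        if len(self.outputs) > len(self.states):
            raise ShapeError(
                f"m={len(self.outputs)} outputs exceed n={len(self.states)} states"
            )
        if self.g.n_polys != len(self.outputs):
            raise ShapeError("g must have one polynomial per declared output")
        universe = set(self.params) | set(self.states)
        for name in self.known:
            if name not in universe:
                raise NamingError(f"known value for undeclared symbol {name!r}")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_outputs(self) -> int:
        return len(self.outputs)

    @property
    def free_params(self) -> tuple[str, ...]:
        return tuple(a for a in self.params if a not in self.known)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": list(self.params),
            "states": list(self.states),
            "outputs": list(self.outputs),
            "f": self.f.to_strings(),
            "g": self.g.to_strings(),
            "known": dict(self.known),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        params = tuple(d["params"])
        states = tuple(d["states"])
        fvars = params + states
        f = PolySystem.from_strings(d["f"], fvars)
        g = PolySystem.from_strings(d["g"], fvars)
        return cls(params, states, tuple(d["outputs"]), f, g, dict(d.get("known", {})))

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_json(cls, source) -> "ModelSpec":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                d = json.loads(text)
            else:
                with open(text) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


def bind_known(model: ModelSpec) -> ModelSpec:
    """Substitute the ``known`` values into ``f`` and ``g``.

    Returns a model whose systems involve only the remaining free symbols
    (free params followed by free states); an empty ``known`` map returns an
    equivalent model unchanged.
    """
    if not model.known:
        return model
    f = substitute(model.f, model.known)
    g = substitute(model.g, model.known)
    free_params = tuple(a for a in model.params if a not in model.known)
    free_states = tuple(x for x in model.states if x not in model.known)
    return ModelSpec(free_params, free_states, model.outputs, f, g, {})


@dataclass
class DataPoint:
    """Observed outputs ``y`` with known error variances ``σ²``.

    ``values[i] = None`` (or NaN) marks output *i* unobserved; variances must
    be strictly positive for observed entries and at least one entry must be
    observed.
    """

    values: list[float | None]
    variances: list[float]

    def __post_init__(self) -> None:
        vals = []
        for v in self.values:
            if v is None or (isinstance(v, float) and np.isnan(v)):
                vals.append(None)
            else:
                vals.append(float(v))
        self.values = vals
        self.variances = [float(s) for s in self.variances]
        if len(self.variances) != len(self.values):
            raise DimensionError("values and variances must have equal length")
        if not any(v is not None for v in vals):
            raise ValueError("a data point needs at least one observed output")
        for v, s2 in zip(vals, self.variances):
            if v is not None and not s2 > 0:
                raise ValueError("observed outputs need strictly positive variance")

    @property
    def observed(self) -> list[int]:
        return [i for i, v in enumerate(self.values) if v is not None]

    @property
    def n_observed(self) -> int:
        return len(self.observed)

    def common_variance(self) -> float | None:
        """The shared σ² if all observed variances are equal, else None."""
        s2 = [self.variances[i] for i in self.observed]
        return s2[0] if all(s == s2[0] for s in s2) else None
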