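"""Independent oracles for cross-checking the homotopy solver.

Everything here goes through sympy's exact symbolic machinery (Groebner
bases in lex order with numeric back-substitution), entirely independent of
the continuation tracker it is used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import sympy as sp


def solve_symbolic(exprs: list[str], var_names: list[str]) -> list[tuple[complex, ...]]:
    """All complex solutions of a zero-dimensional square system, symbolically.

    Computes a lex Groebner basis and back-substitutes numerically level by
    level; candidate points are residual-filtered against the original
    system.  Intended for small systems (≤3 variables, low degree).
    """
    syms = sp.symbols(var_names)
    if len(var_names) == 1:
        syms = (syms,) if not isinstance(syms, (tuple, list)) else tuple(syms)
    polys = [
        sp.Poly(sp.nsimplify(sp.sympify(e), rational=True), *syms) for e in exprs
    ]
    gb = sp.groebner(polys, *syms, order="lex")
    if gb.is_zero_dimensional is False:
        raise ValueError("system is not zero-dimensional")
    basis = list(gb.exprs)

    sols: list[dict] = [{}]
    # eliminate variables from the last (lex-smallest) upward
    for v in reversed(syms):
        new_sols = []
        for partial in sols:
            cands = []
            for b in basis:
                e = sp.expand(b.subs(partial))
                fs = e.free_symbols
                if fs == {v}:
                    cands.append(sp.Poly(e, v))
            if not cands:
                # variable unconstrained at this level -> not zero-dimensional
                raise ValueError("triangularization failed")
            poly = min(cands, key=lambda p: p.degree())
            coeffs = np.array([complex(c) for c in poly.all_coeffs()])
            for r in np.roots(coeffs):
                new_sols.append({**partial, v: complex(r)})
        sols = new_sols

    # residual filter + polish on the original system via sympy lambdify
    fns = [sp.lambdify(syms, p.as_expr(), "numpy") for p in polys]
    out = []
    for sdict in sols:
        pt = np.array([sdict[v] for v in syms], dtype=complex)
        pt = _newton_polish(fns, syms, polys, pt)
        res = max(abs(complex(f(*pt))) for f in fns)
        if res < 1e-6 * (1 + np.abs(pt).max()):
            out.append(tuple(pt))
    return _dedup(out)


def _newton_polish(fns, syms, polys, pt, iters: int = 20):
    jac_fns = [[sp.lambdify(syms, sp.diff(p.as_expr(), v), "numpy") for v in syms] for p in polys]
    for _ in range(iters):
        F = np.array([complex(f(*pt)) for f in fns])
        if np.abs(F).max() < 1e-12:
            break
        J = np.array([[complex(jf(*pt)) for jf in row] for row in jac_fns])
        try:
            pt = pt - np.linalg.solve(J, F)
        except np.linalg.LinAlgError:
            break
    return pt


def _dedup(points: list[tuple[complex, ...]], tol: float = 1e-6):
    reps = []
    for p in points:
        arr = np.array(p)
        if not any(
            np.abs(arr - np.array(r)).max() <= tol * (1 + np.abs(np.array(r)).max())
            for r in reps
        ):
            reps.append(p)
    return reps


def set_distance(A: list, B: list) -> float:
    """Symmetric Hausdorff-style distance between two finite point sets."""
    if not A and not B:
        return 0.0
    if not A or not B:
        return np.inf
    A = [np.asarray(a, dtype=complex) for a in A]
    B = [np.asarray(b, dtype=complex) for b in B]
    d_ab = max(min(np.abs(a - b).max() for b in B) for a in A)
    d_ba = max(min(np.abs(b - a).max() for a in A) for b in B)
    return max(d_ab, d_ba)


def lagrange_critical_count(
    f_expr: str, var_names: list[str], y, observed: list[str] | None = None
) -> int:
    """Count critical points of the squared distance on the hypersurface f = 0.

    Symbolic-elimination ED-degree oracle: solves the Lagrange system
    {f = 0, ∇dist = λ∇f} exactly.  ``observed`` restricts the distance to a
    subset of the coordinates (the objective ignores the others, whose
    stationarity reduces to λ·∂f/∂v = 0).
    """
    syms = list(sp.symbols(var_names))
    observed = list(var_names) if observed is None else list(observed)
    ymap = dict(zip(observed, y))
    lam = sp.Symbol("_lam")
    f = sp.sympify(f_expr)
    eqs = [f]
    for v in syms:
        if str(v) in ymap:
            target = sp.nsimplify(ymap[str(v)], rational=True)
            eqs.append(2 * (v - target) - lam * sp.diff(f, v))
        else:
            eqs.append(-lam * sp.diff(f, v))
    sols = solve_symbolic([str(e) for e in eqs], [str(s) for s in syms] + ["_lam"])
    return len(sols)


def grid_min_distance(objective, grid: np.ndarray) -> tuple[float, float]:
    """(argmin, min) of a scalar objective over a dense 1-D grid."""
    vals = np.array([objective(g) for g in grid])
    i = int(np.argmin(vals))
    return float(grid[i]), float(vals[i])
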