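"""Mass-action chemical reaction network frontend.

Parses a plain-text reaction list (one reaction per line, e.g.
``A + 2 B -> C, k1`` or reversible ``A <-> B, kf, kr``), derives the
mass-action steady-state polynomials ``f_s = Σ (prod_s - react_s)·k·Π x^react``
and the conservation laws spanned by the left null space of the
stoichiometric matrix, and assembles :class:`~varfit.polysys.ModelSpec`
objects ready for fitting.

Because conservation laws make rows of the stoichiometric matrix linearly
dependent, the model-building helper replaces dependent steady-state rows
by the conservation relations ``Σ c_s·x_s - T_j`` (one fresh total symbol
T_j each), yielding a steady-state system of full rank — the reduced form
the Fritz John construction expects.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import sympy as sp

from .polysys import ModelSpec, PolyMap, PolySystem

__all__ = [
    "ReactionNetwork",
    "parse_network",
    "steady_state_system",
    "conservation_laws",
    "network_to_model",
    "write_network",
]


class ParseError(ValueError):
    pass


@dataclass
class Reaction:
    reactants: dict[str, int]
    products: dict[str, int]
    rate: str


@dataclass
class ReactionNetwork:
    species: tuple[str, ...]
    reactions: list[Reaction]

    def __post_init__(self) -> None:
        self.species = tuple(self.species)
        seen = set()
        declared = set(self.species)
        for rx in self.reactions:
            if rx.rate in seen:
                raise ParseError(f"duplicate rate symbol {rx.rate!r}")
            seen.add(rx.rate)
            for s, k in {**rx.reactants, **rx.products}.items():
                if s not in declared:
                    raise ParseError(f"undeclared species {s!r}")
                if not (isinstance(k, int) and k >= 0):
                    raise ParseError(f"stoichiometry of {s!r} must be a nonnegative integer")

    @property
    def rates(self) -> tuple[str, ...]:
        return tuple(rx.rate for rx in self.reactions)

    def stoichiometric_matrix(self) -> np.ndarray:
        """Species × reactions matrix of net stoichiometric changes."""
        S = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        idx = {s: i for i, s in enumerate(self.species)}
        for j, rx in enumerate(self.reactions):
            for s, k in rx.reactants.items():
                S[idx[s], j] -= k
            for s, k in rx.products.items():
                S[idx[s], j] += k
        return S


_SIDE_RE = re.compile(r"^\s*(?:(\d+)\s+)?([A-Za-z_]\w*)\s*$")


def _parse_side(text: str, lineno: int) -> dict[str, int]:
    text = text.strip()
    if text in ("", "0"):  # empty side: synthesis / degradation
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        mo = _SIDE_RE.match(term)
        if not mo:
            raise ParseError(f"line {lineno}: cannot parse species term {term.strip()!r}")
        coef = int(mo.group(1) or 1)
        name = mo.group(2)
        out[name] = out.get(name, 0) + coef
    return out


def parse_network(text: str) -> ReactionNetwork:
    """Parse reaction text; ``<->`` lines expand to a forward/reverse pair."""
    reactions: list[Reaction] = []
    species: list[str] = []

    def _note(side: dict[str, int]) -> None:
        for s in side:
            if s not in species:
                species.append(s)

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        arrow_part = parts[0]
        if "<->" in arrow_part:
            if len(parts) != 3:
                raise ParseError(
                    f"line {lineno}: reversible reaction needs two rate symbols"
                )
            lhs, rhs = arrow_part.split("<->")
            rs, ps = _parse_side(lhs, lineno), _parse_side(rhs, lineno)
            _note(rs), _note(ps)
            reactions.append(Reaction(rs, ps, parts[1]))
            reactions.append(Reaction(ps, rs, parts[2]))
        elif "->" in arrow_part:
            if len(parts) != 2:
                raise ParseError(f"line {lineno}: reaction needs exactly one rate symbol")
            lhs, rhs = arrow_part.split("->")
            rs, ps = _parse_side(lhs, lineno), _parse_side(rhs, lineno)
            _note(rs), _note(ps)
            reactions.append(Reaction(rs, ps, parts[1]))
        else:
            raise ParseError(f"line {lineno}: no reaction arrow found")
    if not reactions:
        raise ParseError("no reactions found")
    return ReactionNetwork(tuple(species), reactions)


def write_network(network: ReactionNetwork) -> str:
    """Writer that round-trips through :func:`parse_network`."""

    def _side(side: dict[str, int]) -> str:
        if not side:
            return "0"
        return " + ".join(
            (f"{k} {s}" if k > 1 else s) for s, k in sorted(side.items())
        )

    lines = [
        f"{_side(rx.reactants)} -> {_side(rx.products)}, {rx.rate}"
        for rx in network.reactions
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# steady-state polynomials and conservation laws
# ---------------------------------------------------------------------------

def steady_state_system(network: ReactionNetwork) -> PolySystem:
    """Mass-action steady-state polynomials, one per species.

    Variables are ordered (rates, species); ``f_s`` sums, over reactions,
    the net stoichiometric change of ``s`` times the rate symbol times the
    mass-action monomial of the reactant side.
    """
    variables = network.rates + network.species
    pos = {v: i for i, v in enumerate(variables)}
    nv = len(variables)
    polys: list[PolyMap] = [{} for _ in network.species]
    for j, rx in enumerate(network.reactions):
        mono = [0] * nv
        mono[pos[rx.rate]] = 1
        for s, k in rx.reactants.items():
            mono[pos[s]] += k
        key = tuple(mono)
        for i, s in enumerate(network.species):
            net = rx.products.get(s, 0) - rx.reactants.get(s, 0)
            if net:
                p = polys[i]
                p[key] = p.get(key, 0.0) + float(net)
    return PolySystem(variables, [{e: c for e, c in p.items() if c != 0} for p in polys])


def conservation_laws(
    network: ReactionNetwork, total_prefix: str = "T"
) -> list[tuple[dict[str, int], str]]:
    """Integer basis of conserved linear combinations of species.

    Each law is returned as (coefficient map over species, total symbol);
    the law reads ``Σ c_s·x_s − T_j = 0``.  Coefficients come from the left
    null space of the stoichiometric matrix, scaled to smallest integers
    with the first nonzero coefficient positive.
    """
    S = sp.Matrix(network.stoichiometric_matrix())
    null = S.T.nullspace()
    vecs = []
    for vec in null:
        fracs = [Fraction(sp.Rational(v)) for v in vec]
        denom = np.lcm.reduce([f.denominator for f in fracs]) if fracs else 1
        ints = np.array([int(f * denom) for f in fracs], dtype=np.int64)
        vecs.append(_normalize_int_vec(ints))
    vecs = _prefer_nonnegative(vecs)
    laws = []
    for j, ints in enumerate(vecs):
        coeffs = {s: int(c) for s, c in zip(network.species, ints) if c != 0}
        laws.append((coeffs, f"{total_prefix}{j + 1}"))
    return laws


def _normalize_int_vec(v: np.ndarray) -> np.ndarray:
    g = np.gcd.reduce(np.abs(v[v != 0])) if np.any(v) else 1
    v = v // max(g, 1)
    first = next((c for c in v if c != 0), 1)
    return -v if first < 0 else v


def _prefer_nonnegative(vecs: list[np.ndarray]) -> list[np.ndarray]:
    """Greedy basis change toward nonnegative (moiety-style) coefficients."""
    vecs = [v.copy() for v in vecs]
    for _ in range(len(vecs) * 4):
        changed = False
        for i, v in enumerate(vecs):
            if np.all(v >= 0):
                continue
            for j, u in enumerate(vecs):
                if i == j:
                    continue
                for cand in (u - v, v + u, v + 2 * u, u + 2 * v):
                    if np.any(cand) and np.all(cand >= 0):
                        vecs[i] = _normalize_int_vec(cand)
                        changed = True
                        break
                if changed:
                    break
            if changed:
                break
        if not changed:
            break
    return vecs


def network_to_model(
    network: ReactionNetwork,
    measured: Sequence[str],
    known: Mapping[str, float] | None = None,
) -> ModelSpec:
    """Build a full-rank steady-state :class:`ModelSpec` from a network.

    ``f`` keeps an independent subset of the steady-state rows (pivot rows
    of the stoichiometric matrix) and appends one conservation relation
    ``Σ c_s x_s − T_j`` per dependency, so the constraint system has full
    rank — required by the Fritz John construction.  ``measured`` names the
    species whose concentrations are observed (g is the identity on them);
    ``known`` may bind rate constants and totals.
    """
    for s in measured:
        if s not in network.species:
            raise ParseError(f"measured species {s!r} is not in the network")
    laws = conservation_laws(network)
    S = sp.Matrix(network.stoichiometric_matrix())
    # independent steady-state rows = pivot columns of S^T
    pivot_rows = list(S.T.rref()[1])
    full = steady_state_system(network)
    totals = tuple(t for _, t in laws)
    params = network.rates + totals
    states = network.species
    fvars = params + states
    from .polysys import constant, monomial, poly_add, poly_embed

    f_polys = [poly_embed(full.polynomials[i], full.variables, fvars) for i in pivot_rows]
    for coeffs, total in laws:
        p: PolyMap = {}
        for s, c in coeffs.items():
            p = poly_add(p, monomial(fvars, s, float(c)))
        p = poly_add(p, monomial(fvars, total, -1.0))
        f_polys.append(p)
    f = PolySystem(fvars, f_polys)
    g = PolySystem(fvars, [monomial(fvars, s) for s in measured])
    return ModelSpec(
        params, states, tuple(measured), f, g, dict(known or {})
    )
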