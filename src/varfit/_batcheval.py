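"""Vectorized evaluation of polynomial systems at batches of points.

Path tracking advances hundreds of continuation paths in lockstep, so the
hot loop needs system values and Jacobians for a whole batch of points at
once.  The evaluator pre-compiles a :class:`~varfit.polysys.PolySystem` into
a shared monomial basis: values of all basis monomials at all points are
formed by table-lookup products (no repeated powering), then one complex
matmul produces the system values and another the full Jacobian block.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .polysys import PolySystem, poly_diff

__all__ = ["BatchEvaluator"]


class BatchEvaluator:
    """Compiled batch evaluator for a fixed polynomial system."""

    def __init__(self, system: PolySystem):
        self.system = system
        n_polys, n_vars = system.n_polys, system.n_vars
        # collect the union of monomials over the system and all partials
        basis: dict[tuple[int, ...], int] = {}

        def _index(e: tuple[int, ...]) -> int:
            if e not in basis:
                basis[e] = len(basis)
            return basis[e]

        coeff_entries = []  # (poly, monomial_index, coeff)
        jac_entries = []  # (poly, var, monomial_index, coeff)
        for i, p in enumerate(system.polynomials):
            for e, c in p.items():
                coeff_entries.append((i, _index(e), c))
            for j in range(n_vars):
                for e, c in poly_diff(p, j).items():
                    jac_entries.append((i, j, _index(e), c))

        m = max(len(basis), 1)
        if not basis:
            basis[tuple([0] * n_vars)] = 0
        self.exps = np.array(
            [e for e, _ in sorted(basis.items(), key=lambda t: t[1])], dtype=np.int64
        )  # (M, n_vars)
        self.coeffs = np.zeros((n_polys, m), dtype=complex)
        for i, k, c in coeff_entries:
            self.coeffs[i, k] += c
        self.jac_coeffs = np.zeros((n_polys * n_vars, m), dtype=complex)
        for i, j, k, c in jac_entries:
            self.jac_coeffs[i * n_vars + j, k] += c
        self.max_deg = int(self.exps.max(initial=0))
        # the Jacobian coefficient block is large and sparse; a CSR matmul
        # beats dense once the system has more than a handful of variables
        dens = np.count_nonzero(self.jac_coeffs) / max(self.jac_coeffs.size, 1)
        self._jac_sp = (
            sparse.csr_matrix(self.jac_coeffs)
            if self.jac_coeffs.size > 4096 and dens < 0.25
            else None
        )
        # per-variable nonzero-exponent columns, precomputed for the product
        self._nz = []
        for v in range(n_vars):
            cols = np.nonzero(self.exps[:, v])[0]
            self._nz.append((cols, self.exps[cols, v]))

    # ------------------------------------------------------------------
    def monomials(self, points: np.ndarray) -> np.ndarray:
        """Values of every basis monomial at every point: (P, M)."""
        points = np.asarray(points, dtype=complex)
        P = points.shape[0]
        n_vars = self.system.n_vars
        M = self.exps.shape[0]
        # power table: pow_tab[p, v, k] = points[p, v] ** k
        pow_tab = np.ones((P, n_vars, self.max_deg + 1), dtype=complex)
        for k in range(1, self.max_deg + 1):
            pow_tab[:, :, k] = pow_tab[:, :, k - 1] * points
        vals = np.ones((P, M), dtype=complex)
        for v in range(n_vars):
            cols, ks = self._nz[v]
            if cols.size:
                vals[:, cols] *= pow_tab[:, v, :][:, ks]
        return vals

    def values(self, points: np.ndarray, monoms: np.ndarray | None = None) -> np.ndarray:
        """System values at a batch of points: (P, n_polys)."""
        if monoms is None:
            monoms = self.monomials(points)
        return monoms @ self.coeffs.T

    def jacobians(self, points: np.ndarray, monoms: np.ndarray | None = None) -> np.ndarray:
        """Jacobians at a batch of points: (P, n_polys, n_vars)."""
        if monoms is None:
            monoms = self.monomials(points)
        P = monoms.shape[0]
        n_p, n_v = self.system.n_polys, self.system.n_vars
        if self._jac_sp is not None:
            flat_t = self._jac_sp @ np.ascontiguousarray(monoms.T)
            return flat_t.reshape(n_p, n_v, P).transpose(2, 0, 1)
        flat = monoms @ self.jac_coeffs.T  # (P, n_polys * n_vars)
        return flat.reshape(P, n_p, n_v)

    def values_and_jacobians(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        monoms = self.monomials(points)
        return self.values(points, monoms), self.jacobians(points, monoms)
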