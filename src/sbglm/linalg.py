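"""Sparse symmetric positive-definite factorisation utilities.

GMRF computations need three primitives from a factor of a sparse SPD
matrix Q: solves Q x = b, the log-determinant, and draws from
N(0, Q^{-1}).  We factor with SuperLU after a reverse-Cuthill-McKee
reordering, with symmetric mode and diagonal pivoting disabled so the
factorisation is effectively an LDL^T decomposition: for symmetric Q,
U = D L^T, which yields both the log-determinant (sum log diag U) and a
matrix square root for sampling (x = U^{-1} D^{1/2} z solves
L^T x = D^{-1/2} z, and cov(x) = Q^{-1}).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import reverse_cuthill_mckee
from scipy.sparse.linalg import splu, spsolve_triangular


class NotPositiveDefiniteError(np.linalg.LinAlgError):
    pass


class SparseCholesky:
    """LDL^T-style factorisation of a sparse SPD matrix."""

    def __init__(self, Q: sp.spmatrix):
        Q = sp.csc_matrix(Q)
        if Q.shape[0] != Q.shape[1]:
            raise ValueError("Q must be square")
        self.n = Q.shape[0]
        perm = reverse_cuthill_mckee(Q.tocsr(), symmetric_mode=True)
        self._perm = np.asarray(perm)
        self._iperm = np.argsort(self._perm)
        Qp = Q[self._perm][:, self._perm].tocsc()
        try:
            self._lu = splu(
                Qp,
                permc_spec="NATURAL",
                diag_pivot_thresh=0.0,
                options=dict(SymmetricMode=True),
            )
        except RuntimeError as exc:  # singular factorisation
            raise NotPositiveDefiniteError(str(exc)) from exc
        self._udiag = self._lu.U.diagonal()
        if np.any(self._udiag <= 0):
            raise NotPositiveDefiniteError("matrix is not positive definite")

    @property
    def logdet(self) -> float:
        return float(np.sum(np.log(self._udiag)))

    def solve(self, b: np.ndarray) -> np.ndarray:
        """Solve Q x = b for vector or matrix right-hand sides."""
        b = np.asarray(b, dtype=float)
        x = self._lu.solve(b[self._perm])
        return x[self._iperm]

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        """Draw ``size`` samples from N(0, Q^{-1}); returns (size, n)."""
        z = rng.standard_normal((self.n, size))
        rhs = np.sqrt(self._udiag)[:, None] * z
        x = spsolve_triangular(self._lu.U.tocsr(), rhs, lower=False)
        return x[self._iperm].T


def quad_form_inv(factor: SparseCholesky, A: sp.spmatrix) -> np.ndarray:
    """Columnwise a_i^T Q^{-1} a_i for the columns a_i of sparse A."""
    A = sp.csc_matrix(A)
    X = factor.solve(A.toarray())
    return np.einsum("ij,ij->j", A.toarray(), X)
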