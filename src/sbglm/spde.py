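"""SPDE/Matérn Gaussian Markov random field prior on a triangulated surface.

A latent activation field with Matérn covariance
``cov(d) = sigma^2 (kappa d) K_1(kappa d)`` (smoothness nu = 1) is
represented as a GMRF by discretising the SPDE
``(kappa^2 - Laplacian) (tau beta) = white noise`` with linear finite
elements on the mesh.  The resulting precision matrix,

    Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G),

is sparse: ``C`` is the lumped FEM mass matrix (diagonal) and ``G`` the
cotangent stiffness matrix, so Q couples only second-order mesh
neighbours.  ``kappa`` is an inverse spatial range (1/mm; practical
correlation range ~ sqrt(8)/kappa) and ``tau`` scales precision.  The
smoothness exponent of the SPDE operator is fixed at 2, the value under
which Q takes the closed form above.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import k1

from .mesh import TriangularMesh


@dataclass(frozen=True)
class MaternHyperparams:
    """Matérn/SPDE hyperparameters: ``kappa`` (1/mm) and ``tau``, both > 0."""

    kappa: float
    tau: float

    def __post_init__(self) -> None:
        if not (self.kappa > 0 and self.tau > 0):
            raise ValueError("kappa and tau must be strictly positive")

    @property
    def range_mm(self) -> float:
        """Practical correlation range sqrt(8 nu)/kappa with nu = 1."""
        return float(np.sqrt(8.0) / self.kappa)

    @property
    def marginal_variance(self) -> float:
        """Stationary marginal variance 1 / (4 pi kappa^2 tau^2) on a 2-D manifold."""
        return float(1.0 / (4.0 * np.pi * self.kappa**2 * self.tau**2))


@dataclass
class SPDEOperators:
    """FEM operators for one mesh: mass ``C`` (diagonal, mm^2 per vertex),
    stiffness ``G`` (sparse symmetric, cotangent weights) and the
    N x n data-selection indicator ``Psi``."""

    C: sp.dia_matrix
    G: sp.csr_matrix
    Psi: sp.csr_matrix

    @property
    def n_mesh(self) -> int:
        return self.C.shape[0]

    @property
    def n_data(self) -> int:
        return self.Psi.shape[0]

    @property
    def c_inv(self) -> sp.dia_matrix:
        return sp.diags(1.0 / self.C.diagonal())


def build_fem_matrices(mesh: TriangularMesh) -> SPDEOperators:
    """Assemble the lumped mass matrix C, cotangent stiffness G and Psi.

    C's vertex entry is one third of the total area of its incident
    triangles (row-sum lumping of the consistent linear-FEM mass
    matrix).  G is assembled per element as
    ``G_ab = (e_a . e_b) / (4 A)`` where ``e_a`` is the edge opposite
    local vertex ``a``; interior rows of G sum to zero.
    """
    n = mesh.n_vertices
    f = mesh.faces
    p = mesh.vertices

    # edge vectors opposite each local vertex
    e0 = p[f[:, 2]] - p[f[:, 1]]
    e1 = p[f[:, 0]] - p[f[:, 2]]
    e2 = p[f[:, 1]] - p[f[:, 0]]
    areas = mesh.triangle_areas()
    if np.any(areas <= 0):
        raise ValueError("degenerate triangle encountered during assembly")

    edges = (e0, e1, e2)
    rows, cols, vals = [], [], []
    for a in range(3):
        for b in range(3):
            rows.append(f[:, a])
            cols.append(f[:, b])
            vals.append(np.einsum("ij,ij->i", edges[a], edges[b]) / (4.0 * areas))
    G = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    G.sum_duplicates()

    c_diag = np.zeros(n)
    np.add.at(c_diag, f.ravel(), np.repeat(areas / 3.0, 3))
    if np.any(c_diag <= 0):
        raise ValueError("mesh has isolated vertices (zero lumped mass)")
    C = sp.diags(c_diag)

    data_idx = mesh.data_indices
    Psi = sp.csr_matrix(
        (np.ones(data_idx.size), (np.arange(data_idx.size), data_idx)),
        shape=(data_idx.size, n),
    )
    return SPDEOperators(C=C, G=G, Psi=Psi)


def build_precision(ops: SPDEOperators, hp: MaternHyperparams) -> sp.csc_matrix:
    """Sparse GMRF precision Q = tau^2 (kappa^4 C + 2 kappa^2 G + G C^{-1} G).

    Symmetric positive definite for kappa, tau > 0; the sparsity pattern
    (second-order mesh neighbourhood) does not depend on (kappa, tau).
    """
    if not isinstance(hp, MaternHyperparams):
        hp = MaternHyperparams(*hp)
    k2 = hp.kappa**2
    GCG = (ops.G @ ops.c_inv @ ops.G).tocsc()
    Q = hp.tau**2 * (k2**2 * ops.C + 2.0 * k2 * ops.G + GCG)
    Q = ((Q + Q.T) * 0.5).tocsc()  # enforce exact symmetry
    return Q


def matern_covariance(distance, hp: MaternHyperparams, sigma2: float = 1.0):
    """Matérn (nu = 1) covariance sigma^2 (kappa d) K_1(kappa d).

    Continuous at the origin: the d -> 0 limit is sigma^2.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    x = hp.kappa * d
    with np.errstate(invalid="ignore", over="ignore"):
        out = np.where(x > 0, x * k1(np.maximum(x, 1e-300)), 1.0)
    out = sigma2 * out
    if np.isscalar(distance):
        return float(out)
    return out
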