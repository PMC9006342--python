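"""BOLD preprocessing: scaling, design construction, nuisance regression,
AR estimation and prewhitening.

The pipeline order is: scale to percent signal change -> build the task
design (boxcar * double-Gamma HRF, max-scaled, centred) -> regress
nuisance covariates (motion, polynomial drift, task temporal
derivatives) from both data and design -> fit AR(p) models to classical
residuals by Yule-Walker -> average AR models across runs and smooth
them along the surface -> prewhiten data and design per vertex.
Prewhitening makes the residuals temporally independent with unit
variance, the form both the classical and the spatial Bayesian GLMs
assume.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cholesky, solve_toeplitz, solve_triangular
from scipy.sparse.csgraph import dijkstra
from scipy.stats import gamma as gamma_dist

from .mesh import TriangularMesh

logger = logging.getLogger(__name__)

#: canonical double-Gamma HRF parameters (seconds): response peak ~5-6 s,
#: undershoot ~16 s with 1/6 relative amplitude, 32 s support.
DEFAULT_HRF_PARAMS = dict(
    peak_shape=6.0,
    peak_scale=1.0,
    undershoot_shape=16.0,
    undershoot_scale=1.0,
    undershoot_ratio=1.0 / 6.0,
    total_length_s=32.0,
)


@dataclass
class BoldRun:
    """One run of per-vertex BOLD data: ``data`` is T x N (time by data
    location), ``repetition_time`` in seconds."""

    data: np.ndarray
    repetition_time: float
    vertex_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] < 2:
            raise ValueError("BOLD data must be T x N with T >= 2")
        if np.isnan(self.data).any():
            raise ValueError("BOLD data contain missing values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class TaskDesign:
    """Finalised task design: ``task_matrix`` T x K (max-scaled then
    centred) plus nuisance regressors (drift, motion, task temporal
    derivatives)."""

    task_matrix: np.ndarray
    task_names: list[str]
    nuisance_matrix: np.ndarray | None = None

    @property
    def n_tasks(self) -> int:
        return self.task_matrix.shape[1]


@dataclass
class ARModel:
    """Per-vertex AR(p) noise model: ``coefs`` N x p, ``innovation_variance`` N."""

    coefs: np.ndarray
    innovation_variance: np.ndarray

    def __post_init__(self) -> None:
        self.coefs = np.atleast_2d(np.asarray(self.coefs, dtype=float))
        self.innovation_variance = np.atleast_1d(
            np.asarray(self.innovation_variance, dtype=float)
        )
        if np.any(self.innovation_variance <= 0):
            raise ValueError("innovation variance must be positive")

    @property
    def order(self) -> int:
        return self.coefs.shape[1]

    def is_causal(self) -> np.ndarray:
        """Per-vertex check that the AR polynomial roots lie outside the
        unit circle (stationary, causal filter)."""
        out = np.empty(self.coefs.shape[0], dtype=bool)
        for v, phi in enumerate(self.coefs):
            if not np.any(phi):
                out[v] = True
                continue
            roots = np.roots(np.concatenate([[1.0], -phi]))
            out[v] = np.all(np.abs(roots) < 1.0)
        return out


@dataclass
class SessionData:
    """The unit the GLMs consume: one prewhitened run.

    ``bold`` is T x N.  ``design`` is either T x K (shared across
    vertices) or N x T x K (vertex-specific, the post-prewhitening
    case).
    """

    bold: np.ndarray
    design: np.ndarray
    task_names: list[str] = field(default_factory=list)
    repetition_time: float = 1.0

    @property
    def n_timepoints(self) -> int:
        return self.bold.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.bold.shape[1]

    @property
    def n_tasks(self) -> int:
        return self.design.shape[-1]

    def design_at(self, v: int) -> np.ndarray:
        if self.design.ndim == 3:
            return self.design[v]
        return self.design


# ---------------------------------------------------------------------------
# HRF and design construction
# ---------------------------------------------------------------------------


def make_hrf(
    repetition_time: float,
    total_length_s: float | None = None,
    oversampling: int = 1,
    params: dict | None = None,
) -> np.ndarray:
    """Sample the canonical double-Gamma HRF on the TR grid.

    The kernel is the difference of two Gamma densities (response minus
    scaled undershoot), normalised to unit peak.  With the default
    parameters the response peaks near 5 s and the undershoot near 15 s.
    """
    if repetition_time <= 0:
        raise ValueError("repetition_time must be positive")
    p = dict(DEFAULT_HRF_PARAMS)
    if params:
        p.update(params)
    if total_length_s is None:
        total_length_s = p["total_length_s"]
    dt = repetition_time / oversampling
    t = np.arange(0.0, total_length_s + dt / 2, dt)
    h = gamma_dist.pdf(t, p["peak_shape"], scale=p["peak_scale"]) - p[
        "undershoot_ratio"
    ] * gamma_dist.pdf(t, p["undershoot_shape"], scale=p["undershoot_scale"])
    return h / h.max()


def _boxcar(onsets, durations, n_fine, dt) -> np.ndarray:
    box = np.zeros(n_fine)
    for onset, dur in zip(onsets, durations):
        i0 = int(np.round(onset / dt))
        i1 = int(np.round((onset + dur) / dt))
        box[i0 : max(i1, i0 + 1)] = 1.0
    return box


def build_design(
    onsets: dict[str, Sequence[float]],
    durations: dict[str, Sequence[float]],
    n_timepoints: int,
    repetition_time: float,
    hrf_params: dict | None = None,
    oversampling: int = 16,
) -> TaskDesign:
    """Convolve stimulus boxcars with the double-Gamma HRF.

    Each task column is built on an oversampled grid, downsampled to the
    TR grid, divided by its maximum over time and then centred.  The
    temporal derivative of each (unscaled) convolved regressor is
    returned in the nuisance matrix, to absorb onset-timing differences.
    """
    run_end = n_timepoints * repetition_time
    names = list(onsets)
    dt = repetition_time / oversampling
    n_fine = n_timepoints * oversampling
    hrf_fine = make_hrf(repetition_time, oversampling=oversampling, params=hrf_params)

    cols, derivs = [], []
    for name in names:
        ons = np.asarray(list(onsets[name]), dtype=float)
        durs = np.asarray(list(durations[name]), dtype=float)
        if ons.size and (ons.min() < 0 or ons.max() >= run_end):
            raise ValueError(f"task {name!r}: onset outside the run [0, {run_end}s)")
        if np.any(durs <= 0):
            raise ValueError(f"task {name!r}: durations must be positive")
        if ons.size == 0:
            logger.warning("task %r has no events; design column is all zero", name)
            cols.append(np.zeros(n_timepoints))
            derivs.append(np.zeros(n_timepoints))
            continue
        box = _boxcar(ons, durs, n_fine, dt)
        conv = np.convolve(box, hrf_fine)[:n_fine]
        x = conv[::oversampling].copy()
        d = np.concatenate([[0.0], np.diff(x)])
        cols.append(x)
        derivs.append(d)

    task = np.column_stack(cols)
    maxima = task.max(axis=0)
    nonzero = maxima > 0
    task[:, nonzero] /= maxima[nonzero]
    task -= task.mean(axis=0)
    return TaskDesign(
        task_matrix=task, task_names=names, nuisance_matrix=np.column_stack(derivs)
    )


def drift_regressors(n_timepoints: int) -> np.ndarray:
    """Linear and quadratic polynomial drift terms over scan time."""
    t = np.linspace(-1.0, 1.0, n_timepoints)
    return np.column_stack([t, t**2])


# ---------------------------------------------------------------------------
# Scaling and nuisance regression
# ---------------------------------------------------------------------------


def scale_bold(run: BoldRun) -> BoldRun:
    """Centre and scale to percent local signal change:
    y <- 100 (y - mean(y)) / mean(y) per vertex."""
    means = run.data.mean(axis=0)
    bad = np.flatnonzero(means <= 0)
    if bad.size:
        raise ValueError(
            f"nonpositive temporal mean at vertex {bad[0]} "
            "(unmasked background?); cannot scale to percent signal change"
        )
    scaled = 100.0 * (run.data - means) / means
    return BoldRun(scaled, run.repetition_time, run.vertex_ids)


def nuisance_regress(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residualise both the data and the task design on nuisance
    regressors Z (projection onto the orthogonal complement of col(Z)).

    Dependent/zero columns of Z are dropped with a warning rather than
    failing; returns (y_resid, X_resid).
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    keep = np.linalg.norm(Z, axis=0) > 1e-12
    if not keep.all():
        warnings.warn("dropping all-zero nuisance columns", stacklevel=2)
        Z = Z[:, keep]
    if Z.shape[1] == 0:
        return np.asarray(y, float).copy(), np.asarray(X, float).copy()
    q, r = np.linalg.qr(Z)
    diag = np.abs(np.diag(r))
    indep = diag > 1e-10 * diag.max()
    if not indep.all():
        warnings.warn("nuisance matrix is rank deficient; dropping dependent columns",
                      stacklevel=2)
        q = q[:, indep]

    def proj_out(m):
        m = np.asarray(m, dtype=float)
        return m - q @ (q.T @ m)

    return proj_out(y), proj_out(X)


# ---------------------------------------------------------------------------
# AR noise modelling and prewhitening
# ---------------------------------------------------------------------------


def _sample_autocov(x: np.ndarray, maxlag: int) -> np.ndarray:
    """Biased (1/T) sample autocovariances at lags 0..maxlag."""
    x = x - x.mean()
    T = x.size
    return np.array([x[: T - k] @ x[k:] for k in range(maxlag + 1)]) / T


def fit_ar_yule_walker(series: np.ndarray, order: int = 6) -> tuple[np.ndarray, float]:
    """Fit AR(p) coefficients by solving the Yule-Walker (Toeplitz)
    system of biased sample autocovariances.

    Returns (coefficients, innovation variance).  A numerically singular
    system falls back to zero coefficients with a warning.
    """
    series = np.asarray(series, dtype=float)
    if series.size <= 10 * order:
        raise ValueError("series too short for the requested AR order")
    g = _sample_autocov(series, order)
    if g[0] <= 0:
        warnings.warn("zero-variance series; returning white-noise AR model",
                      stacklevel=2)
        return np.zeros(order), 1.0
    try:
        phi = solve_toeplitz(g[:-1], g[1:])
    except np.linalg.LinAlgError:
        warnings.warn("singular Yule-Walker system; returning zero coefficients",
                      stacklevel=2)
        return np.zeros(order), float(g[0])
    sigma2 = float(g[0] - phi @ g[1:])
    if sigma2 <= 0:
        warnings.warn("nonpositive innovation variance; returning zero coefficients",
                      stacklevel=2)
        return np.zeros(order), float(g[0])
    return phi, sigma2


def fit_ar_models(residuals: np.ndarray, order: int = 6) -> ARModel:
    """Fit per-vertex AR(p) models to a T x N residual matrix."""
    T, N = residuals.shape
    coefs = np.zeros((N, order))
    iv = np.ones(N)
    for v in range(N):
        coefs[v], iv[v] = fit_ar_yule_walker(residuals[:, v], order)
    model = ARModel(coefs, iv)
    causal = model.is_causal()
    if not causal.all():
        warnings.warn(
            f"{np.count_nonzero(~causal)} vertices have non-causal AR fits",
            stacklevel=2,
        )
    return model


def average_ar_across_runs(models: Sequence[ARModel]) -> ARModel:
    """Elementwise mean of coefficients and innovation variances over runs."""
    orders = {m.order for m in models}
    shapes = {m.coefs.shape for m in models}
    if len(orders) != 1 or len(shapes) != 1:
        raise ValueError("AR models must share order and vertex set")
    coefs = np.mean([m.coefs for m in models], axis=0)
    iv = np.mean([m.innovation_variance for m in models], axis=0)
    return ARModel(coefs, iv)


def smooth_on_mesh(
    values: np.ndarray, mesh: TriangularMesh, fwhm_mm: float
) -> np.ndarray:
    """Gaussian kernel smoothing over graph-geodesic distance.

    sigma = fwhm / sqrt(8 ln 2); weights exp(-d^2 / 2 sigma^2) over
    vertices within 3 sigma graph-geodesic distance (shortest paths
    along mesh edges), normalised to sum one.  Accepts per-vertex
    vectors or (n, m) stacks of fields.
    """
    return smooth_on_graph(values, mesh.edge_length_graph(), fwhm_mm)


def smooth_on_graph(
    values: np.ndarray, graph: sp.spmatrix, fwhm_mm: float
) -> np.ndarray:
    """Gaussian kernel smoothing on an edge-length-weighted graph (used
    directly when smoothing values defined only on data locations)."""
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    values = np.asarray(values, dtype=float)
    if fwhm_mm == 0:
        return values.copy()
    sigma = fwhm_mm / np.sqrt(8.0 * np.log(2.0))
    dist = dijkstra(graph, directed=False, limit=3.0 * sigma)
    finite = np.isfinite(dist)
    isolated = finite.sum(axis=1) <= 1
    if isolated.any():
        warnings.warn(
            "some vertices have no neighbours within the 3-sigma kernel "
            "support (disconnected, or kernel narrower than edge spacing); "
            "their values are left unsmoothed",
            stacklevel=2,
        )
    w = np.where(finite, np.exp(-np.where(finite, dist, 0.0) ** 2 / (2 * sigma**2)), 0.0)
    w /= w.sum(axis=1, keepdims=True)
    return w @ values


def ar_process_autocov(phi: np.ndarray, sigma2: float, maxlag: int) -> np.ndarray:
    """Stationary autocovariances gamma(0..maxlag) of a causal AR(p)
    process, from the Yule-Walker relations run in reverse."""
    p = phi.size
    m = max(maxlag, p)
    # solve for gamma(0..p) from gamma(k) - sum_i phi_i gamma(|k-i|) = sigma2 * [k==0]
    A = np.zeros((p + 1, p + 1))
    for k in range(p + 1):
        A[k, k] += 1.0
        for i in range(1, p + 1):
            A[k, abs(k - i)] -= phi[i - 1]
    rhs = np.zeros(p + 1)
    rhs[0] = sigma2
    g = np.linalg.solve(A, rhs)
    out = np.zeros(m + 1)
    out[: p + 1] = g
    for k in range(p + 1, m + 1):
        out[k] = phi @ out[k - 1 : k - p - 1 : -1] if p else 0.0
    return out[: maxlag + 1]


def whitening_matrix_rows(phi: np.ndarray, sigma2: float, n_timepoints: int):
    """Rows of the banded lower-triangular whitening transform W with
    W Sigma W^T = I for an AR(p) noise covariance Sigma.

    Returns (W_head, ar_row): W_head whitens the first p samples (from
    the Cholesky factor of the leading covariance block); every later
    row applies the innovations filter (1, -phi) / sqrt(sigma2).
    """
    p = phi.size
    if p == 0 or not np.any(phi):
        head = np.eye(0)
        return head, np.array([1.0]) / np.sqrt(sigma2)
    g = ar_process_autocov(phi, sigma2, p - 1)
    Sigma_p = np.array([[g[abs(i - j)] for j in range(p)] for i in range(p)])
    L = cholesky(Sigma_p, lower=True)
    head = solve_triangular(L, np.eye(p), lower=True)
    ar_row = np.concatenate([-phi[::-1], [1.0]]) / np.sqrt(sigma2)
    return head, ar_row


def prewhiten(y: np.ndarray, X: np.ndarray, ar: ARModel) -> SessionData:
    """Prewhiten BOLD data and design with per-vertex AR models.

    Applies the banded square-root-precision (innovations) transform of
    each vertex's AR(p) noise model to both the data column and the
    design, then scales by the innovation standard deviation so whitened
    residual variance is one everywhere.  The output design is
    vertex-specific (N x T x K).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    T, N = y.shape
    K = X.shape[-1]
    p = ar.order
    causal = ar.is_causal()
    if not causal.all():
        raise ValueError(
            f"non-causal AR model at vertex {np.flatnonzero(~causal)[0]}"
        )
    yw = np.empty_like(y)
    Xw = np.empty((N, T, K))
    for v in range(N):
        phi = ar.coefs[v]
        s2 = ar.innovation_variance[v]
        head, ar_row = whitening_matrix_rows(phi, s2, T)
        Xv = X[v] if X.ndim == 3 else X
        both = np.column_stack([y[:, v], Xv])
        out = np.empty_like(both)
        q = head.shape[0]
        if q:
            out[:q] = head @ both[:q]
        # innovations filter for rows q..T-1
        acc = ar_row[-1] * both[q:]
        for lag in range(1, q + 1):
            acc = acc + ar_row[-1 - lag] * both[q - lag : T - lag]
        out[q:] = acc
        yw[:, v] = out[:, 0]
        Xw[v] = out[:, 1:]
    return SessionData(bold=yw, design=Xw)


def build_whitening_operator(phi: np.ndarray, sigma2: float, T: int) -> sp.csr_matrix:
    """Full T x T sparse whitening matrix (bandwidth p); mainly for
    testing and small problems."""
    head, ar_row = whitening_matrix_rows(phi, sigma2, T)
    p = head.shape[0]
    W = sp.lil_matrix((T, T))
    if p:
        W[:p, :p] = head
    for t in range(p, T):
        W[t, t - min(t, ar_row.size - 1) : t + 1] = ar_row[-(min(t, ar_row.size - 1) + 1):]
    return W.tocsr()
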