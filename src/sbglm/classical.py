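"""Massive-univariate (classical) GLM benchmark.

An independent least-squares fit at every vertex, one-sided t-tests of
``beta > gamma`` against an activation threshold gamma (percent signal
change), Bonferroni / Benjamini-Hochberg multiplicity correction within
hemisphere, and group analysis by averaging subject coefficient maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .preprocess import SessionData


@dataclass
class ClassicalFit:
    """Per-vertex OLS results: ``beta``/``se`` are N x K, ``dof`` the
    residual degrees of freedom (T - K - 1), ``valid`` marks vertices
    with full-rank designs."""

    beta: np.ndarray
    se: np.ndarray
    dof: int
    residual_variance: np.ndarray
    valid: np.ndarray
    task_names: list[str] | None = None


@dataclass
class ActivationMap:
    """Binary activation per vertex (and task) with its (gamma, alpha)
    provenance; ``method`` is 'bonferroni', 'fdr_bh' or 'excursion'."""

    active: np.ndarray
    gamma: float
    alpha: float
    method: str

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")


def fit_classical(session: SessionData) -> ClassicalFit:
    """Ordinary least squares per vertex.

    beta_v = (X_v'X_v)^{-1} X_v' y_v with standard errors from the
    residual variance on T - K - 1 degrees of freedom (the design is
    centred, so no intercept is fitted; the extra -1 keeps the
    conventional accounting).  Rank-deficient vertices are marked
    invalid and excluded from inference.
    """
    y = session.bold
    T, N = y.shape
    K = session.n_tasks
    dof = T - K - 1
    if dof < 1:
        raise ValueError("too few timepoints for the number of tasks")
    beta = np.zeros((N, K))
    se = np.zeros((N, K))
    resvar = np.zeros(N)
    valid = np.ones(N, dtype=bool)
    shared = session.design.ndim == 2
    if shared:
        X = session.design
        XtX = X.T @ X
        if np.linalg.matrix_rank(XtX) < K:
            raise ValueError("shared design matrix is rank deficient")
        XtX_inv = np.linalg.inv(XtX)
        beta = (XtX_inv @ (X.T @ y)).T
        resid = y - X @ beta.T
        resvar = np.einsum("tv,tv->v", resid, resid) / dof
        se = np.sqrt(np.outer(resvar, np.diag(XtX_inv)))
    else:
        for v in range(N):
            Xv = session.design[v]
            XtX = Xv.T @ Xv
            if np.linalg.matrix_rank(XtX) < K:
                valid[v] = False
                continue
            XtX_inv = np.linalg.inv(XtX)
            b = XtX_inv @ (Xv.T @ y[:, v])
            r = y[:, v] - Xv @ b
            rv = (r @ r) / dof
            beta[v] = b
            resvar[v] = rv
            se[v] = np.sqrt(rv * np.diag(XtX_inv))
    if not valid.all():
        warnings.warn(
            f"{np.count_nonzero(~valid)} vertices had rank-deficient designs",
            stacklevel=2,
        )
    return ClassicalFit(beta, se, dof, resvar, valid, list(session.task_names))


def activation_ttest(fit: ClassicalFit, gamma: float = 0.0) -> np.ndarray:
    """One-sided p-values for H0: beta <= gamma at each vertex/task.

    t = (beta_hat - gamma) / SE, p = upper tail of t_{T-K-1}.  Vertices
    with zero SE get p = 0 where beta_hat > gamma, else 1.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (fit.beta - gamma) / fit.se
    p = stats.t.sf(t, df=fit.dof)
    zero_se = fit.se == 0
    if zero_se.any():
        warnings.warn("zero standard error at some vertices", stacklevel=2)
        p = np.where(zero_se, np.where(fit.beta > gamma, 0.0, 1.0), p)
    p[~fit.valid] = np.nan
    return p


def correct_multiplicity(
    pvals: np.ndarray, alpha: float, method: str = "bonferroni", gamma: float = 0.0
) -> ActivationMap:
    """Familywise (Bonferroni) or FDR (Benjamini-Hochberg) correction.

    The denominator is the number of valid (non-NaN) vertices in the
    hemisphere being corrected; invalid vertices stay inactive.
    """
    if method not in ("bonferroni", "fdr_bh"):
        raise ValueError(f"unknown correction method {method!r}")
    p = np.asarray(pvals, dtype=float)
    flat = p.ravel()
    ok = ~np.isnan(flat)
    active = np.zeros(flat.size, dtype=bool)
    if ok.any():
        active[ok] = multipletests(flat[ok], alpha=alpha, method=method)[0]
    return ActivationMap(active.reshape(p.shape), gamma=gamma, alpha=alpha, method=method)


def group_classical(
    subject_betas: np.ndarray,
    gamma: float = 0.0,
    alpha: float = 0.01,
    method: str = "bonferroni",
) -> tuple[np.ndarray, np.ndarray, ActivationMap]:
    """Classical group analysis: average subject coefficient maps and
    test with a one-sample t against gamma (dof = M - 1, between-subject
    standard errors).

    ``subject_betas`` is M x N (one task) or M x N x K.  Returns
    (group mean, p-values, activation map).
    """
    b = np.asarray(subject_betas, dtype=float)
    M = b.shape[0]
    if M < 2:
        raise ValueError("group analysis requires at least two subjects")
    mean = b.mean(axis=0)
    sd = b.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - gamma) / (sd / np.sqrt(M))
    p = stats.t.sf(t, df=M - 1)
    p = np.where(sd == 0, np.where(mean > gamma, 0.0, 1.0), p)
    amap = correct_multiplicity(p, alpha=alpha, method=method, gamma=gamma)
    return mean, p, amap
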