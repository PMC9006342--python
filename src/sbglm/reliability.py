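"""Test-retest reliability metrics.

Reliability of amplitude estimates is summarised by the vertexwise
intraclass correlation coefficient (ICC) across two visits, with
negative values truncated to zero, and by MSE / Pearson correlation
against a reference map.  Reliability of activation maps is summarised
by the Dice overlap coefficient.
"""

from __future__ import annotations

import warnings

import numpy as np


def icc(B: np.ndarray) -> float:
    """Two-visit intraclass correlation at one vertex.

    ``B`` is M x 2 (subjects by repeated visits).  With population
    (1/n) variances:

        sigma_t^2 = (var(B[:, 0]) + var(B[:, 1])) / 2
        sigma_w^2 = var(B[:, 0] - B[:, 1]) / 2
        sigma_b^2 = sigma_t^2 - sigma_w^2
        ICC       = max(0, sigma_b^2 / sigma_t^2)

    Returns NaN (with a warning) when the total variance is zero.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[1] != 2 or B.shape[0] < 2:
        raise ValueError("B must be an M x 2 matrix with M >= 2")
    var = lambda x: float(np.mean((x - x.mean()) ** 2))  # noqa: E731
    sigma_t2 = 0.5 * (var(B[:, 0]) + var(B[:, 1]))
    if sigma_t2 == 0:
        warnings.warn("zero total variance: ICC undefined", stacklevel=2)
        return float("nan")
    sigma_w2 = 0.5 * var(B[:, 0] - B[:, 1])
    sigma_b2 = sigma_t2 - sigma_w2
    return max(0.0, sigma_b2 / sigma_t2)


def icc_map(estimates: np.ndarray) -> np.ndarray:
    """Vertexwise ICC from an M x 2 x N array of repeated estimates."""
    est = np.asarray(estimates, dtype=float)
    if est.ndim != 3 or est.shape[1] != 2:
        raise ValueError("estimates must be M x 2 x N")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return np.array([icc(est[:, :, v]) for v in range(est.shape[2])])


def icc_categories(icc_values: np.ndarray, mask: np.ndarray | None = None) -> dict:
    """Proportions of masked vertices with fair [0.4, 0.6), good
    [0.6, 0.75) and excellent [0.75, 1] ICC; NaN vertices are counted
    in the denominator but no bin."""
    v = np.asarray(icc_values, dtype=float)
    if mask is None:
        mask = np.ones(v.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must select at least one vertex")
    x = v[mask]
    denom = x.size
    return {
        "fair": float(np.count_nonzero((x >= 0.4) & (x < 0.6)) / denom),
        "good": float(np.count_nonzero((x >= 0.6) & (x < 0.75)) / denom),
        "excellent": float(np.count_nonzero(x >= 0.75) / denom),
        "n_undefined": int(np.count_nonzero(np.isnan(x))),
    }


def dice(A: np.ndarray, B: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|) of two binary maps; NaN
    (flagged) when both maps are empty."""
    A = np.asarray(A, dtype=bool)
    B = np.asarray(B, dtype=bool)
    if A.shape != B.shape:
        raise ValueError("masks must share the same vertex set")
    denom = int(A.sum()) + int(B.sum())
    if denom == 0:
        warnings.warn("both activation maps are empty: Dice undefined", stacklevel=2)
        return float("nan")
    return 2.0 * int((A & B).sum()) / denom


def mse_and_correlation(
    estimate: np.ndarray, reference: np.ndarray, mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Mean squared error and Pearson correlation of an estimate map
    against a reference map over masked vertices."""
    est = np.asarray(estimate, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if est.shape != ref.shape:
        raise ValueError("maps must share the same vertex set")
    if mask is None:
        mask = np.ones(est.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask must select at least one vertex")
    e, r = est[mask], ref[mask]
    mse = float(np.mean((e - r) ** 2))
    if np.ptp(r) == 0:
        warnings.warn("zero-variance reference: correlation undefined", stacklevel=2)
        return mse, float("nan")
    corr = float(np.corrcoef(e, r)[0, 1])
    return mse, corr
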