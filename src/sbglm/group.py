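"""Group-level inference from subject posteriors.

The group effect is a linear combination of subject-level fields:
beta_G = A beta with A = a' (x) I_N, where a is a weight vector over
(subject, run, task) blocks — e.g. the all-subject, cross-run average
of one task places weight 1/(J M) on that task in every (subject, run)
block.  Subjects are treated as independent given their fitted
posteriors (each at its own theta-hat), so the group posterior is
Gaussian with mean A mu and covariance A Sigma A' with Sigma
block-diagonal across subjects.  Group excursion sets are obtained by
passing the result to ``excursion_set``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bayes import DerivedField, FieldPosterior, LinearCombination, derive_field


@dataclass
class GroupContrast:
    """Weights over (subject, run, task) blocks; ``weights`` is
    (M, J, K).  Averages sum to one, between-group differences to
    zero."""

    weights: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 3:
            raise ValueError("weights must be (M, J, K)")
        if not np.any(self.weights):
            raise ValueError("contrast cannot be all zero")

    @property
    def flat(self) -> np.ndarray:
        """Length M*J*K contrast vector a (subject-major, run-major,
        task-minor)."""
        return self.weights.ravel()


def build_group_contrast(
    M: int,
    J: int,
    K: int,
    spec: str = "average",
    task: int = 0,
    groups: np.ndarray | None = None,
    custom: np.ndarray | None = None,
) -> GroupContrast:
    """Construct a group contrast.

    ``average``: weight 1/(J M) on ``task`` in every (subject, run)
    block (weights sum to 1).  ``difference``: +1/(J M1) for subjects
    with ``groups`` label 1 and -1/(J M0) for label 0 (weights sum to
    0).  ``custom``: explicit (M, J, K) weights.
    """
    if min(M, J, K) < 1:
        raise ValueError("M, J, K must all be at least 1")
    if spec == "average":
        w = np.zeros((M, J, K))
        w[:, :, task] = 1.0 / (J * M)
        return GroupContrast(w, label=f"task{task}-average")
    if spec == "difference":
        if groups is None:
            raise ValueError("difference contrast needs group labels")
        groups = np.asarray(groups)
        if groups.shape != (M,):
            raise ValueError("groups must have length M")
        w = np.zeros((M, J, K))
        n1 = np.count_nonzero(groups == 1)
        n0 = np.count_nonzero(groups == 0)
        if n1 == 0 or n0 == 0:
            raise ValueError("both groups must be nonempty")
        w[groups == 1, :, task] = 1.0 / (J * n1)
        w[groups == 0, :, task] = -1.0 / (J * n0)
        return GroupContrast(w, label=f"task{task}-group-difference")
    if spec == "custom":
        if custom is None:
            raise ValueError("custom contrast needs explicit weights")
        custom = np.asarray(custom, dtype=float)
        if custom.shape != (M, J, K):
            raise ValueError(f"custom weights must have shape ({M}, {J}, {K})")
        return GroupContrast(custom, label="custom")
    raise ValueError(f"unknown contrast spec {spec!r}")


def group_posterior(
    posteriors: Sequence[FieldPosterior], contrast: GroupContrast
) -> DerivedField:
    """Gaussian posterior of the group contrast field over data
    locations.

    Exact under the independence-across-subjects combination rule: the
    mean is the weighted sum of subject means, the variance adds across
    subjects, and joint samples draw every subject's posterior.
    """
    M = len(posteriors)
    if contrast.weights.shape[0] != M:
        raise ValueError("contrast subject dimension does not match posteriors")
    n_data = {p.ops.n_data for p in posteriors}
    n_mesh = {p.n_mesh for p in posteriors}
    if len(n_data) != 1 or len(n_mesh) != 1:
        raise ValueError("subjects must share the same mesh")

    parts: list[DerivedField] = []
    for m, post in enumerate(posteriors):
        w = contrast.weights[m]
        if post.n_runs != w.shape[0] or post.n_tasks != w.shape[1]:
            # zero-padded absent run blocks: only leading runs weighted
            if post.n_runs < w.shape[0] and np.any(w[post.n_runs :]):
                raise ValueError(
                    f"subject {m}: contrast weights nonzero for absent runs"
                )
            w = w[: post.n_runs, : post.n_tasks]
        if np.any(w):
            parts.append(derive_field(post, LinearCombination(w)))

    if not parts:
        raise ValueError("contrast gives zero weight to every subject")
    N = parts[0].mean.size
    mean = np.sum([p.mean for p in parts], axis=0)
    var = np.sum([p.marginal_variance for p in parts], axis=0)

    def sampler(rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.zeros((size, N))
        for p in parts:
            out += p.sample(rng, size)
        return out

    return DerivedField(mean=mean, marginal_variance=var, _sampler=sampler)
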