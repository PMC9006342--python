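"""Synthetic surface task-fMRI studies with known ground truth.

The generator emulates a motor-task block design in the style of the
HCP protocol: each task is presented as 12 s blocks preceded by 3 s
cues, repeated twice per run, with multiple runs, two visits and
multiple subjects.  True activation fields are spatially smooth Matérn
draws on the mesh; noise is a spatially varying AR(6) process; a
baseline is added so percent-signal-change scaling is exercised.

The variance decomposition is additive at the field level: each
subject's true field is a shared group field plus a subject-specific
Matérn deviation, and each visit's truth adds a visit-specific
deviation.  This makes the intraclass correlation of noiseless
estimates exactly subject_sd^2 / (subject_sd^2 + visit_sd^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import trimesh
from scipy.signal import lfilter

from .linalg import SparseCholesky
from .mesh import TriangularMesh
from .preprocess import BoldRun, TaskDesign, ar_process_autocov, build_design
from .spde import MaternHyperparams, SPDEOperators, build_fem_matrices, build_precision

#: causal, nonnegative AR(6) base coefficients (sum < 1) resembling the
#: slowly decaying residual autocorrelation of unsmoothed BOLD.
DEFAULT_AR_COEFS = (0.35, 0.15, 0.08, 0.05, 0.03, 0.02)


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the generator.

    Defaults follow the emulated protocol: TR 0.72 s, ~284 volumes,
    five tasks with two 12 s blocks (3 s cues) per run, two runs per
    visit, two visits.  The icosphere is scaled to 30 mm radius so the
    default Matérn range sqrt(8)/kappa ~ 9.4 mm spans several mesh
    edges (a level-3 icosphere then has ~4 mm edges).  Field scales are
    percent signal change.
    """

    mesh_kind: Literal["icosphere", "grid"] = "icosphere"
    mesh_size: int = 3
    radius_mm: float = 30.0
    grid_spacing_mm: float = 1.0
    medial_wall: bool = False
    n_tasks: int = 5
    n_runs: int = 2
    n_subjects: int = 1
    n_visits: int = 2
    repetition_time: float = 0.72
    n_timepoints: int = 284
    block_duration_s: float = 12.0
    cue_duration_s: float = 3.0
    blocks_per_task: int = 2
    kappa: float = 0.3
    field_sd: float = 1.0
    subject_sd: float = 0.5
    visit_sd: float = 0.25
    ar_coefs: tuple = DEFAULT_AR_COEFS
    ar_spatial_modulation: float = 0.2
    noise_sd: float = 1.0
    baseline: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_tasks, self.n_runs, self.n_subjects, self.n_visits) < 1:
            raise ValueError("counts must be at least 1")
        for name in ("field_sd", "subject_sd", "visit_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if sum(abs(c) for c in self.ar_coefs) * (1 + self.ar_spatial_modulation) >= 1:
            raise ValueError("AR coefficients too large to stay causal everywhere")
        total = self.trial_length_s * self.n_tasks * self.blocks_per_task + 8.0
        if total >= self.n_timepoints * self.repetition_time:
            raise ValueError("task blocks do not fit in the run")

    @property
    def trial_length_s(self) -> float:
        return self.cue_duration_s + self.block_duration_s

    def tau_for(self, sd: float) -> float:
        """tau giving a Matérn marginal standard deviation ``sd`` at
        this spec's kappa."""
        return 1.0 / (np.sqrt(4.0 * np.pi) * self.kappa * max(sd, 1e-12))


@dataclass
class GroundTruth:
    """Everything the generator knows: true fields (percent signal
    change) at every level of the hierarchy, AR coefficient fields and
    the resolved spec."""

    group_fields: np.ndarray  # (K, n_mesh)
    subject_fields: np.ndarray  # (M, K, n_mesh)
    visit_fields: np.ndarray  # (M, V, K, n_mesh)
    ar_coefs: np.ndarray  # (N_data, p)
    ar_innovation_sd: np.ndarray  # (N_data,)
    spec: SimulationSpec


@dataclass
class StudyData:
    """A simulated study: mesh + operators, per-subject/visit/run raw
    BOLD, the shared task design, and the ground truth."""

    mesh: TriangularMesh
    ops: SPDEOperators
    design: TaskDesign
    runs: list  # runs[m][v][j] -> BoldRun (raw units)
    truth: GroundTruth


# ---------------------------------------------------------------------------
# meshes
# ---------------------------------------------------------------------------


def make_mesh(
    kind: str,
    size: int,
    radius_mm: float = 100.0,
    grid_spacing_mm: float = 1.0,
    medial_wall: bool = False,
) -> TriangularMesh:
    """Construct a synthetic mesh.

    ``icosphere``: subdivision level ``size`` scaled to ``radius_mm``
    (level 3 has 642 vertices / 1280 faces).  ``grid``: a planar
    ``size`` x ``size`` right-triangle grid with spacing
    ``grid_spacing_mm``.  With ``medial_wall=True`` a padding layer is
    marked non-data: the outermost vertex ring of a grid, or a polar
    cap of the icosphere, emulating the medial wall.
    """
    if kind == "icosphere":
        ico = trimesh.creation.icosphere(subdivisions=size, radius=radius_mm)
        verts = np.asarray(ico.vertices, dtype=float)
        faces = np.asarray(ico.faces, dtype=np.int64)
        mask = np.ones(len(verts), dtype=bool)
        if medial_wall:
            mask = verts[:, 2] < radius_mm * np.cos(np.deg2rad(25.0))
    elif kind == "grid":
        g = size
        if g < 2:
            raise ValueError("grid size must be at least 2")
        xs = np.arange(g) * grid_spacing_mm
        xv, yv = np.meshgrid(xs, xs, indexing="ij")
        verts = np.column_stack([xv.ravel(), yv.ravel(), np.zeros(g * g)])
        faces = []
        for i in range(g - 1):
            for j in range(g - 1):
                a = i * g + j
                b = a + 1
                c = a + g
                d = c + 1
                faces.append([a, c, b])
                faces.append([b, c, d])
        faces = np.asarray(faces, dtype=np.int64)
        mask = np.ones(g * g, dtype=bool)
        if medial_wall:
            ij = np.stack(np.meshgrid(np.arange(g), np.arange(g), indexing="ij"), -1)
            border = (
                (ij[..., 0] == 0)
                | (ij[..., 0] == g - 1)
                | (ij[..., 1] == 0)
                | (ij[..., 1] == g - 1)
            )
            mask = ~border.ravel()
    else:
        raise ValueError(f"unsupported mesh kind {kind!r}")
    return TriangularMesh(verts, faces, mask)


def sample_matern_field(
    ops: SPDEOperators,
    hp: MaternHyperparams,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One exact draw from the GMRF prior N(0, Q^{-1}) over mesh
    vertices, via sparse factorisation of Q."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = build_precision(ops, hp)
    return SparseCholesky(Q).sample(rng, 1)[0]


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------


def make_task_timing(spec: SimulationSpec) -> tuple[dict, dict]:
    """Paced block timing: an 8 s lead-in, then cycles over all tasks;
    every trial is a cue followed by one task block, repeated
    ``blocks_per_task`` times."""
    onsets: dict[str, list[float]] = {f"task{k}": [] for k in range(spec.n_tasks)}
    durations: dict[str, list[float]] = {f"task{k}": [] for k in range(spec.n_tasks)}
    t = 8.0
    for _rep in range(spec.blocks_per_task):
        for k in range(spec.n_tasks):
            onsets[f"task{k}"].append(t + spec.cue_duration_s)
            durations[f"task{k}"].append(spec.block_duration_s)
            t += spec.trial_length_s
    return onsets, durations


def _ar_noise(
    rng: np.random.Generator,
    coefs: np.ndarray,
    innov_sd: np.ndarray,
    T: int,
) -> np.ndarray:
    """T x N AR noise with per-vertex coefficients, stationary start
    discarded via a burn-in."""
    N, p = coefs.shape
    burn = 10 * p if p else 0
    eps = rng.standard_normal((T + burn, N)) * innov_sd
    out = np.empty((T + burn, N))
    for v in range(N):
        out[:, v] = lfilter([1.0], np.concatenate([[1.0], -coefs[v]]), eps[:, v])
    return out[burn:]


def _smooth_unit_field(ops: SPDEOperators, spec: SimulationSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """A Matérn draw normalised to unit empirical sd (for modulating AR
    coefficient fields)."""
    f = sample_matern_field(ops, MaternHyperparams(spec.kappa, spec.tau_for(1.0)), rng)
    sd = f.std()
    return f / sd if sd > 0 else f


def simulate_study(spec: SimulationSpec, null: bool = False) -> StudyData:
    """Generate a full multi-subject, multi-visit, multi-run study.

    BOLD at data location v is
    ``baseline * (1 + (sum_k X[t,k] beta_k[v] + ar_noise[t,v]) / 100)``
    with X the finalised (max-scaled, centred) task design, so the
    true amplitudes are in percent-signal-change units.  With
    ``null=True`` all true fields are exactly zero.
    """
    rng = np.random.default_rng(spec.seed)
    mesh = make_mesh(
        spec.mesh_kind,
        spec.mesh_size,
        radius_mm=spec.radius_mm,
        grid_spacing_mm=spec.grid_spacing_mm,
        medial_wall=spec.medial_wall,
    )
    ops = build_fem_matrices(mesh)
    n = mesh.n_vertices
    data_idx = mesh.data_indices
    N = data_idx.size
    K, M, V, J = spec.n_tasks, spec.n_subjects, spec.n_visits, spec.n_runs
    T = spec.n_timepoints

    onsets, durations = make_task_timing(spec)
    design = build_design(onsets, durations, T, spec.repetition_time)

    def draw(sd: float) -> np.ndarray:
        if sd == 0 or null:
            return np.zeros(n)
        return sample_matern_field(
            ops, MaternHyperparams(spec.kappa, spec.tau_for(sd)), rng
        )

    group = np.stack([draw(spec.field_sd) for _ in range(K)])
    subject = np.stack(
        [[group[k] + draw(spec.subject_sd) for k in range(K)] for _ in range(M)]
    )
    visit = np.stack(
        [
            [[subject[m, k] + draw(spec.visit_sd) for k in range(K)] for _ in range(V)]
            for m in range(M)
        ]
    )

    base = np.asarray(spec.ar_coefs, dtype=float)
    if base.size and spec.ar_spatial_modulation > 0:
        mod = _smooth_unit_field(ops, spec, rng)[data_idx]
        mod = np.clip(mod, -2.0, 2.0) * spec.ar_spatial_modulation / 2.0
        ar_coefs = base[None, :] * (1.0 + mod[:, None])
    else:
        ar_coefs = np.tile(base, (N, 1))
    # innovation sd chosen so the stationary process sd equals noise_sd
    innov_sd = np.empty(N)
    for v in range(N):
        g0 = ar_process_autocov(ar_coefs[v], 1.0, 0)[0] if base.size else 1.0
        innov_sd[v] = spec.noise_sd / np.sqrt(g0)

    X = design.task_matrix
    runs: list = []
    for m in range(M):
        per_subject = []
        for vi in range(V):
            per_visit = []
            signal = X @ visit[m, vi][:, data_idx]  # (T, N), percent units
            for _j in range(J):
                noise = (
                    _ar_noise(rng, ar_coefs, innov_sd, T)
                    if spec.noise_sd > 0
                    else np.zeros((T, N))
                )
                raw = spec.baseline * (1.0 + (signal + noise) / 100.0)
                per_visit.append(
                    BoldRun(raw, spec.repetition_time, vertex_ids=data_idx)
                )
            per_subject.append(per_visit)
        runs.append(per_subject)

    truth = GroundTruth(
        group_fields=group,
        subject_fields=subject,
        visit_fields=visit,
        ar_coefs=ar_coefs,
        ar_innovation_sd=innov_sd,
        spec=spec,
    )
    return StudyData(mesh=mesh, ops=ops, design=design, runs=runs, truth=truth)


def simulate_null(spec: SimulationSpec) -> StudyData:
    """A study whose true activation fields are all exactly zero."""
    return simulate_study(spec, null=True)
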