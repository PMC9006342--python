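"""Pipeline configuration: a validated YAML-backed schema.

Unknown keys are rejected so that typos fail before any computation.
Defaults follow the analysis settings of the implemented protocol:
alpha 0.01, activation thresholds gamma = 0, 0.5, 1 percent signal
change, AR order 6, 6 mm FWHM smoothing of AR parameters.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class HrfConfig(_Strict):
    peak_shape: float = 6.0
    peak_scale: float = 1.0
    undershoot_shape: float = 16.0
    undershoot_scale: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    total_length_s: float = 32.0


class ArConfig(_Strict):
    order: int = Field(6, ge=0)


class SmoothingConfig(_Strict):
    fwhm_mm: float = Field(6.0, ge=0)


class ScalingConfig(_Strict):
    percent: bool = True


class PriorConfig(_Strict):
    log_kappa_mean: float = 0.0
    log_kappa_sd: float = 10.0
    log_tau_mean: float = 0.0
    log_tau_sd: float = 10.0
    noise_precision_shape: float = 1.0
    noise_precision_rate: float = 5e-5


class SimulationConfig(_Strict):
    mesh_kind: str = "icosphere"
    mesh_size: int = 2
    radius_mm: float = 30.0
    medial_wall: bool = False
    n_tasks: int = 2
    n_runs: int = 2
    n_subjects: int = 1
    n_visits: int = 2
    n_timepoints: int = 284
    repetition_time: float = 0.72
    kappa: float = 0.3
    field_sd: float = 1.0
    subject_sd: float = 0.5
    visit_sd: float = 0.25
    noise_sd: float = 1.0


class PipelineConfig(_Strict):
    """Top-level configuration for ``run_pipeline`` and the CLI."""

    output_dir: str = "sbglm_out"
    surface: str | None = None
    bold: list[str] = Field(default_factory=list)
    events: str | None = None
    motion: list[str] = Field(default_factory=list)
    gamma: list[float] = Field(default_factory=lambda: [0.0, 0.5, 1.0])
    alpha: float = Field(0.01, gt=0, lt=1)
    correction: str = "bonferroni"
    n_excursion_samples: int = Field(10_000, ge=1000)
    seed: int = 0
    task_hemisphere_exclusions: dict[str, list[str]] = Field(default_factory=dict)
    hrf: HrfConfig = Field(default_factory=HrfConfig)
    ar: ArConfig = Field(default_factory=ArConfig)
    smoothing: SmoothingConfig = Field(default_factory=SmoothingConfig)
    scaling: ScalingConfig = Field(default_factory=ScalingConfig)
    prior: PriorConfig = Field(default_factory=PriorConfig)
    simulation: SimulationConfig = Field(default_factory=SimulationConfig)


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(raw)


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)
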