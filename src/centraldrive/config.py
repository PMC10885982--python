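"""Run configuration: schema-validated YAML for the end-to-end pipeline.

Unknown keys are rejected so a typo in a threshold name fails loudly
instead of silently running with defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .qc import QcConfig
from .simulate import CohortConfig, GroupParams, WalkConfig, TABLE1_GROUPS

__all__ = ["FilterSettings", "QcSettings", "RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterSettings(_Strict):
    cutoff_hz: float = 10.0
    order: int = 4
    zero_phase: bool = True
    post_window_s: float = 0.5


class QcSettings(_Strict):
    variance_threshold: float = 0.1
    steady_slope_threshold: float = 2.0
    steady_window_s: float = 0.5
    submax_ratio: float = 0.90
    mvc_acceptance_ratio: float = 0.95
    max_mvc_attempts: int = 3
    submax_excludes: bool = True

    def to_qc_config(self) -> QcConfig:
        return QcConfig(**self.model_dump())


class GroupSettings(_Strict):
    mfga_mean: float
    mfga_sd: float
    true_cd_mean: float
    true_cd_sd: float


class WalkSettings(_Strict):
    total_mean: float = 321.0
    total_signal_sd: float = 70.0
    total_noise_sd: float = 75.0
    cd_center: float = 0.68
    cd_scale: float = 0.25
    pct_mean: float = -3.0
    pct_signal_sd: float = 9.0
    pct_noise_sd: float = 12.0
    minute_jitter_sd: float = 2.0


def _default_groups() -> dict[str, GroupSettings]:
    return {
        name: GroupSettings(
            mfga_mean=g.mfga_mean,
            mfga_sd=g.mfga_sd,
            true_cd_mean=g.true_cd_mean,
            true_cd_sd=g.true_cd_sd,
        )
        for name, g in TABLE1_GROUPS.items()
    }


class CohortSettings(_Strict):
    n_neurotypical: int = 16
    n_stroke: int = 26
    groups: dict[str, GroupSettings] = Field(default_factory=_default_groups)
    effort_levels: tuple[float, ...] = (0.25, 0.50, 0.75)
    trials_per_submax_level: int = 2
    mvc_trials_exp2: int = 3
    efficacy_range: tuple[float, float] = (0.6, 0.9)
    pw_sat_range: tuple[float, float] = (350.0, 600.0)
    noise_sd: float = 0.35
    device_b_offset_mean: float = 3.7
    device_b_offset_sd: float = 6.64
    device_b_gain_mean: float = 1.0
    device_b_gain_sd: float = 0.0
    qc_violation_rate: float = 0.0
    walk: WalkSettings = Field(default_factory=WalkSettings)

    def to_cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_neurotypical=self.n_neurotypical,
            n_stroke=self.n_stroke,
            groups={
                name: GroupParams(**g.model_dump()) for name, g in self.groups.items()
            },
            effort_levels=self.effort_levels,
            trials_per_submax_level=self.trials_per_submax_level,
            mvc_trials_exp2=self.mvc_trials_exp2,
            efficacy_range=self.efficacy_range,
            pw_sat_range=self.pw_sat_range,
            noise_sd=self.noise_sd,
            device_b_offset_mean=self.device_b_offset_mean,
            device_b_offset_sd=self.device_b_offset_sd,
            device_b_gain_mean=self.device_b_gain_mean,
            device_b_gain_sd=self.device_b_gain_sd,
            qc_violation_rate=self.qc_violation_rate,
            walk=WalkConfig(**self.walk.model_dump()),
        )


class RunConfig(_Strict):
    """Top-level pipeline configuration (see module docstring)."""

    seed: int = 0
    experiment: str = "exp2"  # exp1 | exp2
    filter: FilterSettings = Field(default_factory=FilterSettings)
    qc: QcSettings = Field(default_factory=QcSettings)
    cohort: CohortSettings = Field(default_factory=CohortSettings)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (defaults when absent)."""
    if path is None:
        return RunConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig.model_validate(data)
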