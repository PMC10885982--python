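"""Trial-validity rules and per-participant aggregation.

A burst-superimposition trial is only usable when the stimulation was
delivered on a steady voluntary plateau.  The rules here automate that
judgement: a variance ceiling on the 100-ms pre-burst window, a slope
ceiling (stimulation on a rising/falling torque recruits or derecruits
motor units and biases the post-burst peak), a check that the pre-burst
torque had not dropped below 90% of the within-trial peak, and the
MVC-acceptance rule requiring voluntary torque to reach 95% of MFGA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .processing import TrialMeasurement

__all__ = [
    "QcConfig",
    "variance_flag",
    "steady_state_flag",
    "submax_flag",
    "mvc_acceptance",
    "aggregate_participant",
    "ParticipantAggregate",
]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for trial quality control.

    variance_threshold
        Sample-variance ceiling for the 100-ms pre-burst window,
        (ft-lbs)^2.  Trials above it are flagged ``high_variance``.
    steady_slope_threshold
        Absolute OLS-slope ceiling for the pre-burst steadiness window,
        ft-lbs/s.  Automates the "torque visibly increasing or
        decreasing" exclusion.
    steady_window_s
        Length of the pre-burst window the slope is fitted over.  A
        visual steadiness judgement integrates over an appreciable
        stretch of the plateau; 0.5 s keeps the slope estimate's noise
        floor well under the threshold (over 100 ms the OLS slope SE
        would be an order of magnitude larger).
    submax_ratio
        Pre-burst voluntary torque must be at least this fraction of the
        within-trial pre-burst peak (guards against a peak-then-drop-off).
    mvc_acceptance_ratio
        Fraction of MFGA the voluntary effort must reach for an MVC test
        to count as a true estimate of MFGA.
    max_mvc_attempts
        MVC tests are repeated up to this many times before dismissal.
    submax_excludes
        Whether a ``submax_90`` flag invalidates the trial (default) or is
        only recorded.
    """

    variance_threshold: float = 0.1
    steady_slope_threshold: float = 2.0
    steady_window_s: float = 0.5
    submax_ratio: float = 0.90
    mvc_acceptance_ratio: float = 0.95
    max_mvc_attempts: int = 3
    submax_excludes: bool = True

    def __post_init__(self) -> None:
        if self.variance_threshold <= 0 or self.steady_slope_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.steady_window_s <= 0:
            raise ValueError("steady_window_s must be positive")
        for r in (self.submax_ratio, self.mvc_acceptance_ratio):
            if not (0 < r <= 1):
                raise ValueError("ratios must lie in (0, 1]")
        if self.max_mvc_attempts < 1:
            raise ValueError("max_mvc_attempts must be >= 1")


def _check_window(window: np.ndarray) -> np.ndarray:
    window = np.asarray(window, dtype=float)
    if window.size < 2:
        raise ValueError("pre-burst window must contain at least 2 samples")
    return window


def variance_flag(window: np.ndarray, config: QcConfig = QcConfig()) -> bool:
    """True iff the sample variance (ddof=1) exceeds the threshold (strict)."""
    window = _check_window(window)
    return bool(np.var(window, ddof=1) > config.variance_threshold)


def steady_state_flag(
    window: np.ndarray, sampling_rate: float, config: QcConfig = QcConfig()
) -> bool:
    """True (nonsteady) iff |OLS slope of torque vs time| exceeds the threshold.

    The comparison is strict: a ramp exactly at the threshold passes
    (a tiny relative guard absorbs least-squares rounding at the
    boundary).
    """
    window = _check_window(window)
    t = np.arange(window.size) / sampling_rate
    slope = np.polyfit(t, window, 1)[0]
    threshold = config.steady_slope_threshold
    return bool(abs(slope) > threshold * (1.0 + 1e-9))


def submax_flag(
    f_vol: float, pre_burst_peak: float, config: QcConfig = QcConfig()
) -> bool:
    """True iff f_vol fell (strictly) below ``submax_ratio`` x pre-burst peak."""
    if pre_burst_peak <= 0:
        raise ValueError("pre_burst_peak must be positive")
    return bool(f_vol < config.submax_ratio * pre_burst_peak)


def mvc_acceptance(f_vol: float, mfga: float, config: QcConfig = QcConfig()) -> bool:
    """True iff the voluntary effort reached ``mvc_acceptance_ratio`` x MFGA."""
    if mfga <= 0:
        raise ValueError("mfga must be positive")
    return bool(f_vol >= config.mvc_acceptance_ratio * mfga)


@dataclass(frozen=True)
class ParticipantAggregate:
    """Per-limb averages over the valid trials of one participant."""

    f_vol_mean: float | None
    f_stim_mean: float | None
    n_valid: int
    n_total: int
    limb: str = ""


def aggregate_participant(
    trials: Iterable["TrialMeasurement"], limb: str = ""
) -> ParticipantAggregate:
    """Average F_vol and F_stim across valid trials only.

    A participant-limb with zero valid trials is a reportable state (the
    means are absent), not an error; downstream analyses exclude it.
    """
    trials = list(trials)
    valid = [t for t in trials if t.valid]
    if valid:
        f_vol = float(np.mean([t.f_vol for t in valid]))
        f_stim = float(np.mean([t.f_stim for t in valid]))
    else:
        f_vol = f_stim = None
    return ParticipantAggregate(
        f_vol_mean=f_vol,
        f_stim_mean=f_stim,
        n_valid=len(valid),
        n_total=len(trials),
        limb=limb,
    )
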