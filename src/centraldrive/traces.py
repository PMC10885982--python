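"""Torque-trace data model and file I/O.

The pipeline's native signal is an isometric plantarflexion torque trace
sampled at 1 kHz with a binary stimulation-trigger channel marking the
superimposed electrical burst.  Torque is carried in ft-lbs throughout
(the unit every downstream statistic is reported in); :func:`convert_torque`
is provided for interchange but never applied implicitly.

Conventions (fixed so burst-relative windows are reproducible):

* sample indices are 0-based; the time of sample ``i`` is ``i / sampling_rate``
* windows are half-open ``[start, end)``
* burst onset is the index of the first trigger sample equal to 1
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TorqueTrace",
    "TraceFormatError",
    "BurstSpec",
    "WalkTestRecord",
    "read_trace",
    "write_trace",
    "convert_torque",
    "FTLB_TO_NM",
]

#: Exact definition of the foot-pound force in newton-metres.
FTLB_TO_NM = 1.3558179483314004

_TRACE_COLUMNS = ("time_s", "torque_ftlb", "stim_trigger")


class TraceFormatError(ValueError):
    """A trace file or trace object violates the trace-CSV contract."""


def _trigger_runs(trigger: np.ndarray) -> list[tuple[int, int]]:
    """Return [start, end) bounds of each contiguous run of 1s."""
    on = np.flatnonzero(trigger == 1)
    if on.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(on) > 1)
    starts = np.concatenate(([on[0]], on[breaks + 1]))
    ends = np.concatenate((on[breaks] + 1, [on[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))


@dataclass(frozen=True)
class TraceMeta:
    """Trial metadata attached to a torque trace."""

    participant_id: str = ""
    device: str = ""
    limb: str = ""  # dominant | paretic | non-paretic | neurotypical
    trial: str = ""
    target_effort: float | None = None  # fraction of MFGA: 0.25/0.50/0.75/1.00


@dataclass(frozen=True)
class TorqueTrace:
    """A sampled torque signal plus stimulation-trigger channel.

    Invariants enforced at construction: equal channel lengths, finite
    torque, binary trigger with at most one contiguous run of 1s (the
    burst), and a positive sampling rate.
    """

    samples: np.ndarray
    trigger: np.ndarray
    sampling_rate: float
    meta: TraceMeta = field(default_factory=TraceMeta)

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        trigger = np.asarray(self.trigger, dtype=int)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "trigger", trigger)
        if samples.ndim != 1 or trigger.ndim != 1:
            raise TraceFormatError("samples and trigger must be 1-D")
        if samples.size == 0:
            raise TraceFormatError("empty trace")
        if trigger.shape != samples.shape:
            raise TraceFormatError(
                f"trigger length {trigger.size} != samples length {samples.size}"
            )
        if not self.sampling_rate > 0:
            raise TraceFormatError("sampling_rate must be positive")
        if not np.all(np.isfinite(samples)):
            raise TraceFormatError("non-finite torque values")
        if not np.isin(trigger, (0, 1)).all():
            raise TraceFormatError("trigger values must be 0 or 1")
        if len(_trigger_runs(trigger)) > 1:
            raise TraceFormatError("multiple trigger runs")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.sampling_rate

    def burst_run(self) -> tuple[int, int] | None:
        """[start, end) of the trigger run, or None if no burst was marked."""
        runs = _trigger_runs(self.trigger)
        return runs[0] if runs else None

    def with_samples(self, samples: np.ndarray) -> "TorqueTrace":
        """Copy of this trace with replaced torque samples (trigger kept)."""
        return dataclasses.replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class BurstSpec:
    """Stimulation-burst parameters for burst-superimposition testing.

    Defaults are the supramaximal burst used for central-drive tests:
    150 ms at 100 Hz and 150 mA (15 biphasic pulses); pulse width is
    individualized per participant by the twitch-ramp protocol.
    """

    duration_ms: float = 150.0
    frequency_hz: float = 100.0
    amplitude_ma: float = 150.0
    pulse_width_us: float = 500.0

    def __post_init__(self) -> None:
        if not (50 <= self.pulse_width_us <= 600):
            raise ValueError("pulse_width_us must lie in [50, 600]")
        if self.duration_ms <= 0 or self.frequency_hz <= 0:
            raise ValueError("duration and frequency must be positive")

    @property
    def n_pulses(self) -> int:
        return int(round(self.duration_ms * self.frequency_hz / 1000.0))


@dataclass(frozen=True)
class WalkTestRecord:
    """Six-minute walk test: per-minute distances and derived outcomes.

    ``pct_delta_speed`` is the distance-induced change in walking speed:
    positive values mean the participant sped up between the first and
    sixth minutes.
    """

    minute_distances: tuple[float, ...]
    total_distance: float
    pct_delta_speed: float

    def __post_init__(self) -> None:
        if len(self.minute_distances) != 6:
            raise ValueError("exactly 6 minute distances required")
        if any(d < 0 for d in self.minute_distances):
            raise ValueError("minute distances must be nonnegative")
        if not np.isclose(self.total_distance, sum(self.minute_distances)):
            raise ValueError("total_distance inconsistent with minute distances")

    @classmethod
    def from_minutes(cls, minute_distances: Sequence[float]) -> "WalkTestRecord":
        d = tuple(float(x) for x in minute_distances)
        if len(d) != 6:
            raise ValueError("exactly 6 minute distances required")
        if d[0] <= 0:
            raise ValueError("first-minute distance must be positive")
        pct = 100.0 * (d[5] - d[0]) / d[0]
        return cls(minute_distances=d, total_distance=float(sum(d)), pct_delta_speed=pct)


def read_trace(path: str | Path, *, dt_tolerance: float = 0.01,
               meta: TraceMeta | None = None) -> TorqueTrace:
    """Read a trace CSV (columns ``time_s, torque_ftlb, stim_trigger``).

    The sampling rate is inferred from the median time step and checked
    for uniformity: any step deviating from the median by more than
    ``dt_tolerance`` (relative) is a format error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise TraceFormatError(f"{path}: at least 2 samples required")
    dt = np.diff(t)
    dt_med = float(np.median(dt))
    if dt_med <= 0:
        raise TraceFormatError(f"{path}: non-increasing time stamps")
    if np.any(np.abs(dt - dt_med) > dt_tolerance * dt_med):
        raise TraceFormatError(f"{path}: non-uniform sampling beyond {dt_tolerance:.0%}")
    return TorqueTrace(
        samples=df["torque_ftlb"].to_numpy(dtype=float),
        trigger=df["stim_trigger"].to_numpy(),
        sampling_rate=1.0 / dt_med,
        meta=meta or TraceMeta(),
    )


def write_trace(trace: TorqueTrace, path: str | Path) -> Path:
    """Write a trace to CSV with time stamps ``i / sampling_rate`` from 0."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": trace.times,
            "torque_ftlb": trace.samples,
            "stim_trigger": trace.trigger,
        }
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path


# size of one unit, expressed in N·m
_UNITS = {"ft-lb": FTLB_TO_NM, "N·m": 1.0, "Nm": 1.0}


def convert_torque(value: float, from_unit: str, to_unit: str) -> float:
    """Convert torque between ``ft-lb`` and ``N·m`` (exact constant)."""
    try:
        f, t = _UNITS[from_unit], _UNITS[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown torque unit: {exc.args[0]!r}") from None
    return value if f == t else value * f / t
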