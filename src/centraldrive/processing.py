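"""Torque-trace filtering and burst-superimposition feature extraction.

Processing follows the standard burst-superimposition workflow: torque is
low-pass filtered at 10 Hz (fourth-order Butterworth), the burst onset is
read from the trigger channel, the voluntary torque F_vol is the mean over
the 100 ms immediately preceding the burst, and the stimulation-elicited
torque F_stim is the peak following burst onset.

Filtering is zero-phase by default (forward-backward application of a
second-order design, giving a fourth-order magnitude response) so that
filtering does not shift features relative to the burst-locked windows;
a causal single-pass fourth-order variant is available via
``zero_phase=False``.

One subtlety: a zero-phase filter is non-causal, so the sharp evoked
torque rise leaks *backward* into the 100-ms pre-burst window (the
filter kernel has ~100-ms support at a 10-Hz cutoff).  F_vol is barely
biased by this, but the pre-burst steadiness and variance checks are
sensitive to the leaked ringing.  QC quantities are therefore computed
on a causally filtered copy of the trace, which by construction cannot
be contaminated by anything at or after burst onset; the feature values
F_vol/F_stim keep the zero-phase path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .qc import QcConfig, steady_state_flag, submax_flag, variance_flag
from .traces import TorqueTrace

__all__ = [
    "TrialMeasurement",
    "lowpass_filter",
    "detect_burst_onset",
    "extract_fvol",
    "extract_fstim",
    "summarize_trial",
    "FVOL_WINDOW_S",
]

#: Length of the pre-burst averaging window for F_vol (s).
FVOL_WINDOW_S = 0.1


@dataclass(frozen=True)
class TrialMeasurement:
    """Extracted quantities and QC verdict for one burst-superimposition trial.

    ``f_vol``/``f_stim`` are NaN when the trace carries no burst marker
    (flag ``no_burst``), since the burst-relative windows are undefined.
    """

    f_vol: float
    f_stim: float
    pre_burst_variance: float
    pre_burst_slope: float
    pre_burst_peak: float
    flags: frozenset[str] = field(default_factory=frozenset)
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return not self.flags

    def to_dict(self) -> dict:
        return {
            "f_vol": None if np.isnan(self.f_vol) else self.f_vol,
            "f_stim": None if np.isnan(self.f_stim) else self.f_stim,
            "pre_burst_variance": _none_if_nan(self.pre_burst_variance),
            "pre_burst_slope": _none_if_nan(self.pre_burst_slope),
            "pre_burst_peak": _none_if_nan(self.pre_burst_peak),
            "flags": sorted(self.flags),
            "valid": self.valid,
            **self.meta,
        }


def _none_if_nan(x: float):
    return None if np.isnan(x) else float(x)


def lowpass_filter(
    trace: TorqueTrace,
    cutoff_hz: float = 10.0,
    order: int = 4,
    zero_phase: bool = True,
) -> TorqueTrace:
    """Low-pass Butterworth filter of the torque channel (trigger untouched).

    With ``zero_phase`` the filter is applied forward and backward
    (``order``/2 poles per pass), giving zero phase lag and the full
    ``order``-pole magnitude response.  Edges are handled by reflect
    padding to avoid startup transients.
    """
    nyquist = trace.sampling_rate / 2.0
    if not (0 < cutoff_hz < nyquist):
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist})")
    if len(trace) <= 3 * order:
        raise ValueError("trace too short to filter")
    if zero_phase:
        if order % 2:
            raise ValueError("zero-phase filtering requires an even order")
        b, a = sps.butter(order // 2, cutoff_hz, fs=trace.sampling_rate)
        padlen = min(3 * max(len(a), len(b)), len(trace) - 1)
        filtered = sps.filtfilt(b, a, trace.samples, padtype="even", padlen=padlen)
    else:
        b, a = sps.butter(order, cutoff_hz, fs=trace.sampling_rate)
        filtered = sps.lfilter(b, a, trace.samples)
    return trace.with_samples(filtered)


def detect_burst_onset(trace: TorqueTrace) -> int | None:
    """Index of the first trigger sample of the burst, or None if no burst.

    The trace invariant guarantees at most one contiguous trigger run;
    more than one is a format error raised at construction.
    """
    run = trace.burst_run()
    return None if run is None else run[0]


def _fvol_window(trace: TorqueTrace, onset: int) -> np.ndarray:
    n = int(round(FVOL_WINDOW_S * trace.sampling_rate))
    if onset < n:
        raise ValueError(
            f"insufficient pre-burst data: onset {onset} < {n} samples (100 ms)"
        )
    return trace.samples[onset - n : onset]


def extract_fvol(trace: TorqueTrace, onset: int) -> float:
    """Mean torque over the 100 ms before burst onset: window [onset-0.1s, onset)."""
    return float(np.mean(_fvol_window(trace, onset)))


def extract_fstim(trace: TorqueTrace, onset: int, post_window_s: float = 0.5) -> float:
    """Peak torque in the window [onset, onset + post_window_s) after the burst."""
    n = int(round(post_window_s * trace.sampling_rate))
    if onset + n > len(trace):
        raise ValueError(
            f"trace too short after onset: need {n} samples, have {len(trace) - onset}"
        )
    return float(np.max(trace.samples[onset : onset + n]))


def summarize_trial(
    trace: TorqueTrace,
    qc_config: QcConfig = QcConfig(),
    *,
    cutoff_hz: float = 10.0,
    filter_order: int = 4,
    zero_phase: bool = True,
    post_window_s: float = 0.5,
    apply_filter: bool = True,
) -> TrialMeasurement:
    """Filter once, locate the burst, extract F_vol/F_stim, and apply QC.

    Deterministic for a fixed trace and configuration.  ``apply_filter``
    exists for already-filtered (or noiseless) input.
    """
    meta = {
        "participant_id": trace.meta.participant_id,
        "device": trace.meta.device,
        "limb": trace.meta.limb,
        "trial": trace.meta.trial,
        "post_window_s": post_window_s,
    }
    if apply_filter:
        filtered = lowpass_filter(trace, cutoff_hz, filter_order, zero_phase)
        # causal pass for pre-burst QC: no backward leakage from the burst
        qc_trace = (
            lowpass_filter(trace, cutoff_hz, filter_order, zero_phase=False)
            if zero_phase
            else filtered
        )
    else:
        filtered = qc_trace = trace
    onset = detect_burst_onset(filtered)
    if onset is None:
        return TrialMeasurement(
            f_vol=np.nan,
            f_stim=np.nan,
            pre_burst_variance=np.nan,
            pre_burst_slope=np.nan,
            pre_burst_peak=np.nan,
            flags=frozenset({"no_burst"}),
            meta=meta,
        )
    window = _fvol_window(filtered, onset)
    f_vol = float(np.mean(window))
    f_stim = extract_fstim(filtered, onset, post_window_s)
    pre_peak = float(np.max(filtered.samples[:onset]))
    qc_window = _fvol_window(qc_trace, onset)
    n_steady = int(round(qc_config.steady_window_s * qc_trace.sampling_rate))
    steady_window = qc_trace.samples[max(0, onset - n_steady) : onset]
    t = np.arange(steady_window.size) / qc_trace.sampling_rate
    slope = float(np.polyfit(t, steady_window, 1)[0])

    flags: set[str] = set()
    if variance_flag(qc_window, qc_config):
        flags.add("high_variance")
    if steady_state_flag(steady_window, qc_trace.sampling_rate, qc_config):
        flags.add("nonsteady")
    if pre_peak > 0 and submax_flag(f_vol, pre_peak, qc_config):
        if qc_config.submax_excludes:
            flags.add("submax_90")
        else:
            meta["submax_90_noted"] = True
    return TrialMeasurement(
        f_vol=f_vol,
        f_stim=f_stim,
        pre_burst_variance=float(np.var(qc_window, ddof=1)),
        pre_burst_slope=slope,
        pre_burst_peak=pre_peak,
        flags=frozenset(flags),
        meta=meta,
    )
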