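"""Synthetic torque-trace and cohort generator with ground-truth labels.

The generator emulates the burst-superimposition protocol end to end so
every downstream stage can be tested against known truth:

* a voluntary contraction ramps smoothly to a plateau at
  ``effort x true_cd_max x MFGA`` ft-lbs;
* a supramaximal burst (150 ms, 100 Hz) is superimposed once torque is
  steady; the evoked torque rises with an S-shaped critically damped
  second-order response (tau = 30 ms; evoked force develops with zero
  initial slope) toward ``F_vol + k (MFGA - F_vol)`` while the burst is
  on and decays first-order (tau = 150 ms) afterwards, after a short
  electromechanical delay;
* the stimulator-efficacy parameter ``k`` in (0, 1] is the single
  mechanism producing central-drive overestimation: the measured ratio
  F_vol/F_stim exceeds the true ratio F_vol/MFGA whenever k < 1, which
  is exactly the systematic error the adjustment equation corrects;
* twitch torque at rest grows linearly with pulse width and saturates
  at a participant-specific width in [350, 600] us;
* two devices may differ by a small gain/offset;
* cohort parameters default to the three limb groups' published
  means/SDs, and six-minute-walk distances are generated so that total
  distance and the distance-induced speed change correlate with paretic
  central drive at realistic strength.

All randomness flows from one seed through per-participant/trial
``SeedSequence`` spawns, so cohorts are bitwise reproducible.

Every generated trial carries a :class:`GroundTruth` record whose
``f_vol``/``f_stim`` are computed from the noiseless sampled waveform,
making exact (to float precision) pipeline-vs-truth comparisons possible
at zero noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .traces import BurstSpec, TorqueTrace, TraceMeta
from .adjustment import measured_cd as _measured_cd

__all__ = [
    "DeviceModel",
    "ParticipantParams",
    "GroupParams",
    "WalkConfig",
    "CohortConfig",
    "GroundTruth",
    "SimulatedTrial",
    "Experiment1Result",
    "Exp2Limb",
    "Exp2Cohort",
    "simulate_twitch_ramp",
    "select_pulse_duration",
    "simulate_trial",
    "simulate_experiment1",
    "simulate_cohort_exp2",
    "TABLE1_GROUPS",
]

SAMPLING_RATE = 1000.0


@dataclass(frozen=True)
class DeviceModel:
    """Linear measurement model of one device: reading = gain * torque + offset."""

    label: str = "cedrs"
    gain: float = 1.0
    offset: float = 0.0


@dataclass(frozen=True)
class ParticipantParams:
    """Ground-truth physiology of one simulated participant-limb."""

    id: str
    group: str  # neurotypical | post-stroke
    limb: str  # dominant | paretic | non-paretic | neurotypical
    mfga: float  # true maximum force-generating ability, ft-lbs
    true_cd_max: float  # volitional ceiling F_vol_max / MFGA, in (0, 1]
    efficacy_k: float  # fraction of the F_vol->MFGA gap the burst elicits
    pw_sat: float = 450.0  # twitch saturation pulse width, us
    noise_sd: float = 0.35  # measurement noise, ft-lbs

    def __post_init__(self) -> None:
        if self.mfga <= 0:
            raise ValueError("mfga must be positive")
        if not (0 < self.true_cd_max <= 1):
            raise ValueError("true_cd_max must lie in (0, 1]")
        if not (0 <= self.efficacy_k <= 1):
            raise ValueError("efficacy_k must lie in [0, 1]")
        if not (350 <= self.pw_sat <= 600):
            raise ValueError("pw_sat must lie in [350, 600] us")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-side truth for one trial (device coordinates).

    ``f_vol``/``f_stim`` are the exact pre-burst window mean and
    post-burst peak of the noiseless device-transformed waveform.
    ``measured_cd_asymptote`` is the closed-form device-free ratio
    F_vol / (F_vol + k (MFGA - F_vol)).
    """

    f_vol: float
    f_stim: float
    measured_cd: float
    true_cd: float
    measured_cd_asymptote: float
    effort: float
    clean: bool = True
    violation: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SimulatedTrial:
    trace: TorqueTrace
    truth: GroundTruth


def simulate_twitch_ramp(
    params: ParticipantParams,
    widths: Sequence[float] | None = None,
    rng: np.random.Generator | int | None = None,
    t_max_fraction: float = 0.12,
) -> list[tuple[float, float]]:
    """Twitch peak torque vs stimulation pulse width at rest.

    The recruitment model is saturating-linear: the twitch peak grows as
    ``T_max * min(1, pw / pw_sat)`` and plateaus at the participant's
    saturation width.  ``T_max`` defaults to 12% of MFGA.  Noise is a
    tenth of the participant's trace noise (twitch peaks are read from
    averaged resting traces).
    """
    if widths is None:
        widths = np.arange(50.0, 601.0, 50.0)
    widths = np.asarray(widths, dtype=float)
    if np.any((widths < 50) | (widths > 600)):
        raise ValueError("pulse widths must lie in [50, 600] us")
    if np.any(np.diff(widths) <= 0):
        raise ValueError("pulse widths must be strictly ascending")
    rng = np.random.default_rng(rng)
    t_max = t_max_fraction * params.mfga
    peaks = t_max * np.minimum(1.0, widths / params.pw_sat)
    peaks = peaks + rng.normal(0.0, 0.1 * params.noise_sd, widths.size)
    return list(zip(widths.tolist(), peaks.tolist()))


def select_pulse_duration(
    ramp: Sequence[tuple[float, float]], rel_tolerance: float = 0.0
) -> float:
    """Minimum pulse width whose twitch peak reaches (1 - tol) x the maximum."""
    if not ramp:
        raise ValueError("empty twitch ramp")
    widths = np.array([w for w, _ in ramp])
    peaks = np.array([p for _, p in ramp])
    threshold = (1.0 - rel_tolerance) * peaks.max()
    return float(widths[np.flatnonzero(peaks >= threshold)[0]])


def simulate_trial(
    params: ParticipantParams,
    effort_fraction: float,
    burst: BurstSpec = BurstSpec(),
    device: DeviceModel = DeviceModel(),
    duration_s: float = 6.0,
    burst_time_s: float = 3.0,
    rng: np.random.Generator | int | None = None,
    *,
    ramp_s: float = 1.0,
    tau_burst_s: float = 0.030,
    tau_decay_s: float = 0.150,
    emd_s: float = 0.040,
    violation: str | None = None,
    trial_label: str = "",
) -> SimulatedTrial:
    """Simulate one burst-superimposition trial at 1 kHz.

    The voluntary envelope is a raised-cosine ramp reaching the plateau
    exactly at ``ramp_s``; the evoked response starts after an
    electromechanical delay ``emd_s`` (force lags stimulation onset)
    and develops S-shaped (zero initial slope), closing >= 95% of the
    gap to the target by burst end with the default time constant.
    ``violation`` injects a QC failure: ``"nonsteady"`` keeps torque
    ramping through the burst, ``"high_variance"`` adds a large slow
    oscillation to the plateau.
    """
    if not (0 < effort_fraction <= 1):
        raise ValueError("effort_fraction must lie in (0, 1]")
    burst_dur_s = burst.duration_ms / 1000.0
    if burst_time_s - 0.1 < ramp_s or burst_time_s < 0.1:
        raise ValueError("burst must leave >= 100 ms of plateau before onset")
    if duration_s - (burst_time_s + burst_dur_s) < 0.5:
        raise ValueError("burst must leave >= 500 ms of trace after onset")
    rng = np.random.default_rng(rng)

    fs = SAMPLING_RATE
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    f_vol = effort_fraction * params.true_cd_max * params.mfga
    gap = params.mfga - f_vol

    # voluntary envelope: raised-cosine ramp, exact plateau afterwards
    env = np.where(t < ramp_s, 0.5 * (1.0 - np.cos(np.pi * t / ramp_s)), 1.0)
    torque = f_vol * env

    if violation == "nonsteady":
        # effort keeps creeping upward instead of holding a plateau
        torque = torque + np.where(t > ramp_s, 8.0 * (t - ramp_s), 0.0)
    elif violation == "high_variance":
        # effort oscillation inside the filter passband, on the plateau
        torque = torque + np.where(
            t > ramp_s, 1.0 * np.sin(2 * np.pi * 6.0 * (t - ramp_s)), 0.0
        )
    elif violation is not None:
        raise ValueError(f"unknown violation type: {violation!r}")

    # evoked response: critically damped second-order rise toward closing
    # k x gap while the burst is on, first-order decay afterwards
    t_on = burst_time_s + emd_s
    t_off = t_on + burst_dur_s
    aug_target = params.efficacy_k * gap

    def _rise(s):
        s = np.clip(s, 0.0, None) / tau_burst_s
        return aug_target * (1.0 - (1.0 + s) * np.exp(-s))

    aug_end = float(_rise(np.array(burst_dur_s)))
    decay = aug_end * np.exp(-np.clip(t - t_off, 0.0, None) / tau_decay_s)
    aug = np.where(t < t_on, 0.0, np.where(t < t_off, _rise(t - t_on), decay))

    clean = device.gain * (torque + aug) + device.offset
    samples = clean + rng.normal(0.0, params.noise_sd, n)

    onset = int(round(burst_time_s * fs))
    trig_end = int(round((burst_time_s + burst_dur_s) * fs))
    trigger = np.zeros(n, dtype=int)
    trigger[onset:trig_end] = 1

    w = int(round(0.1 * fs))
    post = int(round(0.5 * fs))
    gt_fvol = float(np.mean(clean[onset - w : onset]))
    gt_fstim = float(np.max(clean[onset : onset + post]))
    mcd, _ = _measured_cd(gt_fvol, gt_fstim)
    mcd_asym = f_vol / (f_vol + params.efficacy_k * gap) if params.efficacy_k * gap + f_vol > 0 else 1.0

    trace = TorqueTrace(
        samples=samples,
        trigger=trigger,
        sampling_rate=fs,
        meta=TraceMeta(
            participant_id=params.id,
            device=device.label,
            limb=params.limb,
            trial=trial_label,
            target_effort=effort_fraction,
        ),
    )
    truth = GroundTruth(
        f_vol=gt_fvol,
        f_stim=gt_fstim,
        measured_cd=mcd,
        true_cd=effort_fraction * params.true_cd_max,
        measured_cd_asymptote=float(min(mcd_asym, 1.0)),
        effort=effort_fraction,
        clean=violation is None,
        violation=violation,
    )
    return SimulatedTrial(trace=trace, truth=truth)


# --- cohort-level configuration -------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Per-limb-group sampling distribution for MFGA and true central drive."""

    mfga_mean: float
    mfga_sd: float
    true_cd_mean: float
    true_cd_sd: float


#: Published per-group strength parameters (MFGA row) with true-central-drive
#: distributions derived from the Fvol/MFGA group means and the printed
#: central-drive SDs.
TABLE1_GROUPS: dict[str, GroupParams] = {
    "neurotypical": GroupParams(76.47, 13.59, 76.21 / 76.47, 0.0171),
    "paretic": GroupParams(41.07, 13.41, 27.99 / 41.07, 0.2144),
    "non-paretic": GroupParams(56.54, 15.71, 48.25 / 56.54, 0.2025),
}


@dataclass(frozen=True)
class WalkConfig:
    """Six-minute-walk generator: distances track paretic central drive.

    Walking speed is driven by a logistic function of paretic true
    central drive (standardized within the cohort); the signal/noise SDs
    split the published total-distance SD so the generated correlation
    matches the published strength.
    """

    total_mean: float = 321.0
    total_signal_sd: float = 70.0
    total_noise_sd: float = 75.0
    cd_center: float = 0.68
    cd_scale: float = 0.25
    pct_mean: float = -3.0
    pct_signal_sd: float = 9.0
    pct_noise_sd: float = 12.0
    minute_jitter_sd: float = 2.0


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters for the two simulated experiments."""

    n_neurotypical: int = 16
    n_stroke: int = 26
    groups: dict[str, GroupParams] = field(default_factory=lambda: dict(TABLE1_GROUPS))
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
    walk: WalkConfig = field(default_factory=WalkConfig)

    def __post_init__(self) -> None:
        if self.n_neurotypical < 0 or self.n_stroke < 0:
            raise ValueError("cohort sizes must be nonnegative")
        if not (0 <= self.qc_violation_rate <= 1):
            raise ValueError("qc_violation_rate must lie in [0, 1]")
        for g in self.groups.values():
            if g.mfga_sd < 0 or g.true_cd_sd < 0:
                raise ValueError("SDs must be nonnegative")


def _draw_participant(
    pid: str,
    group: str,
    limb: str,
    gp: GroupParams,
    config: CohortConfig,
    rng: np.random.Generator,
) -> ParticipantParams:
    mfga = float(np.clip(rng.normal(gp.mfga_mean, gp.mfga_sd), 5.0, None))
    cd = float(np.clip(rng.normal(gp.true_cd_mean, gp.true_cd_sd), 0.05, 1.0))
    k = float(rng.uniform(*config.efficacy_range))
    pw = float(rng.uniform(*config.pw_sat_range))
    return ParticipantParams(
        id=pid,
        group=group,
        limb=limb,
        mfga=mfga,
        true_cd_max=cd,
        efficacy_k=k,
        pw_sat=pw,
        noise_sd=config.noise_sd,
    )


# --- experiment 1: two-device accuracy + calibration ----------------------

@dataclass
class Experiment1Result:
    """Two-device trial set for the accuracy/calibration experiment."""

    participants: list[ParticipantParams]
    devices: dict[str, dict[str, DeviceModel]]  # participant id -> label -> device
    trials: list[SimulatedTrial]

    def pairs_table(self) -> pd.DataFrame:
        """(measured, true) central-drive pairs per trial from ground truth.

        ``true`` follows the calibration convention: F_vol divided by the
        device-measured MFGA, i.e. the F_stim of that participant-device
        MVC trial.
        """
        rows = []
        mfga_meas: dict[tuple[str, str], float] = {}
        for tr in self.trials:
            if tr.truth.effort == 1.0:
                key = (tr.trace.meta.participant_id, tr.trace.meta.device)
                mfga_meas[key] = tr.truth.f_stim
        for tr in self.trials:
            key = (tr.trace.meta.participant_id, tr.trace.meta.device)
            rows.append(
                {
                    "participant_id": key[0],
                    "device": key[1],
                    "trial": tr.trace.meta.trial,
                    "effort": tr.truth.effort,
                    "measured": tr.truth.measured_cd,
                    "true": min(tr.truth.f_vol / mfga_meas[key], 1.0),
                }
            )
        return pd.DataFrame(rows)

    def mvc_by_device(self) -> pd.DataFrame:
        """Per-participant MVC voluntary torque on each device (wide form)."""
        rows = [
            {
                "participant_id": tr.trace.meta.participant_id,
                "device": tr.trace.meta.device,
                "f_vol": tr.truth.f_vol,
            }
            for tr in self.trials
            if tr.truth.effort == 1.0
        ]
        df = pd.DataFrame(rows)
        return df.pivot(index="participant_id", columns="device", values="f_vol")


def simulate_experiment1(
    config: CohortConfig = CohortConfig(), seed: int | None = 0
) -> Experiment1Result:
    """Simulate the two-device accuracy experiment.

    Each neurotypical participant performs, on each device, one MVC
    burst-superimposition trial plus two trials at each of 25/50/75%
    MFGA — seven central-drive tests per device.  The second device
    differs from the reference by a per-participant offset (and
    optionally gain).
    """
    root = np.random.SeedSequence(seed)
    participants: list[ParticipantParams] = []
    devices: dict[str, dict[str, DeviceModel]] = {}
    trials: list[SimulatedTrial] = []
    gp = config.groups["neurotypical"]
    for i, ss in enumerate(root.spawn(max(config.n_neurotypical, 1))[: config.n_neurotypical]):
        rng = np.random.default_rng(ss)
        p = _draw_participant(f"NT{i:02d}", "neurotypical", "dominant", gp, config, rng)
        participants.append(p)
        dev_b = DeviceModel(
            label="cedrs",
            gain=float(rng.normal(config.device_b_gain_mean, config.device_b_gain_sd)),
            offset=float(rng.normal(config.device_b_offset_mean, config.device_b_offset_sd)),
        )
        devices[p.id] = {"reference": DeviceModel(label="reference"), "cedrs": dev_b}
        efforts = [1.0] + [
            e for e in config.effort_levels for _ in range(config.trials_per_submax_level)
        ]
        for device in devices[p.id].values():
            for j, effort in enumerate(efforts):
                trials.append(
                    simulate_trial(
                        p,
                        effort,
                        device=device,
                        rng=rng,
                        trial_label=f"{device.label}-t{j}",
                    )
                )
    return Experiment1Result(participants=participants, devices=devices, trials=trials)


# --- experiment 2: post-stroke cohort with walk tests ---------------------

@dataclass
class Exp2Limb:
    """One participant-limb of the post-stroke validation cohort."""

    params: ParticipantParams
    trials: list[SimulatedTrial]


@dataclass
class Exp2Cohort:
    """Post-stroke + neurotypical cohort with per-minute walk distances."""

    limbs: list[Exp2Limb]
    walk_minutes: dict[str, tuple[float, ...]]  # stroke participant id -> 6 distances

    def iter_trials(self) -> Iterator[SimulatedTrial]:
        for limb in self.limbs:
            yield from limb.trials


def _walk_minutes(
    cds: np.ndarray, cfg: WalkConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-minute 6MWT distances for each paretic true central drive."""
    u = 1.0 / (1.0 + np.exp(-(cds - cfg.cd_center) / cfg.cd_scale))
    z = (u - u.mean()) / u.std() if u.size > 1 and u.std() > 0 else np.zeros_like(u)
    total = cfg.total_mean + cfg.total_signal_sd * z + rng.normal(
        0.0, cfg.total_noise_sd, u.size
    )
    total = np.clip(total, 30.0, None)
    pct = cfg.pct_mean + cfg.pct_signal_sd * z + rng.normal(0.0, cfg.pct_noise_sd, u.size)
    delta = np.clip(pct / 100.0, -0.9, 3.0)
    d1 = total / (6.0 * (1.0 + delta / 2.0))
    minutes = d1[:, None] * (1.0 + delta[:, None] * np.arange(6)[None, :] / 5.0)
    jitter = rng.normal(0.0, cfg.minute_jitter_sd, minutes.shape)
    jitter[:, 0] = 0.0
    jitter[:, 5] = 0.0
    return np.clip(minutes + jitter, 0.1, None)


def simulate_cohort_exp2(
    config: CohortConfig = CohortConfig(), seed: int | None = 0
) -> Exp2Cohort:
    """Simulate the post-stroke validation cohort.

    Each post-stroke participant contributes a paretic and a non-paretic
    limb with three MVC burst-superimposition trials each (single
    device), plus a six-minute walk test whose outcomes track paretic
    central drive.  Neurotypical participants contribute their MVC
    central-drive test.  With ``qc_violation_rate`` > 0, a matching
    fraction of trials is generated with an injected steadiness or
    variance violation (labelled in the ground truth).
    """
    root = np.random.SeedSequence(seed)
    limbs: list[Exp2Limb] = []
    walk_minutes: dict[str, tuple[float, ...]] = {}
    n_children = config.n_stroke + config.n_neurotypical + 1
    children = np.random.SeedSequence(seed).spawn(max(n_children, 1))
    paretic_cds: list[float] = []
    stroke_ids: list[str] = []

    def _maybe_violation(rng: np.random.Generator) -> str | None:
        if config.qc_violation_rate > 0 and rng.random() < config.qc_violation_rate:
            return "nonsteady" if rng.random() < 0.5 else "high_variance"
        return None

    for i in range(config.n_stroke):
        rng = np.random.default_rng(children[i])
        pid = f"ST{i:02d}"
        stroke_ids.append(pid)
        for limb_name in ("paretic", "non-paretic"):
            p = _draw_participant(
                pid, "post-stroke", limb_name, config.groups[limb_name], config, rng
            )
            if limb_name == "paretic":
                paretic_cds.append(p.true_cd_max)
            trials = [
                simulate_trial(
                    p,
                    1.0,
                    rng=rng,
                    violation=_maybe_violation(rng),
                    trial_label=f"mvc{j}",
                )
                for j in range(config.mvc_trials_exp2)
            ]
            limbs.append(Exp2Limb(params=p, trials=trials))

    gp = config.groups["neurotypical"]
    for i in range(config.n_neurotypical):
        rng = np.random.default_rng(children[config.n_stroke + i])
        p = _draw_participant(
            f"NT{i:02d}", "neurotypical", "neurotypical", gp, config, rng
        )
        trials = [
            simulate_trial(
                p, 1.0, rng=rng, violation=_maybe_violation(rng), trial_label="mvc0"
            )
        ]
        limbs.append(Exp2Limb(params=p, trials=trials))

    if stroke_ids:
        rng_walk = np.random.default_rng(children[-1])
        minutes = _walk_minutes(np.asarray(paretic_cds), config.walk, rng_walk)
        walk_minutes = {
            pid: tuple(minutes[i].tolist()) for i, pid in enumerate(stroke_ids)
        }
    return Exp2Cohort(limbs=limbs, walk_minutes=walk_minutes)
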