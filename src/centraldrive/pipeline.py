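"""End-to-end orchestration: simulate -> process -> calibrate -> adjust -> report.

The in-memory helpers (`process_trials`, `limb_summary`, `group_comparisons`,
`walk_associations`, `device_agreement`, `build_report`) are the analysis
surface used programmatically and by the tests; the ``cmd_*`` functions wrap
them with a cohort-directory layout (trace CSVs + JSON metadata) for the
command-line interface.  Every stage is deterministic for a fixed seed and
configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict

from . import adjustment as adj
from . import stats as cds
from .config import RunConfig
from .processing import TrialMeasurement, summarize_trial
from .qc import QcConfig, aggregate_participant
from .simulate import (
    Exp2Cohort,
    Experiment1Result,
    SimulatedTrial,
    simulate_cohort_exp2,
    simulate_experiment1,
)
from .traces import TorqueTrace, read_trace, write_trace, TraceMeta

logger = logging.getLogger("centraldrive")

__all__ = [
    "process_trials",
    "limb_summary",
    "group_comparisons",
    "walk_associations",
    "device_agreement",
    "calibration_pairs_from_measurements",
    "build_report",
    "Report",
    "cmd_simulate",
    "cmd_process",
    "cmd_calibrate",
    "cmd_adjust",
    "cmd_report",
]

GROUP_ORDER = ("neurotypical", "paretic", "non-paretic")


# --- in-memory analysis ----------------------------------------------------

def process_trials(
    traces: Iterable[TorqueTrace],
    qc_config: QcConfig = QcConfig(),
    **filter_kwargs,
) -> list[TrialMeasurement]:
    """Run filtering, extraction, and QC on every trace."""
    return [summarize_trial(t, qc_config, **filter_kwargs) for t in traces]


def limb_summary(
    measurements: Sequence[TrialMeasurement],
    model: adj.AdjustmentModel | None = None,
) -> pd.DataFrame:
    """Aggregate trials per participant-limb and compute central drive.

    F_vol and F_stim are averaged over valid trials; the measured ratio
    of the averages is adjusted with ``model`` (the published equation
    by default).  Limbs with zero valid trials are retained with null
    estimates and ``n_valid = 0`` so exclusions stay visible.
    """
    model = model or adj.published_model()
    by_limb: dict[tuple[str, str], list[TrialMeasurement]] = {}
    for m in measurements:
        key = (m.meta.get("participant_id", ""), m.meta.get("limb", ""))
        by_limb.setdefault(key, []).append(m)
    rows = []
    for (pid, limb), trials in by_limb.items():
        agg = aggregate_participant(trials, limb)
        row = {
            "participant_id": pid,
            "limb": limb,
            "n_valid": agg.n_valid,
            "n_total": agg.n_total,
            "f_vol": agg.f_vol_mean,
            "f_stim": agg.f_stim_mean,
            "measured_cd": None,
            "adjusted_cd": None,
            "capped": None,
        }
        if agg.n_valid > 0:
            mcd, capped = adj.measured_cd(agg.f_vol_mean, agg.f_stim_mean)
            row.update(
                measured_cd=mcd,
                adjusted_cd=adj.apply_adjustment(model, mcd),
                capped=capped,
            )
        else:
            logger.info("limb %s/%s excluded: zero valid trials", pid, limb)
        rows.append(row)
    return pd.DataFrame(rows)


def group_comparisons(summary: pd.DataFrame) -> dict[str, cds.GroupComparison]:
    """One-way ANOVA + Sidak pairwise tests per strength variable.

    Variables mirror the validation analysis: average voluntary torque
    (f_vol), strength capacity (f_stim, the MFGA estimate), and adjusted
    central drive, compared across the neurotypical/paretic/non-paretic
    limb groups.  Limbs with no valid trials are excluded.
    """
    out = {}
    usable = summary[summary["n_valid"] > 0]
    for var in ("f_vol", "f_stim", "adjusted_cd"):
        groups, labels = [], []
        for g in GROUP_ORDER:
            vals = usable.loc[usable["limb"] == g, var].dropna().to_numpy(dtype=float)
            if vals.size >= 2:
                groups.append(vals)
                labels.append(g)
        if len(groups) >= 2:
            comp = cds.one_way_anova_eta(groups)
            pairwise = cds.sidak_pairwise(groups, labels)
            out[var] = cds.GroupComparison(
                f_statistic=comp.f_statistic,
                p_value=comp.p_value,
                eta_squared=comp.eta_squared,
                eta_squared_ci=comp.eta_squared_ci,
                pairwise=pairwise,
                group_means={
                    g: float(np.mean(v)) for g, v in zip(labels, groups)
                },
            )
    return out


def walk_associations(
    summary: pd.DataFrame, walk_minutes: dict[str, Sequence[float]]
) -> dict[str, dict[str, float]]:
    """Correlate paretic adjusted central drive with 6MWT outcomes."""
    paretic = summary[(summary["limb"] == "paretic") & (summary["n_valid"] > 0)]
    cd, total, pct = [], [], []
    for _, row in paretic.iterrows():
        minutes = walk_minutes.get(row["participant_id"])
        if minutes is None:
            continue
        cd.append(row["adjusted_cd"])
        total.append(float(sum(minutes)))
        pct.append(cds.pct_delta_6mwt(minutes))
    out: dict[str, dict[str, float]] = {}
    if len(cd) >= 3:
        for name, y in (("total_distance", total), ("pct_delta_speed", pct)):
            r, p = cds.pearson_r(cd, y)
            out[name] = {"r": r, "p": p, "n": len(cd)}
    return out


def device_agreement(mvc_wide: pd.DataFrame) -> cds.AgreementResult:
    """ICC(2,1) + Bland-Altman on per-participant MVC torque across devices."""
    if mvc_wide.shape[1] != 2:
        raise ValueError("expected exactly two device columns")
    x = mvc_wide.to_numpy(dtype=float)
    icc = cds.icc_2_1(x)
    ba = cds.bland_altman(x[:, 0], x[:, 1])
    return cds.AgreementResult(
        icc=icc.icc,
        icc_ci=icc.icc_ci,
        bias=ba.bias,
        loa_lower=ba.loa_lower,
        loa_upper=ba.loa_upper,
        diff_sd=ba.diff_sd,
    )


def calibration_pairs_from_measurements(
    measurements: Sequence[TrialMeasurement],
) -> pd.DataFrame:
    """(measured, true) pairs from processed two-device trials.

    The per-participant-device MFGA is the largest F_stim across that
    participant-device's valid MVC-target trials; ``true`` is each
    trial's F_vol over that MFGA.
    """
    rows = []
    mfga: dict[tuple[str, str], float] = {}
    for m in measurements:
        if not m.valid:
            continue
        if m.meta.get("target_effort", None) in (None, 1.0):
            key = (m.meta.get("participant_id", ""), m.meta.get("device", ""))
            mfga[key] = max(mfga.get(key, 0.0), m.f_stim)
    for m in measurements:
        if not m.valid:
            continue
        key = (m.meta.get("participant_id", ""), m.meta.get("device", ""))
        if key not in mfga or mfga[key] <= 0:
            continue
        mcd, _ = adj.measured_cd(m.f_vol, m.f_stim)
        rows.append(
            {
                "participant_id": key[0],
                "device": key[1],
                "measured": mcd,
                "true": adj.true_cd(m.f_vol, mfga[key]),
            }
        )
    return pd.DataFrame(rows)


# --- report ----------------------------------------------------------------

class AgreementSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    icc: float
    icc_ci: tuple[float, float]
    bias: float
    loa_lower: float
    loa_upper: float


class CalibrationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    b3: float
    b2: float
    b1: float
    r_squared: float | None
    r_squared_uncentered: float | None
    rmse_pct: float | None
    coef_ci: tuple[tuple[float, float], ...] | None
    loocv_rmse_mean: float | None
    loocv_rmse_sd: float | None
    bp_lm: float | None
    bp_p_value: float | None
    n_pairs: int | None
    provenance: str


class GroupSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    f_statistic: float
    p_value: float
    eta_squared: float
    eta_squared_ci: tuple[float, float]
    pairwise: dict[str, float]
    group_means: dict[str, float]


class CorrelationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    r: float
    p: float
    n: int


class Report(BaseModel):
    """Schema-validated results report (agreement, calibration, cohort)."""

    model_config = ConfigDict(extra="forbid")
    agreement: AgreementSection | None = None
    calibration: CalibrationSection | None = None
    groups: dict[str, GroupSection] | None = None
    correlations: dict[str, CorrelationSection] | None = None
    qc_summary: dict[str, int] | None = None
    metadata: dict[str, str | int | float] = {}

    def to_text(self) -> str:
        lines = ["Central-drive analysis report", "=" * 31]
        if self.agreement:
            a = self.agreement
            lines += [
                "",
                "Device agreement (MVC torque)",
                f"  ICC(2,1) = {a.icc:.3f} [{a.icc_ci[0]:.3f}, {a.icc_ci[1]:.3f}]",
                f"  Bland-Altman bias = {a.bias:.2f} ft-lbs, "
                f"LoA [{a.loa_lower:.2f}, {a.loa_upper:.2f}]",
            ]
        if self.calibration:
            c = self.calibration
            lines += [
                "",
                "Adjustment equation (origin-constrained cubic)",
                f"  adjusted = {c.b3:.3f} x^3 + {c.b2:.3f} x^2 + {c.b1:.3f} x",
                f"  R^2 = {c.r_squared:.3f}" if c.r_squared is not None else "",
                f"  RMSE = {c.rmse_pct:.1f}%" if c.rmse_pct is not None else "",
            ]
            if c.loocv_rmse_mean is not None:
                lines.append(
                    f"  LOOCV RMSE = {c.loocv_rmse_mean:.1f} +/- {c.loocv_rmse_sd:.2f}%"
                )
            if c.bp_p_value is not None:
                lines.append(f"  Breusch-Pagan p = {c.bp_p_value:.3f}")
        if self.groups:
            lines += ["", "Group comparison", "  variable | " + " | ".join(
                g.capitalize() for g in ("neurotypical", "paretic", "non-paretic")
            )]
            for var, sec in self.groups.items():
                means = [
                    f"{sec.group_means.get(g, float('nan')):.2f}"
                    for g in ("neurotypical", "paretic", "non-paretic")
                ]
                lines.append(
                    f"  {var}: " + " | ".join(means)
                    + f"  (F = {sec.f_statistic:.2f}, p = {sec.p_value:.2g}, "
                    f"eta^2 = {sec.eta_squared:.3f})"
                )
        if self.correlations:
            lines += ["", "6MWT associations (paretic adjusted central drive)"]
            for name, sec in self.correlations.items():
                lines.append(f"  {name}: r = {sec.r:.3f}, p = {sec.p:.3g}, n = {sec.n}")
        if self.qc_summary:
            lines += ["", "QC summary"]
            for flag, count in sorted(self.qc_summary.items()):
                lines.append(f"  {flag}: {count}")
        return "\n".join(line for line in lines if line is not None) + "\n"


def build_report(
    *,
    agreement: cds.AgreementResult | None = None,
    model: adj.AdjustmentModel | None = None,
    comparisons: dict[str, cds.GroupComparison] | None = None,
    correlations: dict[str, dict[str, float]] | None = None,
    measurements: Sequence[TrialMeasurement] | None = None,
    metadata: dict | None = None,
) -> Report:
    """Assemble (and schema-validate) a report from computed stages."""
    agreement_sec = None
    if agreement is not None and agreement.icc is not None:
        agreement_sec = AgreementSection(
            icc=agreement.icc,
            icc_ci=agreement.icc_ci,
            bias=agreement.bias,
            loa_lower=agreement.loa_lower,
            loa_upper=agreement.loa_upper,
        )
    calib_sec = None
    if model is not None:
        d = asdict(model)
        calib_sec = CalibrationSection(**d)
    groups_sec = None
    if comparisons:
        groups_sec = {
            var: GroupSection(
                f_statistic=c.f_statistic,
                p_value=c.p_value,
                eta_squared=c.eta_squared,
                eta_squared_ci=c.eta_squared_ci,
                pairwise={f"{a} vs {b}": p for (a, b), p in c.pairwise.items()},
                group_means=c.group_means or {},
            )
            for var, c in comparisons.items()
        }
    corr_sec = None
    if correlations:
        corr_sec = {
            name: CorrelationSection(r=v["r"], p=v["p"], n=int(v["n"]))
            for name, v in correlations.items()
        }
    qc_summary = None
    if measurements is not None:
        qc_summary = {"n_trials": len(measurements), "n_valid": 0}
        for m in measurements:
            if m.valid:
                qc_summary["n_valid"] += 1
            for flag in m.flags:
                qc_summary[flag] = qc_summary.get(flag, 0) + 1
    return Report(
        agreement=agreement_sec,
        calibration=calib_sec,
        groups=groups_sec,
        correlations=corr_sec,
        qc_summary=qc_summary,
        metadata=metadata or {},
    )


# --- cohort directory layout ----------------------------------------------

def _trace_filename(trace: TorqueTrace, index: int) -> str:
    m = trace.meta
    return f"{m.participant_id}_{m.device or 'cedrs'}_{m.limb or 'na'}_{m.trial or index}.csv"


def cmd_simulate(config: RunConfig, out_dir: str | Path) -> Path:
    """Simulate a cohort and write it as a directory of trace CSVs + JSON."""
    out = Path(out_dir)
    (out / "traces").mkdir(parents=True, exist_ok=True)
    cohort_cfg = config.cohort.to_cohort_config()
    if config.experiment == "exp1":
        result = simulate_experiment1(cohort_cfg, config.seed)
        trials = list(result.trials)
        extra = {"devices": sorted({t.trace.meta.device for t in trials})}
        walk = None
    elif config.experiment == "exp2":
        cohort = simulate_cohort_exp2(cohort_cfg, config.seed)
        trials = list(cohort.iter_trials())
        extra = {}
        walk = cohort.walk_minutes
    else:
        raise ValueError(f"unknown experiment {config.experiment!r}")

    truth, files = [], []
    for i, tr in enumerate(trials):
        name = _trace_filename(tr.trace, i)
        write_trace(tr.trace, out / "traces" / name)
        files.append(name)
        truth.append(
            {
                "file": name,
                "participant_id": tr.trace.meta.participant_id,
                "device": tr.trace.meta.device,
                "limb": tr.trace.meta.limb,
                "trial": tr.trace.meta.trial,
                "target_effort": tr.trace.meta.target_effort,
                **tr.truth.to_dict(),
            }
        )
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    meta = {
        "experiment": config.experiment,
        "seed": config.seed,
        "n_trials": len(trials),
        **extra,
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    if walk is not None:
        (out / "walk_tests.json").write_text(json.dumps(walk, indent=1, sort_keys=True))
    (out / "config.yaml").write_text(yaml.safe_dump(config.model_dump(mode="json")))
    logger.info("simulated %d trials into %s", len(trials), out)
    return out


def _load_cohort_traces(cohort_dir: Path) -> list[TorqueTrace]:
    truth = json.loads((cohort_dir / "ground_truth.json").read_text())
    traces = []
    for rec in truth:
        meta = TraceMeta(
            participant_id=rec["participant_id"],
            device=rec["device"],
            limb=rec["limb"],
            trial=rec["trial"],
            target_effort=rec["target_effort"],
        )
        traces.append(read_trace(cohort_dir / "traces" / rec["file"], meta=meta))
    return traces


def cmd_process(cohort_dir: str | Path, config: RunConfig, out_dir: str | Path) -> Path:
    """Process every trace of a cohort directory: trial + participant JSON."""
    cohort_dir, out = Path(cohort_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    traces = _load_cohort_traces(cohort_dir)
    qc = config.qc.to_qc_config()
    f = config.filter
    measurements = process_trials(
        traces,
        qc,
        cutoff_hz=f.cutoff_hz,
        filter_order=f.order,
        zero_phase=f.zero_phase,
        post_window_s=f.post_window_s,
    )
    (out / "trials.json").write_text(
        json.dumps([m.to_dict() for m in measurements], indent=1, sort_keys=True)
    )
    summary = limb_summary(measurements)
    summary.to_json(out / "participants.json", orient="records", indent=1)
    n_valid = sum(m.valid for m in measurements)
    logger.info("processed %d trials (%d valid)", len(measurements), n_valid)
    return out


def cmd_calibrate(pairs_csv: str | Path, out_path: str | Path) -> adj.AdjustmentModel:
    """Fit the adjustment equation from a (participant, measured, true) table."""
    df = pd.read_csv(pairs_csv)
    for col in ("participant_id", "measured", "true"):
        if col not in df.columns:
            raise ValueError(f"pairs table missing column {col!r}")
    model = adj.fit_adjustment(
        df["measured"], df["true"], participant_ids=df["participant_id"]
    )
    model.to_json(out_path)
    return model


def cmd_adjust(
    model_path: str | Path, measured: Sequence[float]
) -> list[float]:
    """Apply a stored adjustment model to measured central-drive ratios."""
    model = adj.AdjustmentModel.from_json(model_path)
    return [adj.apply_adjustment(model, float(x)) for x in measured]


def cmd_report(
    processed_dir: str | Path,
    out_dir: str | Path,
    model_path: str | Path | None = None,
    cohort_dir: str | Path | None = None,
) -> Report:
    """Build the results report from processed outputs (+ optional stages)."""
    processed, out = Path(processed_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = pd.read_json(processed / "participants.json")
    trials = json.loads((processed / "trials.json").read_text())

    model = (
        adj.AdjustmentModel.from_json(model_path) if model_path else adj.published_model()
    )
    comparisons = group_comparisons(summary)
    correlations = None
    if cohort_dir is not None:
        walk_path = Path(cohort_dir) / "walk_tests.json"
        if walk_path.exists():
            walk = json.loads(walk_path.read_text())
            correlations = walk_associations(summary, walk) or None

    qc_summary = {"n_trials": len(trials), "n_valid": sum(t["valid"] for t in trials)}
    for t in trials:
        for flag in t["flags"]:
            qc_summary[flag] = qc_summary.get(flag, 0) + 1

    report = build_report(
        model=model,
        comparisons=comparisons,
        correlations=correlations,
        metadata={"n_limbs": int(summary.shape[0])},
    )
    report = report.model_copy(update={"qc_summary": qc_summary})
    (out / "report.json").write_text(report.model_dump_json(indent=1))
    (out / "report.txt").write_text(report.to_text())
    return report
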