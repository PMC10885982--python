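"""Simulator ground truth, protocol structure, and cohort statistics."""

import dataclasses

import numpy as np
import pytest

from centraldrive.adjustment import fit_adjustment
from centraldrive.processing import summarize_trial
from centraldrive.qc import QcConfig
from centraldrive.simulate import (
    CohortConfig,
    ParticipantParams,
    TABLE1_GROUPS,
    select_pulse_duration,
    simulate_cohort_exp2,
    simulate_experiment1,
    simulate_trial,
    simulate_twitch_ramp,
)
from centraldrive.stats import icc_2_1
from centraldrive import pipeline as pl


class TestTwitchRamp:
    def test_noiseless_ramp_increases_then_saturates(self):
        p = ParticipantParams(
            id="x", group="neurotypical", limb="dominant", mfga=60.0,
            true_cd_max=1.0, efficacy_k=0.8, pw_sat=400.0, noise_sd=0.0,
        )
        ramp = simulate_twitch_ramp(p, rng=0)
        peaks = np.array([pk for _, pk in ramp])
        widths = np.array([w for w, _ in ramp])
        below = peaks[widths <= 400]
        above = peaks[widths >= 400]
        assert np.all(np.diff(below) > 0)
        np.testing.assert_allclose(above, above[0])

    def test_default_protocol_has_twelve_levels(self, paretic_params):
        assert len(simulate_twitch_ramp(paretic_params, rng=0)) == 12

    def test_saturation_extremes_producible(self):
        for pw_sat in (350.0, 600.0):
            p = dataclasses.replace(
                ParticipantParams(
                    id="x", group="neurotypical", limb="dominant", mfga=60.0,
                    true_cd_max=1.0, efficacy_k=0.8, noise_sd=0.0,
                ),
                pw_sat=pw_sat,
            )
            ramp = simulate_twitch_ramp(p, rng=0)
            assert select_pulse_duration(ramp) == pytest.approx(pw_sat)


class TestSelectPulseDuration:
    def test_first_attainment_of_maximum(self):
        ramp = list(zip((50, 100, 150, 200, 250), (1, 2, 3, 3, 3)))
        assert select_pulse_duration(ramp) == 150

    def test_strictly_increasing_selects_largest(self):
        ramp = list(zip(np.arange(50, 601, 50), np.arange(12)))
        assert select_pulse_duration(ramp) == 600

    def test_flat_ramp_selects_minimum(self):
        ramp = [(w, 5.0) for w in np.arange(50, 601, 50)]
        assert select_pulse_duration(ramp) == 50

    def test_empty_ramp_rejected(self):
        with pytest.raises(ValueError):
            select_pulse_duration([])


class TestSimulateTrial:
    def test_zero_efficacy_gives_no_augmentation(self):
        p = ParticipantParams(
            id="x", group="post-stroke", limb="paretic", mfga=60.0,
            true_cd_max=0.5, efficacy_k=0.0, noise_sd=0.0,
        )
        trial = simulate_trial(p, 1.0, rng=0)
        assert trial.truth.f_stim == pytest.approx(trial.truth.f_vol, abs=1e-9)
        assert trial.truth.measured_cd == pytest.approx(1.0)

    def test_full_efficacy_closes_most_of_the_gap(self):
        # burst length >> rise time constant: >= 95% of (MFGA - F_vol) closed
        p = ParticipantParams(
            id="x", group="neurotypical", limb="dominant", mfga=60.0,
            true_cd_max=0.5, efficacy_k=1.0, noise_sd=0.0,
        )
        trial = simulate_trial(p, 1.0, rng=0)
        gap = 60.0 - trial.truth.f_vol
        assert trial.truth.f_stim - trial.truth.f_vol >= 0.95 * gap

    def test_ground_truth_measured_cd_closed_form(self):
        # F_vol = 30, MFGA = 60, k = 0.8 -> 30 / (30 + 0.8 * 30) = 0.5555...
        p = ParticipantParams(
            id="x", group="post-stroke", limb="paretic", mfga=60.0,
            true_cd_max=0.5, efficacy_k=0.8, noise_sd=0.0,
        )
        trial = simulate_trial(p, 1.0, rng=0)
        assert trial.truth.measured_cd_asymptote == pytest.approx(30 / 54)
        assert trial.truth.true_cd == pytest.approx(0.5)

    def test_zero_noise_extraction_matches_truth_exactly(self, paretic_params):
        p = dataclasses.replace(paretic_params, noise_sd=0.0)
        trial = simulate_trial(p, 1.0, rng=0)
        m = summarize_trial(trial.trace, apply_filter=False)
        assert abs(m.f_vol - trial.truth.f_vol) < 1e-6
        assert abs(m.f_stim - trial.truth.f_stim) < 1e-6

    def test_extraction_error_shrinks_with_noise(self, paretic_params):
        errs = []
        for sd in (0.8, 0.2, 0.05):
            errors = []
            for seed in range(10):
                p = dataclasses.replace(paretic_params, noise_sd=sd)
                trial = simulate_trial(p, 1.0, rng=seed)
                m = summarize_trial(trial.trace)
                errors.append(abs(m.f_vol - trial.truth.f_vol))
            errs.append(np.mean(errors))
        assert errs[0] > errs[2]

    def test_overestimation_invariant_for_partial_efficacy(self):
        # measured CD > true CD strictly whenever k < 1 and F_vol < MFGA
        rng = np.random.default_rng(12)
        for _ in range(25):
            p = ParticipantParams(
                id="x", group="post-stroke", limb="paretic",
                mfga=float(rng.uniform(20, 90)),
                true_cd_max=float(rng.uniform(0.2, 0.95)),
                efficacy_k=float(rng.uniform(0.1, 0.95)),
                noise_sd=0.0,
            )
            effort = float(rng.choice([0.25, 0.5, 0.75, 1.0]))
            trial = simulate_trial(p, effort, rng=0)
            assert trial.truth.measured_cd > trial.truth.true_cd

    def test_burst_timing_precondition(self, paretic_params):
        with pytest.raises(ValueError, match="plateau"):
            simulate_trial(paretic_params, 1.0, burst_time_s=0.5, rng=0)


class TestExperiment1:
    def test_seven_trials_per_device(self):
        cfg = CohortConfig(n_neurotypical=2, n_stroke=0)
        res = simulate_experiment1(cfg, seed=0)
        for p in res.participants:
            for device in ("reference", "cedrs"):
                n = sum(
                    1
                    for t in res.trials
                    if t.trace.meta.participant_id == p.id
                    and t.trace.meta.device == device
                )
                assert n == 7

    def test_identical_devices_give_perfect_agreement(self):
        cfg = CohortConfig(
            n_neurotypical=6, noise_sd=0.0,
            device_b_offset_mean=0.0, device_b_offset_sd=0.0,
        )
        res = simulate_experiment1(cfg, seed=1)
        mvc = res.mvc_by_device()
        agr = icc_2_1(mvc.to_numpy())
        assert agr.icc == pytest.approx(1.0, abs=1e-12)

    def test_bland_altman_recovers_configured_offset(self):
        from centraldrive.stats import bland_altman

        biases = []
        for seed in range(25):
            res = simulate_experiment1(CohortConfig(n_stroke=0), seed=seed)
            mvc = res.mvc_by_device()
            biases.append(bland_altman(mvc["reference"], mvc["cedrs"]).bias)
        # CLT tolerance: SE = 6.64 / sqrt(16 * 25) = 0.33
        assert np.mean(biases) == pytest.approx(3.7, abs=1.0)

    def test_calibration_closure_constant_efficacy(self):
        # noiseless constant-k cohort: fitted cubic must map fresh measured
        # ratios back to true central drive within RMSE 0.03
        cfg = CohortConfig(
            n_neurotypical=8, noise_sd=0.0, efficacy_range=(0.75, 0.75),
            device_b_offset_mean=0.0, device_b_offset_sd=0.0,
        )
        res = simulate_experiment1(cfg, seed=2)
        pairs = res.pairs_table()
        model = fit_adjustment(
            pairs["measured"], pairs["true"], pairs["participant_id"], run_loocv=False
        )
        m = np.linspace(0.2, 0.95, 100)
        closed = 0.75 * m / (1 - 0.25 * m)
        rmse = np.sqrt(np.mean((model.predict(m) - closed) ** 2))
        assert rmse <= 0.03


class TestExperiment2:
    def test_generated_mfga_matches_configured_group_means(self):
        cfg = CohortConfig()
        cohort = simulate_cohort_exp2(cfg, seed=7)
        by_group: dict[str, list[float]] = {}
        for limb in cohort.limbs:
            by_group.setdefault(limb.params.limb, []).append(limb.params.mfga)
        for name in ("neurotypical", "paretic", "non-paretic"):
            g = TABLE1_GROUPS[name]
            vals = np.asarray(by_group[name])
            se = g.mfga_sd / np.sqrt(vals.size)
            assert abs(vals.mean() - g.mfga_mean) <= 2 * se + 1e-9

    def test_every_trace_survives_validation_and_roundtrip(self, tmp_path):
        from centraldrive.traces import read_trace, write_trace

        cohort = simulate_cohort_exp2(CohortConfig(n_stroke=2, n_neurotypical=2), seed=3)
        for i, trial in enumerate(cohort.iter_trials()):
            path = write_trace(trial.trace, tmp_path / f"{i}.csv")
            back = read_trace(path)
            np.testing.assert_allclose(back.samples, trial.trace.samples, atol=1e-6)

    def test_injected_violations_reduce_usable_trials_binomially(self):
        q = 0.3
        cfg = CohortConfig(n_stroke=10, n_neurotypical=0, qc_violation_rate=q)
        cohort = simulate_cohort_exp2(cfg, seed=5)
        trials = list(cohort.iter_trials())
        n = len(trials)
        clean_truth = sum(t.truth.clean for t in trials)
        # generator labels: binomial around (1-q) n
        assert abs(clean_truth - (1 - q) * n) <= 4 * np.sqrt(n * q * (1 - q))
        # pipeline QC recovers the labels
        measurements = [summarize_trial(t.trace) for t in trials]
        for truth, m in zip(trials, measurements):
            assert m.valid == truth.truth.clean

    def test_walk_outcomes_track_paretic_central_drive(self):
        from centraldrive.stats import pearson_r

        cohort = simulate_cohort_exp2(CohortConfig(), seed=11)
        cds, totals = [], []
        for limb in cohort.limbs:
            if limb.params.limb == "paretic":
                cds.append(limb.params.true_cd_max)
                totals.append(sum(cohort.walk_minutes[limb.params.id]))
        r, p = pearson_r(cds, totals)
        assert r > 0.3 and p < 0.05

    def test_same_seed_reproduces_cohort_exactly(self):
        a = simulate_cohort_exp2(CohortConfig(n_stroke=2, n_neurotypical=1), seed=9)
        b = simulate_cohort_exp2(CohortConfig(n_stroke=2, n_neurotypical=1), seed=9)
        for ta, tb in zip(a.iter_trials(), b.iter_trials()):
            np.testing.assert_array_equal(ta.trace.samples, tb.trace.samples)
            assert ta.truth == tb.truth
        assert a.walk_minutes == b.walk_minutes
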