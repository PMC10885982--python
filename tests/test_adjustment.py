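"""Central-drive ratios and the origin-constrained cubic adjustment."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from centraldrive.adjustment import (
    PUBLISHED_COEFFICIENTS,
    apply_adjustment,
    breusch_pagan,
    fit_adjustment,
    loocv_adjustment,
    measured_cd,
    published_model,
    true_cd,
)


class TestRatios:
    @pytest.mark.parametrize(
        "f_vol, f_stim, expected, capped",
        [(30.0, 60.0, 0.5, False), (60.0, 60.0, 1.0, False), (61.0, 60.0, 1.0, True)],
    )
    def test_measured_cd_with_capping(self, f_vol, f_stim, expected, capped):
        assert measured_cd(f_vol, f_stim) == (pytest.approx(expected), capped)

    def test_measured_cd_requires_positive_fstim(self):
        with pytest.raises(ValueError):
            measured_cd(10.0, 0.0)

    @pytest.mark.parametrize("f_vol, mfga, expected", [(0.0, 80.0, 0.0), (40.0, 80.0, 0.5)])
    def test_true_cd(self, f_vol, mfga, expected):
        assert true_cd(f_vol, mfga) == pytest.approx(expected)


class TestFitAdjustment:
    def test_identity_relationship_recovered_exactly(self):
        x = np.linspace(0.05, 1.0, 12)
        model = fit_adjustment(x, x, run_loocv=False)
        assert model.b3 == pytest.approx(0.0, abs=1e-9)
        assert model.b2 == pytest.approx(0.0, abs=1e-9)
        assert model.b1 == pytest.approx(1.0, abs=1e-9)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_published_coefficients_recovered_from_noiseless_pairs(self):
        x = np.arange(0.1, 1.05, 0.1)
        y = published_model().predict(x)
        model = fit_adjustment(x, y, run_loocv=False)
        b3, b2, b1 = PUBLISHED_COEFFICIENTS
        assert model.b3 == pytest.approx(b3, abs=1e-9)
        assert model.b2 == pytest.approx(b2, abs=1e-9)
        assert model.b1 == pytest.approx(b1, abs=1e-9)

    def test_coefficient_ci_coverage_under_noise(self):
        # 112 pairs (16 participants x 7 trials), sigma = 0.03: each true
        # coefficient should fall inside its own fit's 95% CI in >= 90%
        # of 100 seeds
        hits = np.zeros(3)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.1, 1.0, 112)
            y = published_model().predict(x) + rng.normal(0.0, 0.03, 112)
            model = fit_adjustment(x, y, run_loocv=False)
            for i, truth in enumerate(PUBLISHED_COEFFICIENTS):
                lo, hi = model.coef_ci[i]
                hits[i] += lo <= truth <= hi
        assert np.all(hits / 100 >= 0.90)

    def test_rank_deficient_design_rejected(self):
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_adjustment([0.5, 0.5, 0.6, 0.6], [0.4, 0.4, 0.5, 0.5])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_adjustment([0.2, 0.5, 0.8], [0.1, 0.4, 0.7])

    @given(
        b3=st.floats(-1, 1),
        b2=st.floats(-1, 1),
        b1=st.floats(0.05, 1),
    )
    def test_parameter_recovery_for_arbitrary_origin_cubics(self, b3, b2, b1):
        # monotone-on-[0,1] filter: derivative 3 b3 x^2 + 2 b2 x + b1 > 0
        grid = np.linspace(0, 1, 50)
        if np.any(3 * b3 * grid**2 + 2 * b2 * grid + b1 <= 1e-3):
            return
        x = np.linspace(0.05, 1.0, 25)
        y = b3 * x**3 + b2 * x**2 + b1 * x
        model = fit_adjustment(x, y, run_loocv=False)
        assert np.allclose([model.b3, model.b2, model.b1], [b3, b2, b1], atol=1e-8)


class TestApplyAdjustment:
    def test_origin_constraint(self):
        assert apply_adjustment(published_model(), 0.0) == 0.0

    def test_ceiling_at_full_measured_drive(self):
        # published equation at x = 1: 0.798 - 0.772 + 0.868 = 0.894 -> 89%
        y = apply_adjustment(published_model(), 1.0)
        assert y == pytest.approx(0.894, abs=1e-12)
        assert round(100 * y) == 89

    def test_hand_evaluated_midpoint(self):
        # 0.798*0.125 - 0.772*0.25 + 0.868*0.5 = 0.34075
        assert apply_adjustment(published_model(), 0.5) == pytest.approx(0.34075)

    def test_domain_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            apply_adjustment(published_model(), 1.2)

    def test_published_model_strictly_increasing_on_unit_interval(self):
        x = np.linspace(0, 1, 1000)
        y = published_model().predict(x)
        assert np.all(np.diff(y) > 0)


class TestLoocv:
    @staticmethod
    def _pairs(n_participants=6, per=7, sd=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ids = np.repeat(np.arange(n_participants), per)
        x = rng.uniform(0.1, 1.0, ids.size)
        y = published_model().predict(x) + rng.normal(0, sd, ids.size)
        return x, y, ids

    def test_noiseless_data_gives_zero_error(self):
        x, y, ids = self._pairs()
        mean, sd = loocv_adjustment(x, y, ids)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_outlier_participant_inflates_own_fold(self):
        x, y, ids = self._pairs()
        y = y + np.where(ids == 0, 0.2, 0.0)  # shift participant 0 upward
        mean, sd = loocv_adjustment(x, y, ids)
        # brute-force the held-out fold for participant 0
        mask = ids != 0
        beta = np.linalg.lstsq(
            np.column_stack([x[mask], x[mask] ** 2, x[mask] ** 3]), y[mask], rcond=None
        )[0]
        pred = beta[0] * x[~mask] + beta[1] * x[~mask] ** 2 + beta[2] * x[~mask] ** 3
        fold_rmse = 100 * np.sqrt(np.mean((y[~mask] - pred) ** 2))
        assert fold_rmse >= 15.0  # most of the injected 20-point shift remains
        assert sd > 0.0
        assert mean > 0.0

    def test_homogeneous_cohort_has_stable_folds(self):
        # rmse_sd / rmse_mean < 0.25 for a homogeneous noisy cohort.  Each
        # fold's RMSE is a chi-type statistic whose own sampling CV is
        # ~1/sqrt(2 n_fold), so the bound requires folds richer than a
        # handful of pairs; 25 pairs/participant puts the intrinsic CV
        # near 0.14, well inside the bound.
        ratios = []
        for seed in range(20):
            x, y, ids = self._pairs(n_participants=16, per=25, sd=0.03, seed=seed)
            mean, sd = loocv_adjustment(x, y, ids)
            ratios.append(sd / mean)
        assert np.all(np.asarray(ratios) < 0.25)

    def test_requires_three_participants(self):
        with pytest.raises(ValueError, match="3 participants"):
            loocv_adjustment([0.1, 0.9], [0.1, 0.8], [0, 1])


class TestBreuschPagan:
    def test_constant_magnitude_residuals_are_homoscedastic(self):
        resid = np.tile([0.1, -0.1], 10)
        lm, p = breusch_pagan(resid, np.linspace(0.1, 1, 20))
        assert lm == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_power_against_proportional_heteroscedasticity(self):
        rejections = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.uniform(0.1, 1.0, 200)
            resid = rng.normal(0.0, 0.2 * x)
            _, p = breusch_pagan(resid, x)
            rejections += p < 0.05
        assert rejections >= 80

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            breusch_pagan([0.1, -0.2, 0.3], [0.5, 0.5, 0.5])


class TestClosedFormLimit:
    @pytest.mark.parametrize("k", [0.6, 0.75, 0.9])
    def test_cubic_tracks_constant_efficacy_closed_form(self, k):
        # with constant stimulator efficacy k, true = k m / (1 - (1-k) m);
        # the fitted cubic must track the closed form within RMSE 0.03
        m = np.linspace(0.2, 0.95, 120)
        t = k * m / (1.0 - (1.0 - k) * m)
        model = fit_adjustment(m, t, run_loocv=False)
        rmse = np.sqrt(np.mean((model.predict(m) - t) ** 2))
        assert rmse <= 0.03
        assert model.predict(0.0) == 0.0
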