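"""Central-drive ratios and the device-specific adjustment equation.

Central drive is the fraction of a muscle's force-generating capacity
accessed volitionally.  Because a superimposed electrical burst may not
fully activate the residual capacity, the *device-measured* ratio
``F_vol / F_stim`` systematically overestimates the *true* ratio
``F_vol / MFGA``.  The correction is an origin-constrained cubic fitted
to (measured, true) pairs from a calibration cohort:

    adjusted = b3*x**3 + b2*x**2 + b1*x

with the intercept fixed at zero (a measured central drive of 0 must map
to a true central drive of 0).  The module provides the least-squares
fit, participant-wise leave-one-out cross-validation of its RMSE, and
the Breusch-Pagan heteroscedasticity check on its residuals, plus the
published coefficients (0.798, -0.772, 0.868) for cohorts lacking
calibration data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "CentralDriveEstimate",
    "AdjustmentModel",
    "PUBLISHED_COEFFICIENTS",
    "published_model",
    "measured_cd",
    "true_cd",
    "fit_adjustment",
    "apply_adjustment",
    "loocv_adjustment",
    "breusch_pagan",
]

#: (b3, b2, b1) of the published origin-constrained cubic adjustment.
PUBLISHED_COEFFICIENTS = (0.798, -0.772, 0.868)


@dataclass(frozen=True)
class CentralDriveEstimate:
    """Measured, true (when MFGA ground truth exists), and adjusted ratios."""

    measured: float
    adjusted: float
    true: float | None = None
    capped: bool = False


@dataclass(frozen=True)
class AdjustmentModel:
    """Origin-constrained cubic mapping measured to true central drive.

    Coefficients are (cubic, quadratic, linear); the intercept is
    structurally zero.  Diagnostics are populated by :func:`fit_adjustment`;
    RMSE quantities are in percentage points of central drive.
    """

    b3: float
    b2: float
    b1: float
    r_squared: float | None = None
    r_squared_uncentered: float | None = None
    rmse_pct: float | None = None
    coef_ci: tuple[tuple[float, float], ...] | None = None
    loocv_rmse_mean: float | None = None
    loocv_rmse_sd: float | None = None
    bp_lm: float | None = None
    bp_p_value: float | None = None
    n_pairs: int | None = None
    provenance: str = ""

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.b3 * x**3 + self.b2 * x**2 + self.b1 * x

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "AdjustmentModel":
        d = json.loads(Path(path).read_text())
        if d.get("coef_ci") is not None:
            d["coef_ci"] = tuple(tuple(ci) for ci in d["coef_ci"])
        return cls(**d)


def published_model() -> AdjustmentModel:
    """The published adjustment equation, for cohorts without calibration data."""
    b3, b2, b1 = PUBLISHED_COEFFICIENTS
    return AdjustmentModel(b3=b3, b2=b2, b1=b1, provenance="published")


def measured_cd(f_vol: float, f_stim: float) -> tuple[float, bool]:
    """Device-measured central drive F_vol/F_stim, capped at 1.

    Under noise (or a fully activating burst) F_vol can exceed F_stim;
    the ratio is then capped at 1.0 and flagged, keeping the adjustment
    domain [0, 1].
    """
    if f_stim <= 0:
        raise ValueError("f_stim must be positive")
    ratio = f_vol / f_stim
    if ratio > 1.0:
        return 1.0, True
    return float(ratio), False


def true_cd(f_vol: float, mfga: float) -> float:
    """True central drive F_vol/MFGA (capped at 1 if f_vol exceeds MFGA)."""
    if mfga <= 0:
        raise ValueError("mfga must be positive")
    return float(min(f_vol / mfga, 1.0))


def _design(x: np.ndarray) -> np.ndarray:
    return np.column_stack([x, x**2, x**3])


def fit_adjustment(
    measured: Sequence[float],
    true: Sequence[float],
    participant_ids: Sequence | None = None,
    *,
    run_loocv: bool = True,
) -> AdjustmentModel:
    """Fit the origin-constrained cubic by ordinary least squares.

    R^2 is reported against the mean of the response (centered total sum
    of squares) with the uncentered variant alongside, since conventions
    differ for no-intercept models.  RMSE is in percentage points.
    Coefficient CIs are 95% intervals from the OLS covariance.  When
    participant ids are given (and cover >= 3 participants) the
    participant-wise LOOCV RMSE and the Breusch-Pagan test are run too.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(true, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measured and true must be equal-length 1-D sequences")
    if x.size < 4:
        raise ValueError("at least 4 pairs required to fit 3 coefficients")
    if np.unique(x).size < 3:
        raise ValueError("design is rank-deficient: too few distinct measured values")

    res = sm.OLS(y, _design(x)).fit()
    b1, b2, b3 = res.params
    resid = y - res.fittedvalues
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_centered = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    rmse_pct = 100.0 * float(np.sqrt(np.mean(resid**2)))
    ci = res.conf_int(alpha=0.05)
    # order CIs as (b3, b2, b1) to match coefficient order
    coef_ci = (tuple(ci[2]), tuple(ci[1]), tuple(ci[0]))

    bp_lm, bp_p = breusch_pagan(resid, x)

    loocv_mean = loocv_sd = None
    if run_loocv and participant_ids is not None:
        ids = np.asarray(participant_ids)
        if np.unique(ids).size >= 3:
            loocv_mean, loocv_sd = loocv_adjustment(x, y, ids)

    return AdjustmentModel(
        b3=float(b3),
        b2=float(b2),
        b1=float(b1),
        r_squared=r2_centered,
        r_squared_uncentered=float(res.rsquared),
        rmse_pct=rmse_pct,
        coef_ci=coef_ci,
        loocv_rmse_mean=loocv_mean,
        loocv_rmse_sd=loocv_sd,
        bp_lm=bp_lm,
        bp_p_value=bp_p,
        n_pairs=int(x.size),
        provenance="fitted",
    )


def apply_adjustment(model: AdjustmentModel, x: float) -> float:
    """Evaluate the adjustment at measured central drive ``x`` in [0, 1].

    Predictions outside [0, 1] (possible for a poorly calibrated model)
    are clipped with a warning.
    """
    if not (0.0 <= x <= 1.0):
        raise ValueError(f"measured central drive {x} outside [0, 1]")
    y = float(model.predict(x))
    if y < 0.0 or y > 1.0:
        warnings.warn(
            f"adjusted central drive {y:.4f} outside [0, 1]; clipping", stacklevel=2
        )
        y = float(np.clip(y, 0.0, 1.0))
    return y


def loocv_adjustment(
    measured: Sequence[float],
    true: Sequence[float],
    participant_ids: Sequence,
) -> tuple[float, float]:
    """Participant-wise leave-one-out cross-validation of the cubic fit.

    Each participant's pairs are held out in turn, the cubic refit on the
    rest, and the held-out RMSE recorded.  Returns (mean, SD) of the
    per-participant RMSEs in percentage points; a small SD relative to
    the mean indicates no single participant dominates the fit.
    """
    x = np.asarray(measured, dtype=float)
    y = np.asarray(true, dtype=float)
    ids = np.asarray(participant_ids)
    unique = np.unique(ids)
    if unique.size < 3:
        raise ValueError("LOOCV requires at least 3 participants")
    rmses = []
    for pid in unique:
        held = ids == pid
        beta = np.linalg.lstsq(_design(x[~held]), y[~held], rcond=None)[0]
        pred = _design(x[held]) @ beta
        rmses.append(100.0 * float(np.sqrt(np.mean((y[held] - pred) ** 2))))
    rmses = np.asarray(rmses)
    return float(rmses.mean()), float(rmses.std(ddof=1))


def breusch_pagan(
    residuals: Sequence[float], regressor: Sequence[float]
) -> tuple[float, float]:
    """Breusch-Pagan LM test of the residuals against a single regressor.

    Squared residuals are regressed on {1, regressor}; the statistic is
    n * R^2 of that auxiliary regression, chi-square with 1 df under
    homoscedasticity.
    """
    resid = np.asarray(residuals, dtype=float)
    reg = np.asarray(regressor, dtype=float)
    if resid.size != reg.size or resid.size < 3:
        raise ValueError("residuals and regressor must be equal length >= 3")
    if np.ptp(reg) == 0:
        raise ValueError("regressor is constant")
    if np.ptp(resid**2) == 0:
        # squared residuals are constant: the auxiliary regression has
        # zero explainable variance, LM = 0 by definition
        return 0.0, 1.0
    lm, p, _, _ = het_breuschpagan(resid, sm.add_constant(reg))
    return float(lm), float(p)
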