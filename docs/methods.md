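# Methods

This note documents the models, rules, and numerical conventions the
package implements, the design choices made where the method leaves room,
and what the synthetic-data generator does and does not emulate.

## Signal processing

Torque traces (1 kHz, ft-lbs, binary stimulation-trigger channel) are
low-pass filtered at 10 Hz with a fourth-order Butterworth response.
Zero-phase filtering is the default — a second-order design applied
forward and backward, which squares the magnitude response (fourth-order
overall) and cancels phase — so that burst-locked windows are not shifted
by filter delay. A causal single-pass fourth-order variant is available
(`zero_phase=False`). Edges are handled by reflect padding.

Burst onset is the first sample where the trigger channel equals 1; the
trace model enforces a single contiguous trigger run. Windows are
half-open, sample indices 0-based, and the time of sample *i* is
*i*/fs. From the filtered trace:

- `F_vol` = mean over `[onset − 0.1 s, onset)`;
- `F_stim` = max over `[onset, onset + 0.5 s)`. The burst lasts 150 ms and
  the evoked torque peaks shortly after it ends, so 500 ms comfortably
  brackets the peak; the window length is configurable and recorded in
  output metadata because the original post-burst search horizon is a
  convention, not a physical constant.

One non-obvious interaction drives a design choice here: a zero-phase
filter is non-causal, so the evoked-torque rise leaks *backward* ~100 ms
into the pre-burst window (the kernel support at a 10-Hz cutoff). The
F_vol mean is barely affected (≈−0.05 ft-lbs under default conditions),
but window *slope* and *variance* estimates are badly contaminated by the
leaked ringing. Quality-control quantities are therefore computed on a
causally filtered copy of the trace, which structurally cannot be
influenced by anything at or after burst onset. Feature values keep the
zero-phase path.

## Trial quality control

A trial is valid iff no flag is raised. Defaults (all configurable):

| rule | window | threshold | rationale |
|---|---|---|---|
| `high_variance` | 100-ms F_vol window | sample variance (ddof = 1) > 0.1 (ft-lbs)² | stimulation must land on a steady plateau |
| `nonsteady` | 0.5 s pre-burst | absolute OLS slope > 2.0 ft-lbs/s | automates the visual "torque increasing/decreasing" exclusion; over only 100 ms the slope estimator's noise SE (~1.2 ft-lbs/s at realistic noise) would swamp the threshold, so the slope is fitted over 0.5 s |
| `submax_90` | pre-burst history | F_vol < 0.90 × within-trial pre-burst peak | catches "reach a peak then drop off" efforts; configurable whether it excludes or merely annotates (default: excludes) |
| `no_burst` | — | trigger channel empty | burst-relative quantities undefined |

MVC acceptance: a maximal effort counts as a true MFGA estimate only if
F_vol ≥ 0.95 × MFGA; the protocol allows up to three attempts. All
comparisons use strict/inclusive boundaries exactly as stated (with a
1e-9 relative guard on the slope comparison so a ramp *exactly* at
threshold is not flagged by rounding). Per participant-limb, F_vol and
F_stim are averaged over valid trials only; zero valid trials is a
reportable state that excludes the limb downstream, never an error.

## Central drive and the adjustment equation

- measured CD = F_vol/F_stim, capped at 1 (noise can push F_vol above
  F_stim; the adjustment domain is [0, 1]), with a `capped` flag;
- true CD = F_vol/MFGA (available in calibration experiments, where MFGA
  is taken as the largest F_stim across that participant-device's valid
  MVC trials, and in simulation, where it is known);
- adjustment: OLS on the basis {x, x², x³} with no intercept, so a
  measured ratio of 0 maps to 0 exactly. R² is reported against the mean
  of the response (centered total sum of squares); the uncentered variant
  that some software reports for through-origin fits is included in the
  diagnostics. RMSE values are in percentage points of central drive.
  Coefficient CIs are 95% Wald intervals from the OLS covariance.
- leave-one-out cross-validation is by *participant*: each participant's
  pairs are held out, the cubic refit, and the held-out RMSE recorded;
  the mean ± SD across participants measures whether any individual
  dominates the fit. Note the per-fold RMSE is a chi-type statistic with
  intrinsic CV ≈ 1/√(2·n_fold); with few pairs per participant the SD
  across folds is dominated by that sampling noise rather than by
  participant heterogeneity.
- heteroscedasticity: Breusch–Pagan LM test, squared residuals regressed
  on {1, measured CD}, LM = n·R² of the auxiliary regression, χ²(1).
  If the squared residuals are exactly constant the LM statistic is 0 by
  definition.
- the package ships the published coefficients (0.798, −0.772, 0.868) as
  `published_model()` for cohorts lacking calibration data. This mapping
  is monotone on [0, 1] and attains its maximum 0.894 (89%) at x = 1 —
  high-performing individuals cannot be resolved above that ceiling.
  Fitted models whose predictions leave [0, 1] are clipped with a
  warning.

Under a constant stimulator efficacy *k* (the burst closes a fraction
*k* of the F_vol→MFGA gap), measured and true CD are related in closed
form by `true = k·m / (1 − (1 − k)·m)`; the cubic approximates this
family well (RMSE < 1e-3 on [0.2, 0.95] for fixed k), and a mixture of
k values across participants is what bends the pooled relationship into
the cubic shape.

## Cohort statistics

- **ICC(2,1)** (two-way random effects, absolute agreement, single
  measurement) from the two-way ANOVA decomposition, with the F-based CI
  using a Satterthwaite denominator df. Implemented in-package and
  cross-checked in the tests against an independent library
  implementation to 1e-9. If the error mean square is exactly zero the
  CI degenerates to the point estimate.
- **Bland–Altman**: bias = mean(b − a), limits = bias ± 1.96·SD (ddof = 1).
- **One-way ANOVA** with η² = SS_between/SS_total; 95% CI by inverting the
  noncentral-F cdf over the noncentrality parameter (robust bisection;
  the scipy `ncf.sf` edge case at λ = 0 is avoided by working with the
  cdf) and mapping λ → λ/(λ+N).
- **Šidák** pairwise: pooled-variance two-sample t per pair, adjusted
  p = 1 − (1 − p)^m over the m pairs.
- **%Δ6MWT speed** = 100·(d6 − d1)/d1 over the six per-minute distances;
  positive = sped up (the sign convention is recorded in output
  metadata).

The between-limb ANOVA treats the paretic and non-paretic limbs of the
same participants as independent groups, mirroring the validation design
it replicates; that ignores within-participant correlation and is a known
statistical caveat of the design, not of the implementation.

## Synthetic-data generator

No torque recordings are distributed with this package; the generator
exists to give every pipeline stage a labelled test bed.

Per trial (1 kHz, default 6 s, burst at 3 s):

- voluntary torque rises along a raised-cosine ramp reaching the plateau
  `F_vol = effort × true_cd_max × MFGA` **exactly** at 1.0 s (an
  asymptotic rise would never attain the plateau, making exact
  ground-truth comparisons impossible);
- after an electromechanical delay (default 40 ms — evoked force lags
  stimulus onset physiologically), the evoked torque rises along a
  critically damped second-order response (τ = 30 ms, zero initial
  slope) toward closing `k × (MFGA − F_vol)` while the burst is on
  (≥95% closed by burst end), then decays first-order (τ = 150 ms). The
  S-shaped onset matters: a first-order (kinked) onset rings through the
  zero-phase filter strongly enough to corrupt pre-burst QC on perfectly
  clean trials;
- device transform `gain·torque + offset`, then white Gaussian noise
  (default SD 0.35 ft-lbs, a realistic plateau fluctuation at 10-Hz
  bandwidth);
- the trigger channel marks `[3.0 s, 3.15 s)`; ground truth (F_vol,
  F_stim, measured/true CD) is computed from the *noiseless sampled*
  waveform, so at zero noise the pipeline must reproduce it to float
  precision (asserted at 1e-6 on the unfiltered path).

Twitch recruitment for pulse-width selection is saturating-linear:
`peak = 0.12·MFGA · min(1, pw/pw_sat)` + noise, with the saturation width
`pw_sat` per participant in [350, 600] µs; the selection rule picks the
minimum width whose twitch reaches the ramp maximum.

Cohorts: per-limb-group MFGA is drawn from the published group
means/SDs; true central drive from a normal with mean equal to the ratio
of the published group F_vol and MFGA means and SD equal to the published
central-drive SD, truncated to [0.05, 1] (the three published group rows
are mutually linked, so matching all of them simultaneously with
independent draws is impossible; this parameterization reproduces the
F_vol and MFGA rows and, through the measurement model, lands within
about one point of the published adjusted-central-drive row).
Stimulator efficacy k ~ U(0.6, 0.9) per participant — the efficacy
mixture is the single mechanism producing central-drive overestimation.
The two-device experiment gives device B a per-participant offset
(default 3.7 ± 6.64 ft-lbs). Six-minute-walk distances follow a logistic
function of paretic true central drive, standardized within-cohort, with
the signal/noise split derived from the published totals (321 ± 103 m)
and correlation strengths (≈0.6–0.7); per-minute distances follow a
linear drift consistent with the generated %Δ speed plus small jitter.
All randomness flows from one seed through per-participant
`SeedSequence` spawns (bitwise-reproducible cohorts).

What the generator does **not** emulate: fatigue within or across trials,
antagonist co-contraction, electrode-placement or stimulus-intensity
physics, non-Gaussian or autocorrelated measurement noise, and any
within-participant correlation between limbs. Passing tests demonstrate
the pipeline's correctness against this model's ground truth, not
robustness to every artifact of real recordings.

### A replication caveat

With the published group distributions (adjusted central drive
50.39 ± 21.44 vs 70.12 ± 20.25 for paretic vs non-paretic, n = 26 per
limb), the paretic-vs-non-paretic contrast has Cohen's d ≈ 0.95 — about
80% power per simulated cohort at the Šidák-adjusted α. Group *ordering*
replicates essentially always, but demanding all nine pairwise
comparisons significant in ≥95% of cohorts is beyond what those effect
sizes support; the corresponding test documents the observed rates.

## Problem sizes

Default simulations are sized to the study they emulate (16 calibration
participants × 2 devices × 7 trials; 26 post-stroke participants × 2
limbs × 3 trials + 16 controls), and simulation-based tests use
10–1000 replicates per property — enough for the Monte-Carlo error to
sit well inside each asserted tolerance. Coefficient-recovery checks
average over replicated 112-pair experiments because a single fit of the
collinear basis {x, x², x³} carries a cubic-coefficient SE of ≈0.11 at
noise SD 0.03: the replicate mean is an unbiased estimate of the same
coefficient with controlled Monte-Carlo error.
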