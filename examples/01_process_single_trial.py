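"""Process one burst-superimposition trial: filter, locate the burst,
extract F_vol and F_stim, and apply trial QC.

Simulates a paretic-limb MVC trial (known ground truth), runs it through
the same processing any recorded trace CSV would get, and compares the
extracted quantities with the generator's truth.
"""

from centraldrive import summarize_trial, measured_cd
from centraldrive.simulate import ParticipantParams, simulate_trial

participant = ParticipantParams(
    id="S01",
    group="post-stroke",
    limb="paretic",
    mfga=42.0,          # true maximum force-generating ability, ft-lbs
    true_cd_max=0.65,   # volitional ceiling: F_vol_max / MFGA
    efficacy_k=0.8,     # burst closes 80% of the F_vol -> MFGA gap
    noise_sd=0.35,
)

trial = simulate_trial(participant, effort_fraction=1.0, rng=7)
m = summarize_trial(trial.trace)
ratio, capped = measured_cd(m.f_vol, m.f_stim)

print(f"extracted F_vol  = {m.f_vol:6.2f} ft-lbs (truth {trial.truth.f_vol:6.2f})")
print(f"extracted F_stim = {m.f_stim:6.2f} ft-lbs (truth {trial.truth.f_stim:6.2f})")
print(f"measured central drive = {ratio:.3f} (truth {trial.truth.measured_cd:.3f})")
print(f"true central drive     = {trial.truth.true_cd:.3f}")
print(f"QC flags: {sorted(m.flags) or 'none'} -> trial valid = {m.valid}")
print()
print(
    "The measured ratio F_vol/F_stim overestimates the true ratio F_vol/MFGA\n"
    "because the burst only recovers 80% of the unaccessed capacity here;\n"
    "that systematic gap is what the adjustment equation corrects."
)
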