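"""End-to-end post-stroke cohort analysis.

Simulates the validation cohort (26 post-stroke participants, both limbs,
3 MVC burst-superimposition trials each, plus 16 neurotypical controls
and six-minute walk tests), processes every trace, aggregates valid
trials per limb, adjusts central drive with the published equation, and
runs the group comparisons and walking-function correlations.
"""

from centraldrive import pipeline as pl
from centraldrive.simulate import simulate_cohort_exp2

cohort = simulate_cohort_exp2(seed=99)
measurements = pl.process_trials(t.trace for t in cohort.iter_trials())
summary = pl.limb_summary(measurements)

print(f"{len(measurements)} trials processed, "
      f"{sum(m.valid for m in measurements)} valid")
table = summary[summary.n_valid > 0].groupby("limb")[
    ["f_vol", "f_stim", "adjusted_cd"]
].mean()
print("\ngroup means (F_vol / strength capacity in ft-lbs, adjusted CD as a ratio):")
print(table.round(2).to_string())

comparisons = pl.group_comparisons(summary)
print("\none-way ANOVA across limb groups:")
for var, c in comparisons.items():
    print(f"  {var}: F = {c.f_statistic:.1f}, p = {c.p_value:.2g}, "
          f"eta^2 = {c.eta_squared:.3f} "
          f"[{c.eta_squared_ci[0]:.3f}, {c.eta_squared_ci[1]:.3f}]")

correlations = pl.walk_associations(summary, cohort.walk_minutes)
print("\n6MWT associations with paretic adjusted central drive:")
for name, v in correlations.items():
    print(f"  {name}: r = {v['r']:.3f}, p = {v['p']:.3g} (n = {v['n']})")
print()
print(
    "Expected pattern: paretic < non-paretic < neurotypical on every\n"
    "variable, with large effect sizes, and a moderate positive correlation\n"
    "between paretic central drive and walking function."
)
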