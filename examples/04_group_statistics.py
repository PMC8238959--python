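"""Group-level inference on a simulated cohort.

Fits the diagnosis x culture model (treatment-coded, control/US reference,
sex and age covariates) per condition, adjusts the p-value family with
Benjamini-Hochberg, and follows up with Tukey-adjusted cell contrasts plus
the non-parametric and correlation helpers.
"""

import numpy as np

from ranevs import (bh_adjust, cohort_table, default_group_params,
                    fit_group_model, mann_whitney, pairwise_contrasts,
                    partial_pearson, score_cohort, simulate_cohort)

gp = default_group_params(asd_extra_p_regression=0.08)
people, runs = simulate_cohort(gp, n_per_group=12, seed=11)
table = cohort_table(score_cohort(runs), people)

result = fit_group_model(table, "refixations", "non_symbolic")
print("refixations ~ diagnosis * culture + sex + age (non-symbolic):")
print(result.effects_frame().round(4).to_string(index=False))
lr, p_lr = result.lr_interaction
print(f"interaction LR test: LR = {lr:.3f}, p = {p_lr:.3f}")

# BH adjustment across the family of effect p-values
ps = [e.p for e in result.effects]
print("BH-adjusted p:", np.round(bh_adjust(ps), 4))

print("\nTukey cell contrasts:")
for c in pairwise_contrasts(result):
    print(f"  {c.cell_a:>10} vs {c.cell_b:<10} "
          f"diff = {c.estimate:+.2f}, p_tukey = {c.p_tukey:.4f}")

# non-parametric group comparison of mean EVS (ASD vs control, one culture)
sub = table[(table.condition == "non_symbolic") & (table.culture == "HK")]
asd = sub[sub.diagnosis == "ASD"].mean_evs_items
ctl = sub[sub.diagnosis == "control"].mean_evs_items
u, p = mann_whitney(asd, ctl)
print(f"\nMann-Whitney EVS ASD vs control (HK): U = {u:.1f}, p = {p:.3f}")

# partial correlation controlling for age
r, p = partial_pearson(sub.refixations, sub.naming_time_s,
                       covariates=sub[["age"]].to_numpy())
print(f"partial r(refixations, naming time | age) = {r:.3f}, p = {p:.3f}")
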