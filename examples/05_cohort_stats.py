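"""Cohort-level analysis: phantom cohort, descriptive summary, mixed model.

Generates a small phantom cohort (every animal carries every treatment,
with an animal-level random effect), extracts the tidy parameter table,
summarises per group, and fits the mixed model with Tukey-type contrasts
for one parameter.
"""

import warnings

from histobridge import (
    fit_mixed_model,
    generate_cohort,
    reports_to_table,
    summarise,
)
from histobridge.phantom import PhantomConfig

manifest, truths = generate_cohort(
    n_animals=8,
    groups=["empty", "nHA-LC"],
    seed=42,
    base_config=PhantomConfig(pixel_pitch_um=20.0, noise_sd=0.0),
    group_configs={"empty": {"new_bone_fill_fraction": 0.35},
                   "nHA-LC": {"new_bone_fill_fraction": 0.70}},
    animal_sd=2.0,
    defect_sd=1.5,
)
table = reports_to_table([t.true_report for t in truths], manifest)

param = "nBV_TV_pct"
sub = table[(table.parameter == param) & (table.roi == "cortical")]
print(summarise(sub).to_string(index=False))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    fit = fit_mixed_model(sub)
c = fit.contrast("nHA-LC", "empty")
print(f"\nmodel: {fit.method}; animal variance {fit.animal_variance:.2f}")
print(
    f"nHA-LC - empty on {param}: {c.estimate:+.1f} pp "
    f"(95% CI {c.ci_low:.1f} to {c.ci_high:.1f}), "
    f"Tukey-adjusted p = {c.p_adjusted:.2g}"
)

# The contrast recovers the 35-percentage-point difference injected through
# the groups' new-bone fill fractions; the random intercept absorbs the
# shared animal effect.
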