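"""Generate a synthetic household survey and write it as a CSV fixture.

Two strata (urban/rural) with the rural stratum oversampled, so design
weights are unequal; one coverage indicator concentrated among the rich
(beta > 0). The truth.json sidecar stores the latent wealth and the true
(alpha, beta) so downstream estimates can be checked against ground truth.
"""

from pathlib import Path

import mchequity as me

cfg = me.default_config(
    n_households=2000,
    indicators=[
        me.IndicatorSpec("facility_delivery", "coverage", alpha=-1.8, beta=1.2,
                         residence_effect=0.6, education_effect=0.5),
    ],
    seed=7,
)
survey = me.generate_survey(cfg)
out = Path("scratch/demo_fixture")
paths = me.write_fixture(survey, out)

weights = sorted({round(h.weight, 4) for h in survey.households})
print(f"households: {len(survey.households)}, individuals: {len(survey.individuals)}")
print(f"distinct design weights (rural oversampled -> lower weight): {weights}")
prev = me.weighted_prevalence(
    [r.values['facility_delivery'] for r in survey.individuals],
    [r.weight for r in survey.individuals],
)
print(f"weighted prevalence of facility_delivery: {prev:.3f}")
print("wrote:", ", ".join(str(p) for p in paths.values()))
# The two weights are share/fraction per stratum (normalized to mean 1);
# the prevalence is the design-weighted population estimate.
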