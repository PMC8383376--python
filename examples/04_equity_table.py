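"""Assemble a full equity table for several indicators at once.

One row per indicator: weighted prevalence, concentration index with
stars, richest-vs-poorest risk ratios (quintile 5 vs 1, decile 10 vs 1),
and stratified urban:rural and higher:lower-education risk ratios.
"""

import mchequity as me

cfg = me.default_config(
    n_households=4000,
    indicators=[
        me.IndicatorSpec("teen_pregnancy", "outcome", alpha=-2.4, beta=-0.8,
                         residence_effect=-0.4),
        me.IndicatorSpec("skilled_prenatal_care", "coverage", alpha=-1.0, beta=0.9,
                         residence_effect=0.5, education_effect=0.6),
        me.IndicatorSpec("immunization", "coverage", alpha=-1.7, beta=0.4,
                         residence_effect=0.5, education_effect=0.7),
    ],
    seed=2024,
)
survey = me.generate_survey(cfg)
rows = me.build_equity_table(survey)
df = me.equity_table_frame(rows)
cols = ["indicator", "indicator_class", "avg_prevalence_pct", "CI", "CI_stars",
        "rr_q5_q1_rr", "rr_d10_d1_rr", "rr_urban_rural_rr", "rr_higher_lower_educ_rr"]
print(df[cols].round(3).to_string(index=False))
print("\nnote:", df.attrs["variance_note"])
# Outcome rows with negative CI are concentrated among the poor and show
# richest:poorest RR < 1; coverage rows with positive CI show RR > 1.
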