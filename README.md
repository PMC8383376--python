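# mchequity

Socioeconomic equity analysis for maternal-and-child-health (MCH)
indicators from household surveys, for epidemiologists and health-policy
analysts working with MICS/DHS-style microdata. The package implements the
standard measurement chain end to end, and ships a synthetic
household-survey generator with known ground-truth inequity so every stage
can be verified without access to restricted microdata.

## What it computes

**Wealth index.** Binary asset-ownership indicators are standardized
(mean 0, sd 1) and weighted by the first principal component; household
scores are the loading-weighted sums, re-standardized, then ranked and cut
into design-weighted quintiles and deciles (1 = poorest). A single index
is fitted to the whole sample — never separately by residence.

**Concentration curve and index.** With households ranked poorest →
richest and L_h(p) the cumulative share of a health variable h against the
cumulative population fraction p, the concentration index is

    C = 1 − 2 ∫₀¹ L_h(p) dp

equivalently, for a discrete sample with equal weights and ranks
r_i = i/N,

    C = 2/(Nμ) · Σ h_i r_i − 1 − 1/N

and, the computational workhorse for weighted data,

    C = (2/μ) · cov_w(h, r)

where μ is the weighted mean of h and r the weighted fractional rank.
C ∈ [−1, 1]; C < 0 means h is concentrated among the poor (pro-poor
concentration, curve above the 45° diagonal), C > 0 among the rich.
Standard errors come from the convenient regression of 2σ²_r·h/μ on r
(robust slope SE), with a unit bootstrap as an alternative; significance
stars follow the \*/\*\*/\*\*\* ladder at p < 0.1 / 0.05 / 0.01.

**Equity tables.** Per indicator: weighted prevalence, CI with stars and
direction, richest-vs-poorest risk ratios (quintile 5 : quintile 1 and
decile 10 : decile 1), and stratified risk ratios urban : rural and
higher : lower education, with Katz log-method intervals and p-values.

**Synthetic surveys.** Latent standard-normal household wealth drives
binary asset ownership (one-factor logit model) and indicator prevalence
through a logit link with a controllable wealth effect β; strata with
unequal sampling fractions induce unequal design weights. A calibration
routine finds the β that reproduces any target concentration index.

## Worked example

```python
import mchequity as me

cfg = me.default_config(
    n_households=4000,
    indicators=[
        me.IndicatorSpec("teen_pregnancy", "outcome", alpha=-2.4, beta=-0.8,
                         residence_effect=-0.4),
        me.IndicatorSpec("skilled_prenatal_care", "coverage", alpha=-1.0, beta=0.9,
                         residence_effect=0.5, education_effect=0.6),
    ],
    seed=2024,
)
survey = me.generate_survey(cfg)
df = me.equity_table_frame(me.build_equity_table(survey))
print(df[["indicator", "avg_prevalence_pct", "CI", "CI_stars",
          "rr_q5_q1_rr", "rr_urban_rural_rr"]].round(3).to_string(index=False))
```

prints

```
            indicator  avg_prevalence_pct     CI CI_stars  rr_q5_q1_rr  rr_urban_rural_rr
       teen_pregnancy               9.282 -0.355      ***        0.138              0.630
skilled_prenatal_care              35.825  0.287      ***        4.436              1.292
```

The outcome generated with a negative wealth effect shows a negative,
highly significant concentration index (the burden sits with the poor)
and a richest:poorest risk ratio well below 1; the coverage indicator
generated with a positive wealth effect shows the mirror image. The
`examples/` directory has one short script per capability: survey
simulation, wealth-index construction, the three concentration-index
routes, full equity tables, and calibration of β to a target C.

A thin CLI wraps the same pipeline for shell use:

```
mchequity simulate --config demo.yaml --seed 7 --out fixture/
mchequity wealth-index fixture/households.csv --out wealth/
mchequity equity-table fixture/ --out tables/
```

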