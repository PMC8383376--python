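# Methods

## The measurement chain

The package measures socioeconomic inequity in binary MCH indicators in
three steps: (i) choose the indicator whose distribution is examined;
(ii) stratify the population by an equity stratifier — household wealth
(asset index), residence, or education; (iii) quantify inequality with
the concentration index and richest-vs-poorest risk ratios. All
estimators are design-weighted: each unit carries an inverse-sampling
weight, and every weighted statistic is invariant to rescaling all
weights by a positive constant (the generator normalizes weights to mean
1 purely so fixtures are comparable).

## Wealth index

Assets are binary ownership indicators. Each column is standardized to
mean 0, sd 1 with the population (denominator-N) convention — immaterial
to ranks, fixed for bit-reproducibility. Constant columns are dropped
with a warning rather than raising: field data routinely contain
saturated assets. The index weights are the first principal component of
the standardized matrix (equivalently, the leading eigenvector of the
sample correlation matrix), computed **unweighted** over all sampled
households; design weights enter only at the ranking/quantile stage. The
PC sign is fixed by an orientation rule — scores must correlate
nonnegatively with the raw asset count — so "more assets ⇒ richer" holds
regardless of eigenvector sign conventions. Scores are the loading-
weighted sums re-standardized to mean 0, sd 1. A single index covers the
entire sample; urban and rural subsamples are never scored separately.

Ranks ascend in score with ties broken by household id, making every
downstream output deterministic. Weighted k-quantiles walk households in
score order and assign each to the group containing its cumulative-weight
midpoint, `ceil(k · (cum_before + w/2) / W)`; each group's total weight
is then within one household's weight of W/k, and decile labels are
always consistent with quintile labels (decile ∈ {2q−1, 2q}).

## Concentration index

Three routes, used as mutual cross-checks:

* curve form: C = 1 − 2·∫L_h(p)dp with a trapezoid rule on the
  piecewise-linear curve; agrees with the covariance form to within 1/N;
* discrete form: C = 2/(Nμ)·Σh_i r_i − 1 − 1/N with r_i = i/N (equal
  weights);
* covariance form: C = (2/μ)·cov_w(h, r), the default estimator, using
  the weighted **population** covariance (total-weight denominator).

Fractional ranks use the endpoint convention r_i = (Σ_{j≤i} w_j)/W by
default, because under it the covariance form reproduces the discrete
form *exactly* for equal weights — an algebraic identity the test suite
asserts to 1e-12. The common midpoint convention
(cum_before + w/2)/W is available behind a flag; it does not reduce to
i/N on small N, but it is the convention under which rank reversal
negates C exactly for *unequal* weights (with endpoint ranks that
antisymmetry is exact only for equal weights, and approximate otherwise,
with error bounded by the largest weight share). Both conventions agree
to O(1/N).

Binary indicators are analyzed with the plain CI. For bounded variables
the Wagstaff (C/(1−μ)) and Erreygers (4μC for binary h) normalizations
are provided as opt-in post-corrections (`wagstaff_normalized`,
`erreygers_corrected`); they are deliberately not the default, since the
plain index is what equity tables of this kind report.

### Inference

No closed-form SE accompanies published CI tables of this kind, so the
package provides two routes. The analytic default is the "convenient
regression": regressing the transformed variable 2σ²_r·h_i/μ on the
fractional rank by weighted least squares gives a slope equal to the
covariance-form C, and the slope's standard error is the SE of C. The
package uses the heteroskedasticity-robust (HC1) slope SE rather than the
classical WLS one: with design weights and binary h the classical WLS
variance assumes a weight-variance relationship that does not hold, and
the robust form is what keeps the test's type-I error calibrated (the
suite verifies a rejection rate within [0.03, 0.07] at the 5% level under
a null wealth effect, 1,000 datasets of 5,000 households). The analytic
path refuses N < 30. The alternative is a unit bootstrap (resample units
with their weights, recompute ranks and C per replicate, B ≥ 100
recommended, seed-controlled); analytic and bootstrap SEs agree within
~15% on series of a few hundred units. p-values use the normal reference.
Both routes ignore survey clustering — p-values are design-naïve, and the
equity-table metadata carries a note saying so.

Direction is classified from the sign of C when p < 0.1 (the loosest star
threshold), otherwise "equal". Stars: \*\*\* p<0.01, \*\* p<0.05, \* p<0.1.
Published tables of this kind sometimes print a garbled star footnote
(assigning \*\* to two thresholds); the standard ladder above is used.

## Risk ratios

RR = weighted prevalence of group a / weighted prevalence of group b,
with a's label always listed first (quintile5:quintile1,
decile10:decile1, urban:rural, higher:lower education). Only the top and
bottom wealth groups enter the richest-vs-poorest ratios. Intervals and
p-values use the Katz log-normal method; effective sample sizes are the
Kish approximation (Σw)²/Σw², i.e. weights are accounted for but
clustering is not. A 0.5 continuity correction on effective counts is
applied only when a zero cell blocks the log-RR variance, and the result
is flagged; a zero denominator prevalence yields an infinite-RR sentinel
with a warning so one empty cell never aborts a whole table.

## Synthetic surveys

The generator emulates the structure the analysis assumes, with ground
truth stored in a sidecar so estimates are checkable:

* latent wealth w ~ N(0,1) per household;
* K binary assets, conditionally independent given w (one-factor model),
  owned with probability logistic(γ_j·w + c_j); γ_j uniform on the
  configured loading range, intercepts c_j spread evenly over
  [−1.25, 1.25] so ownership rates span roughly 22–78%;
* strata with population shares and sampling fractions; sampled counts
  follow share×fraction (largest-remainder rounding) and design weights
  are share/fraction normalized to mean 1 — unequal fractions emulate a
  non-self-weighting design with oversampled strata;
* education (higher/lower) via logistic(−1.4 + 0.9·w + 0.8·urban);
* each indicator drawn per individual with probability
  logistic(α + β·w + residence effect·urban + education effect·higher).

Defaults — 12 assets, loadings in (0.8, 2.5), urban 45% (fraction 0.8) /
rural 55% (fraction 1.2), one record per household — are the package's
reference study conditions: a deliberately plain two-stratum design whose
asset battery is informative enough that the index ranks households well
(Spearman ρ ≈ 0.9 with latent wealth at n = 10,000). One global seed
drives all stages through per-stage child seeds, so adding an indicator
never changes earlier draws and identical configs give byte-identical
fixtures. Records-per-household is a knob standing in for the unspecified
real-world denominator (women, births, children per household).

What the generator does *not* emulate: multi-stage cluster sampling (so
no intra-cluster correlation), non-response, item missingness, correlated
asset batteries beyond the single factor, or continuous/count outcomes.
Passing tests therefore demonstrate correctness of the estimators under a
clean one-factor, independent-unit world — not robustness to the messier
dependence structure of real survey data, where design-naïve p-values
would be anticonservative.

### Calibration

`calibrate_effect` finds β such that the *estimated* CI (through the full
pipeline: asset generation, PCA index, weighted ranking) matches a target
to ±0.01, by monotone bisection with common random numbers across β
evaluations (default 8 replicates per evaluation). Calibrating on the
estimated rather than the true-wealth CI means the attenuation from
imperfect asset-based ranking is folded into β, so downstream recovery
tests are honest about the whole chain. β = 0 maps to target 0 exactly by
the symmetry of the logit link in w.

## Numerical choices and edge cases

* μ = 0 (empty indicator) ⇒ CI undefined; equity tables emit the row with
  the CI marked undefined and continue.
* Ties in wealth score share a rank block in household-id order; the CI
  is invariant to within-tie ordering under the midpoint convention and
  approximately (≤ tie weight/W) under the endpoint default.
* k ∉ {5, 10} quantiles raise unless explicitly allowed.
* Fixture CSVs are written with %.17g floats and read with pandas'
  round-trip parser, so read(write(s)) is exact.
* Problem sizes in the test suite (10,000-household recovery runs, 1,000
  null datasets of 5,000 households, 50-survey table scans) were chosen
  as the smallest sizes at which Monte-Carlo noise is comfortably inside
  the asserted bands.
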