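# Methods

This note documents the models, defaults and numerical choices behind
`pvsignal`, and what the synthetic data can and cannot demonstrate.

## Data model

An ICSR carries exactly one suspected drug, one or more coded reactions
(preferred term + per-reaction outcome), and report-level attributes:
age group (the eight portal strata from "0–1 Month" to "More than 85
Years", plus Not Specified), sex, reporter group, ISO country code
("XX" = unknown), EEA/non-EEA region, seriousness and calendar year.
Outcome is deliberately a *reaction-level* attribute while seriousness
is *report-level*: outcome denominators in the reference tables exceed
the report counts, so outcomes are event-level facts.  Reports with
several suspected drugs are rejected at parse time — the comparison
design needs disjoint per-drug report sets, and multi-drug attribution
is a known confounder this package does not attempt to resolve.

The on-disk format is one CSV/TSV row per report–reaction pair
(`report_id, drug, pt, outcome, age_group, sex, reporter_group,
country, region, seriousness, year`).  Parsing normalizes case,
surrounding/internal whitespace and hyphen variants onto canonical
spellings; anything else is an error with the offending row number,
never a guess.  Exact duplicate (report_id, pt, outcome) rows collapse
with a logged warning.  Region is cross-checked against a packaged EEA
membership list whenever the country is known.

Because the licensed MedDRA dictionary cannot ship, a mock PT→SOC
mini-hierarchy is packaged: all preferred terms appearing in the
reference listings mapped to their SOCs, plus a few realistic terms for
every remaining SOC so all 27 classes are populated.  Users can supply
their own mapping TSV.  PTs absent from the mapping route to an
`Unmapped` sentinel: they are excluded when iterating SOCs but stay in
the b/d margins of every table (a reaction must land somewhere) and in
reaction totals.

## Contingency tables

One drug of interest against the pooled remaining drugs, per SOC.  Two
counting bases are both first class and labelled in every output:

* **report-level** (default): `a` counts reports with ≥ 1 reaction in
  the SOC — the "at least one ADR" convention of the per-SOC reference
  table; N is the number of reports.
* **reaction-level**: every reaction counts; N is the number of
  reactions.

The default is report-level because that is the only basis whose inputs
the public portal actually exposes.  The reference publication's printed
SOC-level RORs could not be regenerated from its own printed counts
under either basis (the hand value for the strongest cardiac signal is
≈19.6 against a printed 26.29, and the printed interval widths imply
far larger cells), so the statistics here are validated against
independent oracles and properties rather than against that table.

## Signal statistics

**ROR / PRR / χ².**  Point estimates are the textbook ratios; intervals
are Wald intervals on the log scale with multiplier 1.96 (95%).  When a
table contains a zero, intervals switch to Haldane–Anscombe
+0.5-corrected cells and the result is flagged `corrected`; the raw
point estimate is kept whenever defined (a = 0 reports a raw 0, which
can never satisfy a lower-bound rule).  With the correction disabled,
an undefined ratio raises instead.  The χ² is Pearson's without
continuity correction (the proportion test on shares is the same
statistic); Yates' correction is available and only ever shrinks it.

**BCPNN information component.**  IC = log₂ p₁₁/(p₁·p₂) with
independent posteriors p₁₁ ~ Beta(a + γ₁₁, N − a + γ − γ₁₁),
p₁ ~ Beta(a+b+α₁, N−(a+b)+α−α₁), p₂ ~ Beta(a+c+β₁, N−(a+c)+β−β₁);
defaults α₁=β₁=1, α=β=2, γ₁₁=1, and γ scaled as
γ₁₁(N+α)(N+β)/((a+b+α₁)(a+c+β₁)) so the prior IC expectation is zero.
The implementation uses the *exact* posterior mean and variance of IC
(digamma/trigamma sums divided by ln 2) rather than the historical
log-of-expectation/delta-method approximations: the exact moments agree
with a Monte-Carlo evaluation of the same posterior to sampling error,
which is what the test suite asserts, while the approximations diverge
noticeably for small cells.  IC025 = mean − 1.96·sd.  A one-parameter
gamma approximation (IC = log₂ (a+½)/(E+½) with a Gamma(a+½, E+½)
posterior) is available behind `BCPNNConfig(method="gamma-approx")`;
it agrees with the exact moments only where counts are large and the
ratio near 1, and is provided for comparison with that strand of
practice, not as the default.

**MGPS.**  The reporting-rate ratio λ has a two-component gamma mixture
prior (shape/rate), a | λ ~ Poisson(λE), E = (a+b)(a+c)/N.  The prior
is fitted once per screening run by maximizing the summed log of the
implied negative-binomial mixture over all (drug, SOC) cells, on
log/logit-transformed parameters, Nelder–Mead from five deterministic
starts — the canonical start (0.2, 0.1, 2, 4, ⅓) first — with 1e-8
objective tolerance; non-convergence from every start raises, carrying
the best parameters found.  At least 20 cells are required to identify
five parameters; the mixture weight can be frozen (`fix_p=1` gives a
single-component fit, used in recovery tests).  The posterior is
Q·Gamma(α₁+a, β₁+E) + (1−Q)·Gamma(α₂+a, β₂+E) with Q the posterior
component weight; EBGM = 2^{E[log₂ λ]} via digamma terms, and EB05
solves mixture CDF = 0.05 by Brent root-finding (tolerance 1e-6)
bracketed by the component quantiles, defensively widened against
rounding when the components nearly coincide.

**Thresholds.**  ROR/PRR flag on lower bound > 1 (strict) and a ≥
min_cases (inclusive); BCPNN on IC025 > 0 (strict); MGPS on EB05 ≥ cut
and EBGM ≥ 2.5 (inclusive).  The published rule set prints two
alternatives for the case count (3/5) and the EB05 cut (1.8/2.0); both
are configurable with defaults 3 and 2.0, and both choices are
exercised in tests.  The screen reports the four methods side by side
with a 0–4 count of flagging methods; no conjunction and no
multiplicity adjustment is applied, matching practice for hypothesis-
generating screens.

A structural caveat the test suite documents explicitly: with few drugs
in the database, a/E for a drug that dominates its own SOC margin
saturates near N/(a+b), so the observed/expected methods (MGPS, BCPNN)
cannot reach their cut-offs for a strong signal in a drug that
contributes a large share of the database — a small signal drug against
a large comparator pool is the regime these statistics are built for.

## Synthetic cohorts

The generator emulates the line-listing structure: per drug, a fixed
report count; reactions per report geometric with mean 2.6 (minimum 1,
optional cap) — chosen to match the observed reaction/report ratios of
roughly 2.1–2.7; reaction SOCs from a 27-class baseline profile;
preferred terms uniform within the chosen SOC; demographics independent
draws from categorical marginals; country drawn conditionally on region
so the region/country invariant holds by construction.  A planted
(drug, SOC, θ) signal multiplies that SOC's selection *odds* by θ and
renormalizes (baseline p becomes θp/(1−p+θp)), so both counting bases
respond the way a genuine reporting excess would.  Each drug has its
own deterministic sub-stream derived from (seed, drug label): per-drug
output is invariant to the other drugs in the configuration, and equal
seeds reproduce byte-identical listings.

`make_paper_like_config()` pools the packaged reference tables into the
default study conditions: 822/4222/852 reports, pooled demographic and
SOC marginals.  The packaged yearly table is synthetic fill around
three exactly-known anchor counts (see `fixtures.py`); its only role is
to carry plausible year structure.

What the generator does **not** emulate — and therefore what passing
calibration/power tests do not establish about real data: reporting
delays and secular trends, duplicate and multi-drug reports, masking of
one signal by another, correlated demographics, PT-level reporting
heterogeneity within a SOC, and under-reporting.  The calibration
result (null flag rates at or below the nominal level) and the power
result (θ=5 at a ≥5% baseline SOC detected essentially always at 2000
reports/drug) characterize the statistics under the generator's
idealized independence structure only.

## Fixture expansions

The packaged characteristics table is expanded into a report collection
by assigning strata independently per field in fixed row order: every
univariate marginal (including event-level outcomes) reproduces the
printed counts exactly, while joint distributions are artificial and
must not be interpreted.  The per-SOC table expands into one
single-reaction report per counting unit.  These expansions exist so the
descriptive layer and table builders can be verified end to end against
published numbers without any network access.

## Problem sizes and determinism

Default verification runs use: 30-table grids for the ratio statistics,
20 tables × 10⁶ draws for the sampling check of the IC moments, 5000
cells for single-gamma prior recovery (20 000 for the two-component
fit), 200 replicates × 600 reports/drug for null calibration and 200 ×
2000/drug for power; the acceptance script defaults to 100 replicates.
All randomness flows from explicit seeds; screening output is
deterministic for a fixed input and configuration (fixed optimizer
starts, no sampling in the closed-form statistics), which the suite
checks bytewise through the CLI.

## Known limitations

* No duplicate-report detection, no stratified (age/sex) or adjusted
  analyses, no PT-level MGPS prior refitting (PT-level screening reuses
  the SOC machinery).
* The mock MedDRA map is flat (PT→SOC only); no HLT/HLGT levels,
  multi-axiality, or versioning.
* Wald intervals for ROR/PRR are poor at very small cells even with the
  continuity correction; the Bayesian statistics are the better-behaved
  choice there.
* Expectedness assessment against product information and any clinical
  interpretation of flags are out of scope: a flag is a statistical
  reporting signal, not a causal claim.
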