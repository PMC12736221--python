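# pvsignal

Disproportionality analysis and signal screening for spontaneous
adverse-event reports.

## What this is for

Pharmacovigilance databases such as EudraVigilance collect Individual
Case Safety Reports (ICSRs): one spontaneous report of suspected adverse
drug reactions (ADRs), each reaction coded as a MedDRA preferred term
(PT) rolled up into one of 27 system organ classes (SOCs).  Signal
detection asks whether a drug–event combination is reported
*disproportionately* often relative to the rest of the database.

`pvsignal` implements the complete screening pipeline used to compare
antiseizure drugs for difficult-to-treat epileptic syndromes
(stiripentol, cannabidiol, fenfluramine) against each other: parsing and
validating portal-style line listings, descriptive stratification
(demographics, seriousness, outcomes, SOC and PT counts, yearly trends),
two-by-two contingency tables of one drug against the pooled
comparators, and four signal statistics with their standard thresholds.
A synthetic ICSR generator with plantable drug–SOC association signals
makes every stage testable offline, including type-I calibration and
power studies.

## The statistics

For each (drug, SOC), counts are arranged as

|                   | SOC of interest | other SOCs |
|-------------------|-----------------|------------|
| drug of interest  | a               | b          |
| pooled comparators| c               | d          |

with N = a+b+c+d and E = (a+b)(a+c)/N the count expected under
independence.

* **ROR** = (a·d)/(b·c), 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  Signal: lower bound > 1 and a ≥ 3 (configurable 3/5).
* **PRR** = [a/(a+b)] / [c/(c+d)], analogous Wald interval, same rule;
  plus the Pearson χ² on the 2×2.
* **BCPNN information component** IC = log₂ p₁₁/(p₁·p₂) under
  independent Beta posteriors for the cell and margin probabilities,
  with the joint-cell prior scaled so E[IC] = 0 a priori.  Closed-form
  digamma/trigamma posterior moments; signal: IC025 > 0.
* **MGPS**: empirical-Bayes gamma-Poisson shrinkage of a/E under a
  two-component gamma mixture prior fitted by maximum likelihood over
  all cells of the run (negative-binomial mixture marginal).  EBGM is
  the posterior geometric mean, EB05 its 5th percentile; signal:
  EB05 ≥ 2.0 (or 1.8) and EBGM ≥ 2.5.

Both counting bases are first class: *report-level* (a report counts
once per SOC it touches) and *reaction-level* (every reaction counts).

## Worked example

```python
>>> import pvsignal as pv
>>> from pvsignal.fixtures import soc_collection
>>> coll = soc_collection()          # packaged per-SOC reference counts
>>> t = pv.build_2x2(coll, "fenfluramine", "Cardiac disorders")
>>> (t.a, t.b, t.c, t.d)
(269, 1653, 87, 10501)
>>> est = pv.ror(t)
>>> round(est.value, 2), round(est.low, 2), round(est.high, 2)
(19.64, 15.34, 25.15)
```

Fenfluramine reports mention cardiac disorders with 19.6 times the odds
of the pooled stiripentol/cannabidiol reports, and the interval is far
above 1 — the well-known valvulopathy/pulmonary-hypertension signal of
the drug.  The full screen over every (drug, SOC):

```python
>>> report = pv.screen(coll)
>>> row = report.frame.query("drug == 'fenfluramine' and soc == 'Cardiac disorders'").iloc[0]
>>> bool(row.flag_ror), bool(row.flag_prr), bool(row.flag_bcpnn), bool(row.flag_mgps)
(True, True, True, True)
```

From the shell, the same pipeline end to end on synthetic data:

```sh
pvsignal simulate --out runs/listing.csv --seed 123
pvsignal screen --input runs/listing.csv --out-dir runs/screen
pvsignal describe --input runs/listing.csv --out-dir runs/tables
pvsignal validate-fixtures
```

`simulate` with no config draws a cohort with the reference study's
structure (822/4222/852 reports, pooled demographic and SOC marginals);
a YAML config can change cohort sizes, marginals, and plant (drug, SOC,
θ) association signals whose selection odds are multiplied by θ.

## Layout

| module | contents |
|---|---|
| `pvsignal.icsr` | ICSR/reaction domain types, MedDRA map, line-listing I/O |
| `pvsignal.simulate` | synthetic cohort generator and configs |
| `pvsignal.descriptives` | characteristics/SOC/PT/yearly tables, proportion test |
| `pvsignal.contingency` | 2×2 table construction, both counting bases |
| `pvsignal.stats` | ROR, PRR, χ², BCPNN IC, MGPS prior fit and EBGM/EB05 |
| `pvsignal.rules` | decision thresholds and the screening report |
| `pvsignal.fixtures` | packaged reference tables and their expansions |
| `pvsignal.cli` | `pvsignal` command-line entry point |

See `docs/methods.md` for the model details, defaults and limitations.
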