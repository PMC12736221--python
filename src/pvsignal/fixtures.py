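"""Packaged reference tables and their expansion into ICSR collections.

Three delimited-text tables ship inside the package so the descriptive
layer can be exercised completely offline:

* ``table1_characteristics.csv`` — per-drug counts for the demographic,
  reporter, geographic, seriousness and (event-level) outcome strata of
  the stiripentol / cannabidiol / fenfluramine EudraVigilance cohorts.
* ``table2_soc_counts.csv`` — per-drug numbers of reports with at least
  one reaction in each of the 27 system organ classes.
* ``yearly_counts_synthetic.csv`` — per-drug report counts by year.  Only
  three cells are as published (cannabidiol 2021 = 1065, fenfluramine
  2024 = 213, stiripentol 2024 = 183); the remaining years are synthetic
  fill that preserves the per-drug totals and the year-on-year increase,
  hence the filename.

The expansion helpers rebuild ICSR collections whose marginals reproduce
the packaged counts exactly, which lets every downstream stage (summary
tables, contingency building, screening) run end-to-end on them.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .exceptions import ValidationError
from .icsr import ICSR, ICSRCollection, MedDRAMap, ReactionRecord

DRUGS = ("stiripentol", "cannabidiol", "fenfluramine")

#: Table-1 country rows that are EEA members (assigned to EEA-region
#: reports during expansion); "GB" is non-EEA, "Others" becomes "XX".
_EEA_NAMED = ("FR", "DE", "IT", "ES", "NL", "AT")


def _data(name: str):
    return resources.files("pvsignal").joinpath(f"data/{name}")


@lru_cache(maxsize=1)
def load_mock_meddra() -> MedDRAMap:
    """The packaged mock PT -> SOC mapping (27 SOC mini-hierarchy)."""
    with resources.as_file(_data("meddra_mock.tsv")) as p:
        return MedDRAMap.from_tsv(p)


def load_table1() -> pd.DataFrame:
    """Characteristics counts: columns section, stratum, one per drug."""
    with resources.as_file(_data("table1_characteristics.csv")) as p:
        return pd.read_csv(p, dtype={"section": str, "stratum": str})


def load_table2() -> pd.DataFrame:
    """Report-level SOC counts: columns soc, one per drug."""
    with resources.as_file(_data("table2_soc_counts.csv")) as p:
        return pd.read_csv(p)


def load_yearly() -> pd.DataFrame:
    """Per-drug yearly report counts (synthetic fill, three exact anchors)."""
    with resources.as_file(_data("yearly_counts_synthetic.csv")) as p:
        return pd.read_csv(p)


def report_totals() -> dict:
    t1 = load_table1()
    sec = t1[t1["section"] == "sex"]
    return {d: int(sec[d].sum()) for d in DRUGS}


def _expand(counts: pd.Series) -> list:
    """[('a', 2), ('b', 1)] -> ['a', 'a', 'b'] preserving row order."""
    out = []
    for stratum, n in counts.items():
        out.extend([stratum] * int(n))
    return out


def _country_sequence(t1: pd.DataFrame, drug: str, n_eea: int, n_non: int):
    """Country codes aligned with an EEA-first region ordering.

    Named EEA countries fill the EEA slots (remainder 'XX'); 'GB' and the
    unlisted remainder fill the non-EEA slots as 'XX'.
    """
    c = t1[t1["section"] == "country"].set_index("stratum")[drug]
    eea_part = []
    for code in _EEA_NAMED:
        eea_part.extend([code] * int(c.get(code, 0)))
    if len(eea_part) > n_eea:
        raise ValidationError(f"{drug}: EEA country counts exceed EEA total")
    eea_part.extend(["XX"] * (n_eea - len(eea_part)))
    non_part = ["GB"] * int(c.get("GB", 0))
    non_part.extend(["XX"] * (n_non - len(non_part)))
    return eea_part + non_part


def characteristics_collection() -> ICSRCollection:
    """Expand the characteristics and yearly tables into an ICSR collection.

    Strata are assigned independently per field (in the fixed row order of
    the packaged table), so every univariate marginal — including the
    event-level outcome distribution — matches the packaged counts
    exactly, while joint distributions are artificial.  Reactions are
    spread over reports so the per-drug reaction totals equal the outcome
    denominators; all preferred terms are 'Seizure' (this expansion feeds
    the characteristics layer, not the SOC layer).
    """
    t1 = load_table1()
    yearly = load_yearly()
    meddra = load_mock_meddra()
    reports = []
    for drug in DRUGS:
        per_section = {
            name: t1[t1["section"] == name].set_index("stratum")[drug]
            for name in ("age_group", "sex", "reporter_group", "region",
                         "seriousness", "outcome")
        }
        n = int(per_section["sex"].sum())
        age = _expand(per_section["age_group"])
        sex = _expand(per_section["sex"])
        reporter = _expand(per_section["reporter_group"])
        serious = _expand(per_section["seriousness"])
        region = _expand(per_section["region"])  # EEA rows first
        n_eea = int(per_section["region"].get("EEA", 0))
        country = _country_sequence(t1, drug, n_eea, n - n_eea)
        yr = yearly[yearly["drug"] == drug]
        years = []
        for _, row in yr.iterrows():
            years.extend([int(row["year"])] * int(row["count"]))
        if len(years) != n:
            raise ValidationError(f"{drug}: yearly counts do not sum to {n}")

        outcomes = _expand(per_section["outcome"])
        total_rx = len(outcomes)
        base, extra = divmod(total_rx, n)
        rx_counts = [base + 1] * extra + [base] * (n - extra)
        cursor = 0
        for i in range(n):
            k = rx_counts[i]
            reactions = tuple(
                ReactionRecord(pt="Seizure", outcome=o)
                for o in outcomes[cursor:cursor + k]
            )
            cursor += k
            reports.append(
                ICSR(
                    report_id=f"{drug}-C{i + 1:05d}",
                    drug=drug,
                    reactions=reactions,
                    age_group=age[i],
                    sex=sex[i],
                    reporter_group=reporter[i],
                    country=country[i],
                    region=region[i],
                    seriousness=serious[i],
                    year=years[i],
                )
            )
    return ICSRCollection(reports=reports, meddra=meddra)


def soc_collection() -> ICSRCollection:
    """Expand the SOC count table into single-reaction reports.

    One report per counting unit, each with one reaction whose preferred
    term is a fixed representative of its SOC, so report-level and
    reaction-level SOC counts both equal the packaged numbers.
    """
    t2 = load_table2()
    meddra = load_mock_meddra()
    rep_pt = {soc: meddra.pts_in(soc)[0] for soc in meddra.socs}
    reports = []
    for drug in DRUGS:
        i = 0
        for _, row in t2.iterrows():
            soc = row["soc"]
            for _ in range(int(row[drug])):
                i += 1
                reports.append(
                    ICSR(
                        report_id=f"{drug}-S{i:05d}",
                        drug=drug,
                        reactions=(ReactionRecord(pt=rep_pt[soc],
                                                  outcome="Unknown"),),
                        age_group="Not Specified",
                        sex="Not Specified",
                        reporter_group="Not Specified",
                        country="XX",
                        region="Non-EEA",
                        seriousness="Not Specified",
                        year=2024,
                    )
                )
    return ICSRCollection(reports=reports, meddra=meddra)


def validate_fixtures() -> pd.DataFrame:
    """Recompute the packaged-table reference numbers through the pipeline.

    Returns a frame with one row per check: name, expected, actual, passed.
    Used by the ``validate-fixtures`` CLI subcommand.
    """
    from . import contingency, descriptives

    checks = []

    def check(name, expected, actual):
        checks.append(
            {"check": name, "expected": expected, "actual": actual,
             "passed": bool(expected == actual)}
        )

    coll = characteristics_collection()
    summary = descriptives.characteristics_table(coll)
    pct = summary.percentages
    check("total reports", 5896, int(len(coll)))
    check("stiripentol male %", 51.46,
          round(float(pct.loc[("sex", "Male"), "stiripentol"]), 2))
    check("stiripentol serious %", 88.6,
          round(float(pct.loc[("seriousness", "Serious"), "stiripentol"]), 1))
    check("cannabidiol HCP reporter %", 94.13,
          round(float(pct.loc[("reporter_group", "Healthcare Professional"),
                              "cannabidiol"]), 2))
    check("fenfluramine female %", 59.39,
          round(float(pct.loc[("sex", "Female"), "fenfluramine"]), 2))
    check("cannabidiol fatal outcome %", 5.7,
          round(float(pct.loc[("outcome", "Fatal"), "cannabidiol"]), 1))

    sex_counts = summary.counts.loc["sex"].drop(index="Not Specified")
    stat, dof, p = descriptives.compare_proportions(sex_counts.T)
    check("sex proportion test p < 0.001", True, bool(p < 0.001))

    yearly = descriptives.yearly_counts(coll)
    share = 100 * yearly.loc[2021, "cannabidiol"] / yearly["cannabidiol"].sum()
    check("cannabidiol 2021 share %", 25.2, round(float(share), 1))

    socs = soc_collection()
    soc_summary = descriptives.soc_table(socs, mode="report-level")
    soc_pct = soc_summary.percentages
    for drug, expected in (("stiripentol", 26.6), ("cannabidiol", 27.1),
                           ("fenfluramine", 19.1)):
        check(f"{drug} nervous system share %", expected,
              round(float(soc_pct.loc[("soc", "Nervous system disorders"),
                                      drug]), 1))

    table = contingency.build_2x2(socs, "fenfluramine", "Cardiac disorders",
                                  basis="report-level")
    check("fenfluramine x cardiac cells", (269, 1653, 87, 10501),
          (table.a, table.b, table.c, table.d))

    return pd.DataFrame(checks)
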