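"""Descriptive layer: characteristics tables, SOC/PT counts, yearly
counts, and the between-drug proportion (chi-square) test.

Percentage conventions follow the reporting style of public
spontaneous-report summaries: 'Not Specified' strata stay in the
denominators; report-level sections use report counts, the outcome
section uses reaction-event counts; SOC shares use the column total of
the SOC table itself (which exceeds the number of reports because one
report can touch several SOCs).  Percentages are stored at full
precision and rounded only when rendering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import vocab
from .exceptions import ValidationError
from .icsr import ICSRCollection
from .vocab import UNMAPPED_SOC

_SECTION_ORDERS = {
    "age_group": vocab.AGE_GROUPS,
    "sex": vocab.SEXES,
    "reporter_group": vocab.REPORTER_GROUPS,
    "region": vocab.REGIONS,
    "seriousness": ("Non-Serious", "Serious", "Not Specified"),
    "outcome": tuple(sorted(vocab.OUTCOMES)),
}


@dataclass
class SummaryTable:
    """Stratified counts with per-section denominators.

    ``counts`` is indexed by (section, stratum) with one column per drug;
    ``denominators`` is indexed by section; ``basis`` tags each section as
    'reports' or 'reaction-events'.
    """

    counts: pd.DataFrame
    denominators: pd.DataFrame
    basis: dict = field(default_factory=dict)

    @property
    def percentages(self) -> pd.DataFrame:
        den = self.denominators.reindex(
            self.counts.index.get_level_values("section")
        ).to_numpy()
        return 100.0 * self.counts / den

    def render(self, decimals: int = 2) -> pd.DataFrame:
        """Presentation view: 'count (pct)' strings, rounded here only."""
        pct = self.percentages.round(decimals)
        out = self.counts.astype(str)
        for col in out.columns:
            out[col] = [
                f"{c} ({p})" for c, p in zip(self.counts[col], pct[col])
            ]
        return out


def _section_counts(df: pd.DataFrame, column: str, drugs, order=None) -> pd.DataFrame:
    tab = df.groupby([column, "drug"]).size().unstack("drug", fill_value=0)
    tab = tab.reindex(columns=drugs, fill_value=0)
    if order is not None:
        tab = tab.reindex([o for o in order if o in tab.index]
                          + [i for i in tab.index if i not in order])
        tab = tab.fillna(0).astype(int)
    return tab


def characteristics_table(collection: ICSRCollection) -> SummaryTable:
    """Per-drug counts and percentages for every report stratum.

    Sections: age group, sex, reporter group, region, country and
    seriousness (denominator: reports) and outcome (denominator:
    reaction events).
    """
    if len(collection) == 0:
        raise ValidationError("cannot summarise an empty collection")
    drugs = list(collection.drugs)
    reports = collection.report_frame()
    reactions = collection.reaction_frame(with_soc=False)

    pieces, denominators, basis = [], {}, {}
    report_totals = reports.groupby("drug").size().reindex(drugs, fill_value=0)
    for section in ("age_group", "sex", "reporter_group", "region",
                    "country", "seriousness"):
        tab = _section_counts(reports, section, drugs,
                              _SECTION_ORDERS.get(section))
        tab.index = pd.MultiIndex.from_product([[section], tab.index],
                                               names=["section", "stratum"])
        pieces.append(tab)
        denominators[section] = report_totals
        basis[section] = "reports"

    out_tab = _section_counts(reactions, "outcome", drugs,
                              _SECTION_ORDERS["outcome"])
    out_tab.index = pd.MultiIndex.from_product([["outcome"], out_tab.index],
                                               names=["section", "stratum"])
    pieces.append(out_tab)
    denominators["outcome"] = reactions.groupby("drug").size().reindex(
        drugs, fill_value=0)
    basis["outcome"] = "reaction-events"

    counts = pd.concat(pieces)
    den = pd.DataFrame(denominators).T
    den.index.name = "section"
    return SummaryTable(counts=counts, denominators=den, basis=basis)


def soc_table(collection: ICSRCollection, mode: str = "report-level") -> SummaryTable:
    """Per-drug SOC counts.

    ``report-level`` counts each report at most once per SOC ("at least
    one reaction in the SOC"); ``reaction-level`` counts every reaction.
    Percentages are shares of the per-drug column totals of this table.
    Unmapped reactions are excluded.
    """
    if len(collection) == 0:
        raise ValidationError("cannot summarise an empty collection")
    if mode not in ("report-level", "reaction-level"):
        raise ValidationError(f"unknown counting mode {mode!r}")
    drugs = list(collection.drugs)
    df = collection.reaction_frame(with_soc=True)
    df = df[df["soc"] != UNMAPPED_SOC]
    if mode == "report-level":
        df = df.drop_duplicates(subset=["report_id", "soc"])
    tab = df.groupby(["soc", "drug"]).size().unstack("drug", fill_value=0)
    tab = tab.reindex(columns=drugs, fill_value=0).sort_index()
    tab.index = pd.MultiIndex.from_product([["soc"], tab.index],
                                           names=["section", "stratum"])
    den = pd.DataFrame({d: [int(tab[d].sum())] for d in drugs}, index=["soc"])
    den.index.name = "section"
    return SummaryTable(counts=tab, denominators=den, basis={"soc": mode})


def pt_table(collection: ICSRCollection, drug: str, soc: str | None = None,
             min_count: int = 10, year_from: int | None = None) -> pd.Series:
    """Case counts per preferred term for one drug.

    A case is a distinct report mentioning the PT.  Terms with fewer than
    ``min_count`` cases are omitted; ``year_from`` keeps only reports
    from that year on.
    """
    if min_count < 0:
        raise ValidationError("min_count must be >= 0")
    if drug not in collection.drugs:
        raise ValidationError(f"unknown drug {drug!r}")
    df = collection.reaction_frame(with_soc=True)
    df = df[df["drug"] == drug]
    if soc is not None:
        df = df[df["soc"] == soc]
    if year_from is not None:
        df = df[df["year"] >= year_from]
    counts = (
        df.drop_duplicates(subset=["report_id", "pt"])
        .groupby("pt").size().sort_index()
    )
    counts.name = drug
    return counts[counts >= min_count] if min_count else counts


def yearly_counts(collection: ICSRCollection) -> pd.DataFrame:
    """Report counts per (year, drug); per-drug sums equal report totals."""
    reports = collection.report_frame()
    tab = reports.groupby(["year", "drug"]).size().unstack("drug", fill_value=0)
    return tab.reindex(columns=list(collection.drugs), fill_value=0).sort_index()


def compare_proportions(counts) -> tuple:
    """Pearson chi-square homogeneity test on a k x m count table.

    No continuity correction (the proportion test on shares is
    mathematically the same statistic).  Returns (statistic, dof, p).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("need at least a 2 x 2 table of counts")
    if (table < 0).any():
        raise ValidationError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValidationError("every row and column margin must be positive")
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def plot_yearly(collection: ICSRCollection, path) -> None:
    """Grouped bar chart of report counts per year and drug."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = yearly_counts(collection)
    ax = tab.plot.bar(figsize=(9, 4.5))
    ax.set_xlabel("Year")
    ax.set_ylabel("Reports")
    ax.figure.tight_layout()
    ax.figure.savefig(path, dpi=150)
    plt.close(ax.figure)
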