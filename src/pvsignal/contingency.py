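"""Two-by-two contingency tables: one drug of interest against the
pooled remaining drugs, per system organ class.

Cell layout (drug x SOC):

    ============  ===============  ==========
                  SOC of interest  other SOCs
    ============  ===============  ==========
    drug          a                b
    comparators   c                d
    ============  ===============  ==========

Two counting bases are first-class.  ``report-level`` (default) counts a
report in ``a`` when it has at least one reaction in the SOC;
``reaction-level`` counts every reaction.  Reactions whose preferred term
is absent from the mapping are excluded from SOC iteration but remain in
the ``b``/``d`` margins — a reaction always lands somewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .exceptions import ValidationError
from .icsr import ICSRCollection
from .vocab import UNMAPPED_SOC

BASES = ("report-level", "reaction-level")


@dataclass(frozen=True)
class ContingencyTable:
    """a/b/c/d cells with their counting basis."""

    a: int
    b: int
    c: int
    d: int
    basis: str = "report-level"

    def __post_init__(self):
        for cell in ("a", "b", "c", "d"):
            if getattr(self, cell) < 0:
                raise ValidationError(f"cell {cell} must be non-negative")
        if self.basis not in BASES:
            raise ValidationError(f"basis must be one of {BASES}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected ``a`` under row/column independence: (a+b)(a+c)/N."""
        if self.n == 0:
            raise ValidationError("empty table has no expected count")
        return (self.a + self.b) * (self.a + self.c) / self.n

    def as_tuple(self) -> tuple:
        return (self.a, self.b, self.c, self.d)


def _counts(collection: ICSRCollection, basis: str):
    """(per-(drug, soc) a-counts, per-drug margins, N) for one basis."""
    if basis not in BASES:
        raise ValidationError(f"basis must be one of {BASES}")
    frame = collection.reaction_frame(with_soc=True)
    mapped = frame[frame["soc"] != UNMAPPED_SOC]
    if basis == "report-level":
        mapped = mapped.drop_duplicates(subset=["report_id", "soc"])
        margins = frame.drop_duplicates(subset="report_id").groupby("drug").size()
        total = len(collection)
    else:
        margins = frame.groupby("drug").size()
        total = len(frame)
    cells = mapped.groupby(["drug", "soc"]).size()
    return cells, margins, total


def _assemble(cells: pd.Series, margins: pd.Series, total: int,
              drug: str, soc: str, basis: str) -> ContingencyTable:
    a = int(cells.get((drug, soc), 0))
    soc_total = int(cells.xs(soc, level="soc").sum()) if soc in cells.index.get_level_values("soc") else 0
    b = int(margins[drug]) - a
    c = soc_total - a
    d = total - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d, basis=basis)


def _require_drug(collection: ICSRCollection, drug: str):
    drugs = collection.drugs
    if drug not in drugs:
        raise ValidationError(f"drug {drug!r} not present in collection")
    if len(drugs) < 2:
        raise ValidationError("need at least two drugs to form a comparator pool")


def build_2x2(collection: ICSRCollection, drug: str, soc: str,
              basis: str = "report-level") -> ContingencyTable:
    """The 2x2 table for one (drug, SOC) against the pooled other drugs."""
    _require_drug(collection, drug)
    cells, margins, total = _counts(collection, basis)
    return _assemble(cells, margins, total, drug, soc, basis)


def build_all(collection: ICSRCollection, basis: str = "report-level",
              socs=None) -> dict:
    """Tables for every (drug, SOC) pair.

    ``socs`` defaults to all observed mapped SOCs; the result maps
    (drug, soc) to its :class:`ContingencyTable` (drugs x SOCs entries).
    """
    drugs = collection.drugs
    if len(drugs) < 2:
        raise ValidationError("need at least two drugs to form a comparator pool")
    cells, margins, total = _counts(collection, basis)
    if socs is None:
        socs = sorted(cells.index.get_level_values("soc").unique())
    out = {}
    for drug in drugs:
        for soc in socs:
            out[(drug, soc)] = _assemble(cells, margins, total, drug, soc, basis)
    return out
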