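"""Domain model and line-listing I/O for individual case safety reports.

An ICSR is one spontaneous safety report: a single suspected drug, one or
more coded reactions (MedDRA preferred terms, each carrying its own
outcome), and report-level demographics, reporter, geography, seriousness
and year.  The on-disk dialect mirrors the public adrreports.eu export:
one row per report–reaction pair with header

    report_id, drug, pt, outcome, age_group, sex, reporter_group,
    country, region, seriousness, year

comma-delimited by default, tab accepted.  Reports with several suspected
drugs are out of scope and rejected at parse time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import pandas as pd

from . import vocab
from .exceptions import FormatError, ValidationError
from .vocab import UNMAPPED_SOC

logger = logging.getLogger(__name__)

LINE_LISTING_COLUMNS = (
    "report_id",
    "drug",
    "pt",
    "outcome",
    "age_group",
    "sex",
    "reporter_group",
    "country",
    "region",
    "seriousness",
    "year",
)


@lru_cache(maxsize=1)
def eea_countries() -> frozenset:
    """ISO 3166-1 alpha-2 codes of the European Economic Area members."""
    text = resources.files("pvsignal").joinpath("data/eea_countries.txt").read_text()
    return frozenset(line.strip() for line in text.splitlines() if line.strip())


def region_of_country(country: str) -> str | None:
    """Region implied by a country code; None when the country is unknown."""
    if country == "XX":
        return None
    return "EEA" if country in eea_countries() else "Non-EEA"


@dataclass(frozen=True)
class ReactionRecord:
    """One coded adverse reaction: a preferred term and its outcome."""

    pt: str
    outcome: str

    def __post_init__(self):
        if not str(self.pt).strip():
            raise ValidationError("preferred term must be non-empty")
        if self.outcome not in vocab.OUTCOMES:
            raise ValidationError(
                f"outcome {self.outcome!r} not in {vocab.OUTCOMES}"
            )


@dataclass(frozen=True)
class ICSR:
    """One individual case safety report with a single suspected drug."""

    report_id: str
    drug: str
    reactions: tuple[ReactionRecord, ...]
    age_group: str
    sex: str
    reporter_group: str
    country: str
    region: str
    seriousness: str
    year: int

    def __post_init__(self):
        if not str(self.report_id).strip():
            raise ValidationError("report_id must be non-empty")
        if not str(self.drug).strip():
            raise ValidationError("drug must be non-empty")
        object.__setattr__(self, "reactions", tuple(self.reactions))
        if len(self.reactions) < 1:
            raise ValidationError(f"report {self.report_id}: needs >= 1 reaction")
        for fname, voc in (
            ("age_group", vocab.AGE_GROUPS),
            ("sex", vocab.SEXES),
            ("reporter_group", vocab.REPORTER_GROUPS),
            ("region", vocab.REGIONS),
            ("seriousness", vocab.SERIOUSNESS),
        ):
            if getattr(self, fname) not in voc:
                raise ValidationError(
                    f"report {self.report_id}: {fname} {getattr(self, fname)!r} "
                    f"not in {voc}"
                )
        implied = region_of_country(self.country)
        if implied is not None and implied != self.region:
            raise ValidationError(
                f"report {self.report_id}: region {self.region!r} inconsistent "
                f"with country {self.country!r} (expected {implied!r})"
            )


@dataclass(frozen=True)
class MedDRAMap:
    """Preferred-term -> system-organ-class lookup (mock MedDRA hierarchy).

    Every PT maps to exactly one SOC; unknown PTs resolve to the
    ``"Unmapped"`` sentinel and are excluded from SOC-level statistics.
    Lookup is tolerant of case and surrounding whitespace.
    """

    entries: dict

    def __post_init__(self):
        index = {}
        for pt, soc in self.entries.items():
            key = vocab.normalization_key(pt)
            if key in index and index[key][1] != soc:
                raise ValidationError(f"PT {pt!r} mapped to more than one SOC")
            index[key] = (pt, soc)
        object.__setattr__(self, "_index", index)

    @classmethod
    def from_tsv(cls, path) -> "MedDRAMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = {"pt", "soc"} - set(df.columns)
        if missing:
            raise FormatError(
                f"MedDRA mapping {path}: missing column(s) {sorted(missing)}"
            )
        return cls(dict(zip(df["pt"].str.strip(), df["soc"].str.strip())))

    def soc_of(self, pt: str) -> str:
        hit = self._index.get(vocab.normalization_key(pt))
        return hit[1] if hit is not None else UNMAPPED_SOC

    @property
    def socs(self) -> tuple:
        return tuple(sorted(set(self.entries.values())))

    def pts_in(self, soc: str) -> tuple:
        return tuple(sorted(pt for pt, s in self.entries.items() if s == soc))


def soc_of(pt: str, meddra: MedDRAMap) -> str:
    """SOC label for a preferred term, ``"Unmapped"`` when absent."""
    return meddra.soc_of(pt)


@dataclass
class ICSRCollection:
    """A set of ICSRs together with the PT->SOC mapping used to code them."""

    reports: list
    meddra: MedDRAMap

    def __post_init__(self):
        seen = set()
        for r in self.reports:
            if r.report_id in seen:
                raise ValidationError(f"duplicate report_id {r.report_id!r}")
            seen.add(r.report_id)

    def __len__(self) -> int:
        return len(self.reports)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ICSRCollection)
            and self.reports == other.reports
            and self.meddra.entries == other.meddra.entries
        )

    @property
    def drugs(self) -> tuple:
        out = []
        for r in self.reports:
            if r.drug not in out:
                out.append(r.drug)
        return tuple(out)

    @property
    def total_reactions(self) -> int:
        return sum(len(r.reactions) for r in self.reports)

    def report_frame(self) -> pd.DataFrame:
        """One row per report (no reaction fields)."""
        return pd.DataFrame(
            {
                "report_id": [r.report_id for r in self.reports],
                "drug": [r.drug for r in self.reports],
                "age_group": [r.age_group for r in self.reports],
                "sex": [r.sex for r in self.reports],
                "reporter_group": [r.reporter_group for r in self.reports],
                "country": [r.country for r in self.reports],
                "region": [r.region for r in self.reports],
                "seriousness": [r.seriousness for r in self.reports],
                "year": [r.year for r in self.reports],
                "n_reactions": [len(r.reactions) for r in self.reports],
            }
        )

    def reaction_frame(self, with_soc: bool = True) -> pd.DataFrame:
        """One row per report–reaction pair, optionally with the SOC."""
        rows = {c: [] for c in LINE_LISTING_COLUMNS}
        for r in self.reports:
            for rx in r.reactions:
                rows["report_id"].append(r.report_id)
                rows["drug"].append(r.drug)
                rows["pt"].append(rx.pt)
                rows["outcome"].append(rx.outcome)
                rows["age_group"].append(r.age_group)
                rows["sex"].append(r.sex)
                rows["reporter_group"].append(r.reporter_group)
                rows["country"].append(r.country)
                rows["region"].append(r.region)
                rows["seriousness"].append(r.seriousness)
                rows["year"].append(r.year)
        df = pd.DataFrame(rows)
        if with_soc:
            df["soc"] = [self.meddra.soc_of(pt) for pt in df["pt"]]
            n_unmapped = int((df["soc"] == UNMAPPED_SOC).sum())
            if n_unmapped:
                logger.warning(
                    "%d reaction(s) with preferred terms absent from the "
                    "MedDRA mapping routed to the %r SOC",
                    n_unmapped,
                    UNMAPPED_SOC,
                )
        return df


def _infer_delimiter(path, delimiter):
    if delimiter is not None:
        return delimiter
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_line_listing(path, meddra_path=None, *, meddra: MedDRAMap | None = None,
                      delimiter: str | None = None) -> ICSRCollection:
    """Parse a line listing (one row per report–reaction pair) into ICSRs.

    Rows sharing a ``report_id`` merge into one report with several
    reactions; exact duplicate (report_id, pt, outcome) rows collapse with
    a logged warning.  Either ``meddra_path`` (a pt/soc TSV) or a
    ``meddra`` object must be supplied.
    """
    if meddra is None:
        if meddra_path is None:
            raise ValidationError("either meddra_path or meddra must be given")
        meddra = MedDRAMap.from_tsv(meddra_path)
    df = pd.read_csv(path, sep=_infer_delimiter(path, delimiter), dtype=str,
                     keep_default_na=False)
    missing = [c for c in LINE_LISTING_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"line listing {path}: missing column(s) {missing}")

    # Row numbers as in the file: header is line 1, data starts at line 2.
    reports: dict[str, dict] = {}
    for pos, raw in enumerate(df.itertuples(index=False), start=2):
        row = raw._asdict()
        rid = str(row["report_id"]).strip()
        drug = str(row["drug"]).strip()
        rec = {
            "drug": drug,
            "age_group": vocab.normalize("age_group", row["age_group"], row=pos),
            "sex": vocab.normalize("sex", row["sex"], row=pos),
            "reporter_group": vocab.normalize("reporter_group",
                                              row["reporter_group"], row=pos),
            "country": vocab.normalize_country(row["country"], row=pos),
            "region": vocab.normalize("region", row["region"], row=pos),
            "seriousness": vocab.normalize("seriousness", row["seriousness"],
                                           row=pos),
            "year": vocab.normalize_year(row["year"], row=pos),
        }
        reaction = ReactionRecord(
            pt=str(row["pt"]).strip(),
            outcome=vocab.normalize("outcome", row["outcome"], row=pos),
        )
        if rid not in reports:
            reports[rid] = {"fields": rec, "reactions": [], "seen": set()}
        elif reports[rid]["fields"]["drug"] != drug:
            raise ValidationError(
                f"report {rid!r} (row {pos}): multiple suspected drugs "
                f"({reports[rid]['fields']['drug']!r}, {drug!r}) are out of scope"
            )
        key = (reaction.pt, reaction.outcome)
        if key in reports[rid]["seen"]:
            logger.warning(
                "row %d: duplicate (report_id, pt, outcome) %r collapsed",
                pos, (rid, *key),
            )
            continue
        reports[rid]["seen"].add(key)
        reports[rid]["reactions"].append(reaction)

    icsrs = [
        ICSR(report_id=rid, reactions=tuple(entry["reactions"]), **entry["fields"])
        for rid, entry in reports.items()
    ]
    return ICSRCollection(reports=icsrs, meddra=meddra)


def write_line_listing(collection: ICSRCollection, path, *,
                       delimiter: str = ",") -> int:
    """Write one row per report–reaction pair; returns the row count."""
    df = collection.reaction_frame(with_soc=False)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=delimiter, index=False)
    return len(df)
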