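"""Synthetic ICSR cohorts with plantable drug–SOC association signals.

The generator emulates the statistical structure of a spontaneous-report
line listing: a fixed number of reports per drug, a truncated-geometric
number of reactions per report (minimum one), reaction SOCs drawn from a
baseline profile over the 27 system organ classes, preferred terms drawn
uniformly within the chosen SOC, and report-level demographics drawn
independently from categorical marginals.

A planted signal (drug, SOC, θ) multiplies that SOC's selection *odds*
by θ for that drug's reactions and renormalizes, so a baseline
probability p becomes θp/(1−p+θp).  Planting on the selection odds—not
on report counts—moves both counting bases (report-level and
reaction-level) the way a genuine adverse-reaction excess would.

Randomness: one seed per run; each drug draws from a sub-stream derived
deterministically from (seed, drug label), so a drug's output does not
depend on the other drugs in the configuration.
"""

from __future__ import annotations

import zlib

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, NonNegativeInt

from . import vocab
from .exceptions import ValidationError
from .icsr import ICSR, ICSRCollection, MedDRAMap, ReactionRecord, region_of_country

_SUM_TOL = 1e-9


class ReactionsPerReport(BaseModel):
    """Truncated-geometric reaction count: support {1, 2, ...} (optionally
    capped at ``maximum``), mean ``mean`` before truncation."""

    model_config = ConfigDict(frozen=True)

    mean: float = Field(default=2.6, gt=1.0)
    maximum: int | None = Field(default=None, ge=1)


class PlantedSignal(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug: str
    soc: str
    theta: float = Field(gt=0.0)


def _check_marginal(name: str, marginal: dict, problems: list):
    if not marginal:
        problems.append(f"{name}: empty marginal")
        return
    for cat, p in marginal.items():
        if not 0.0 <= p <= 1.0:
            problems.append(f"{name}[{cat}]: probability {p} outside [0, 1]")
    total = sum(marginal.values())
    if abs(total - 1.0) > _SUM_TOL:
        problems.append(f"{name}: probabilities sum to {total}, not 1")


class SimulationConfig(BaseModel):
    """Full specification of a synthetic cohort; validated on construction."""

    model_config = ConfigDict(frozen=True)

    drugs: list[tuple[str, NonNegativeInt]]
    soc_profile: dict[str, float]
    reactions_per_report: ReactionsPerReport = ReactionsPerReport()
    demographic_marginals: dict[str, dict]
    country_by_region: dict[str, dict] = Field(
        default={
            "EEA": {"FR": 0.30, "DE": 0.20, "IT": 0.15, "ES": 0.15,
                    "NL": 0.10, "AT": 0.10},
            "Non-EEA": {"US": 0.35, "GB": 0.15, "JP": 0.05, "XX": 0.45},
        }
    )
    planted_signals: list[PlantedSignal] = Field(default_factory=list)
    seed: int = Field(default=0, ge=0)

    def model_post_init(self, _context):
        # raises the package's own ValidationError, listing every offending
        # field at once (pydantic handles types; this handles semantics)
        problems = []
        labels = [d for d, _ in self.drugs]
        if len(set(labels)) != len(labels):
            problems.append("drugs: duplicate drug labels")
        _check_marginal("soc_profile", self.soc_profile, problems)
        required = ("age_group", "sex", "reporter_group", "region",
                    "seriousness", "outcome", "year")
        for name in required:
            if name not in self.demographic_marginals:
                problems.append(f"demographic_marginals: missing {name!r}")
            else:
                _check_marginal(f"demographic_marginals[{name}]",
                                self.demographic_marginals[name], problems)
        for name, voc in vocab.FIELD_VOCABULARIES.items():
            if name == "outcome":
                continue
            for cat in self.demographic_marginals.get(name, {}):
                if cat not in voc:
                    problems.append(
                        f"demographic_marginals[{name}]: unknown category {cat!r}")
        for cat in self.demographic_marginals.get("outcome", {}):
            if cat not in vocab.OUTCOMES:
                problems.append(
                    f"demographic_marginals[outcome]: unknown category {cat!r}")
        for region, countries in self.country_by_region.items():
            if region not in vocab.REGIONS:
                problems.append(f"country_by_region: unknown region {region!r}")
                continue
            _check_marginal(f"country_by_region[{region}]", countries, problems)
            for code in countries:
                implied = region_of_country(code)
                if implied is not None and implied != region:
                    problems.append(
                        f"country_by_region[{region}]: country {code!r} "
                        f"belongs to {implied}")
        for sig in self.planted_signals:
            if sig.soc not in self.soc_profile:
                problems.append(
                    f"planted_signals: SOC {sig.soc!r} not in soc_profile")
            if sig.drug not in labels:
                problems.append(
                    f"planted_signals: drug {sig.drug!r} not in drugs")
        if problems:
            raise ValidationError("invalid simulation config: "
                                  + "; ".join(problems))


def _drug_rng(seed: int, drug: str) -> np.random.Generator:
    """Sub-stream for one drug, invariant to the rest of the config."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(drug.encode("utf-8"))])
    )


def _draw(rng, marginal: dict, size: int) -> np.ndarray:
    cats = list(marginal)
    probs = np.array([marginal[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(len(cats), size=size, p=probs)
    return np.array(cats, dtype=object)[idx]


def adjusted_soc_probabilities(config: SimulationConfig, drug: str) -> dict:
    """Baseline SOC profile with planted odds multipliers applied for
    ``drug`` and renormalized."""
    weights = dict(config.soc_profile)
    for sig in config.planted_signals:
        if sig.drug == drug:
            weights[sig.soc] = weights[sig.soc] * sig.theta
    total = sum(weights.values())
    return {soc: w / total for soc, w in weights.items()}


def generate_cohort(config: SimulationConfig,
                    meddra: MedDRAMap | None = None) -> ICSRCollection:
    """Draw a full synthetic collection under ``config``.

    Identical configurations (including the seed) give identical output.
    ``meddra`` defaults to the packaged mock map; every SOC in the
    profile must have at least one preferred term in the map.
    """
    if meddra is None:
        from .fixtures import load_mock_meddra
        meddra = load_mock_meddra()
    socs = list(config.soc_profile)
    pt_lists = {}
    for soc in socs:
        pts = meddra.pts_in(soc)
        if not pts:
            raise ValidationError(f"no preferred terms mapped to SOC {soc!r}")
        pt_lists[soc] = pts
    marg = config.demographic_marginals

    reports = []
    for drug, n_reports in config.drugs:
        if n_reports == 0:
            continue
        rng = _drug_rng(config.seed, drug)
        soc_probs = adjusted_soc_probabilities(config, drug)
        p_vec = np.array([soc_probs[s] for s in socs])

        geo_p = 1.0 / config.reactions_per_report.mean
        n_rx = rng.geometric(geo_p, size=n_reports)
        if config.reactions_per_report.maximum is not None:
            n_rx = np.minimum(n_rx, config.reactions_per_report.maximum)
        total_rx = int(n_rx.sum())

        soc_idx = rng.choice(len(socs), size=total_rx, p=p_vec)
        pt_pick = rng.random(total_rx)
        outcomes = _draw(rng, marg["outcome"], total_rx)

        age = _draw(rng, marg["age_group"], n_reports)
        sex = _draw(rng, marg["sex"], n_reports)
        reporter = _draw(rng, marg["reporter_group"], n_reports)
        region = _draw(rng, marg["region"], n_reports)
        serious = _draw(rng, marg["seriousness"], n_reports)
        years = _draw(rng, marg["year"], n_reports)
        country = np.empty(n_reports, dtype=object)
        for reg in vocab.REGIONS:
            mask = region == reg
            if mask.any():
                country[mask] = _draw(rng, config.country_by_region[reg],
                                      int(mask.sum()))

        cursor = 0
        for i in range(n_reports):
            k = int(n_rx[i])
            reactions = []
            for j in range(cursor, cursor + k):
                soc = socs[soc_idx[j]]
                pts = pt_lists[soc]
                pt = pts[int(pt_pick[j] * len(pts)) % len(pts)]
                reactions.append(ReactionRecord(pt=pt, outcome=str(outcomes[j])))
            cursor += k
            reports.append(
                ICSR(
                    report_id=f"{drug}-{i + 1:06d}",
                    drug=drug,
                    reactions=tuple(reactions),
                    age_group=str(age[i]),
                    sex=str(sex[i]),
                    reporter_group=str(reporter[i]),
                    country=str(country[i]),
                    region=str(region[i]),
                    seriousness=str(serious[i]),
                    year=int(years[i]),
                )
            )
    return ICSRCollection(reports=reports, meddra=meddra)


def make_paper_like_config(seed: int = 0, planted_signals=()) -> SimulationConfig:
    """A configuration matching the published cohort structure.

    Drug report counts are stiripentol 822, cannabidiol 4222 and
    fenfluramine 852; the SOC profile and all demographic marginals are
    the packaged reference tables pooled over the three drugs and
    normalized.
    """
    from .fixtures import DRUGS, load_table1, load_table2, load_yearly

    t1 = load_table1()
    t2 = load_table2()
    yearly = load_yearly()

    totals = {d: int(t1[t1["section"] == "sex"][d].sum()) for d in DRUGS}

    def pooled(section: str) -> dict:
        sec = t1[t1["section"] == section]
        counts = {row["stratum"]: sum(int(row[d]) for d in DRUGS)
                  for _, row in sec.iterrows()}
        total = sum(counts.values())
        probs = {k: v / total for k, v in counts.items()}
        # close the floating sum exactly on the largest stratum
        gap = 1.0 - sum(probs.values())
        top = max(probs, key=probs.get)
        probs[top] += gap
        return probs

    soc_counts = {row["soc"]: sum(int(row[d]) for d in DRUGS)
                  for _, row in t2.iterrows()}
    soc_total = sum(soc_counts.values())
    soc_profile = {k: v / soc_total for k, v in soc_counts.items()}
    gap = 1.0 - sum(soc_profile.values())
    top = max(soc_profile, key=soc_profile.get)
    soc_profile[top] += gap

    year_counts: dict[int, int] = {}
    for _, row in yearly.iterrows():
        year_counts[int(row["year"])] = (
            year_counts.get(int(row["year"]), 0) + int(row["count"]))
    year_total = sum(year_counts.values())
    year_marg = {y: c / year_total for y, c in year_counts.items()}
    gap = 1.0 - sum(year_marg.values())
    top = max(year_marg, key=year_marg.get)
    year_marg[top] += gap

    # Country mix per region pooled from the named Table-1 countries;
    # the unattributed remainder reports an unknown country ("XX").
    country_sec = t1[t1["section"] == "country"].set_index("stratum")
    region_sec = t1[t1["section"] == "region"].set_index("stratum")
    eea_total = int(region_sec.loc["EEA", list(DRUGS)].sum())
    non_total = int(region_sec.loc["Non-EEA", list(DRUGS)].sum())
    eea_named = {c: int(country_sec.loc[c, list(DRUGS)].sum())
                 for c in ("FR", "DE", "IT", "ES", "NL", "AT")}
    gb = int(country_sec.loc["GB", list(DRUGS)].sum())
    eea_mix = {c: v / eea_total for c, v in eea_named.items()}
    eea_mix["XX"] = 1.0 - sum(eea_mix.values())
    non_mix = {"GB": gb / non_total}
    non_mix["XX"] = 1.0 - non_mix["GB"]

    return SimulationConfig(
        drugs=[(d, totals[d]) for d in DRUGS],
        soc_profile=soc_profile,
        demographic_marginals={
            "age_group": pooled("age_group"),
            "sex": pooled("sex"),
            "reporter_group": pooled("reporter_group"),
            "region": pooled("region"),
            "seriousness": pooled("seriousness"),
            "outcome": pooled("outcome"),
            "year": year_marg,
        },
        country_by_region={"EEA": eea_mix, "Non-EEA": non_mix},
        planted_signals=list(planted_signals),
        seed=seed,
    )
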