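"""Signal thresholds and the full screening report.

Decision rules (per method, evaluated independently):

* ROR — lower 95% bound > 1 and a ≥ ``min_cases``
* PRR — lower 95% bound > 1 and a ≥ ``min_cases``
* BCPNN — IC025 > 0
* MGPS — EB05 ≥ ``ebgm_p5_cut`` and EBGM ≥ ``ebgm_cut``

The interval-bound and IC025 comparisons are strict; the case-count and
EBGM/EB05 cut-offs are non-strict.  The published rule set offers two
printed alternatives for the case count (3 or 5) and the EB05 cut (1.8
or 2.0); both are configurable, with defaults 3 and 2.0.  A combined
column counts how many of the four methods flag (0–4) — methods are
reported side by side, never conjoined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, NonNegativeInt, PositiveFloat

from . import contingency, stats
from .exceptions import ValidationError
from .icsr import ICSRCollection
from .stats import BCPNNConfig, DEFAULT_BCPNN, MGPSPrior, SignalResult

METHODS = ("ror", "prr", "bcpnn", "mgps")


class ThresholdConfig(BaseModel):
    """Cut-offs of the four decision rules."""

    model_config = ConfigDict(frozen=True)

    min_cases: NonNegativeInt = 3
    ebgm_p5_cut: PositiveFloat = 2.0
    ebgm_cut: PositiveFloat = 2.5


DEFAULT_THRESHOLDS = ThresholdConfig()


def apply_thresholds(result: SignalResult,
                     config: ThresholdConfig = DEFAULT_THRESHOLDS) -> dict:
    """Per-method boolean flags for one (drug, SOC) result."""
    a = result.table.a
    return {
        "ror": bool(result.ror.low > 1.0 and a >= config.min_cases),
        "prr": bool(result.prr.low > 1.0 and a >= config.min_cases),
        "bcpnn": bool(result.ic.ic025 > 0.0),
        "mgps": bool(result.eb05 >= config.ebgm_p5_cut
                     and result.ebgm >= config.ebgm_cut),
    }


@dataclass
class ScreenReport:
    """Screening output: one row per (drug, SOC) with all four methods."""

    frame: pd.DataFrame
    basis: str
    thresholds: ThresholdConfig
    bcpnn: BCPNNConfig
    prior: MGPSPrior
    prior_converged: bool
    results: list

    def config_echo(self) -> dict:
        return {
            "basis": self.basis,
            "thresholds": self.thresholds.model_dump(),
            "bcpnn": self.bcpnn.model_dump(),
            "mgps_prior": {
                "alpha1": self.prior.alpha1, "beta1": self.prior.beta1,
                "alpha2": self.prior.alpha2, "beta2": self.prior.beta2,
                "p": self.prior.p, "converged": self.prior_converged,
            },
        }

    def to_csv(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.frame.to_csv(path, index=False)

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        bundle = {
            "config": self.config_echo(),
            "rows": json.loads(self.frame.to_json(orient="records")),
        }
        Path(path).write_text(json.dumps(bundle, indent=2, sort_keys=True))


def screen(collection: ICSRCollection, basis: str = "report-level",
           thresholds: ThresholdConfig = DEFAULT_THRESHOLDS,
           bcpnn: BCPNNConfig = DEFAULT_BCPNN,
           socs=None) -> ScreenReport:
    """Evaluate all four statistics and flags for every (drug, SOC).

    The MGPS prior is fitted once on all cells of the run; rows are
    sorted by SOC then drug, and the report carries the basis and a full
    configuration echo for reproducibility.
    """
    if len(collection.drugs) < 2:
        raise ValidationError("screening needs at least two drugs")
    tables = contingency.build_all(collection, basis=basis, socs=socs)
    fit = stats.mgps_fit_prior(list(tables.values()))

    results = []
    for (drug, soc) in sorted(tables, key=lambda key: (key[1], key[0])):
        result = stats.compute_signal(drug, soc, tables[(drug, soc)],
                                      fit.prior, bcpnn)
        result.flags = apply_thresholds(result, thresholds)
        results.append(result)

    rows = []
    for r in results:
        rows.append({
            "soc": r.soc,
            "drug": r.drug,
            "basis": basis,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "ror": r.ror.value, "ror_low": r.ror.low, "ror_high": r.ror.high,
            "ror_corrected": r.ror.corrected,
            "prr": r.prr.value, "prr_low": r.prr.low, "prr_high": r.prr.high,
            "prr_corrected": r.prr.corrected,
            "chi2": r.chi2, "chi2_p": r.chi2_p,
            "ic": r.ic.ic, "ic025": r.ic.ic025,
            "ebgm": r.ebgm, "eb05": r.eb05,
            "flag_ror": r.flags["ror"], "flag_prr": r.flags["prr"],
            "flag_bcpnn": r.flags["bcpnn"], "flag_mgps": r.flags["mgps"],
            "n_methods_flagging": sum(r.flags.values()),
        })
    frame = pd.DataFrame(rows)
    return ScreenReport(frame=frame, basis=basis, thresholds=thresholds,
                        bcpnn=bcpnn, prior=fit.prior,
                        prior_converged=fit.converged, results=results)
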