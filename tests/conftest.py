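import pytest

from pvsignal.fixtures import load_mock_meddra
from pvsignal.icsr import ICSR, ICSRCollection, ReactionRecord


@pytest.fixture(scope="session")
def meddra():
    return load_mock_meddra()


def make_report(report_id, drug, pts, outcome="Unknown", **overrides):
    """Compact ICSR factory with sensible defaults for tests."""
    fields = dict(
        age_group="3–11 Years",
        sex="Female",
        reporter_group="Healthcare Professional",
        country="FR",
        region="EEA",
        seriousness="Serious",
        year=2023,
    )
    fields.update(overrides)
    reactions = tuple(ReactionRecord(pt=pt, outcome=outcome) for pt in pts)
    return ICSR(report_id=report_id, drug=drug, reactions=reactions, **fields)


@pytest.fixture
def two_drug_collection(meddra):
    """Two drugs, mixed SOCs, one multi-reaction report."""
    reports = [
        make_report("R1", "drugA", ["Seizure", "Somnolence", "Pyrexia"]),
        make_report("R2", "drugA", ["Tachycardia"]),
        make_report("R3", "drugB", ["Diarrhoea"]),
        make_report("R4", "drugB", ["Seizure", "Rash"]),
        make_report("R5", "drugB", ["Pyrexia"]),
    ]
    return ICSRCollection(reports=reports, meddra=meddra)
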