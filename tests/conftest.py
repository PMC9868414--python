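import pytest

from pharmsig.models import ReportRecord, ReportSet
from pharmsig.vocabulary import DrugVocabulary, VocabularyEntry, EventDefinition


@pytest.fixture
def small_vocab() -> DrugVocabulary:
    return DrugVocabulary(
        entries=[
            VocabularyEntry("furosemide", "Diuretics", ("Lasix", "FUROSEMIDE 40MG")),
            VocabularyEntry("losartan", "Angiotensin II receptor blockers",
                            ("Cozaar", "LOSARTAN POTASSIUM")),
            VocabularyEntry("amlodipine", "Calcium channel blockers", ("Norvasc",)),
            VocabularyEntry(
                "Hyzaar (losartan potassium and hydrochlorothiazide)",
                "Compound preparations",
                ("Hyzaar",),
            ),
        ]
    )


@pytest.fixture
def gout_event() -> EventDefinition:
    return EventDefinition("gout", ["gout"])


@pytest.fixture
def urate_events() -> list[EventDefinition]:
    return [
        EventDefinition("hyperuricaemia", ["hyperuricaemia"]),
        EventDefinition("gout", ["gout"]),
        EventDefinition("gouty arthritis", ["gouty arthritis"]),
    ]


def make_report(report_id, drugs, pts=(), case_id=None, version=1, **kw) -> ReportRecord:
    return ReportRecord(
        report_id=report_id,
        case_id=case_id or f"case-{report_id}",
        version=version,
        drug_mentions=tuple(drugs),
        reaction_pts=tuple(pts),
        **kw,
    )


@pytest.fixture
def report_factory():
    return make_report


@pytest.fixture
def small_reports() -> ReportSet:
    """10 deduplicated reports: 2 furosemide+gout, 3 furosemide only,
    1 gout only, 4 neither -> contingency (2, 3, 1, 4)."""
    recs = [
        make_report("r01", ["Lasix"], ["gout"]),
        make_report("r02", ["FUROSEMIDE 40MG"], ["Gout", "nausea"]),
        make_report("r03", ["furosemide"]),
        make_report("r04", ["furosemide"], ["nausea"]),
        make_report("r05", ["furosemide", "Norvasc"]),
        make_report("r06", ["amlodipine"], ["gout"]),
        make_report("r07", ["amlodipine"]),
        make_report("r08", ["Cozaar"]),
        make_report("r09", ["losartan"], ["headache"]),
        make_report("r10", ["unmapped drug"], []),
    ]
    return ReportSet(records=recs)
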