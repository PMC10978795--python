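"""Shared fixtures: hand-built report sets and quarter-file writers."""

from __future__ import annotations

import datetime as dt

import pytest

from pvsignals import DrugMention, ReportCase, ReportSet


def make_report(
    case_id: str,
    focal: bool = False,
    events: list[str] | None = None,
    version: int = 1,
    outcomes: frozenset[str] = frozenset(),
    country: str | None = "US",
    onset: int | None = 10,
    role: str = "PS",
    record_id: str = "",
) -> ReportCase:
    """A minimal report; focal reports name XCOPRI in ``role``."""
    drugs = [DrugMention("XCOPRI", role)] if focal else [DrugMention("LEVETIRACETAM", "PS")]
    start = dt.date(2021, 3, 1)
    return ReportCase(
        case_id=case_id,
        version_key=version,
        drugs=drugs,
        events=events if events is not None else ["Dizziness"],
        outcomes=outcomes,
        country=country,
        therapy_start=None if onset is None else start,
        event_date=None if onset is None else start + dt.timedelta(days=onset),
        record_id=record_id or f"{case_id}v{version}",
    )


@pytest.fixture
def four_cell_reports() -> ReportSet:
    """One report in each cell of the 2x2 table for PT 'Somnolence'."""
    return ReportSet(reports=[
        make_report("1", focal=True, events=["Somnolence"]),
        make_report("2", focal=True, events=["Fatigue"]),
        make_report("3", focal=False, events=["Somnolence"]),
        make_report("4", focal=False, events=["Fatigue"]),
    ])


@pytest.fixture
def quarter_dir(tmp_path):
    """Five hand-written '$'-delimited files: 3 cases plus one orphan row.

    Case 10: XCOPRI/PS, two PTs, serious (HO), US, dated.
    Case 11: XCOPRI/C only (concomitant), one PT.
    Case 12: background drug, one PT, bad event date.
    Orphan: REAC row for primaryid absent from DEMO.
    """
    (tmp_path / "DEMO.txt").write_text(
        "primaryid$caseid$caseversion$event_dt$occr_country\n"
        "101$10$1$20210315$US\n"
        "111$11$1$20210401$GB\n"
        "121$12$1$garbage$US\n"
    )
    (tmp_path / "DRUG.txt").write_text(
        "primaryid$caseid$drug_seq$role_cod$drugname\n"
        "101$10$1$PS$ xcopri \n"
        "101$10$2$C$LEVETIRACETAM\n"
        "111$11$1$C$XCOPRI\n"
        "111$11$2$PS$LAMOTRIGINE\n"
        "121$12$1$PS$VALPROATE\n"
    )
    (tmp_path / "REAC.txt").write_text(
        "primaryid$caseid$pt\n"
        "101$10$Somnolence\n"
        "101$10$Dizziness\n"
        "111$11$Fatigue\n"
        "121$12$Seizure\n"
        "999$99$Orphan event\n"
    )
    (tmp_path / "OUTC.txt").write_text(
        "primaryid$caseid$outc_cod\n"
        "101$10$HO\n"
    )
    (tmp_path / "THER.txt").write_text(
        "primaryid$caseid$dsg_drug_seq$start_dt\n"
        "101$10$1$20210301\n"
        "101$10$2$20210310\n"
        "121$12$1$20210105\n"
    )
    return tmp_path
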