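"""Core record containers for spontaneous adverse-event reports.

A spontaneous-reporting database is modelled as an ordered collection of
:class:`ReportCase` records, each describing one safety report: the drugs it
implicates (with their reporter-assigned roles), the adverse events coded as
MedDRA Preferred Terms (PTs), seriousness outcome codes, reporter country and
the therapy/event dates needed for time-to-onset analysis.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Any, Iterator

#: Drug role codes: primary suspect, secondary suspect, concomitant, interacting.
DRUG_ROLES = frozenset({"PS", "SS", "C", "I"})

#: Outcome codes: death, life-threatening, hospitalization, disability,
#: congenital anomaly, required intervention, other serious.
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})


@dataclass(frozen=True, slots=True)
class DrugMention:
    """One drug named on a report, with the reporter-assigned role code."""

    name: str
    role: str = "PS"

    def __post_init__(self) -> None:
        if self.role not in DRUG_ROLES:
            raise ValueError(f"unknown drug role {self.role!r}; expected one of {sorted(DRUG_ROLES)}")


@dataclass(slots=True)
class ReportCase:
    """One spontaneous report (a single version of a case).

    ``case_id`` identifies the case across report versions; ``version_key``
    orders versions of the same case (deduplication keeps the highest).
    ``record_id`` is the raw per-version record identifier (FAERS primaryid),
    used only as a deterministic tie-break when version keys collide.
    """

    case_id: str
    version_key: int = 1
    drugs: list[DrugMention] = field(default_factory=list)
    events: list[str] = field(default_factory=list)
    outcomes: frozenset[str] = frozenset()
    country: str | None = None
    therapy_start: _dt.date | None = None
    event_date: _dt.date | None = None
    record_id: str = ""

    def __post_init__(self) -> None:
        bad = set(self.outcomes) - OUTCOME_CODES
        if bad:
            raise ValueError(f"unknown outcome codes {sorted(bad)}")
        if not self.record_id:
            self.record_id = f"{self.case_id}{self.version_key}"

    def onset_days(self) -> int | None:
        """Days from therapy start to event date, or None if either is missing."""
        if self.therapy_start is None or self.event_date is None:
            return None
        return (self.event_date - self.therapy_start).days

    def mentions(self, names: frozenset[str], role: str | None, substring: bool) -> bool:
        """True if any drug mention matches ``names`` (case/whitespace-insensitive)."""
        for d in self.drugs:
            if role is not None and d.role != role:
                continue
            name = d.name.strip().upper()
            if substring:
                if any(q in name for q in names):
                    return True
            elif name in names:
                return True
        return False


@dataclass(slots=True)
class ReportSet:
    """Ordered collection of reports plus the provenance that produced it.

    ``provenance`` records either the simulation configuration or the
    ingestion inputs, so a result table can always be traced back to its
    source database.
    """

    reports: list[ReportCase] = field(default_factory=list)
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.reports:
            if r.record_id in seen:
                raise ValueError(f"duplicate record id {r.record_id!r}")
            seen.add(r.record_id)
            if any(not pt for pt in r.events):
                raise ValueError(f"empty PT name in report {r.record_id!r}")

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[ReportCase]:
        return iter(self.reports)

    def __getitem__(self, i: int) -> ReportCase:
        return self.reports[i]

    def replace(self, reports: list[ReportCase], **extra: Any) -> "ReportSet":
        """A new ReportSet with the same provenance plus ``extra`` annotations."""
        return ReportSet(reports=reports, provenance={**self.provenance, **extra})
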