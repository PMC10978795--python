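"""Per-PT 2x2 contingency tables and SOC-level aggregation.

Disproportionality analysis reduces a reporting database to one fourfold
table per adverse event: ``a`` focal-drug reports with the event, ``b``
focal-drug reports without it, ``c`` other reports with it and ``d`` other
reports without it.  The counting unit is the deduplicated report — a report
contributes at most once to the focal row and at most once to an event
column, however many times a PT is mentioned on it.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .ingest import DEFAULT_DRUG_NAMES
from .records import ReportSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    """Fourfold table for one (drug, event) pair."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.n == 0:
            raise ValueError("empty table (N = 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def _split_focal(reports: ReportSet, drug_names, role, substring) -> tuple[list, list]:
    queries = frozenset(n.strip().upper() for n in drug_names)
    focal, other = [], []
    for r in reports:
        (focal if r.mentions(queries, role, substring) else other).append(r)
    return focal, other


def build_table(
    reports: ReportSet,
    drug_names=DEFAULT_DRUG_NAMES,
    pt: str = "",
    role: str | None = "PS",
    substring: bool = False,
) -> ContingencyTable:
    """The 2x2 table for one PT against the focal drug.

    ``reports`` must already be deduplicated; cells sum to ``len(reports)``.
    """
    if len(reports) == 0:
        raise ValueError("no reports")
    if not pt:
        raise ValueError("pt must be a non-empty PT name")
    focal, other = _split_focal(reports, drug_names, role, substring)
    a = sum(1 for r in focal if pt in r.events)
    c = sum(1 for r in other if pt in r.events)
    return ContingencyTable(a=a, b=len(focal) - a, c=c, d=len(other) - c)


def build_all_tables(
    reports: ReportSet,
    drug_names=DEFAULT_DRUG_NAMES,
    role: str | None = "PS",
    substring: bool = False,
) -> dict[str, ContingencyTable]:
    """One table per PT observed on at least one focal-drug report.

    PTs never co-reported with the focal drug (a = 0) carry no signal
    information for it and are omitted.  All returned tables share the same
    focal margin a + b.  Keys are sorted PT names.
    """
    if len(reports) == 0:
        raise ValueError("no reports")
    focal, other = _split_focal(reports, drug_names, role, substring)
    n_focal, n_other = len(focal), len(other)
    a_counts: dict[str, int] = {}
    for r in focal:
        for pt in set(r.events):
            a_counts[pt] = a_counts.get(pt, 0) + 1
    c_counts: dict[str, int] = {}
    for r in other:
        for pt in set(r.events):
            c_counts[pt] = c_counts.get(pt, 0) + 1
    out: dict[str, ContingencyTable] = {}
    for pt in sorted(a_counts):
        a = a_counts[pt]
        c = c_counts.get(pt, 0)
        out[pt] = ContingencyTable(a=a, b=n_focal - a, c=c, d=n_other - c)
    return out


class MeddraMap:
    """PT -> (SOC name, SOC code) under the primary-SOC convention.

    MedDRA is multi-axial, but aggregate safety tables assign each PT to its
    primary SOC so SOC counts partition the PT counts.  Lookups are
    case-insensitive.  Real analyses must supply a licensed dictionary as a
    CSV with header ``pt,soc,soc_code``; a small toy map bundled for tests
    and examples is available via :meth:`toy`.
    """

    def __init__(self, mapping: dict[str, tuple[str, str]]):
        self._map = {pt.strip().lower(): (soc, str(code)) for pt, (soc, code) in mapping.items()}

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return pt.strip().lower() in self._map

    def lookup(self, pt: str) -> tuple[str, str] | None:
        return self._map.get(pt.strip().lower())

    @classmethod
    def from_csv(cls, path: str | Path) -> "MeddraMap":
        mapping: dict[str, tuple[str, str]] = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            need = {"pt", "soc"}
            if reader.fieldnames is None or not need <= set(reader.fieldnames):
                raise ValueError(f"{path}: expected CSV header with columns pt,soc[,soc_code]")
            for row in reader:
                mapping[row["pt"]] = (row["soc"], row.get("soc_code", ""))
        return cls(mapping)

    @classmethod
    def toy(cls) -> "MeddraMap":
        """The bundled toy map (synthetic-vocabulary PTs only)."""
        with resources.as_file(resources.files("pvsignals.data") / "toy_meddra.csv") as p:
            return cls.from_csv(p)


def aggregate_soc(pt_counts: dict[str, int], meddra: MeddraMap) -> pd.DataFrame:
    """Roll PT case counts up to SOC level.

    Returns a DataFrame with columns ``soc, soc_code, case_reports`` sorted
    by descending count (ties by SOC name); the total conserves the input
    PT counts.  PTs absent from the map are pooled under ``UNMAPPED`` with a
    warning.
    """
    rows: dict[str, tuple[str, int]] = {}
    unmapped = []
    for pt, count in pt_counts.items():
        hit = meddra.lookup(pt)
        if hit is None:
            unmapped.append(pt)
            soc, code = "UNMAPPED", ""
        else:
            soc, code = hit
        prev = rows.get(soc, (code, 0))
        rows[soc] = (prev[0], prev[1] + int(count))
    if unmapped:
        logger.warning("aggregate_soc: %d PT(s) missing from the MedDRA map: %s", len(unmapped), sorted(unmapped))
    df = pd.DataFrame(
        [(soc, code, count) for soc, (code, count) in rows.items()],
        columns=["soc", "soc_code", "case_reports"],
    )
    return df.sort_values(["case_reports", "soc"], ascending=[False, True], ignore_index=True)


def write_tables_csv(tables: dict[str, ContingencyTable], path: str | Path) -> None:
    """Write per-PT cells as CSV (``pt,a,b,c,d``)."""
    df = pd.DataFrame(
        [(pt, t.a, t.b, t.c, t.d) for pt, t in tables.items()],
        columns=["pt", "a", "b", "c", "d"],
    )
    df.to_csv(path, index=False)
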