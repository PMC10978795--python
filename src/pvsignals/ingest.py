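"""Reading FAERS-dialect quarterly files, deduplication and drug selection.

FAERS distributes each quarter as a set of "$"-delimited ASCII tables keyed
by a per-version record identifier (``primaryid``) and a per-case identifier
(``caseid``): DEMO (one row per report version), DRUG (one row per drug
mention), REAC (one row per reacted PT), OUTC (outcome codes) and THER
(therapy episodes).  Cases are re-submitted as follow-up versions, so a
disproportionality analysis must first keep a single version per case, then
restrict to reports naming the focal drug in the required role.
"""

from __future__ import annotations

import datetime as _dt
import logging
from pathlib import Path

import pandas as pd

from .records import DRUG_ROLES, OUTCOME_CODES, DrugMention, ReportCase, ReportSet

logger = logging.getLogger(__name__)

DEFAULT_DRUG_NAMES = ("XCOPRI", "CENOBAMATE")

_REQUIRED = {
    "DEMO": ["primaryid", "caseid", "caseversion"],
    "DRUG": ["primaryid", "caseid", "role_cod", "drugname"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "start_dt"],
}


class FormatError(ValueError):
    """A quarterly file is missing a required column."""


def _classify(path: Path) -> str | None:
    stem = path.name.upper()
    for key in _REQUIRED:
        if key in stem:
            return key
    return None


def _read_table(path: Path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED[kind] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing} for {kind}")
    return df


def _parse_date(raw: str) -> _dt.date | None:
    raw = raw.strip()
    if not raw:
        return None
    # FAERS dates are YYYYMMDD integers but partial dates (YYYY, YYYYMM)
    # and garbage occur; anything unparseable becomes missing.
    if len(raw) == 8 and raw.isdigit():
        try:
            return _dt.date(int(raw[:4]), int(raw[4:6]), int(raw[6:8]))
        except ValueError:
            return None
    return None


def read_quarter(paths: list[str | Path]) -> ReportSet:
    """Read one quarter's DEMO/DRUG/REAC/OUTC/THER files into a ReportSet.

    DEMO is the spine: one :class:`ReportCase` per DEMO row.  Rows in the
    satellite tables whose ``primaryid`` has no DEMO row are orphans and are
    dropped with a warning; unparseable dates become missing.  DEMO rows with
    no reaction row are dropped (a FAERS report always carries >= 1 PT).
    """
    tables: dict[str, list[pd.DataFrame]] = {k: [] for k in _REQUIRED}
    for p in paths:
        p = Path(p)
        kind = _classify(p)
        if kind is None:
            raise FormatError(f"{p}: cannot classify file (expected DEMO/DRUG/REAC/OUTC/THER in name)")
        tables[kind].append(_read_table(p, kind))

    def stacked(kind: str) -> pd.DataFrame:
        frames = tables[kind]
        if not frames:
            return pd.DataFrame(columns=_REQUIRED[kind])
        return pd.concat(frames, ignore_index=True)

    demo = stacked("DEMO")
    known = set(demo["primaryid"])

    def keep_known(df: pd.DataFrame, kind: str) -> pd.DataFrame:
        orphans = ~df["primaryid"].isin(known)
        if orphans.any():
            logger.warning("%s: dropping %d orphan row(s) with no DEMO case", kind, int(orphans.sum()))
        return df[~orphans]

    drug = keep_known(stacked("DRUG"), "DRUG")
    reac = keep_known(stacked("REAC"), "REAC")
    outc = keep_known(stacked("OUTC"), "OUTC")
    ther = keep_known(stacked("THER"), "THER")

    drugs_by_pid: dict[str, list[DrugMention]] = {}
    for pid, role, name in zip(drug["primaryid"], drug["role_cod"], drug["drugname"]):
        role = role.strip().upper()
        if role not in DRUG_ROLES:
            logger.warning("DRUG: dropping mention with unknown role %r on case %s", role, pid)
            continue
        drugs_by_pid.setdefault(pid, []).append(DrugMention(name.strip(), role))

    events_by_pid: dict[str, list[str]] = {}
    for pid, pt in zip(reac["primaryid"], reac["pt"]):
        pt = pt.strip()
        if pt and pt not in events_by_pid.setdefault(pid, []):
            events_by_pid[pid].append(pt)

    outc_by_pid: dict[str, set[str]] = {}
    for pid, code in zip(outc["primaryid"], outc["outc_cod"]):
        code = code.strip().upper()
        if code in OUTCOME_CODES:
            outc_by_pid.setdefault(pid, set()).add(code)
        else:
            logger.warning("OUTC: dropping unknown outcome code %r on case %s", code, pid)

    start_by_pid: dict[str, _dt.date] = {}
    for pid, raw in zip(ther["primaryid"], ther["start_dt"]):
        d = _parse_date(raw)
        if d is not None and (pid not in start_by_pid or d < start_by_pid[pid]):
            start_by_pid[pid] = d  # earliest therapy record

    reports: list[ReportCase] = []
    n_no_events = 0
    for row in demo.itertuples(index=False):
        pid = row.primaryid
        events = events_by_pid.get(pid, [])
        if not events:
            n_no_events += 1
            continue
        try:
            version = int(str(row.caseversion).strip() or "1")
        except ValueError:
            version = 1
        country = getattr(row, "occr_country", "").strip() or None
        reports.append(
            ReportCase(
                case_id=str(row.caseid).strip(),
                version_key=version,
                drugs=drugs_by_pid.get(pid, []),
                events=events,
                outcomes=frozenset(outc_by_pid.get(pid, set())),
                country=country,
                therapy_start=start_by_pid.get(pid),
                event_date=_parse_date(getattr(row, "event_dt", "")),
                record_id=pid,
            )
        )
    if n_no_events:
        logger.warning("DEMO: dropping %d case(s) with no reaction rows", n_no_events)
    prov = {"source": "faers_dialect", "paths": [str(Path(p)) for p in paths]}
    return ReportSet(reports=reports, provenance=prov)


def deduplicate(reports: ReportSet) -> ReportSet:
    """Keep one report per case: highest version, ties broken by record id.

    Follow-up submissions supersede earlier versions of the same case, so
    retaining the maximal ``version_key`` (FAERS: latest caseversion /
    highest primaryid) removes both duplicates and stale versions.  The
    operation is idempotent and preserves first-appearance order.
    """
    best: dict[str, ReportCase] = {}
    order: list[str] = []
    for r in reports:
        cur = best.get(r.case_id)
        if cur is None:
            best[r.case_id] = r
            order.append(r.case_id)
        elif (r.version_key, r.record_id) > (cur.version_key, cur.record_id):
            best[r.case_id] = r
    return reports.replace([best[cid] for cid in order], deduplicated=True)


def select_drug_reports(
    reports: ReportSet,
    names: tuple[str, ...] = DEFAULT_DRUG_NAMES,
    role: str | None = "PS",
    substring: bool = False,
) -> ReportSet:
    """Reports naming any of ``names`` (case/whitespace-insensitive) in ``role``.

    Matching is exact by default; pass ``substring=True`` to match drug-name
    substrings (useful for combination products, at the cost of false
    positives).  ``role=None`` accepts any role.
    """
    if not names:
        raise ValueError("names must be non-empty")
    if role is not None and role not in DRUG_ROLES:
        raise ValueError(f"unknown role {role!r}")
    queries = frozenset(n.strip().upper() for n in names)
    kept = [r for r in reports if r.mentions(queries, role, substring)]
    return reports.replace(kept, focal_query={"names": sorted(queries), "role": role})
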