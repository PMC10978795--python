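"""Descriptive summaries, onset-time distribution and the end-to-end pipeline.

Beyond the per-PT signal scan, a safety profile reports who and what the
reports describe: country of origin, seriousness outcomes, and the
distribution of time from therapy start to event onset (bucketed monthly —
the first bucket typically dominates for drugs whose adverse events surface
during titration).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ingest import DEFAULT_DRUG_NAMES, deduplicate, read_quarter, select_drug_reports
from .records import OUTCOME_CODES, ReportSet
from .stats import (
    BcpnnPriors,
    SignalCriteria,
    compute_metrics,
    evaluate_criteria,
    venn_counts,
)
from .synthetic import SimConfig, generate_reports
from .tables import MeddraMap, aggregate_soc, build_all_tables

logger = logging.getLogger(__name__)

#: Outcome codes that mark a report as serious (any one suffices).
DEFAULT_SERIOUS_CODES = frozenset(OUTCOME_CODES)


@dataclass(frozen=True)
class DescriptiveSummary:
    """Counts describing a deduplicated report set."""

    n_reports: int
    by_country: dict[str, int]
    by_outcome: dict[str, int]
    n_serious: int
    serious_fraction: float   # exact proportion, n_serious / n_reports
    serious_percent: float    # percentage rounded to 1 decimal


@dataclass(frozen=True)
class OnsetDistribution:
    """Monthly onset-time buckets (half-open 30-day intervals).

    Bucket k covers onset days [30(k-1), 30k); day 0 falls in bucket 1.
    Negative onsets and reports missing either date are excluded from the
    buckets and counted separately.
    """

    buckets: dict[int, int]
    n_with_dates: int
    n_negative: int
    n_missing: int
    bucket_days: int = 30


def descriptive_summary(
    reports: ReportSet, serious_codes: frozenset[str] = DEFAULT_SERIOUS_CODES
) -> DescriptiveSummary:
    """Country, outcome and seriousness breakdown of a report set.

    A report is serious when it carries at least one outcome code from
    ``serious_codes``.  The serious share is also reported as a percentage
    rounded to one decimal.
    """
    if len(reports) == 0:
        raise ValueError("no reports")
    by_country: Counter[str] = Counter()
    by_outcome: Counter[str] = Counter()
    n_serious = 0
    for r in reports:
        if r.country:
            by_country[r.country] += 1
        for code in r.outcomes:
            by_outcome[code] += 1
        if r.outcomes & serious_codes:
            n_serious += 1
    frac = n_serious / len(reports)
    return DescriptiveSummary(
        n_reports=len(reports),
        by_country=dict(by_country.most_common()),
        by_outcome=dict(by_outcome.most_common()),
        n_serious=n_serious,
        serious_fraction=frac,
        serious_percent=round(100.0 * frac, 1),
    )


def onset_time_distribution(reports: ReportSet, bucket_days: int = 30) -> OnsetDistribution:
    """Distribution of (event date - earliest therapy start) in monthly buckets."""
    buckets: Counter[int] = Counter()
    n_negative = n_missing = 0
    for r in reports:
        days = r.onset_days()
        if days is None:
            n_missing += 1
        elif days < 0:
            n_negative += 1
        else:
            buckets[days // bucket_days + 1] += 1
    return OnsetDistribution(
        buckets=dict(sorted(buckets.items())),
        n_with_dates=sum(buckets.values()),
        n_negative=n_negative,
        n_missing=n_missing,
        bucket_days=bucket_days,
    )


SIGNAL_COLUMNS = [
    "pt", "soc", "case_reports",
    "ror", "ror_ci_low", "ror_ci_high", "prr", "chi2",
    "e_ic", "ic025", "ebgm", "ebgm05",
    "ror_pos", "mhra_pos", "bcpnn_pos", "mgps_pos", "tier",
]


def signal_table(
    reports: ReportSet,
    drug_names=DEFAULT_DRUG_NAMES,
    meddra: MeddraMap | None = None,
    criteria: SignalCriteria = SignalCriteria(),
    priors: BcpnnPriors = BcpnnPriors(),
    continuity: bool = False,
    role: str | None = "PS",
) -> pd.DataFrame:
    """Full per-PT scan: 2x2 tables, all four statistics, decisions, SOC.

    One row per PT co-reported with the focal drug, full floating-point
    precision (use :func:`write_signals_csv` for the rounded export).  The
    EBGM columns hold the unshrunk relative reporting ratio.
    """
    tables = build_all_tables(reports, drug_names, role=role)
    rows = []
    for pt, table in tables.items():
        m = compute_metrics(table, priors=priors, continuity=continuity)
        d = evaluate_criteria(m, table.a, criteria)
        soc = ""
        if meddra is not None:
            hit = meddra.lookup(pt)
            soc = hit[0] if hit is not None else "UNMAPPED"
        rows.append((
            pt, soc, table.a,
            m.ror, m.ror_ci_low, m.ror_ci_high, m.prr, m.chi2,
            m.e_ic, m.ic025, m.ebgm, m.ebgm05,
            d.ror_pos, d.mhra_pos, d.bcpnn_pos, d.mgps_pos, d.tier,
        ))
    return pd.DataFrame(rows, columns=SIGNAL_COLUMNS)


def decisions_from_table(df: pd.DataFrame) -> dict:
    """Rebuild the per-PT decision mapping from a signal table."""
    from .stats import SignalDecision

    return {
        row.pt: SignalDecision(
            ror_pos=bool(row.ror_pos), mhra_pos=bool(row.mhra_pos),
            bcpnn_pos=bool(row.bcpnn_pos), mgps_pos=bool(row.mgps_pos),
        )
        for row in df.itertuples(index=False)
    }


def top_signals_table(results: pd.DataFrame, n: int = 30, sort: str = "case_reports") -> pd.DataFrame:
    """Top-``n`` strong-tier PTs sorted by descending case count.

    Ties are broken by descending ROR, then PT name.  Fewer than ``n``
    strong PTs simply yields fewer rows.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(results) == 0:
        raise ValueError("empty results")
    strong = results[results["tier"] == "strong"]
    strong = strong.sort_values(
        [sort, "ror", "pt"], ascending=[False, False, True], ignore_index=True
    )
    return strong.head(n)


def write_signals_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Export a signal table with statistics rounded to 2 decimals."""
    out = df.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(2)
    out.to_csv(path, index=False)


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    drug_names: tuple[str, ...] = DEFAULT_DRUG_NAMES
    role: str | None = "PS"
    substring: bool = False
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    priors: BcpnnPriors = field(default_factory=BcpnnPriors)
    continuity: bool = False
    serious_codes: frozenset[str] = DEFAULT_SERIOUS_CODES
    top_n: int = 30


def run_pipeline(
    out_dir: str | Path,
    reports: ReportSet | None = None,
    quarter_files: list[str | Path] | None = None,
    sim_config: SimConfig | None = None,
    meddra: MeddraMap | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Ingest -> dedup -> select -> tables -> statistics -> summaries.

    Exactly one report source must be given: an in-memory ``reports`` set,
    FAERS-dialect ``quarter_files``, or a ``sim_config`` to simulate.  Writes
    ``signals.csv``, ``top_signals.csv``, ``soc.csv``, ``onset.csv``,
    ``venn.json``, ``summary.json`` and ``run_log.json`` into ``out_dir`` and
    returns the run log (stage counts, parameters, outputs).  Identical
    inputs and configuration produce byte-identical outputs.
    """
    sources = [s is not None for s in (reports, quarter_files, sim_config)]
    if sum(sources) != 1:
        raise ValueError("give exactly one of reports, quarter_files, sim_config")

    log: dict = {"parameters": {
        "drug_names": list(config.drug_names),
        "role": config.role,
        "criteria": dataclasses.asdict(config.criteria),
        "priors": dataclasses.asdict(config.priors),
        "continuity": config.continuity,
        "top_n": config.top_n,
    }}

    def stage(name: str, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # annotate with the failing stage
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if sim_config is not None:
        raw = stage("simulate", generate_reports, sim_config)
        log["parameters"]["seed"] = sim_config.seed
    elif quarter_files is not None:
        raw = stage("ingest", read_quarter, quarter_files)
    else:
        raw = reports
    log["n_raw_reports"] = len(raw)

    deduped = stage("deduplicate", deduplicate, raw)
    log["n_deduplicated"] = len(deduped)
    focal = stage("select", select_drug_reports, deduped, config.drug_names,
                  config.role, config.substring)
    log["n_focal_reports"] = len(focal)

    df = stage("signals", signal_table, deduped, config.drug_names, meddra,
               config.criteria, config.priors, config.continuity, config.role)
    log["n_pts_scanned"] = int(len(df))
    venn = venn_counts(decisions_from_table(df))
    log["venn"] = venn

    summary = stage("descriptive", descriptive_summary, focal, config.serious_codes)
    onset = stage("onset", onset_time_distribution, focal)
    strong_counts = {
        row.pt: int(row.case_reports)
        for row in df.itertuples(index=False) if row.tier == "strong"
    }
    soc_df = aggregate_soc(strong_counts, meddra) if meddra is not None and strong_counts \
        else pd.DataFrame(columns=["soc", "soc_code", "case_reports"])

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_signals_csv(df, out_dir / "signals.csv")
    try:
        top = top_signals_table(df, config.top_n)
    except ValueError:
        top = df.head(0)
    write_signals_csv(top, out_dir / "top_signals.csv")
    soc_df.to_csv(out_dir / "soc.csv", index=False)
    pd.DataFrame(
        sorted(onset.buckets.items()), columns=["month_bucket", "reports"]
    ).to_csv(out_dir / "onset.csv", index=False)
    (out_dir / "venn.json").write_text(json.dumps(venn, indent=2, sort_keys=True))
    (out_dir / "summary.json").write_text(json.dumps({
        **dataclasses.asdict(summary),
        "onset_n_with_dates": onset.n_with_dates,
        "onset_n_missing": onset.n_missing,
        "onset_n_negative": onset.n_negative,
    }, indent=2, sort_keys=True))
    log["n_strong_pts"] = len(strong_counts)
    log["outputs"] = sorted(p.name for p in out_dir.iterdir())
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    return log


def plot_summary(out_dir: str | Path, onset: OnsetDistribution, soc_df: pd.DataFrame) -> list[Path]:
    """Optional bar charts of onset buckets and SOC counts (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    if onset.buckets:
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.bar(list(onset.buckets), list(onset.buckets.values()), color="#4878a8")
        ax.set_xlabel("Months since therapy start")
        ax.set_ylabel("Reports")
        fig.tight_layout()
        p = out_dir / "onset.png"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    if len(soc_df):
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.barh(soc_df["soc"][::-1], soc_df["case_reports"][::-1], color="#a85448")
        ax.set_xlabel("Case reports")
        fig.tight_layout()
        p = out_dir / "soc.png"
        fig.savefig(p)
        plt.close(fig)
        paths.append(p)
    return paths
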