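"""Synthetic spontaneous-reporting databases with known ground truth.

Real pharmacovigilance databases (FAERS and its peers) cannot ship with a
package, and their contents drift quarter to quarter.  This module generates
databases whose data-generating process is fully specified, so every
downstream stage — ingestion, deduplication, 2x2 tables, disproportionality
statistics, decisions — can be tested against analytic expectations and an
injected ground-truth signal list.

Generative model
----------------
Each of ``n_reports`` reports independently:

* lists the focal drug as primary suspect with probability
  ``focal_drug_fraction`` (otherwise a background drug is the primary
  suspect);
* draws each background PT as an independent Bernoulli event: probability
  ``rate`` for non-focal reports and ``min(1, rate * reporting_ratio)`` for
  focal reports, where ``reporting_ratio`` is 1 unless the PT carries an
  injected signal;
* reports that draw no event at all receive a catch-all filler PT instead,
  so every report carries at least one reaction while the per-PT marginal
  rates above stay exact;
* is serious with probability ``serious_fraction``; serious reports draw one
  outcome code from ``outcome_weights``;
* draws a reporter country from ``country_weights`` and an event onset
  (days from therapy start) from ``onset_day_distribution``.

All randomness flows from one ``numpy`` generator seeded by ``seed``, so a
fixed configuration reproduces a bit-identical database.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .records import OUTCOME_CODES, DrugMention, ReportCase, ReportSet

# Default conditions emulate a focal-drug scan of a spontaneous-report
# database at desk scale: 10,000 reports, 5% naming the focal drug as
# primary suspect, ~30 background events at realistic per-report rates,
# seriousness and country mix matching published FAERS summaries.
DEFAULT_FOCAL_DRUG = "XCOPRI"

DEFAULT_BACKGROUND_DRUGS = (
    "LEVETIRACETAM",
    "LAMOTRIGINE",
    "VALPROATE",
    "CARBAMAZEPINE",
    "GABAPENTIN",
    "TOPIRAMATE",
)

DEFAULT_BACKGROUND_PTS: tuple[tuple[str, float], ...] = (
    ("Seizure", 0.020),
    ("Somnolence", 0.015),
    ("Dizziness", 0.018),
    ("Fatigue", 0.025),
    ("Headache", 0.030),
    ("Nausea", 0.028),
    ("Vomiting", 0.015),
    ("Fall", 0.012),
    ("Product dose omission issue", 0.010),
    ("Balance disorder", 0.005),
    ("Memory impairment", 0.006),
    ("Hypersomnia", 0.003),
    ("Lethargy", 0.004),
    ("Generalised tonic-clonic seizure", 0.002),
    ("Dysarthria", 0.003),
    ("Aura", 0.001),
    ("Disturbance in attention", 0.004),
    ("Amnesia", 0.004),
    ("Speech disorder", 0.003),
    ("Partial seizures", 0.001),
    ("Tremor", 0.010),
    ("Feeling abnormal", 0.012),
    ("Gait disturbance", 0.008),
    ("Vision blurred", 0.009),
    ("Diplopia", 0.003),
    ("Irritability", 0.006),
    ("Anger", 0.003),
    ("Insomnia", 0.015),
    ("Anxiety", 0.014),
    ("Rash", 0.020),
    ("Pruritus", 0.012),
    ("Arthralgia", 0.015),
    ("Myalgia", 0.010),
    ("Cough", 0.008),
    ("Dyspnoea", 0.012),
)

DEFAULT_OUTCOME_WEIGHTS = {"HO": 315.0, "OT": 375.0, "DE": 36.0, "LT": 22.0, "DS": 22.0}
DEFAULT_COUNTRY_WEIGHTS = {"US": 2378.0, "GB": 29.0, "CA": 40.0, "FR": 40.0, "JP": 24.0, "ES": 24.0}

#: Earliest therapy start used for synthetic dates; starts are spread
#: uniformly over a three-year reporting window from this origin.
DATE_ORIGIN = _dt.date(2020, 7, 1)
DATE_WINDOW_DAYS = 1095


def _check(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"SimConfig.{fieldname}: {msg}")


@dataclass
class SimConfig:
    """Full parameterization of one synthetic reporting database."""

    n_reports: int = 10_000
    focal_drug_fraction: float = 0.05
    background_pts: list[tuple[str, float]] = field(
        default_factory=lambda: [list(t) for t in DEFAULT_BACKGROUND_PTS]
    )
    injected_signals: list[tuple[str, float]] = field(default_factory=list)
    serious_fraction: float = 0.304
    outcome_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OUTCOME_WEIGHTS))
    country_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS))
    onset_day_distribution: tuple[str, dict[str, float]] = ("geometric", {"mean": 30.0})
    seed: int = 0
    focal_drug: str = DEFAULT_FOCAL_DRUG
    background_drugs: list[str] = field(default_factory=lambda: list(DEFAULT_BACKGROUND_DRUGS))
    filler_pt: str = "Drug ineffective"
    missing_date_fraction: float = 0.0

    def __post_init__(self) -> None:
        self.background_pts = [(str(p), float(r)) for p, r in self.background_pts]
        self.injected_signals = [(str(p), float(r)) for p, r in self.injected_signals]
        _check(int(self.n_reports) == self.n_reports and self.n_reports >= 1, "n_reports", "must be a positive integer")
        self.n_reports = int(self.n_reports)
        _check(0.0 < self.focal_drug_fraction < 1.0, "focal_drug_fraction", "must lie in (0, 1)")
        _check(len(self.background_pts) > 0, "background_pts", "must name at least one PT")
        names = [p for p, _ in self.background_pts]
        _check(len(set(names)) == len(names), "background_pts", "PT names must be unique")
        _check(all(r >= 0 for _, r in self.background_pts), "background_pts", "rates must be >= 0")
        _check(all(r <= 1 for _, r in self.background_pts), "background_pts", "rates are probabilities (<= 1)")
        known = set(names)
        for p, ratio in self.injected_signals:
            _check(p in known, "injected_signals", f"signal PT {p!r} is not a background PT")
            _check(ratio >= 0, "injected_signals", "reporting ratios must be >= 0")
        _check(0.0 <= self.serious_fraction <= 1.0, "serious_fraction", "must lie in [0, 1]")
        _check(set(self.outcome_weights) <= OUTCOME_CODES, "outcome_weights", "unknown outcome code")
        _check(all(w >= 0 for w in self.outcome_weights.values()) and sum(self.outcome_weights.values()) > 0,
               "outcome_weights", "weights must be >= 0 with a positive sum")
        _check(all(w >= 0 for w in self.country_weights.values()) and sum(self.country_weights.values()) > 0,
               "country_weights", "weights must be >= 0 with a positive sum")
        name, params = self.onset_day_distribution
        _check(name == "geometric", "onset_day_distribution", f"unknown distribution {name!r}")
        _check(params.get("mean", 0) > 0, "onset_day_distribution", "mean must be > 0")
        _check(int(self.seed) == self.seed, "seed", "must be an integer")
        self.seed = int(self.seed)
        _check(len(self.background_drugs) > 0, "background_drugs", "pool must be non-empty")
        _check(self.filler_pt not in known, "filler_pt", "must not shadow a background PT")
        _check(0.0 <= self.missing_date_fraction <= 1.0, "missing_date_fraction", "must lie in [0, 1]")

    # -- plain-text round trip -------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        """Serialize to a plain-text key-value (YAML) file."""
        d = dataclasses.asdict(self)
        d["background_pts"] = [list(t) for t in self.background_pts]
        d["injected_signals"] = [list(t) for t in self.injected_signals]
        d["onset_day_distribution"] = [self.onset_day_distribution[0], dict(self.onset_day_distribution[1])]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "onset_day_distribution" in d:
            name, params = d["onset_day_distribution"]
            d["onset_day_distribution"] = (name, params)
        return cls(**d)


def generate_reports(config: SimConfig) -> ReportSet:
    """Draw one synthetic reporting database from ``config``.

    Identical configurations (including the seed) produce bit-identical
    report sets.  Each report carries at least one event and each PT appears
    at most once per report.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    pts = [p for p, _ in config.background_pts]
    rates = np.array([r for _, r in config.background_pts])
    ratios = np.ones(len(pts))
    idx = {p: i for i, p in enumerate(pts)}
    for p, ratio in config.injected_signals:
        ratios[idx[p]] = ratio
    focal_rates = np.minimum(1.0, rates * ratios)

    focal = rng.random(n) < config.focal_drug_fraction
    u = rng.random((n, len(pts)))
    thresh = np.where(focal[:, None], focal_rates[None, :], rates[None, :])
    events = u < thresh

    bg_drug = rng.integers(0, len(config.background_drugs), size=n)
    serious = rng.random(n) < config.serious_fraction
    out_codes = list(config.outcome_weights)
    out_p = np.array([config.outcome_weights[c] for c in out_codes], dtype=float)
    out_p /= out_p.sum()
    outcome_idx = rng.choice(len(out_codes), size=n, p=out_p)
    c_codes = list(config.country_weights)
    c_p = np.array([config.country_weights[c] for c in c_codes], dtype=float)
    c_p /= c_p.sum()
    country_idx = rng.choice(len(c_codes), size=n, p=c_p)
    start_off = rng.integers(0, DATE_WINDOW_DAYS, size=n)
    mean = config.onset_day_distribution[1]["mean"]
    # geometric on {0, 1, 2, ...} with the requested mean
    onset = rng.geometric(1.0 / (mean + 1.0), size=n) - 1
    missing = rng.random(n) < config.missing_date_fraction

    reports: list[ReportCase] = []
    for i in range(n):
        evs = [pts[j] for j in np.flatnonzero(events[i])]
        if not evs:
            evs = [config.filler_pt]
        bg = DrugMention(config.background_drugs[bg_drug[i]], "C" if focal[i] else "PS")
        drugs = [DrugMention(config.focal_drug, "PS"), bg] if focal[i] else [bg]
        if missing[i]:
            start = event = None
        else:
            start = DATE_ORIGIN + _dt.timedelta(days=int(start_off[i]))
            event = start + _dt.timedelta(days=int(onset[i]))
        reports.append(
            ReportCase(
                case_id=f"{10_000_000 + i}",
                version_key=1,
                drugs=drugs,
                events=evs,
                outcomes=frozenset({out_codes[outcome_idx[i]]}) if serious[i] else frozenset(),
                country=c_codes[country_idx[i]],
                therapy_start=start,
                event_date=event,
            )
        )
    prov = {"source": "synthetic", "config": dataclasses.asdict(config)}
    return ReportSet(reports=reports, provenance=prov)


def expected_cells(config: SimConfig, pt: str) -> tuple[float, float, float, float]:
    """Analytic expectations of the 2x2 cells (a, b, c, d) for one PT.

    Under the generative model, with ``f = focal_drug_fraction``, ``r`` the
    PT's background rate and ``q = min(1, r * reporting_ratio)``::

        E[a] = n f q          E[b] = n f (1 - q)
        E[c] = n (1 - f) r    E[d] = n (1 - f) (1 - r)

    These match :func:`generate_reports` exactly: the filler mechanism never
    alters a background PT's marginal rate.
    """
    lookup = dict(config.background_pts)
    if pt not in lookup:
        raise KeyError(f"unknown PT {pt!r}: not in background_pts")
    r = lookup[pt]
    ratio = dict(config.injected_signals).get(pt, 1.0)
    q = min(1.0, r * ratio)
    n, f = config.n_reports, config.focal_drug_fraction
    return (n * f * q, n * f * (1.0 - q), n * (1.0 - f) * r, n * (1.0 - f) * (1.0 - r))


# -- FAERS ASCII dialect -------------------------------------------------------

_FMT = "%Y%m%d"


def _date_str(d: _dt.date | None) -> str:
    return d.strftime(_FMT) if d is not None else ""


def write_faers_dialect(reports: ReportSet, directory: str | Path) -> dict[str, Path]:
    """Write a report set as "$"-delimited quarterly ASCII tables.

    Emits DEMO, DRUG, REAC, OUTC and THER files (one header row each, dates
    as YYYYMMDD) such that :func:`pvsignals.ingest.read_quarter` recovers an
    equivalent report set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    demo, drug, reac, outc, ther = [], [], [], [], []
    for r in reports:
        pid = r.record_id
        demo.append((pid, r.case_id, r.version_key, _date_str(r.event_date), r.country or ""))
        for seq, d in enumerate(r.drugs, start=1):
            drug.append((pid, r.case_id, seq, d.role, d.name))
            ther.append((pid, r.case_id, seq, _date_str(r.therapy_start)))
        for pt in r.events:
            reac.append((pid, r.case_id, pt))
        for code in sorted(r.outcomes):
            outc.append((pid, r.case_id, code))
    tables = {
        "DEMO": (demo, ["primaryid", "caseid", "caseversion", "event_dt", "occr_country"]),
        "DRUG": (drug, ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"]),
        "REAC": (reac, ["primaryid", "caseid", "pt"]),
        "OUTC": (outc, ["primaryid", "caseid", "outc_cod"]),
        "THER": (ther, ["primaryid", "caseid", "dsg_drug_seq", "start_dt"]),
    }
    paths: dict[str, Path] = {}
    for name, (rows, header) in tables.items():
        path = directory / f"{name}.txt"
        with open(path, "w") as fh:
            fh.write("$".join(header) + "\n")
            for row in rows:
                fh.write("$".join(str(v) for v in row) + "\n")
        paths[name] = path
    return paths
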