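# pvsignals

Disproportionality signal detection for spontaneous adverse-event reporting
databases, FAERS-style: from quarterly "$"-delimited report tables (or a
fully specified synthetic stand-in) to per-event 2×2 tables, the four
standard screening statistics, consensus signal tiers, System Organ Class
rollups, onset-time distributions and descriptive summaries.

It is written for pharmacovigilance analysts and methods researchers who
want the whole chain — ingestion, case deduplication, primary-suspect
selection, statistics, decisions — as tested, composable library functions
rather than a spreadsheet, and who need a ground-truth simulator to
validate a screening workflow before pointing it at real data.

## The statistics

For a focal drug and each MedDRA Preferred Term (PT), reports are collapsed
to a fourfold table (a, b, c, d; N = a+b+c+d) counting focal/background
reports with/without the event. Four algorithms are computed per PT:

| Method | Statistic | Signal threshold |
|--------|-----------|------------------|
| ROR    | ROR = ad/bc, 95% CI = exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | a > 3 and CI lower bound > 1 |
| MHRA   | PRR = [a/(a+b)]/[c/(c+d)]; Yates χ² = N(\|ad−bc\|−N/2)²/[(a+b)(c+d)(a+c)(b+d)] | a > 3, PRR > 2 and χ² > 4 |
| BCPNN  | shrunk information component E(IC), IC025 = E(IC) − 2·SD(IC) | IC025 > 0 |
| MGPS   | EBGM = aN/[(a+b)(a+c)] (unshrunk relative reporting ratio), log-normal lower bound EBGM05 | EBGM05 > 2 |

All thresholds are strict and configurable. A PT is a **positive** signal
when at least one algorithm fires and a **strong** signal when all four do;
the four-way consensus stands in for multiplicity control, as is standard
in disproportionality screening. Note the EBGM here is the observed/expected
ratio exactly as defined above — not the DuMouchel gamma-Poisson shrinkage
estimate. See `docs/methods.md` for formulas, priors and caveats.

## Worked example

Simulate a 10,000-report database in which 5% of reports name the focal
drug as primary suspect and three PTs carry injected signals, then scan it:

```python
import pvsignals as pv

cfg = pv.SimConfig(
    n_reports=10_000,
    focal_drug_fraction=0.05,
    injected_signals=[("Balance disorder", 10.0), ("Diplopia", 15.0), ("Aura", 40.0)],
    seed=42,
)
reports = pv.deduplicate(pv.generate_reports(cfg))
df = pv.signal_table(reports, meddra=pv.MeddraMap.toy())
top = pv.top_signals_table(df, n=5)
print(top[["pt", "soc", "case_reports", "ror", "ror_ci_low", "prr",
           "chi2", "ic025", "ebgm", "ebgm05"]].round(2).to_string(index=False))

focal = pv.select_drug_reports(reports)
s = pv.descriptive_summary(focal)
print("focal reports:", s.n_reports, "serious:", s.n_serious, f"({s.serious_percent}%)")
```

prints

```
              pt                      soc  case_reports   ror  ror_ci_low   prr   chi2  ic025  ebgm  ebgm05
        Diplopia            Eye disorders            27 16.59        9.86 15.77 195.32   2.12  9.01    5.35
            Aura Nervous system disorders            23 74.98       30.39 71.63 317.09   2.45 15.61    6.33
Balance disorder Nervous system disorders            23  9.53        5.74  9.14 107.07   1.69  6.47    3.90
focal reports: 508 serious: 140 (27.6%)
```

Exactly the three injected PTs reach the strong tier (every algorithm's
threshold cleared: e.g. Diplopia was co-reported on 27 focal reports, 16.6
times the odds of the background, with IC025 = 2.12 bits and EBGM05 = 5.35,
all far above their cut-offs), and none of the 30+ null background PTs do.
Of the 508 deduplicated focal reports, 140 (27.6%) carry a serious outcome
code, consistent with the configured serious fraction of 0.304.

The same pipeline runs from the shell against a directory of quarterly
files (`DEMO*.txt`, `DRUG*.txt`, `REAC*.txt`, `OUTC*.txt`, `THER*.txt`):

```bash
pvsignals simulate --seed 42 --out quarter/
pvsignals signals --quarter-dir quarter/ --drug XCOPRI --out results/
pvsignals report --quarter-dir quarter/
```

`results/` then contains `signals.csv` (one row per PT with all statistics
and per-algorithm flags), `top_signals.csv`, `soc.csv`, `onset.csv`,
`venn.json` (per-algorithm and intersection counts) and a machine-readable
`run_log.json` with the counts at every stage.

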