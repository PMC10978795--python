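# Methods

## Problem setting

Spontaneous-reporting databases (FAERS and its international peers) collect
voluntary reports of suspected adverse drug events. Because there is no
denominator of exposed patients, drug safety signals are screened by
*disproportionality*: for a focal drug and each adverse event (a MedDRA
Preferred Term, PT), the database is collapsed to a fourfold table

|              | event         | no event      |
|--------------|---------------|---------------|
| focal drug   | a             | b             |
| other drugs  | c             | d             |

with N = a + b + c + d, and one asks whether the event is reported with the
focal drug more often than the database background predicts. The counting
unit throughout is the *report*: a report contributes at most once to the
focal row and at most once to each event column, however many times a PT is
repeated on it. Pair counting (one unit per drug–event mention) is a known
alternative in the literature; `build_table` counts reports, and the
repeated-PT contract is tested explicitly.

## Statistics

Four established screening statistics are computed per PT
(`pvsignals.stats`):

* **ROR** (reporting odds ratio): `ROR = ad/bc`,
  `SE(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d)`,
  95% CI `exp(ln ROR ± 1.96 SE)`. Undefined (NaN) when any cell is zero,
  unless the optional Haldane–Anscombe correction (+0.5 to every cell) is
  enabled; the correction applies to ROR and EBGM only.
* **MHRA**: `PRR = [a/(a+b)] / [c/(c+d)]` plus the Yates
  continuity-corrected chi-squared
  `N (|ad − bc| − N/2)² / [(a+b)(c+d)(a+c)(b+d)]`, with the continuity term
  floored at zero. PRR is NaN when c = 0.
* **BCPNN**: the information component `IC = log2[aN / ((a+b)(a+c))]` under
  Dirichlet/Beta shrinkage. With prior counts γ₁₁ (joint cell), α₁, β₁
  (margins) and totals α, β, the joint prior count is calibrated from the
  margins, `γ = γ₁₁(N+α)(N+β) / [(a+b+α₁)(a+c+β₁)]`, making the prior IC
  expectation zero, and

  ```
  E(IC)  = log2[ (a+γ₁₁)(N+α)(N+β) / ((N+γ)(a+b+α₁)(a+c+β₁)) ]
  V(IC)  = (1/ln 2)² [ (N−a+γ−γ₁₁)/((a+γ₁₁)(1+N+γ))
                     + (N−(a+b)+α−α₁)/((a+b+α₁)(1+N+α))
                     + (N−(a+c)+β−β₁)/((a+c+β₁)(1+N+β)) ]
  IC025  = E(IC) − 2 sqrt(V(IC))
  ```

  Defaults γ₁₁ = α₁ = β₁ = 1, α = β = 2 are the classical BCPNN choice.
  V(IC) is the first-order (delta-method) posterior variance of the
  log-ratio of Beta means; `tests/test_acceptance.py` validates the closed
  form against direct Monte-Carlo sampling of the Beta posteriors
  (10⁶ draws per table, agreement within 0.05 bits on tables with a ≥ 20).
  At very small a the delta-method mean is biased upward by roughly
  `1/(2(a+γ₁₁) ln 2)` bits relative to the sampled posterior, which is why
  the sampling check is stated for a ≥ 20. The unshrunk IC is reported for
  reference but plays no role in decisions.
* **MGPS/EBGM**: here the *unshrunk* relative reporting ratio
  `EBGM = aN / ((a+b)(a+c))` with the same log-normal interval form as the
  ROR (lower bound EBGM05). This is deliberate: the output is the
  observed/expected ratio without the DuMouchel gamma-Poisson mixture fit,
  and the docstrings say so. Users needing true EM-fitted MGPS shrinkage
  should use a dedicated implementation (e.g. openEBGM).

### Decision rule

Strict thresholds, all configurable (`SignalCriteria`): ROR arm requires
a > 3 and CI lower bound > 1; MHRA arm a > 3, PRR > 2 and χ² > 4; BCPNN arm
IC025 > 0; MGPS arm EBGM05 > 2. "a > 3" means a ≥ 4; IC025 = 0 and
EBGM05 = 2 fail. NaN metrics fail their arm. A PT is a **positive** signal
when ≥ 1 arm fires and a **strong** signal when all four fire; the four-way
consensus is the false-positive control — no multiple-testing adjustment is
applied, matching standard disproportionality practice.

A caution on interpretation: the unshrunk EBGM (and E(IC)) is *not*
monotone in a with b, c, d fixed — the expected count grows with a through
both margins, so e.g. EBGM(1,1,1,6) > EBGM(2,1,1,6). ROR and PRR are
monotone unconditionally; the property test asserts the EBGM/IC version
only under the sufficient condition `b(a+1+c) ≥ (a+1)(a+1+b)` (verified by
brute force over 200,000 tables).

## Ingestion and deduplication

`read_quarter` parses the "$"-delimited quarterly dialect (DEMO spine;
DRUG/REAC/OUTC/THER satellites joined on `primaryid`). Policy choices:

* orphan satellite rows (no DEMO case) are dropped with a warning, as are
  DEMO rows with no reaction — real quarters contain both;
* unparseable dates become missing and exclude a report only from the
  onset-time analysis, never from signal detection;
* deduplication keeps, per `caseid`, the record with the highest
  `caseversion`, ties broken by the lexicographically larger `primaryid` —
  the standard "latest version wins" convention; the operation is
  idempotent;
* focal-drug selection matches drug names exactly after trimming and
  case-folding (default names XCOPRI/CENOBAMATE, default role PS =
  primary suspect); substring matching is an explicit opt-in flag because
  it admits false positives.

## Synthetic databases

`pvsignals.synthetic` generates databases with known ground truth (see the
module docstring for the generative model). Design points:

* **Marginal exactness.** Reports that draw zero events receive a catch-all
  filler PT rather than being redrawn: conditioning on "≥ 1 event" would
  inflate every per-PT rate by a drug-status-dependent factor and break the
  analytic cell expectations `E[a] = n·f·min(1, rate·ratio)`,
  `E[c] = n(1−f)·rate` that `expected_cells` documents and the tests use as
  an oracle. The filler PT is excluded from the background vocabulary and
  behaves like any other PT downstream.
* **Defaults.** 10,000 reports, focal fraction 0.05, ~35 background PTs at
  per-report rates 0.001–0.03 (the vocabulary of a neurology safety
  profile), serious fraction 0.304 with outcome weights and country weights
  proportional to published FAERS report margins for an antiseizure drug,
  onset days geometric with mean 30 (first-month clustering). These sizes
  keep a full pipeline run under half a second while giving expected focal
  cell counts (a ≈ 5–25) in the range where the decision thresholds are
  actually exercised.
* **Determinism.** One `numpy` PCG64 generator seeded from `SimConfig.seed`
  drives every draw; identical configs give bit-identical databases, and
  the pipeline writes byte-identical CSVs for identical inputs.
* **What is not modelled.** Drug co-prescription structure, duplicate
  submission patterns beyond version replication, reporting-rate drift over
  calendar time, PT co-occurrence correlations, and missingness mechanisms
  other than missing-completely-at-random dates. Passing tests therefore
  demonstrate correctness of the statistical machinery under independent
  Bernoulli reporting, not robustness to real FAERS artefacts
  (indication bias, stimulated reporting, duplicate clusters).

## Descriptive outputs

A report is *serious* when it carries ≥ 1 outcome code from a configurable
set (default: all of DE, LT, HO, DS, CA, RI, OT); the serious share is
reported as a percentage rounded to one decimal. Onset time is
`event_date − earliest therapy start`, bucketed into half-open 30-day
months (day 0 → bucket 1, day 30 → bucket 2); negative and missing onsets
are excluded and counted separately. Top-N signal tables keep strong-tier
PTs sorted by descending case count, ties by descending ROR then PT name.
Output CSVs round statistics to 2 decimals; full precision is kept
in-memory.

## SOC aggregation

Each PT maps to exactly one System Organ Class (primary-SOC convention), so
SOC counts partition PT counts. A toy map covering the synthetic vocabulary
ships with the package for tests and examples; real analyses must supply a
licensed MedDRA map as `pt,soc,soc_code` CSV. Unmapped PTs pool under
`UNMAPPED` with a warning.

## Problem sizes used in tests

Formula oracle: 1,000 random tables with cells in [0, 500] against exact
rational/30-digit symbolic arithmetic (12 significant digits). BCPNN
sampling oracle: 20 tables, 10⁶ posterior draws each. Null calibration:
100 databases of 10,000 reports, all reporting ratios 1 (strong-flag rate
≤ 1% of scanned PTs). Signal recovery: 5 injected PTs at reporting ratio
10 (E[a] = 25), 100 replicates (all five strong in ≥ 95). Round trip: 20
random configurations through the quarterly-file dialect. The acceptance
script repeats the calibration and recovery runs at 50 replicates.
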