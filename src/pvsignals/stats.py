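"""The four disproportionality statistics and tiered signal decisions.

Given a fourfold table (a, b, c, d; N = a+b+c+d) for one drug-event pair,
four established algorithms quantify reporting disproportionality:

* **ROR** — reporting odds ratio ``ad / bc`` with the log-normal 95% CI
  ``exp(ln ROR ± 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``.
* **MHRA** — proportional reporting ratio ``PRR = [a/(a+b)] / [c/(c+d)]``
  together with the Yates continuity-corrected chi-squared
  ``N (|ad - bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)]``.
* **BCPNN** — the information component ``IC = log2[aN / ((a+b)(a+c))]``
  shrunk under a Dirichlet/Beta prior; the decision statistic is
  ``IC025 = E(IC) - 2 * SD(IC)``.
* **MGPS (EBGM)** — here the relative reporting ratio
  ``EBGM = aN / ((a+b)(a+c))`` with the same log-normal interval form as the
  ROR.  This is the unshrunk observed/expected ratio, not the DuMouchel
  gamma-Poisson shrinkage estimate; output metadata says so.

A pair is a **positive** signal when at least one algorithm exceeds its
threshold and a **strong** signal when all four do — the four-way consensus
is the false-positive control in place of any multiplicity adjustment.
All thresholds are strict inequalities (``a > 3`` means ``a >= 4``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .tables import ContingencyTable

_LN2_SQ_INV = 1.0 / math.log(2.0) ** 2
_Z95 = 1.96


@dataclass(frozen=True)
class BcpnnPriors:
    """Dirichlet/Beta prior counts for the BCPNN shrinkage.

    Defaults are the classical choice (all pseudo-counts 1, totals 2) that
    makes the prior expectation of the IC zero for any table margins.
    """

    gamma11: float = 1.0  # prior count on the (drug, event) cell
    alpha1: float = 1.0   # prior count on the drug row margin
    beta1: float = 1.0    # prior count on the event column margin
    alpha: float = 2.0    # prior total for the row Beta
    beta: float = 2.0     # prior total for the column Beta

    def __post_init__(self) -> None:
        if min(self.gamma11, self.alpha1, self.beta1, self.alpha, self.beta) <= 0:
            raise ValueError("BCPNN prior counts must be strictly positive")
        if self.alpha < self.alpha1 or self.beta < self.beta1:
            raise ValueError("prior totals must be >= their first-component counts")


@dataclass(frozen=True)
class SignalMetrics:
    """All statistics and interval bounds for one drug-event pair.

    Undefined quantities (zero cells without continuity correction) are NaN;
    they fail every strict threshold downstream.
    """

    ror: float
    se_ln_ror: float
    ror_ci_low: float
    ror_ci_high: float
    prr: float
    chi2: float
    ic: float
    e_ic: float
    ic_sd: float
    ic025: float
    ebgm: float
    ebgm05: float
    ebgm95: float


@dataclass(frozen=True)
class SignalCriteria:
    """Detection thresholds; every comparison is a strict inequality."""

    min_a: int = 3          # case count: require a > min_a (ROR and MHRA arms)
    ror_lower_gt: float = 1.0
    prr_gt: float = 2.0
    chi2_gt: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0

    def __post_init__(self) -> None:
        for f in ("ror_lower_gt", "prr_gt", "chi2_gt", "ic025_gt", "ebgm05_gt"):
            if not math.isfinite(getattr(self, f)):
                raise ValueError(f"threshold {f} must be finite")


@dataclass(frozen=True)
class SignalDecision:
    """Per-algorithm flags and the consensus tier for one pair."""

    ror_pos: bool
    mhra_pos: bool
    bcpnn_pos: bool
    mgps_pos: bool

    @property
    def n_positive(self) -> int:
        return sum((self.ror_pos, self.mhra_pos, self.bcpnn_pos, self.mgps_pos))

    @property
    def tier(self) -> str:
        n = self.n_positive
        return "strong" if n == 4 else ("positive" if n >= 1 else "none")


def _corrected(table: ContingencyTable, continuity: bool) -> tuple[float, float, float, float]:
    a, b, c, d = table.cells()
    if continuity:
        return (a + 0.5, b + 0.5, c + 0.5, d + 0.5)
    return (float(a), float(b), float(c), float(d))


def ror(table: ContingencyTable, continuity: bool = False) -> tuple[float, float, tuple[float, float]]:
    """Reporting odds ratio, SE of its log, and the 95% CI.

    With any zero cell the statistic is undefined (NaN) unless ``continuity``
    adds the Haldane-Anscombe 0.5 to every cell.
    """
    a, b, c, d = _corrected(table, continuity)
    if min(a, b, c, d) == 0:
        nan = float("nan")
        return nan, nan, (nan, nan)
    r = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    half = _Z95 * se
    return r, se, (r * math.exp(-half), r * math.exp(half))


def prr_chi2(table: ContingencyTable) -> tuple[float, float]:
    """Proportional reporting ratio and Yates-corrected chi-squared.

    Requires both drug margins non-empty.  PRR is NaN when the background
    event count c is zero (the ratio has no finite value); the chi-squared
    continuity term ``|ad - bc| - N/2`` is floored at zero.
    """
    a, b, c, d = table.cells()
    if a + b == 0 or c + d == 0:
        raise ValueError("zero drug margin: need a+b > 0 and c+d > 0")
    prr = (a / (a + b)) / (c / (c + d)) if c > 0 else float("nan")
    n = table.n
    col1, col2 = a + c, b + d
    if col1 == 0 or col2 == 0:
        return prr, 0.0
    t = max(0.0, abs(a * d - b * c) - n / 2.0)
    chi2 = n * t * t / ((a + b) * (c + d) * col1 * col2)
    return prr, chi2


def bcpnn_ic(
    table: ContingencyTable, priors: BcpnnPriors = BcpnnPriors()
) -> tuple[float, float, float]:
    """Shrunk information component: E(IC), its posterior SD, and IC025.

    The posterior model places independent Beta distributions on the joint
    cell probability and the two margins, with the joint prior count
    ``gamma`` calibrated from the margins so that the prior IC expectation
    is zero::

        gamma = gamma11 (N+alpha)(N+beta) / [(a+b+alpha1)(a+c+beta1)]
        E(IC) = log2[ (a+gamma11)(N+alpha)(N+beta) /
                      ((N+gamma)(a+b+alpha1)(a+c+beta1)) ]

    The variance is the first-order (delta-method) posterior variance of the
    log-ratio; IC025 = E(IC) - 2 * sqrt(V(IC)).  Zero cells are allowed —
    the prior regularizes them.
    """
    a, b, c, _ = table.cells()
    n = table.n
    g11, a1, b1, al, be = priors.gamma11, priors.alpha1, priors.beta1, priors.alpha, priors.beta
    row = a + b + a1
    col = a + c + b1
    gamma = g11 * (n + al) * (n + be) / (row * col)
    e_ic = math.log2((a + g11) * (n + al) * (n + be) / ((n + gamma) * row * col))
    v = _LN2_SQ_INV * (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - (a + b) + al - a1) / (row * (1 + n + al))
        + (n - (a + c) + be - b1) / (col * (1 + n + be))
    )
    sd = math.sqrt(v)
    return e_ic, sd, e_ic - 2.0 * sd


def raw_ic(table: ContingencyTable) -> float:
    """Unshrunk information component log2[aN / ((a+b)(a+c))]; reference only."""
    a, b, c, _ = table.cells()
    if a == 0 or a + b == 0 or a + c == 0:
        return float("nan")
    return math.log2(a * table.n / ((a + b) * (a + c)))


def ebgm(table: ContingencyTable, continuity: bool = False) -> tuple[float, float, float]:
    """Relative reporting ratio aN/((a+b)(a+c)) and its log-normal 95% bounds.

    This is the printed, unshrunk form of the MGPS statistic (no gamma-Poisson
    shrinkage).  The interval uses the same SE as the ROR and is NaN for zero
    cells unless ``continuity`` is enabled.
    """
    ai, bi, ci, _ = table.cells()
    if ai + bi == 0 or ai + ci == 0:
        raise ValueError("zero margin: need a+b > 0 and a+c > 0")
    point = ai * table.n / ((ai + bi) * (ai + ci))
    a, b, c, d = _corrected(table, continuity)
    if min(a, b, c, d) == 0:
        nan = float("nan")
        return point, nan, nan
    if continuity:
        n = a + b + c + d
        point = a * n / ((a + b) * (a + c))
    half = _Z95 * math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return point, point * math.exp(-half), point * math.exp(half)


def compute_metrics(
    table: ContingencyTable,
    priors: BcpnnPriors = BcpnnPriors(),
    continuity: bool = False,
) -> SignalMetrics:
    """All four statistics for one table, full precision."""
    r, se, (lo, hi) = ror(table, continuity)
    prr, chi2 = prr_chi2(table)
    e_ic, sd, ic025 = bcpnn_ic(table, priors)
    eb, eb05, eb95 = ebgm(table, continuity)
    return SignalMetrics(
        ror=r, se_ln_ror=se, ror_ci_low=lo, ror_ci_high=hi,
        prr=prr, chi2=chi2,
        ic=raw_ic(table), e_ic=e_ic, ic_sd=sd, ic025=ic025,
        ebgm=eb, ebgm05=eb05, ebgm95=eb95,
    )


def evaluate_criteria(
    metrics: SignalMetrics, a: int, criteria: SignalCriteria = SignalCriteria()
) -> SignalDecision:
    """Apply the per-algorithm thresholds; NaN metrics fail their criterion."""
    enough = a > criteria.min_a
    return SignalDecision(
        ror_pos=bool(enough and metrics.ror_ci_low > criteria.ror_lower_gt),
        mhra_pos=bool(enough and metrics.prr > criteria.prr_gt and metrics.chi2 > criteria.chi2_gt),
        bcpnn_pos=bool(metrics.ic025 > criteria.ic025_gt),
        mgps_pos=bool(metrics.ebgm05 > criteria.ebgm05_gt),
    )


def venn_counts(decisions: dict[str, SignalDecision]) -> dict[str, int]:
    """Per-algorithm positive-PT counts and the four-way intersection."""
    out = {"ror": 0, "mhra": 0, "bcpnn": 0, "mgps": 0, "all_four": 0}
    for d in decisions.values():
        out["ror"] += d.ror_pos
        out["mhra"] += d.mhra_pos
        out["bcpnn"] += d.bcpnn_pos
        out["mgps"] += d.mgps_pos
        out["all_four"] += d.tier == "strong"
    return out
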