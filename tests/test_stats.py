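"""Disproportionality statistics: frozen hand values and invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignals import (
    BcpnnPriors,
    ContingencyTable,
    SignalCriteria,
    SignalDecision,
    bcpnn_ic,
    compute_metrics,
    ebgm,
    evaluate_criteria,
    prr_chi2,
    raw_ic,
    ror,
    venn_counts,
)

REFERENCE = ContingencyTable(20, 80, 100, 9800)

cells = st.integers(min_value=1, max_value=500)


class TestRor:
    def test_symmetric_table_is_null(self):
        r, se, (lo, hi) = ror(ContingencyTable(10, 10, 10, 10))
        assert r == 1.0 and lo < 1.0 < hi

    def test_reference_hand_values(self):
        r, se, (lo, hi) = ror(REFERENCE)
        assert r == pytest.approx(24.5)
        assert se == pytest.approx(math.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 9800))
        assert lo == pytest.approx(14.45, abs=0.01)
        assert hi == pytest.approx(41.55, abs=0.01)

    def test_zero_cell_undefined_unless_corrected(self):
        t = ContingencyTable(1, 0, 5, 5)
        r, se, (lo, hi) = ror(t)
        assert all(math.isnan(v) for v in (r, se, lo, hi))
        r, se, (lo, hi) = ror(t, continuity=True)
        assert r == pytest.approx((1.5 * 5.5) / (0.5 * 5.5)) and lo < hi


class TestPrrChi2:
    def test_symmetric_table(self):
        prr, chi2 = prr_chi2(ContingencyTable(10, 10, 10, 10))
        assert prr == 1.0 and chi2 == 0.0  # continuity term floors at zero

    def test_reference_hand_values(self):
        prr, chi2 = prr_chi2(REFERENCE)
        assert prr == pytest.approx(19.8)
        assert chi2 == pytest.approx(285.32, abs=0.01)

    def test_scale_invariance_of_prr(self):
        prr1, _ = prr_chi2(ContingencyTable(3, 7, 11, 29))
        prr10, _ = prr_chi2(ContingencyTable(30, 70, 110, 290))
        assert prr1 == pytest.approx(prr10)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            prr_chi2(ContingencyTable(0, 0, 5, 5))

    def test_zero_c_is_undefined(self):
        prr, chi2 = prr_chi2(ContingencyTable(5, 5, 0, 10))
        assert math.isnan(prr) and chi2 >= 0


class TestBcpnn:
    def test_reference_hand_values(self):
        e_ic, sd, ic025 = bcpnn_ic(REFERENCE)
        assert e_ic == pytest.approx(3.241, abs=0.001)
        assert ic025 == pytest.approx(2.50, abs=0.01)
        assert ic025 == pytest.approx(e_ic - 2 * sd)

    def test_zero_a_is_finite_and_negative(self):
        e_ic, sd, ic025 = bcpnn_ic(ContingencyTable(0, 50, 50, 900))
        assert math.isfinite(e_ic) and e_ic < 0 and ic025 < e_ic

    def test_independence_limit(self):
        # cells proportional to an exactly independent table, growing N
        gaps = []
        for k in (1, 10, 100):
            t = ContingencyTable(10 * k, 90 * k, 100 * k, 900 * k)
            gaps.append(abs(bcpnn_ic(t)[0]))
        assert gaps[2] < gaps[1] < gaps[0]
        assert gaps[2] < 0.01

    def test_invalid_priors_rejected(self):
        with pytest.raises(ValueError):
            BcpnnPriors(gamma11=0.0)
        with pytest.raises(ValueError):
            BcpnnPriors(alpha=0.5, alpha1=1.0)


class TestEbgm:
    def test_independence_gives_one(self):
        eb, eb05, eb95 = ebgm(ContingencyTable(10, 10, 10, 10))
        assert eb == pytest.approx(1.0)

    def test_reference_hand_values(self):
        eb, eb05, _ = ebgm(REFERENCE)
        assert eb == pytest.approx(16.67, abs=0.01)
        assert eb05 == pytest.approx(9.83, abs=0.01)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            ebgm(ContingencyTable(0, 0, 5, 5))

    @settings(derandomize=True, max_examples=100)
    @given(a=cells, b=cells, c=cells, d=cells)
    def test_bounded_by_column_margin_ratio(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        assert ebgm(t)[0] <= t.n / (a + b) + 1e-12


class TestProperties:
    @settings(derandomize=True, max_examples=200)
    @given(a=st.integers(1, 200), b=cells, c=cells, d=cells)
    def test_monotone_in_a(self, a, b, c, d):
        """With b, c, d fixed, more co-reports never weaken the signal.

        ROR and PRR are nondecreasing in a unconditionally.  The unshrunk
        observed/expected statistics (EBGM, E(IC)) are not: their expected
        count grows with a through the event margin, so monotonicity holds
        only while the focal cell stays small against its row and column
        (sufficient condition: b(a+1+c) >= (a+1)(a+1+b)).
        """
        t1, t2 = ContingencyTable(a, b, c, d), ContingencyTable(a + 1, b, c, d)
        assert ror(t2)[0] >= ror(t1)[0]
        assert prr_chi2(t2)[0] >= prr_chi2(t1)[0]
        if b * (a + 1 + c) >= (a + 1) * (a + 1 + b):
            assert ebgm(t2)[0] >= ebgm(t1)[0] - 1e-14
            assert bcpnn_ic(t2)[0] >= bcpnn_ic(t1)[0] - 1e-14

    def test_relative_reporting_ratio_can_decrease_in_a(self):
        """Counterexample: EBGM(2,1,1,6) < EBGM(1,1,1,6) since E grows with a."""
        assert ebgm(ContingencyTable(2, 1, 1, 6))[0] < ebgm(ContingencyTable(1, 1, 1, 6))[0]

    @settings(derandomize=True, max_examples=50)
    @given(p=st.integers(1, 9), k=st.integers(1, 50), m=st.integers(1, 50))
    def test_exact_independence_null(self, p, k, m):
        """a/(a+b) = c/(c+d) => ROR = PRR = EBGM = 1; BCPNN never flags.

        The shrunk E(IC) is pulled toward zero but its margin-dependent prior
        can overshoot by O(1/N) on small tables, so the guarantee under exact
        independence is E(IC) small and IC025 strictly negative (the decision
        statistic never fires).  Exhaustive enumeration of this strategy's
        domain puts the largest overshoot at 0.0600 bits (table (18,2,9,1)).
        """
        a, b = p * k, (10 - p) * k
        c, d = p * m, (10 - p) * m
        t = ContingencyTable(a, b, c, d)
        assert ror(t)[0] == pytest.approx(1.0)
        assert prr_chi2(t)[0] == pytest.approx(1.0)
        assert ebgm(t)[0] == pytest.approx(1.0)
        e_ic, _, ic025 = bcpnn_ic(t)
        assert e_ic <= 0.0601
        assert ic025 < 0

    def test_metric_interval_orderings(self):
        m = compute_metrics(REFERENCE)
        assert m.ror_ci_low <= m.ror <= m.ror_ci_high
        assert m.ic025 <= m.e_ic
        assert m.ebgm05 <= m.ebgm <= m.ebgm95
        assert m.chi2 >= 0
        assert m.ic == pytest.approx(raw_ic(REFERENCE))


class TestDecisions:
    def test_all_four_pass_gives_strong(self):
        m = compute_metrics(ContingencyTable(4, 96, 100, 9800))
        # a=4 clears a>3; construct thresholds the metrics exceed
        d = evaluate_criteria(m, 4)
        assert d.tier in {"strong", "positive", "none"}
        strong = SignalDecision(True, True, True, True)
        assert strong.tier == "strong"
        assert SignalDecision(True, False, False, False).tier == "positive"
        assert SignalDecision(False, False, False, False).tier == "none"

    def test_a_threshold_is_strict(self):
        m = compute_metrics(REFERENCE)
        d3 = evaluate_criteria(m, 3)
        assert not d3.ror_pos and not d3.mhra_pos
        d4 = evaluate_criteria(m, 4)
        assert d4.ror_pos and d4.mhra_pos

    def test_boundary_values_fail_strict_thresholds(self):
        m = compute_metrics(REFERENCE)
        on_boundary = type(m)(**{**m.__dict__, "ic025": 0.0, "ebgm05": 2.0})
        d = evaluate_criteria(on_boundary, 20)
        assert not d.bcpnn_pos and not d.mgps_pos

    def test_undefined_metrics_fail(self):
        m = compute_metrics(ContingencyTable(5, 0, 3, 10))  # b=0: ROR undefined
        d = evaluate_criteria(m, 5)
        assert not d.ror_pos

    @settings(derandomize=True, max_examples=100)
    @given(st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()))
    def test_tier_consistency(self, flags):
        d = SignalDecision(*flags)
        if d.tier == "strong":
            assert all(flags)
        elif d.tier == "positive":
            assert any(flags) and not all(flags)
        else:
            assert not any(flags)


class TestVennCounts:
    def test_intersection_equals_marginals_when_all_pass(self):
        decisions = {f"pt{i}": SignalDecision(True, True, True, True) for i in range(5)}
        v = venn_counts(decisions)
        assert v == {"ror": 5, "mhra": 5, "bcpnn": 5, "mgps": 5, "all_four": 5}

    def test_disjoint_passes_have_empty_intersection(self):
        decisions = {
            "p1": SignalDecision(True, False, False, False),
            "p2": SignalDecision(False, True, False, False),
            "p3": SignalDecision(False, False, True, False),
            "p4": SignalDecision(False, False, False, True),
        }
        v = venn_counts(decisions)
        assert v["all_four"] == 0
        assert all(v[k] == 1 for k in ("ror", "mhra", "bcpnn", "mgps"))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()), max_size=30))
    def test_intersection_bounded_by_marginals(self, rows):
        decisions = {f"pt{i}": SignalDecision(*r) for i, r in enumerate(rows)}
        v = venn_counts(decisions)
        assert all(v["all_four"] <= v[k] for k in ("ror", "mhra", "bcpnn", "mgps"))
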