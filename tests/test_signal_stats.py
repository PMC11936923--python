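"""Disproportionality statistics, thresholds, intersections, reconstruction."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.stats import chi2_contingency

from faersignal.contingency import ContingencyTable
from faersignal.signal_stats import (
    SignalThresholds,
    compare_drugs,
    compute_ebgm,
    compute_ic,
    compute_prr,
    compute_ror,
    evaluate_signal,
    intersect_positive,
    reconstruct_counts,
)

from conftest import make_records

positive_cells = st.tuples(
    st.integers(1, 500), st.integers(1, 500), st.integers(1, 500), st.integers(1, 2000)
)


class TestPointEstimates:
    def test_balanced_table_is_null(self):
        t = ContingencyTable(10, 10, 10, 10)
        ror, (lo, hi) = compute_ror(t)
        assert ror == 1.0
        assert lo * hi == pytest.approx(1.0)  # CI symmetric about 1 on log scale
        prr, chi2 = compute_prr(t)
        assert (prr, chi2) == (1.0, 0.0)
        ic, _ = compute_ic(t)
        assert ic == 0.0
        ebgm, _ = compute_ebgm(t)
        assert ebgm == 1.0

    def test_derived_fixture_values(self):
        # hand arithmetic on cells (10, 20, 30, 240), N = 300
        t = ContingencyTable(10, 20, 30, 240)
        ror, (lo, hi) = compute_ror(t)
        assert ror == pytest.approx(4.0)
        # CI frozen from exp(ln4 ± 1.96*sqrt(1/10+1/20+1/30+1/240))
        assert lo == pytest.approx(1.711875, rel=1e-5)
        assert hi == pytest.approx(9.346475, rel=1e-5)
        prr, chi2 = compute_prr(t)
        assert prr == pytest.approx(3.0)
        assert chi2 == pytest.approx(11.538, abs=0.001)
        ic, _ = compute_ic(t)
        assert ic == pytest.approx(math.log2(2.5))
        ebgm, _ = compute_ebgm(t)
        assert ebgm == pytest.approx(2.5)

    @settings(max_examples=100, deadline=None)
    @given(positive_cells)
    def test_chi2_matches_scipy(self, cells):
        t = ContingencyTable(*cells)
        _, chi2 = compute_prr(t)
        expected = chi2_contingency(
            np.array(cells).reshape(2, 2), correction=False
        ).statistic
        assert chi2 == pytest.approx(expected, rel=1e-10)

    @settings(max_examples=200, deadline=None)
    @given(positive_cells)
    def test_ic_is_log2_of_ebgm(self, cells):
        t = ContingencyTable(*cells)
        ic, _ = compute_ic(t)
        ebgm, _ = compute_ebgm(t)
        assert ic == math.log2(ebgm)

    @settings(max_examples=200, deadline=None)
    @given(positive_cells)
    def test_ror_exceeds_prr_iff_above_one(self, cells):
        t = ContingencyTable(*cells)
        ror, _ = compute_ror(t)
        prr, _ = compute_prr(t)
        if ror > 1:
            assert ror > prr
        elif ror < 1:
            assert ror < prr

    def test_ic_variance_modes(self):
        t = ContingencyTable(10, 20, 30, 240)
        ic, ic025_fixed = compute_ic(t, mode="fixed_offset")
        assert ic - ic025_fixed == pytest.approx(1.67)
        _, ic025_delta = compute_ic(t, mode="delta")
        v = (1 / math.log(2)) ** 2 * (1 / 10 - 1 / 30 + 1 / 40 - 1 / 300)
        assert ic025_delta == pytest.approx(ic - 2 * math.sqrt(v))


class TestZeroCells:
    def test_haldane_correction_applied_and_flagged(self):
        r = evaluate_signal(ContingencyTable(5, 10, 0, 100))
        assert r.zero_cell_corrected
        assert math.isfinite(r.ror) and math.isfinite(r.prr)

    def test_a_zero_not_computable(self):
        r = evaluate_signal(ContingencyTable(0, 10, 10, 100))
        assert not r.computable
        assert not any(r.flags.values())


class TestThresholds:
    def test_strong_signal_combined_positive(self):
        r = evaluate_signal(ContingencyTable(20, 80, 50, 2000))
        assert all(r.flags.values()) and r.combined

    def test_small_n_fails_frequentist_rules(self):
        # huge disproportionality but only 2 reports
        r = evaluate_signal(ContingencyTable(2, 5, 3, 5000))
        assert not r.flags["ror"] and not r.flags["prr"]

    def test_ror_only_positive_is_not_combined(self):
        # mirrors a large general-disorders style row: ROR slightly above 1
        # (ror ~= 1.43, CI low ~= 1.35, prr ~= 1.33 < 2)
        t = ContingencyTable(1354, 4337, 109150, 500000)
        r = evaluate_signal(t)
        assert r.flags["ror"]
        assert not r.combined

    def test_combined_monotone_in_thresholds(self):
        t = ContingencyTable(20, 80, 50, 2000)
        strict = evaluate_signal(t, SignalThresholds(ebgm05_min=50.0))
        loose = evaluate_signal(t, SignalThresholds(ebgm05_min=0.5))
        assert not strict.combined and loose.combined

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            SignalThresholds(prr_min=0)


class TestIntersection:
    def _results(self, tables):
        return [evaluate_signal(t, term=f"t{i}") for i, t in enumerate(tables)]

    def test_all_positive_intersection_is_full_set(self):
        results = self._results([ContingencyTable(20, 80, 50, 2000)] * 3)
        inter = intersect_positive(results)
        assert inter.fourway == frozenset({"t0", "t1", "t2"})

    def test_partial_positives_excluded_from_fourway(self):
        mixed = self._results(
            [ContingencyTable(20, 80, 50, 2000), ContingencyTable(1354, 4337, 109150, 500000)]
        )
        inter = intersect_positive(mixed)
        assert inter.fourway == frozenset({"t0"})
        assert inter.region_sizes[frozenset({"ror", "prr", "bcpnn", "mgps"})] == 1
        assert inter.region_sizes[frozenset({"ror"})] == 1

    def test_mixed_levels_rejected(self):
        a = evaluate_signal(ContingencyTable(5, 5, 5, 5), term="x", level="pt")
        b = evaluate_signal(ContingencyTable(5, 5, 5, 5), term="y", level="soc")
        with pytest.raises(ValueError):
            intersect_positive([a, b])


class TestCompareDrugs:
    def test_absent_term_reported_nr(self):
        records = make_records([("A", "p", 10), ("A", "q", 5), ("B", "q", 20)])
        table = compare_drugs(records, ["A", "B"], ["p"])
        row_b = table[(table["drug"] == "B")].iloc[0]
        assert row_b["n"] == 0 and row_b["ror"] == "NR"

    def test_identical_profiles_equal_ror(self):
        records = make_records(
            [("A", "p", 10), ("A", "q", 30), ("B", "p", 10), ("B", "q", 30), ("C", "p", 50), ("C", "r", 200)]
        )
        table = compare_drugs(records, ["A", "B"], ["p"]).set_index("drug")
        assert table.loc["A", "ror"] == pytest.approx(table.loc["B", "ror"])

    def test_consistent_with_compute_ror(self, toy_records):
        table = compare_drugs(toy_records, ["X", "Y"], ["p"]).set_index("drug")
        expected, _ = compute_ror(ContingencyTable(10, 20, 30, 240))
        assert table.loc["X", "ror"] == pytest.approx(expected)

    def test_needs_two_drugs(self, toy_records):
        with pytest.raises(ValueError):
            compare_drugs(toy_records, ["X"], ["p"])


class TestReconstructCounts:
    def test_round_trip_known_cells(self):
        t = ContingencyTable(10, 20, 30, 240)
        ror, _ = compute_ror(t)
        ebgm, _ = compute_ebgm(t)
        rebuilt, _ = reconstruct_counts(10, 30, ror, ebgm)
        assert rebuilt.c == pytest.approx(30, abs=1e-6)
        assert rebuilt.d == pytest.approx(240, abs=1e-6)

    @settings(max_examples=100, deadline=None)
    @given(positive_cells)
    def test_round_trip_random_tables(self, cells):
        from hypothesis import assume

        a_, b_, c_, d_ = (float(x) for x in cells)
        # near-null tables (ad ~ bc) make the linear solve ill-conditioned;
        # the exact null is a one-parameter family (tested separately)
        assume(a_ * d_ > 1.2 * b_ * c_ or b_ * c_ > 1.2 * a_ * d_)
        t = ContingencyTable(*cells)
        ror, _ = compute_ror(t)
        ebgm, _ = compute_ebgm(t)
        rebuilt, report = reconstruct_counts(t.a, t.a + t.b, ror, ebgm)
        assert rebuilt.c == pytest.approx(t.c, rel=1e-6, abs=1e-6)
        assert rebuilt.d == pytest.approx(t.d, rel=1e-6, abs=1e-6)
        _, chi2 = compute_prr(t)
        assert report["chi2"] == pytest.approx(chi2, rel=1e-6)

    def test_matches_independent_bisection(self):
        # solve the scale equation for d by bracketed bisection instead
        a, total, ror, ebgm = 2109.0, 5691.0, 29.56, 18.81
        b = total - a
        r = (a / b) / ror

        def scale_eq(d):
            c = r * d
            n = a + b + c + d
            return a * n / ((a + c) * (a + b)) - ebgm

        d_oracle = brentq(scale_eq, 1.0, 1e9)
        rebuilt, _ = reconstruct_counts(a, total, ror, ebgm)
        assert rebuilt.d == pytest.approx(d_oracle, rel=1e-9)
        assert rebuilt.c / rebuilt.d == pytest.approx(r, rel=1e-12)

    def test_null_signal_is_an_underdetermined_family(self):
        # ror = ebgm = 1 pins only the ratio c/d = a/b; any scale satisfies
        # both equations, so reconstruction reports the degeneracy
        t = ContingencyTable(10, 20, 30, 60)
        ror, _ = compute_ror(t)
        ebgm, _ = compute_ebgm(t)
        assert ror == pytest.approx(1.0) and ebgm == pytest.approx(1.0)
        with pytest.raises(ValueError, match="degenerate"):
            reconstruct_counts(10, 30, 1.0, 1.0)

    def test_inconsistent_statistics_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_counts(100, 200, 0.5, 50.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_counts(10, 5, 2.0, 2.0)
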