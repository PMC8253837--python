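"""Tumor-fraction estimator: expectation model, assignment, grid fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from otterliq.datatypes import SegmentSet
from otterliq.exceptions import ValidationError
from otterliq.otter import (
    CopyStateSet,
    OtterModel,
    TumorFractionGrid,
    build_expectation_matrix,
    estimate_tumor_fraction,
    expected_log2_ratio,
    filter_segments,
    segment_assignment,
    total_loss,
)
from otterliq.synthetic import TruthRecord, simulate_segments

from conftest import make_segment, make_segment_set


def naive_expected(t, c, floor=-8.0):
    """Direct evaluation of the expectation formula, written independently."""
    arg = (2 * (1 - t) + t * c) / 2
    return floor if arg <= 2**floor else math.log2(arg)


def naive_fit(segments, grid, states, floor=-8.0):
    """Triple-nested-loop reference implementation of the grid fit."""
    losses = []
    for t in grid:
        loss = 0.0
        for seg in segments:
            d = [(seg.log2_ratio - naive_expected(t, c, floor)) ** 2 for c in states]
            loss += min(d) * seg.n_bins
        losses.append(loss)
    i_hat = int(np.argmin(losses))
    return grid[i_hat], np.array(losses)


class TestExpectedLog2Ratio:
    def test_worked_example_single_gain_at_half_purity(self):
        # 4 copies at 50% purity: log2(3/2)
        assert round(expected_log2_ratio(0.5, 4), 2) == 0.58

    @pytest.mark.parametrize("t", [0.0, 0.01, 0.37, 0.73, 0.99, 1.0])
    def test_diploid_anchor_is_exactly_zero(self, t):
        assert expected_log2_ratio(t, 2) == 0.0

    def test_full_deletion_at_full_purity_is_floored(self):
        assert expected_log2_ratio(1.0, 0, floor=-8) == -8.0

    def test_tumor_fraction_out_of_domain_rejected(self):
        with pytest.raises(ValidationError):
            expected_log2_ratio(1.5, 2)
        with pytest.raises(ValidationError):
            expected_log2_ratio(-0.1, 2)

    @pytest.mark.parametrize("t", [0.05, 0.3, 0.8])
    @pytest.mark.parametrize("c", range(5))
    def test_matches_direct_formula(self, t, c):
        assert expected_log2_ratio(t, c) == pytest.approx(
            naive_expected(t, c), abs=1e-15
        )


class TestExpectationMatrix:
    def test_default_matrix_is_99_by_5(self):
        m = build_expectation_matrix()
        assert m.entries.shape == (99, 5)

    def test_diploid_column_identically_zero(self):
        m = build_expectation_matrix()
        c2 = list(m.states.values).index(2)
        assert np.all(m.entries[:, c2] == 0.0)

    def test_single_point_grid_matches_direct_evaluations(self):
        m = build_expectation_matrix(TumorFractionGrid([0.5]), CopyStateSet(range(5)))
        expected = [naive_expected(0.5, c) for c in range(5)]
        np.testing.assert_allclose(m.entries[0], expected, atol=1e-15)

    def test_entries_increase_with_copy_state(self):
        m = build_expectation_matrix()
        assert np.all(np.diff(m.entries, axis=1) > 0)

    def test_gain_entries_increase_and_loss_entries_decrease_with_t(self):
        m = build_expectation_matrix()
        states = list(m.states.values)
        for j, c in enumerate(states):
            col = m.entries[:, j]
            if c > 2:
                assert np.all(np.diff(col) > 0)
            elif c < 2:
                floored = col == m.floor
                assert np.all(np.diff(col[~floored]) < 0)


class TestGridAndStates:
    def test_grid_rejects_out_of_range_and_unordered(self):
        for bad in ([], [0.0, 0.5], [0.5, 1.0], [0.3, 0.2]):
            with pytest.raises(ValidationError):
                TumorFractionGrid(bad)

    def test_states_require_diploid_anchor_and_companion(self):
        with pytest.raises(ValidationError):
            CopyStateSet([0, 1, 3])
        with pytest.raises(ValidationError):
            CopyStateSet([2])


class TestSegmentAssignment:
    def test_exact_match_has_zero_error(self):
        states = CopyStateSet(range(5))
        t = 0.4
        row = [expected_log2_ratio(t, c) for c in states.values]
        seg = make_segment(row[3], n_bins=120)
        c_star, eps = segment_assignment(seg, t, row, states)
        assert (c_star, eps) == (3, 0.0)

    def test_equidistant_tie_goes_to_smaller_state(self):
        # CR exactly midway between the c=3 and c=4 expectations
        row = [-1.0, -0.5, 0.0, 0.5, 1.0]
        seg = make_segment(0.75, n_bins=100)
        c_star, eps = segment_assignment(seg, 0.5, row)
        assert c_star == 3
        assert eps == pytest.approx(0.0625 * 100)

    def test_weighted_error_matches_brute_force(self):
        t, l_i = 0.5, 100
        row = [expected_log2_ratio(t, c) for c in range(5)]
        seg = make_segment(0.2, n_bins=l_i)
        _, eps = segment_assignment(seg, t, row)
        brute = min((0.2 - e) ** 2 for e in row) * l_i
        assert eps == pytest.approx(brute, rel=1e-15)


class TestTotalLoss:
    def test_empty_set_has_zero_loss(self):
        assert total_loss(SegmentSet([]), 0.3, [expected_log2_ratio(0.3, c) for c in range(5)]) == 0.0

    def test_noiseless_segment_at_own_expectation_has_zero_loss(self):
        row = [expected_log2_ratio(0.25, c) for c in range(5)]
        s = SegmentSet([make_segment(row[4], n_bins=200)])
        assert total_loss(s, 0.25, row) == 0.0

    def test_matches_naive_per_segment_sum(self, rng):
        s = make_segment_set(rng.normal(0, 0.3, size=3))
        t = 0.42
        row = [expected_log2_ratio(t, c) for c in range(5)]
        expected = sum(
            min((seg.log2_ratio - e) ** 2 for e in row) * seg.n_bins for seg in s
        )
        assert total_loss(s, t, row) == pytest.approx(expected, rel=1e-12)


class TestFilterSegments:
    def test_min_bins_removal_is_strict_less_than(self):
        s = SegmentSet([make_segment(0.1, n_bins=b) for b in (50, 100, 250)])
        kept, n_filtered = filter_segments(s, min_bins=100, excluded_contigs=())
        assert [seg.n_bins for seg in kept] == [100, 250]
        assert n_filtered == 1

    @pytest.mark.parametrize("contig", ["chrX", "X", "chrY", "Y"])
    def test_sex_chromosomes_removed_alias_aware(self, contig):
        s = SegmentSet([make_segment(0.1, contig=contig), make_segment(0.1, contig="chr7")])
        kept, n_filtered = filter_segments(s)
        assert [seg.contig for seg in kept] == ["chr7"]
        assert n_filtered == 1

    def test_empty_input_is_identity(self):
        kept, n = filter_segments(SegmentSet([]))
        assert len(kept) == 0 and n == 0


class TestEstimateTumorFraction:
    def test_noiseless_multi_state_profile_recovers_truth(self):
        truth = TruthRecord(0.30, [(1, 150, "chr1"), (3, 150, "chr2"), (4, 150, "chr3")])
        s, _ = simulate_segments(truth)
        fit = estimate_tumor_fraction(s)
        assert fit.tumor_fraction == 0.30
        assert fit.loss_curve.min() == 0.0

    def test_all_diploid_profile_is_flat_and_flagged(self):
        s = make_segment_set([0.0, 0.0, 0.0])
        fit = estimate_tumor_fraction(s)
        assert np.all(fit.loss_curve == 0.0)
        assert "flat_loss" in fit.qc_flags
        assert fit.tumor_fraction == fit.grid.values[0]

    def test_empty_set_is_flagged_not_raised(self):
        fit = estimate_tumor_fraction(SegmentSet([]))
        assert "no_segments" in fit.qc_flags
        assert fit.tumor_fraction == fit.grid.values[0]

    def test_loss_at_estimate_is_curve_minimum(self, rng):
        s = make_segment_set(rng.normal(0, 0.4, size=8))
        fit = estimate_tumor_fraction(s)
        i = list(fit.grid.values).index(fit.tumor_fraction)
        assert fit.loss_curve[i] == fit.loss_curve.min()
        assert np.all(fit.loss_curve >= 0)

    def test_state_assignments_cover_used_segments(self):
        truth = TruthRecord(0.4, [(1, 150, "chr1"), (3, 150, "chr2"), (4, 150, "chr3")])
        s, _ = simulate_segments(truth)
        fit = estimate_tumor_fraction(s)
        assert list(fit.state_assignments) == [1, 3, 4]

    def test_agrees_with_naive_triple_loop(self, rng):
        grid = TumorFractionGrid.default()
        states = CopyStateSet(range(5))
        for _ in range(10):
            n = rng.integers(1, 21)
            s = SegmentSet(
                [
                    make_segment(x, n_bins=int(b), contig=f"chr{i + 1}")
                    for i, (x, b) in enumerate(
                        zip(rng.normal(0, 0.5, n), rng.integers(100, 500, n))
                    )
                ]
            )
            fit = estimate_tumor_fraction(s, grid, states)
            t_naive, loss_naive = naive_fit(s, grid.values, states.values)
            assert fit.tumor_fraction == t_naive
            np.testing.assert_allclose(fit.loss_curve, loss_naive, rtol=1e-12, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_loss_curve_invariant_under_segment_permutation(self, pyrand):
        n = pyrand.randint(2, 12)
        log2s = [min(max(pyrand.gauss(0, 0.4), -8.0), 3.0) for _ in range(n)]
        s = make_segment_set(log2s)
        perm = list(range(n))
        pyrand.shuffle(perm)
        s_perm = SegmentSet([s[i] for i in perm])
        f1, f2 = estimate_tumor_fraction(s), estimate_tumor_fraction(s_perm)
        assert f1.tumor_fraction == f2.tumor_fraction
        # reordering permutes the float summation order, so the curves
        # agree to rounding, not bitwise
        np.testing.assert_allclose(f1.loss_curve, f2.loss_curve, rtol=1e-12)

    def test_doubling_bin_counts_doubles_loss_and_keeps_estimate(self, rng):
        log2s = rng.normal(0, 0.4, size=6)
        s1 = make_segment_set(log2s, n_bins=150)
        s2 = make_segment_set(log2s, n_bins=300)
        f1, f2 = estimate_tumor_fraction(s1), estimate_tumor_fraction(s2)
        assert f1.tumor_fraction == f2.tumor_fraction
        np.testing.assert_allclose(f2.loss_curve, 2 * f1.loss_curve, rtol=1e-12)

    def test_single_gain_aliases_to_half_purity_and_is_flagged(self):
        # a lone c=3 segment at purity t is exactly fit by c=4 at t/2;
        # the tie resolves to the smaller fraction and is reported
        truth = TruthRecord(0.30, [(3, 200, "chr1")])
        s, _ = simulate_segments(truth)
        fit = estimate_tumor_fraction(s)
        assert fit.tumor_fraction == 0.15
        assert "tie_broken" in fit.qc_flags


class TestOtterModel:
    def test_fit_filters_then_estimates(self):
        truth = TruthRecord(0.25, [(1, 150, "chr1"), (3, 150, "chr2"), (4, 150, "chr3")])
        s, _ = simulate_segments(truth)
        segs = list(s) + [
            make_segment(0.9, n_bins=20, contig="chr5"),  # too short
            make_segment(0.9, n_bins=500, contig="chrX"),  # excluded contig
        ]
        fit = OtterModel(SegmentSet(segs)).fit()
        assert fit.tumor_fraction == 0.25
        assert fit.n_segments_used == 3
        assert fit.n_segments_filtered == 2

    def test_summary_reports_estimate(self):
        s = make_segment_set([0.1, -0.2, 0.3])
        fit = OtterModel(s, min_bins=1).fit()
        assert f"{fit.tumor_fraction:.4f}" in fit.summary()
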