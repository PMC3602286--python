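"""Scoring, reverse coding, and bound-based classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cesdimpute import (
    ITEM_COLUMNS,
    classify_hds,
    classify_partial,
    prevalence_bounds,
    reverse_code,
    round_half_up,
    score_total,
)
from cesdimpute.scale import HDS, NHDS, UNDETERMINED, item_totals, validate_items

from conftest import items_frame, random_partial_rows


def brute_force_status(row: np.ndarray, cutoff: float = 16.0) -> str:
    """Oracle: enumerate every completion of the missing items."""
    missing = np.isnan(row)
    observed_sum = np.nansum(row)
    k = int(missing.sum())
    totals = [
        observed_sum + sum(combo)
        for combo in itertools.product(range(4), repeat=k)
    ]
    if all(t >= cutoff for t in totals):
        return HDS
    if all(t < cutoff for t in totals):
        return NHDS
    return UNDETERMINED


class TestReverseCode:
    def test_involution_exhaustive(self):
        # one row per possible value, all four positive positions exercised
        rows = [[v] * 20 for v in range(4)]
        frame = items_frame(rows)
        twice = reverse_code(reverse_code(frame))
        pd.testing.assert_frame_equal(twice, frame)

    def test_positive_items_flipped_negative_untouched(self):
        frame = items_frame([[0, 2, 1, 0] * 5])
        coded = reverse_code(frame, positive_items=(4, 8, 12, 16))
        # position 4 held 0 -> 3; position 1 (negative) unchanged
        assert coded.loc[0, "item_04"] == 3
        assert coded.loc[0, "item_01"] == 0
        assert coded.loc[0, "item_02"] == 2

    def test_missing_cells_preserved(self):
        frame = items_frame([[None] + [1] * 19])
        coded = reverse_code(frame)
        assert np.isnan(coded.loc[0, "item_01"])

    def test_unknown_item_id_rejected(self):
        with pytest.raises(ValueError, match="unknown item"):
            reverse_code(items_frame([[1] * 20]), positive_items=(4, 8, 12, 21))


class TestScoreTotal:
    @pytest.mark.parametrize(
        "row,expected",
        [([0] * 20, 0), ([3] * 20, 60), ([1] * 10 + [2] * 10, 30)],
    )
    def test_known_totals(self, row, expected):
        assert score_total(items_frame([row])).iloc[0] == expected

    def test_missing_cell_rejected(self):
        with pytest.raises(ValueError, match="complete"):
            score_total(items_frame([[None] + [1] * 19]))

    @given(st.lists(st.integers(0, 3), min_size=20, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_monotone(self, row):
        base = score_total(items_frame([row])).iloc[0]
        shuffled = row[::-1]
        assert score_total(items_frame([shuffled])).iloc[0] == base
        bumped = list(row)
        if bumped[0] < 3:
            bumped[0] += 1
            assert score_total(items_frame([bumped])).iloc[0] == base + 1

    def test_out_of_range_value_rejected(self):
        with pytest.raises(ValueError, match="integers in"):
            validate_items(items_frame([[4] + [0] * 19]))


class TestClassify:
    @pytest.mark.parametrize(
        "score,expected", [(16, HDS), (15.99, NHDS), (0, NHDS), (60, HDS)]
    )
    def test_cutoff_boundary(self, score, expected):
        assert classify_hds(score) == expected

    @pytest.mark.parametrize(
        "observed,n_missing,expected",
        [
            (16, 4, HDS),          # minimum completion already >= 16
            (3, 4, NHDS),          # 3 + 12 = 15 < 16 under max completion
            (10, 4, UNDETERMINED), # completions span 10..22
        ],
    )
    def test_partial_bounds(self, observed, n_missing, expected):
        row = [None] * n_missing + [3] * (observed // 3) + [observed % 3]
        row += [0] * (20 - len(row))
        frame = items_frame([row])
        assert classify_partial(frame).iloc[0] == expected

    def test_agrees_with_complete_classification(self):
        rng = np.random.default_rng(5)
        frame = items_frame(rng.integers(0, 4, size=(50, 20)))
        partial = classify_partial(frame)
        direct = classify_hds(score_total(frame))
        assert (partial == direct).all()

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(99)
        frame = random_partial_rows(rng, 200, max_missing=5)
        fast = classify_partial(frame)
        for i in range(len(frame)):
            assert fast.iloc[i] == brute_force_status(frame.iloc[i].to_numpy())


class TestPrevalenceBounds:
    @pytest.mark.parametrize(
        "counts,low,high",
        [
            ((14, 12, 8), 41.2, 64.7),
            ((59, 116, 8), 32.2, 36.6),
        ],
    )
    def test_qualitative_study_counts(self, counts, low, high):
        b = prevalence_bounds(*counts)
        assert round_half_up(b.low_pct) == low
        assert round_half_up(b.high_pct) == high

    def test_no_undetermined_collapses(self):
        b = prevalence_bounds(7, 13, 0)
        assert b.low_pct == b.high_pct == 35.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            prevalence_bounds(0, 0, 0)

    def test_bounds_match_min_max_imputation(self):
        """Cross-module consistency: the lower bound equals prevalence under
        minimum imputation and the upper bound under maximum imputation."""
        from cesdimpute import impute_max, impute_min

        rng = np.random.default_rng(31)
        frame = random_partial_rows(rng, 300, max_missing=6)
        status = classify_partial(frame)
        b = prevalence_bounds(
            int((status == HDS).sum()),
            int((status == NHDS).sum()),
            int((status == UNDETERMINED).sum()),
        )
        prev_min = 100.0 * (item_totals(impute_min(frame)) >= 16).mean()
        prev_max = 100.0 * (item_totals(impute_max(frame)) >= 16).mean()
        assert b.low_pct == pytest.approx(prev_min)
        assert b.high_pct == pytest.approx(prev_max)
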