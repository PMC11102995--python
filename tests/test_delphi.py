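"""Delphi screening, panel coefficients and Kendall's W."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import friedmanchisquare

from dmindex.delphi import (
    DelphiScoreTable,
    ExpertProfile,
    authority_coefficient,
    kendall_w,
    positive_coefficient,
    screen_indicators,
)

from conftest import make_score_table


class TestScreening:
    def test_unanimous_high_scores_kept(self):
        report = screen_indicators(make_score_table(np.full((4, 2), 8.0)))
        assert report["keep"].all()
        assert (report["importance_cv"] == 0).all()

    def test_mean_exactly_seven_deleted(self):
        # strict inequality on the mean rule
        report = screen_indicators(make_score_table(np.full((4, 2), 7.0)))
        assert not report["keep"].any()

    def test_high_dispersion_deleted_on_both_rules(self):
        # scores {10,10,4,4}: mean 7, sample-SD CV ~ 0.495
        block = np.array([[10.0, 8.0], [10.0, 8.0], [4.0, 8.0], [4.0, 8.0]])
        report = screen_indicators(make_score_table(block))
        row = report.iloc[0]
        assert row["importance_mean"] == pytest.approx(7.0)
        assert row["importance_cv"] == pytest.approx(np.std([10, 10, 4, 4], ddof=1) / 7, abs=1e-12)
        assert not row["keep"]

    def test_failing_one_dimension_suffices(self):
        # importance strong, feasibility weak -> deleted
        table = make_score_table(np.full((4, 2), 9.0))
        scores = table.scores.copy()
        scores.loc[:, ("ind_0", "feasibility")] = 5.0
        report = screen_indicators(DelphiScoreTable(scores))
        assert not report["keep"].iloc[0]

    def test_statistics_use_nonmissing_scores(self):
        table = make_score_table(np.full((4, 2), 9.0))
        scores = table.scores.copy()
        scores.loc["expert_0", ("ind_0", "importance")] = np.nan
        report = screen_indicators(DelphiScoreTable(scores))
        assert report["keep"].all()

    def test_too_few_scores_is_error(self):
        table = make_score_table(np.full((2, 2), 9.0))
        scores = table.scores.copy()
        scores.loc["expert_0", ("ind_0", "importance")] = np.nan
        with pytest.raises(ValueError, match="non-missing"):
            screen_indicators(DelphiScoreTable(scores))

    @given(shift=st.floats(min_value=0.0, max_value=3.0))
    @settings(max_examples=25, deadline=None)
    def test_screening_monotone_in_level(self, shift):
        # raising every score (dispersion held) never moves keep -> delete
        base = np.array([[6.0, 8.0], [6.5, 8.0], [7.0, 8.0], [6.5, 8.0]])
        lo = screen_indicators(make_score_table(np.clip(base, 1, 10)))
        hi = screen_indicators(make_score_table(np.clip(base + shift, 1, 10)))
        assert hi["keep"].iloc[0] or not lo["keep"].iloc[0]


class TestPanelCoefficients:
    @pytest.mark.parametrize("distributed,returned,expected", [
        (20, 20, 100.0), (20, 19, 95.0), (10, 5, 50.0),
    ])
    def test_positive_coefficient(self, distributed, returned, expected):
        assert positive_coefficient(distributed, returned) == pytest.approx(expected)

    def test_positive_coefficient_scale_free(self):
        assert positive_coefficient(40, 38) == positive_coefficient(20, 19)

    def test_over_returned_is_error(self):
        with pytest.raises(ValueError):
            positive_coefficient(10, 11)

    @pytest.mark.parametrize("ca,cs,expected", [(1.0, 1.0, 1.0), (0.8, 0.9, 0.85), (0.0, 0.0, 0.0)])
    def test_authority_coefficient(self, ca, cs, expected):
        assert authority_coefficient(ExpertProfile(ca, cs)) == pytest.approx(expected)

    def test_out_of_range_profile_is_error(self):
        with pytest.raises(ValueError):
            ExpertProfile(1.2, 0.5)


class TestKendallW:
    def test_identical_rankings_give_one(self):
        res = kendall_w(make_score_table([[1, 2, 3, 4]] * 3), "importance")
        assert res.w == pytest.approx(1.0)

    def test_opposite_rankings_give_zero(self):
        res = kendall_w(make_score_table([[1, 2, 3], [3, 2, 1]]), "importance")
        assert res.w == pytest.approx(0.0)

    def test_hand_computed_example(self):
        # rank sums (4,5,9): S = 14, W = 12*14/(9*24)
        res = kendall_w(make_score_table([[1, 2, 3], [1, 2, 3], [2, 1, 3]]), "importance")
        assert res.w == pytest.approx(14 * 12 / (9 * 24))
        assert res.chi2 == pytest.approx(3 * 2 * res.w)
        assert res.df == 2

    def test_matches_friedman_chi_square(self):
        # tie-free block: chi2 = m(n-1)W equals scipy's Friedman statistic
        rng = np.random.default_rng(42)
        block = rng.permuted(np.tile(np.arange(1, 7, dtype=float), (5, 1)), axis=1)
        res = kendall_w(make_score_table(block), "importance")
        stat, _ = friedmanchisquare(*block.T)
        assert res.chi2 == pytest.approx(stat)

    def test_monotone_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        block = rng.uniform(1, 10, size=(4, 5))
        res = kendall_w(make_score_table(block), "importance")
        res2 = kendall_w(make_score_table(1 + 9 * ((block - 1) / 9) ** 2), "importance")
        assert res2.w == pytest.approx(res.w)

    def test_expert_with_missing_scores_dropped(self):
        table = make_score_table([[1, 2, 3], [1, 2, 3], [3, 2, 1]])
        scores = table.scores.copy()
        scores.loc["expert_2", ("ind_0", "importance")] = np.nan
        res = kendall_w(DelphiScoreTable(scores), "importance")
        assert res.w == pytest.approx(1.0)  # the two complete experts agree

    def test_all_constant_experts_is_error(self):
        with pytest.raises(ValueError, match="tie correction"):
            kendall_w(make_score_table(np.full((3, 4), 5.0)), "importance")

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_w_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        block = rng.integers(1, 11, size=(rng.integers(2, 6), rng.integers(3, 8))).astype(float)
        if all(len(np.unique(row)) == 1 for row in block):
            return
        res = kendall_w(make_score_table(block), "importance")
        assert -1e-12 <= res.w <= 1 + 1e-12


class TestTableValidation:
    def test_scores_outside_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[1, 10\]"):
            make_score_table([[0.5, 2], [3, 4]])

    def test_csv_roundtrip(self, tmp_path):
        table = make_score_table([[1, 2, 3], [4, 5, 6]])
        p = tmp_path / "scores.csv"
        table.to_csv(p)
        back = DelphiScoreTable.from_csv(p)
        pd.testing.assert_frame_equal(back.scores, table.scores, check_names=False)
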