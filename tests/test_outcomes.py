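"""Instrument scoring, paired statistics, and effect-size conventions."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as hst
from scipy import stats

from steptrain import (
    InvalidInputError,
    SurveyBattery,
    adherence_category,
    categorical_change_test,
    cohen_d_from_diffs,
    cohen_d_paired,
    cronbach_alpha,
    csa_positive,
    mms_anxiety_score,
    outcome_report,
    paired_t,
    pclc_score,
    percent_reduction,
    phi_effect,
    phq9_band,
    phq9_score,
    stigma_score,
)


class TestPhq9:
    def test_all_zero_items(self):
        s = phq9_score([0] * 9)
        assert (s.total, s.band, s.above_cutoff) == (0, "minimal", False)

    def test_moderate_total_above_cutoff(self):
        s = phq9_score([2, 2, 2, 2, 2, 1, 1, 1, 0])
        assert (s.total, s.band, s.above_cutoff) == (13, "moderate", True)

    def test_band_boundaries_exhaustive(self):
        expected = (
            {t: "minimal" for t in range(0, 5)}
            | {t: "mild" for t in range(5, 10)}
            | {t: "moderate" for t in range(10, 15)}
            | {t: "moderately-severe" for t in range(15, 20)}
            | {t: "severe" for t in range(20, 28)}
        )
        for total in range(28):
            assert phq9_band(total) == expected[total]

    def test_cutoff_boundary(self):
        nine = phq9_score([1] * 9)
        assert nine.total == 9 and nine.band == "mild" and not nine.above_cutoff
        ten = phq9_score([2, 1, 1, 1, 1, 1, 1, 1, 1])
        assert ten.above_cutoff

    @given(
        items=hst.lists(hst.integers(-5, 10), min_size=0, max_size=15).filter(
            lambda v: len(v) != 9 or any(x < 0 or x > 3 for x in v)
        )
    )
    def test_malformed_items_always_rejected(self, items):
        with pytest.raises(InvalidInputError):
            phq9_score(items)


class TestOtherInstruments:
    def test_pclc_floor_and_ceiling(self):
        lo = pclc_score([1] * 17)
        hi = pclc_score([5] * 17)
        assert (lo.total, lo.screen_positive) == (17, False)
        assert (hi.total, hi.screen_positive) == (85, True)

    def test_pclc_screen_threshold(self):
        s = pclc_score([2] * 13 + [1] * 4)  # total 30
        assert s.total == 30 and s.screen_positive

    def test_pclc_wrong_count_rejected(self):
        with pytest.raises(InvalidInputError):
            pclc_score([3] * 16)

    @pytest.mark.parametrize("total,elevated", [(0, False), (5, False), (6, True), (9, True)])
    def test_mms_anxiety_threshold(self, total, elevated):
        items = [1] * total + [0] * (9 - total)
        assert mms_anxiety_score(items).elevated is elevated

    @pytest.mark.parametrize("vas,expected", [(1, "low"), (2, "low"), (3, "low"), (4, "moderate/high")])
    def test_adherence_bins(self, vas, expected):
        assert adherence_category(vas) == expected

    def test_adherence_out_of_range(self):
        with pytest.raises(InvalidInputError):
            adherence_category(5)

    def test_stigma_and_csa(self):
        assert stigma_score([1, 1, 0, 0, 1, 0]) == 3
        assert csa_positive([0, 1]) and not csa_positive([0, 0])


class TestPairedT:
    def test_identical_vectors_give_zero(self):
        res = paired_t([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.t == 0.0 and res.df == 2 and not res.degenerate

    def test_constant_nonzero_differences_degenerate(self):
        res = paired_t([5.0, 6.0, 7.0], [4.0, 5.0, 6.0])
        assert res.degenerate and math.isinf(res.t)

    def test_textbook_hand_computation(self):
        pre = np.array([18.0, 12.0, 15.0, 10.0, 20.0])
        post = np.array([14.0, 11.0, 10.0, 9.0, 13.0])
        d = pre - post
        t_oracle = d.mean() / (d.std(ddof=1) / math.sqrt(5))
        res = paired_t(pre, post)
        assert res.t == pytest.approx(t_oracle, abs=1e-12)
        assert res.df == 4

    @given(
        data=hst.lists(
            hst.tuples(hst.floats(-50, 50), hst.floats(-50, 50)), min_size=3, max_size=12
        )
    )
    def test_agrees_with_formula_oracle(self, data):
        pre = np.array([a for a, _ in data])
        post = np.array([b for _, b in data])
        diffs = pre - post
        sd = diffs.std(ddof=1)
        if sd < 1e-9:
            return
        n = len(diffs)
        t_oracle = diffs.mean() * math.sqrt(n) / sd
        p_oracle = 2 * stats.t.sf(abs(t_oracle), n - 1)
        res = paired_t(pre, post)
        assert res.t == pytest.approx(t_oracle, abs=1e-10)
        assert res.p == pytest.approx(p_oracle, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            paired_t([1.0], [2.0])


class TestEffectSizes:
    @pytest.mark.parametrize(
        "t,n,digits,expected",
        [(4.16, 12, 1, 1.2), (2.71, 12, 2, 0.78), (3.48, 12, 1, 1.0), (0.0, 5, 2, 0.0)],
    )
    def test_paired_d_convention(self, t, n, digits, expected):
        assert round(cohen_d_paired(t, n), digits) == expected

    def test_d_sign_invariance(self):
        assert cohen_d_paired(-3.25, 12) == cohen_d_paired(3.25, 12)

    def test_secondary_convention_matches_t_over_sqrt_n(self, rng):
        pre = rng.normal(10, 3, size=10)
        post = pre - rng.normal(2, 1, size=10)
        res = paired_t(pre, post)
        assert abs(cohen_d_from_diffs(pre, post)) == pytest.approx(
            cohen_d_paired(res.t, 10), abs=1e-12
        )

    @pytest.mark.parametrize(
        "chi2,n,digits,expected", [(5.6, 12, 2, 0.68), (0.0, 12, 2, 0.0), (12.0, 12, 2, 1.0)]
    )
    def test_phi_from_chi_square(self, chi2, n, digits, expected):
        assert round(phi_effect(chi2, n), digits) == expected

    def test_phi_rejects_negative_chi2(self):
        with pytest.raises(InvalidInputError):
            phi_effect(-1.0, 10)

    @pytest.mark.parametrize(
        "pre,post,expected_pct", [(13.4, 8.6, 36), (10.0, 10.0, 0), (10.0, 5.0, 50)]
    )
    def test_percent_reduction(self, pre, post, expected_pct):
        assert round(percent_reduction(pre, post)) == expected_pct

    def test_percent_reduction_rejects_nonpositive_pre(self):
        with pytest.raises(InvalidInputError):
            percent_reduction(0.0, 1.0)


class TestCronbachAlpha:
    def test_worked_matrix_matches_formula_oracle(self):
        x = np.array([[2, 3, 2], [4, 4, 5], [1, 2, 2], [3, 3, 4]], dtype=float)
        k = 3
        oracle = k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / x.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(x) == pytest.approx(oracle, abs=1e-12)

    def test_perfectly_correlated_items_approach_one(self, rng):
        base = rng.normal(size=200)
        x = np.column_stack([base, base, base])
        assert cronbach_alpha(x) == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_near_zero_in_expectation(self, rng):
        alphas = [cronbach_alpha(rng.normal(size=(300, 9))) for _ in range(50)]
        assert abs(np.mean(alphas)) < 0.05

    def test_zero_total_variance_rejected(self):
        with pytest.raises(InvalidInputError):
            cronbach_alpha(np.ones((4, 3)))


class TestCategoricalChange:
    def test_concentrated_diagonal_table(self):
        pre = ["low"] * 4 + ["moderate/high"] * 6
        res = categorical_change_test(pre, pre)
        # Pearson chi2 of a perfectly associated 2x2 table equals n
        assert res.chi2 == pytest.approx(len(pre))
        assert res.phi == pytest.approx(1.0)

    def test_uniform_table_gives_zero(self):
        pre = ["low", "low", "moderate/high", "moderate/high"]
        post = ["low", "moderate/high", "low", "moderate/high"]
        res = categorical_change_test(pre, post)
        assert res.chi2 == pytest.approx(0.0)

    def test_reported_margins_reproduced(self):
        # 5 low / 7 high at baseline; 3 low / 9 high at posttraining
        pre = ["low"] * 5 + ["moderate/high"] * 7
        post = ["moderate/high"] * 2 + ["low"] * 3 + ["moderate/high"] * 7
        res = categorical_change_test(pre, post)
        assert res.table.sum(axis=1).tolist() == [5, 7]
        assert res.table.sum(axis=0).tolist() == [3, 9]
        assert res.n == 12
        assert 0.0 <= res.phi <= 1.0

    def test_empty_margin_flagged_as_zero(self):
        pre = ["moderate/high"] * 6
        res = categorical_change_test(pre, pre)
        assert res.chi2 == 0.0 and res.phi == 0.0

    def test_unpaired_input_rejected(self):
        with pytest.raises(InvalidInputError):
            categorical_change_test(["low"], [])


class TestOutcomeReport:
    def _battery(self, pid, period, phq_total, vas):
        items = [3] * (phq_total // 3) + ([phq_total % 3] if phq_total % 3 else [])
        items += [0] * (9 - len(items))
        return SurveyBattery(pid, period, tuple(items), vas)

    def test_severity_counts_sum_to_n_and_stats_cohere(self):
        pre = [self._battery(f"p{i}", "baseline", 10 + i, 3 if i < 5 else 4) for i in range(12)]
        post = [self._battery(f"p{i}", "posttraining", 5 + i, 4) for i in range(12)]
        rep = outcome_report(pre, post)
        assert sum(rep.severity_pre_counts.values()) == 12
        assert sum(rep.severity_post_counts.values()) == 12
        assert rep.percent_reduction == pytest.approx(
            100 * (rep.phq9_pre_mean - rep.phq9_post_mean) / rep.phq9_pre_mean
        )
        assert rep.cohen_d == pytest.approx(cohen_d_paired(rep.t, 12))
        assert 0.0 <= rep.phi <= 1.0

    def test_mismatched_cohorts_rejected(self):
        pre = [self._battery("p1", "baseline", 10, 3)]
        post = [self._battery("p2", "posttraining", 5, 4)]
        with pytest.raises(InvalidInputError):
            outcome_report(pre, post)

    def test_battery_validates_on_construction(self):
        with pytest.raises(InvalidInputError):
            SurveyBattery("p1", "baseline", (4, 0, 0, 0, 0, 0, 0, 0, 0), 3)
        with pytest.raises(InvalidInputError):
            SurveyBattery("p1", "baseline", (1,) * 9, 7)
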