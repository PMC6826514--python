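"""Transcript summaries, the REV estimator and group-level comparisons."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special, stats

from genefabric.expression_stats import (
    REVConfig,
    TranscriptSummary,
    coefficient_of_variation,
    compare_rev_distributions,
    fabric_summary,
    group_summary,
    redundancy_correction,
    regulation_call,
    rev,
    summarize_all,
    summarize_transcript,
)
from genefabric.synthetic import _c4
from tests.conftest import G1, G3, normalized_frame


def _summary(spot_values, condition="c1", tid="g"):
    frame = normalized_frame({tid: {f"{tid}_s{i}": v for i, v in enumerate(spot_values)}},
                             condition=condition)
    s = summarize_transcript(frame, condition)
    s.transcript_id = tid
    return s


class TestSummarize:
    def test_single_spot_mean_and_sample_sd(self):
        s = _summary([G3])
        assert s.combined_mean == pytest.approx(1.0)
        assert s.spot_sds[0] == pytest.approx(0.41633, abs=1e-4)

    def test_constant_spot_has_zero_sd(self):
        s = _summary([[2.0, 2.0, 2.0, 2.0]])
        assert s.spot_means[0] == 2.0
        assert s.spot_sds[0] == 0.0

    def test_combined_mean_is_mean_of_spot_means(self):
        s = _summary([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]])
        assert s.redundancy == 2
        assert s.combined_mean == pytest.approx(2.0)

    def test_single_replicate_spot_rejected(self):
        frame = normalized_frame({"g": [1.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            summarize_transcript(frame, "c1")


class TestCoefficientOfVariation:
    def test_worked_example_values_round_to_printed_cvs(self):
        assert round(coefficient_of_variation(G3)) == 42
        assert round(coefficient_of_variation(G1)) == 5

    def test_constant_vector_is_zero(self):
        assert coefficient_of_variation([3.0, 3.0, 3.0]) == 0.0

    def test_zero_mean_is_domain_error(self):
        with pytest.raises(ValueError, match="zero mean"):
            coefficient_of_variation([-1.0, 1.0])


def _chi2_ppf_oracle(q, df):
    """Brute-force chi-square quantile via root-finding on the regularized
    lower incomplete gamma function (independent of scipy.stats.chi2.ppf)."""
    return optimize.brentq(lambda x: special.gammainc(df / 2, x / 2) - q, 1e-12, 10 * df + 100)


class TestRedundancyCorrection:
    def test_sigma_ci_convention_matches_quantile_oracle(self):
        # C(1) = (sqrt(3/chi2_0.975) + sqrt(3/chi2_0.025)) / 2 with df = 3
        lo = _chi2_ppf_oracle(0.025, 3)
        hi = _chi2_ppf_oracle(0.975, 3)
        expected = 0.5 * (math.sqrt(3 / hi) + math.sqrt(3 / lo))
        assert redundancy_correction(1) == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("convention", ["sigma_ci", "variance_ci"])
    def test_monotone_non_increasing_and_positive(self, convention):
        cfg = REVConfig(quantile_convention=convention)
        values = [redundancy_correction(r, cfg) for r in range(1, 29)]
        assert all(v > 0 for v in values)
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_redundancy(self):
        with pytest.raises(ValueError):
            redundancy_correction(0)


class TestREV:
    def test_single_spot_collapses_to_correction_times_cv(self):
        s = _summary([G3])
        expected = redundancy_correction(1) * coefficient_of_variation(G3)
        assert rev(s) == pytest.approx(expected)

    def test_zero_spot_sds_give_zero_rev(self):
        s = _summary([[2.0] * 4, [5.0] * 4])
        assert rev(s) == 0.0

    def test_two_spot_pooling_is_root_mean_square_of_cvs(self):
        # spots with CVs 3% and 4% pool to sqrt((9+16)/2) ~ 3.536%
        s = TranscriptSummary(
            transcript_id="g",
            condition="c1",
            spot_means=np.array([1.0, 1.0]),
            spot_sds=np.array([0.03, 0.04]),
            redundancy=2,
            combined_mean=1.0,
        )
        expected = redundancy_correction(2) * math.sqrt(12.5)
        assert rev(s) == pytest.approx(expected, rel=1e-9)

    def test_zero_spot_mean_is_domain_error(self):
        s = TranscriptSummary("g", "c1", np.array([0.0]), np.array([0.1]), 1, 0.0)
        with pytest.raises(ValueError, match="zero"):
            rev(s)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_invariant_under_global_rescaling(self, scale):
        base = _summary([G3, G1])
        scaled = _summary([G3 * scale, G1 * scale])
        assert rev(scaled) == pytest.approx(rev(base), rel=1e-9)


class TestRegulationCall:
    def test_identical_summaries_are_no_change(self):
        a = _summary([G1], condition="stim")
        b = _summary([G1], condition="ctrl")
        call = regulation_call(a, b)
        assert call.fold_change == pytest.approx(1.0)
        assert call.status == "NC"
        assert "surrogate" in call.method

    def test_strong_clean_shift_is_called_up_and_matches_welch_oracle(self):
        rng = np.random.default_rng(5)
        ctrl_vals = rng.normal(1.0, 0.03, size=(2, 4))
        cond_vals = rng.normal(2.5, 0.075, size=(2, 4))
        a = _summary(cond_vals, condition="stim")
        b = _summary(ctrl_vals, condition="ctrl")
        call = regulation_call(a, b)
        assert call.status == "UP"
        assert call.fold_change == pytest.approx(2.5, rel=0.05)
        oracle = stats.ttest_ind(cond_vals.ravel(), ctrl_vals.ravel(), equal_var=False)
        assert call.p_value == pytest.approx(float(oracle.pvalue), rel=1e-12)
        assert call.corrected_p == pytest.approx(min(1.0, 2 * call.p_value))

    def test_small_shift_below_fold_threshold_is_nc(self):
        rng = np.random.default_rng(6)
        a = _summary(rng.normal(1.2, 0.03, size=(1, 4)), condition="stim")
        b = _summary(rng.normal(1.0, 0.03, size=(1, 4)), condition="ctrl")
        assert regulation_call(a, b).status == "NC"

    def test_downregulation_uses_negative_reciprocal_convention(self):
        a = _summary([[0.5, 0.49, 0.51, 0.5]], condition="stim", tid="g")
        b = _summary([[1.0, 0.99, 1.01, 1.0]], condition="ctrl", tid="g")
        call = regulation_call(a, b)
        assert call.fold_change == pytest.approx(-2.0, rel=0.02)
        assert call.status == "DOWN"

    def test_mismatched_transcripts_rejected(self):
        a = _summary([G1], tid="x")
        b = _summary([G1], tid="y")
        with pytest.raises(ValueError, match="different transcripts"):
            regulation_call(a, b)


class TestGroupSummary:
    def test_singleton_group(self):
        s = _summary([G3])
        s.rev = rev(s)
        avg_rev, med = group_summary([s])
        assert avg_rev == pytest.approx(s.rev)
        assert med == pytest.approx(s.combined_mean)

    def test_average_of_member_revs(self):
        summaries = []
        for i, r in enumerate((10.0, 20.0, 30.0)):
            s = _summary([G1], tid=f"g{i}")
            s.rev = r
            summaries.append(s)
        avg_rev, _ = group_summary(summaries)
        assert avg_rev == pytest.approx(20.0)

    def test_reference_median_normalizes_expression(self):
        s = _summary([[2.0, 2.1, 1.9, 2.0]])
        s.rev = 1.0
        _, med = group_summary([s], reference_median=2.0)
        assert med == pytest.approx(1.0, rel=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_summary([], group="CAS")

    def test_simulated_group_recovers_programmed_average_rev(self):
        # 93 genes at 15% replicate CV, mixed redundancy 1..3: the average
        # REV should land near mean(correction(R_g)) * 15
        rng = np.random.default_rng(42)
        n_genes, cv = 93, 15.0
        sigma = (cv / 100.0) / _c4(4)
        summaries = []
        expected = []
        for i in range(n_genes):
            r_g = 1 + i % 3
            spots = {
                f"g{i}_s{k}": rng.normal(1.0, sigma, 4) for k in range(r_g)
            }
            frame = normalized_frame({f"g{i}": spots})
            s = summarize_transcript(frame, "c1")
            s.transcript_id = f"g{i}"
            s.rev = rev(s)
            summaries.append(s)
            expected.append(redundancy_correction(r_g) * cv)
        avg_rev, _ = group_summary(summaries)
        assert avg_rev == pytest.approx(np.mean(expected), abs=3.0)


class TestCompareRevDistributions:
    def test_identical_lists_give_p_one(self):
        assert compare_rev_distributions([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_separated_lists_give_tiny_p(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [101.0, 102.0, 103.0, 104.0]
        assert compare_rev_distributions(a, b) < 1e-3

    def test_matches_independent_welch_implementation(self):
        from statsmodels.stats.weightstats import ttest_ind as sm_ttest

        rng = np.random.default_rng(9)
        a = rng.normal(10, 2, 30)
        b = rng.normal(11, 3, 25)
        _, p_sm, _ = sm_ttest(a, b, usevar="unequal")
        assert compare_rev_distributions(a, b) == pytest.approx(float(p_sm), abs=1e-10)

    def test_insufficient_entries_rejected(self):
        with pytest.raises(ValueError):
            compare_rev_distributions([1.0], [1.0, 2.0])


class TestFabricSummary:
    def test_means_over_all_unigenes_of_the_condition(self):
        summaries = []
        for i, (mu, r) in enumerate([(1.0, 10.0), (3.0, 30.0)]):
            s = _summary([[mu, mu, mu, mu]], tid=f"g{i}")
            s.rev = r
            summaries.append(s)
        fab = fabric_summary(summaries, "c1")
        assert fab.n_unigenes == 2
        assert fab.mean_expression == pytest.approx(2.0)
        assert fab.mean_rev == pytest.approx(20.0)

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError):
            fabric_summary([], "nope")


def test_summarize_all_fills_rev_for_every_transcript(normalized_builder):
    frame = normalized_builder({"ga": G1, "gb": G3})
    summaries = summarize_all(frame)
    assert set(summaries) == {("ga", "c1"), ("gb", "c1")}
    assert all(s.rev is not None and s.rev >= 0 for s in summaries.values())
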