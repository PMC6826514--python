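"""Pairwise Pearson coordination, significance thresholds and reversals."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize, special

from genefabric.coordination import (
    IND,
    NEG,
    POS,
    UNCLASSIFIED,
    ClassificationConfig,
    CorrelationRecord,
    classify_pair,
    coordination_profile,
    correlate_pairs,
    critical_rho,
    detect_reversals,
    enumerate_pairs,
    pair_count,
    pair_df,
    pair_key,
    pearson_rho,
    replicate_profiles,
    rho_p_value,
)
from tests.conftest import G1, G2, G3, normalized_frame


class TestPearsonRho:
    def test_worked_example_correlations(self):
        # same mean, same-order CVs, yet opposite coordination patterns
        assert pearson_rho(G1, G2) == pytest.approx(-0.985, abs=5e-4)
        assert pearson_rho(G2, G3) == pytest.approx(0.986, abs=5e-4)

    def test_perfect_positive_and_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_rho(x, x) == pytest.approx(1.0)
        assert pearson_rho(x, 10.0 - x) == pytest.approx(-1.0)

    def test_constant_profile_is_undefined(self):
        assert math.isnan(pearson_rho([1.0, 1.0, 1.0, 1.0], G1))

    def test_length_mismatch_and_short_profiles_rejected(self):
        with pytest.raises(ValueError):
            pearson_rho([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            pearson_rho([1, 2], [1, 2])


class TestPairDf:
    @pytest.mark.parametrize("redundancy,expected", [(1, 2), (2, 6), (3, 10)])
    def test_equal_redundancy_rule(self, redundancy, expected):
        assert pair_df(redundancy, redundancy) == expected

    def test_unequal_redundancy_defaults_to_min(self):
        assert pair_df(3, 1) == 2
        assert pair_df(2, 5) == 6

    def test_all_pairings_rule_overstates_df(self):
        assert pair_df(2, 3, rule="all_pairings") == 4 * 6 - 2
        assert pair_df(2, 3, rule="all_pairings") > pair_df(2, 3, rule="min")

    def test_invalid_redundancy_rejected(self):
        with pytest.raises(ValueError):
            pair_df(0, 1)


def _t_sf_oracle(t, df):
    # survival function of Student's t via the regularized incomplete beta,
    # bypassing scipy.stats.t
    x = df / (df + t * t)
    return 0.5 * special.betainc(df / 2.0, 0.5, x)


class TestCriticalRho:
    def test_printed_thresholds(self):
        assert round(critical_rho(2, 0.05), 2) == 0.95
        assert round(critical_rho(6, 0.05), 2) == 0.71

    @pytest.mark.parametrize("df", list(range(1, 121)))
    def test_matches_numeric_inversion_oracle(self, df):
        # brute-force: find |rho| with two-tailed p exactly 0.05
        def p_of_rho(r):
            t = r * math.sqrt(df / (1 - r * r))
            return 2 * _t_sf_oracle(t, df)

        oracle = optimize.brentq(lambda r: p_of_rho(r) - 0.05, 1e-9, 1 - 1e-12)
        assert critical_rho(df, 0.05) == pytest.approx(oracle, rel=1e-8)

    def test_decreasing_in_df_increasing_with_stringency(self):
        values = [critical_rho(df, 0.05) for df in range(1, 60)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert critical_rho(6, 0.01) > critical_rho(6, 0.05)

    def test_p_value_consistent_with_threshold(self):
        thr = critical_rho(6, 0.05)
        assert rho_p_value(thr, 6) == pytest.approx(0.05, rel=1e-9)


class TestClassifyPair:
    def test_examples_at_df2(self):
        assert classify_pair(0.99, 2) == POS
        assert classify_pair(-0.96, 2) == NEG
        assert classify_pair(0.30, 2) == UNCLASSIFIED
        assert classify_pair(0.01, 2) == IND

    def test_undefined_rho_is_unclassified(self):
        assert classify_pair(float("nan"), 2) == UNCLASSIFIED

    @given(rho=st.floats(min_value=-1.0, max_value=1.0), df=st.integers(1, 120))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_negation_swaps_pos_neg_and_fixes_the_rest(self, rho, df):
        a = classify_pair(rho, df)
        b = classify_pair(-rho, df)
        swap = {POS: NEG, NEG: POS, IND: IND, UNCLASSIFIED: UNCLASSIFIED}
        assert b == swap[a]


class TestEnumeratePairs:
    @pytest.mark.parametrize(
        "n,expected",
        [(13974, 97629351), (93, 4278), (934, 435711), (41, 820), (3, 3)],
    )
    def test_within_set_counts(self, n, expected):
        assert pair_count(n) == expected

    def test_cross_set_count(self):
        assert pair_count(93, 934) == 86862

    def test_iterator_matches_brute_force_on_small_sets(self):
        genes = [f"g{i}" for i in range(7)]
        it, count = enumerate_pairs(genes)
        pairs = set(it)
        brute = set(itertools.combinations(genes, 2))
        assert pairs == brute and count == len(brute) == 21

    def test_cross_iterator_and_overlap_rejection(self):
        it, count = enumerate_pairs(["a", "b"], ["x", "y", "z"])
        assert count == 6 and len(list(it)) == 6
        with pytest.raises(ValueError, match="overlap"):
            enumerate_pairs(["a", "b"], ["b", "c"])

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pairs([])


class TestCoordinationProfile:
    def test_all_unclassified_gives_zero_percentages(self):
        recs = [
            CorrelationRecord("a", "b", "c1", 0.3, 2, 0.7, UNCLASSIFIED)
            for _ in range(5)
        ]
        assert coordination_profile(recs) == {POS: 0.0, NEG: 0.0, IND: 0.0}

    def test_percentages_of_total_pairs(self):
        classes = [POS] * 4 + [NEG] + [IND] * 2 + [UNCLASSIFIED] * 3
        recs = [
            CorrelationRecord(f"a{i}", f"b{i}", "c1", 0.0, 2, 1.0, cls)
            for i, cls in enumerate(classes)
        ]
        prof = coordination_profile(recs)
        assert prof == {POS: 40.0, NEG: 10.0, IND: 20.0}
        assert sum(prof.values()) <= 100.0


def _rec(a, b, rho, cls, cond):
    return CorrelationRecord(a, b, cond, rho, 6, rho_p_value(rho, 6), cls)


class TestDetectReversals:
    def test_sign_flip_reported_with_both_rhos(self):
        # mimics a reported reversal: strongly positive in one condition,
        # strongly negative in the other (df = 6, threshold 0.71)
        a = [_rec("Adcy8", "Calm2", 0.93590, POS, "A")]
        b = [_rec("Adcy8", "Calm2", -0.90817, NEG, "B")]
        out = detect_reversals(a, b)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.gene_a, row.gene_b) == ("Adcy8", "Calm2")
        assert row.rho_a == pytest.approx(0.93590)
        assert row.rho_b == pytest.approx(-0.90817)

    def test_same_sign_and_nonsignificant_partners_not_reported(self):
        a = [_rec("x", "y", 0.95, POS, "A"), _rec("x", "z", 0.95, POS, "A")]
        b = [_rec("x", "y", 0.90, POS, "B"), _rec("x", "z", 0.30, UNCLASSIFIED, "B")]
        assert detect_reversals(a, b).empty

    def test_symmetric_up_to_sign_bookkeeping(self):
        a = [_rec("x", "y", 0.95, POS, "A")]
        b = [_rec("y", "x", -0.95, NEG, "B")]
        ab = detect_reversals(a, b)
        ba = detect_reversals(b, a)
        assert len(ab) == len(ba) == 1
        assert ab.iloc[0].rho_a == ba.iloc[0].rho_b


class TestCorrelatePairs:
    def test_record_count_equals_enumeration_and_no_silent_drops(self):
        frame = normalized_frame(
            {"ga": G1, "gb": G2, "gc": G3, "gd": [1.0, 1.0, 1.0, 1.0]}
        )
        prof, red = replicate_profiles(frame, "c1", use_log2=False)
        genes = sorted(prof.index)
        pairs, count = enumerate_pairs(genes)
        recs = correlate_pairs(prof, red, pairs, "c1")
        assert len(recs) == count == 6
        # the constant gene yields UNCLASSIFIED, not a dropped record
        constant = [r for r in recs if "gd" in (r.gene_a, r.gene_b)]
        assert constant and all(r.classification == UNCLASSIFIED for r in constant)
        assert all(math.isnan(r.rho) for r in constant)

    def test_df_follows_min_redundancy_of_profiles(self):
        frame = normalized_frame(
            {
                "ga": {"ga_s1": G1, "ga_s2": G1 * 1.01},
                "gb": {"gb_s1": G2},
            }
        )
        prof, red = replicate_profiles(frame, "c1", use_log2=False)
        recs = correlate_pairs(prof, red, [("ga", "gb")], "c1")
        assert recs[0].df == 2  # min(2, 1) spots x 4 replicates - 2

    def test_missing_gene_yields_unclassified_record(self):
        frame = normalized_frame({"ga": G1})
        prof, red = replicate_profiles(frame, "c1", use_log2=False)
        recs = correlate_pairs(prof, red, [("ga", "ghost")], "c1")
        assert recs[0].classification == UNCLASSIFIED


def test_pair_key_is_canonical_and_rejects_self_pairs():
    assert pair_key("b", "a") == pair_key("a", "b") == ("a", "b")
    with pytest.raises(ValueError):
        pair_key("a", "a")
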