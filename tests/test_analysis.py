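"""Normal-range thresholds, nonparametric comparisons, profile matching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import stpscore as st

from oracles import mwu_exact_p, wilcoxon_exact_p


class TestNormalThreshold:
    def test_zero_variance_reference(self):
        t = st.normal_threshold([0, 0, 0, 0])
        assert t.upper == 0.0 and t.ref_sd == 0.0

    def test_closed_form_mean_sd_upper(self):
        t = st.normal_threshold([-6, -8, -7, -9])
        assert t.ref_mean == pytest.approx(-7.5)
        assert t.ref_sd == pytest.approx((5 / 3) ** 0.5, abs=1e-12)
        assert t.upper == pytest.approx(-7.5 + 2 * (5 / 3) ** 0.5, abs=1e-12)
        assert t.upper - t.ref_mean == pytest.approx(2 * t.ref_sd)
        assert t.n_ref == 4

    def test_zero_k_sd_returns_mean(self):
        t = st.normal_threshold([1.0, 3.0, 2.0], k_sd=0.0)
        assert t.upper == pytest.approx(t.ref_mean)

    def test_single_score_rejected(self):
        with pytest.raises(st.AnalysisError):
            st.normal_threshold([1.0])


class TestClassifyAbnormal:
    def _thr(self, upper, pathway="P"):
        return {pathway: st.ReferenceThreshold(pathway, upper - 2, 1.0, upper, 4)}

    def test_strictly_above_is_abnormal_at_threshold_is_normal(self):
        thr = self._thr(0.0)
        assert st.classify_abnormal({"P": 1e-9}, thr)["P"] == "abnormal_high"
        assert st.classify_abnormal({"P": 0.0}, thr)["P"] == "normal"
        assert st.classify_abnormal({"P": -5.0}, thr)["P"] == "normal"

    def test_missing_threshold_is_an_error(self):
        with pytest.raises(st.AnalysisError):
            st.classify_abnormal({"Q": 0.0}, self._thr(0.0))

    @given(
        hst.floats(-20, 20),
        hst.floats(-20, 20),
        hst.floats(0, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_score(self, score, upper, bump):
        thr = self._thr(upper)
        before = st.classify_abnormal({"P": score}, thr)["P"]
        after = st.classify_abnormal({"P": score + bump}, thr)["P"]
        if before == "abnormal_high":
            assert after == "abnormal_high"


class TestMannWhitney:
    def test_complete_separation_one_sided(self):
        r = st.mann_whitney([1, 2, 3], [4, 5, 6], alternative="less")
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(1 / 20, abs=1e-12)
        assert r.method == "mann_whitney_exact"

    def test_identical_groups_give_p_near_one(self):
        r = st.mann_whitney([1, 2, 3], [1, 2, 3])
        assert r.ties_present
        assert r.p_value >= 0.99

    def test_empty_group_rejected(self):
        with pytest.raises(st.AnalysisError):
            st.mann_whitney([], [1.0])

    def test_u_statistic_within_range(self):
        r = st.mann_whitney([5, 1, 3], [2, 4, 6, 8])
        assert 0 <= r.statistic <= r.n1 * r.n2

    @given(
        hst.lists(hst.integers(0, 10_000), min_size=1, max_size=5),
        hst.lists(hst.integers(0, 10_000), min_size=1, max_size=5),
        hst.sampled_from(["two_sided", "less", "greater"]),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_exact_p_matches_full_enumeration(self, a, b, alternative):
        pooled = a + b
        if len(set(pooled)) != len(pooled):  # oracle contract: no ties
            return
        r = st.mann_whitney(a, b, alternative=alternative)
        assert r.method == "mann_whitney_exact"
        assert r.p_value == pytest.approx(
            mwu_exact_p(a, b, alternative), abs=1e-12
        )

    def test_large_or_tied_inputs_fall_back_to_normal_approximation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 15).tolist()
        b = rng.normal(1, 1, 15).tolist()
        r = st.mann_whitney(a, b)
        assert r.method == "mann_whitney_normal_approx"
        assert 0 <= r.p_value <= 1


class TestWilcoxonPaired:
    def test_all_zero_differences_degenerate(self):
        r = st.wilcoxon_paired([1, 2, 3], [1, 2, 3])
        assert r.p_value == 1.0

    def test_all_positive_differences_one_sided(self):
        x = [11, 12, 13, 14, 15, 16]
        y = [10, 10, 10, 10, 10, 10]
        r = st.wilcoxon_paired(x, y, alternative="greater")
        assert r.p_value == pytest.approx(1 / 64, abs=1e-12)

    def test_mixed_signs_match_sign_pattern_enumeration(self):
        d = [-1, 2, 3, 4, 5, 6]
        r = st.wilcoxon_paired(d, [0] * 6)
        assert r.p_value == pytest.approx(
            wilcoxon_exact_p(d, "two_sided"), abs=1e-12
        )

    @given(
        hst.lists(
            hst.integers(-10_000, 10_000).filter(lambda v: v != 0),
            min_size=1,
            max_size=10,
            unique_by=abs,
        ),
        hst.sampled_from(["two_sided", "less", "greater"]),
    )
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_exact_p_matches_enumeration(self, diffs, alternative):
        r = st.wilcoxon_paired(diffs, [0] * len(diffs), alternative=alternative)
        assert r.p_value == pytest.approx(
            wilcoxon_exact_p(diffs, alternative), abs=1e-12
        )

    def test_unequal_lengths_rejected(self):
        with pytest.raises(st.AnalysisError):
            st.wilcoxon_paired([1, 2], [1])


class TestPearson:
    def test_perfect_linear_and_anticorrelated(self):
        x = [1.0, 2.0, 3.0, 4.0]
        assert st.pearson(x, [2 * v + 1 for v in x]).statistic == pytest.approx(1.0)
        assert st.pearson(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_closed_form_four_points(self):
        r = st.pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert r.statistic == pytest.approx(0.6)
        assert 0 <= r.p_value <= 1

    def test_zero_variance_rejected(self):
        with pytest.raises(st.AnalysisError):
            st.pearson([1, 1, 1], [1, 2, 3])


class TestMatchProfile:
    def test_self_match_ranks_first_with_similarity_one(self):
        refs = {
            "A": {"P1": 1.0, "P2": 5.0, "P3": -2.0},
            "B": {"P1": -1.0, "P2": 0.0, "P3": 4.0},
            "C": {"P1": 3.0, "P2": -5.0, "P3": 1.0},
        }
        m = st.match_profile(dict(refs["B"]), refs, sample_id="s")
        assert m.reference_label == "B"
        assert m.similarity == pytest.approx(1.0)
        assert m.ranking[0][0] == "B"

    def test_disjoint_pathway_sets_rejected(self):
        with pytest.raises(st.AnalysisError):
            st.match_profile({"X": 1.0}, {"A": {"P1": 0.0, "P2": 1.0}})

    def test_planted_itreg_sample_matches_itreg_reference(self, preset_scores):
        table, labels = preset_scores
        ref_labels = ["resting", "activated", "iTreg"]
        refs = {
            l: table.loc[labels[labels == l].index].mean(axis=0).to_dict()
            for l in ref_labels
        }
        itreg_samples = labels[labels == "iTreg"].index
        for sid in itreg_samples:
            m = st.match_profile(table.loc[sid].to_dict(), refs, sample_id=sid)
            assert m.reference_label == "iTreg"

    def test_raw_scores_never_pooled_across_pathways(self):
        # a pathway with a huge offset must not dominate the similarity:
        # standardisation makes the match invariant to per-pathway shifts
        refs = {
            "A": {"P1": 1.0, "P2": 2.0, "P3": 0.0},
            "B": {"P1": -1.0, "P2": 1.0, "P3": 2.0},
        }
        shifted = {
            l: {"P1": v["P1"] + 1000, "P2": v["P2"], "P3": v["P3"]}
            for l, v in refs.items()
        }
        prof = {"P1": 0.5, "P2": 1.9, "P3": 0.2}
        prof_shifted = {"P1": 1000.5, "P2": 1.9, "P3": 0.2}
        m1 = st.match_profile(prof, refs, sample_id="s")
        m2 = st.match_profile(prof_shifted, shifted, sample_id="s")
        assert m1.reference_label == m2.reference_label
        assert m1.similarity == pytest.approx(m2.similarity, abs=1e-9)
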