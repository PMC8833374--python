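"""Calibration, frozen-model scoring, and the FOXO->PI3K inverse inference."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import stpscore as st
from stpscore.model import GeneParams, LOG2_ODDS_CLAMP

from conftest import make_two_class_matrix
from oracles import enum_posterior


def make_model(n_genes, p_act=2 / 3, p_inact=1 / 3, prior=0.5, direction="up"):
    params = {
        f"g{i}": GeneParams(direction, 5.0, p_act, p_inact) for i in range(n_genes)
    }
    return st.FrozenPathwayModel("P", prior, params)


class TestCalibration:
    def test_separable_gene_gets_median_cutoff_and_laplace_cpts(self):
        train, labels = make_two_class_matrix([8, 8, 8, 8], [2, 2, 2, 2])
        gs = st.make_gene_set("P", up=["g1"])
        m = st.calibrate_model(train, labels, gs, pseudocount=1.0)
        gp = m.gene_params["g1"]
        assert gp.cutoff == 5.0
        assert gp.p_high_given_active == pytest.approx(5 / 6)
        assert gp.p_high_given_inactive == pytest.approx(1 / 6)
        assert m.frozen

    def test_identical_class_distributions_are_uninformative(self):
        train, labels = make_two_class_matrix([1, 2, 3, 4], [1, 2, 3, 4])
        gs = st.make_gene_set("P", up=["g1"])
        m = st.calibrate_model(train, labels, gs)
        gp = m.gene_params["g1"]
        assert gp.p_high_given_active == gp.p_high_given_inactive
        score = st.score_sample(m, {"g1": 10.0}, "s")
        assert score.log2_odds == pytest.approx(0.0)  # prior odds 1

    def test_empty_label_class_is_an_error(self):
        train, labels = make_two_class_matrix([8, 8, 7, 9], [2, 3, 2, 4])
        labels = {s: "active" for s in labels}
        gs = st.make_gene_set("P", up=["g1"])
        with pytest.raises(st.CalibrationError):
            st.calibrate_model(train, labels, gs)

    def test_constant_gene_dropped_missing_gene_dropped(self, caplog):
        values = pd.DataFrame(
            {
                "a1": [5.0, 8.0], "a2": [5.0, 7.5],
                "i1": [5.0, 2.0], "i2": [5.0, 2.5],
            },
            index=["flat", "ok"],
        )
        train = st.ExpressionMatrix(values=values)
        labels = {"a1": "active", "a2": "active", "i1": "inactive", "i2": "inactive"}
        gs = st.make_gene_set("P", up=["flat", "ok", "absent"])
        m = st.calibrate_model(train, labels, gs)
        assert set(m.gene_params) == {"ok"}

    def test_direction_recovery_on_planted_cohort(self):
        gs = st.default_gene_sets(n_genes=20, n_down=5, pathways=["P"])[0]
        cohort, labels = st.calibration_cohort(
            gs, n_per_class=20, effect_size=2.0, noise_sd=0.5, seed=123
        )
        m = st.calibrate_model(cohort, labels, gs)
        for gene in gs.genes:
            gp = m.gene_params[gene.gene_id]
            if gene.direction == "up":
                assert gp.p_high_given_active > gp.p_high_given_inactive
            else:
                assert gp.p_high_given_active < gp.p_high_given_inactive

    def test_scoring_training_data_separates_classes(self):
        gs = st.default_gene_sets(n_genes=15, n_down=3, pathways=["P"])[0]
        cohort, labels = st.calibration_cohort(gs, seed=5)
        m = st.calibrate_model(cohort, labels, gs)
        los = {
            s: st.score_sample(m, cohort.sample_values(s), s).log2_odds
            for s in cohort.sample_ids
        }
        act = np.mean([lo for s, lo in los.items() if labels[s] == "active"])
        inact = np.mean([lo for s, lo in los.items() if labels[s] == "inactive"])
        assert act > inact


class TestScoring:
    def test_closed_form_product_of_likelihood_ratios(self):
        m = make_model(20)  # LR(high) = 2 per gene
        sample = {f"g{i}": 6.0 for i in range(20)}  # all above cutoff
        s = st.score_sample(m, sample, "s")
        assert s.log2_odds == pytest.approx(20.0, abs=1e-9)
        assert s.n_genes_used == 20
        assert s.missing_genes == ()
        assert s.prob_active == pytest.approx(2**20 / (1 + 2**20))

    def test_missing_genes_contribute_unit_likelihood_ratio(self):
        m = make_model(4)
        s = st.score_sample(m, {"g0": 6.0, "g1": 6.0}, "s")
        assert s.log2_odds == pytest.approx(2.0)
        assert sorted(s.missing_genes) == ["g2", "g3"]
        assert s.n_genes_used + len(s.missing_genes) == 4

    def test_empty_overlap_is_a_scoring_error_not_a_prior_return(self):
        m = make_model(3)
        with pytest.raises(st.ScoringError):
            st.score_sample(m, {"other": 1.0}, "s")

    def test_unfrozen_model_refused(self):
        m = make_model(2)
        unfrozen = dataclasses.replace(m, frozen=False)
        with pytest.raises(st.ScoringError):
            st.score_sample(unfrozen, {"g0": 6.0}, "s")

    def test_log2_odds_clamped(self):
        m = make_model(100, p_act=0.95, p_inact=0.05)
        sample = {f"g{i}": 6.0 for i in range(100)}
        s = st.score_sample(m, sample, "s")
        assert s.log2_odds == LOG2_ODDS_CLAMP

    def test_probability_odds_consistency(self):
        m = make_model(8)
        rng = np.random.default_rng(0)
        for _ in range(20):
            sample = {f"g{i}": float(rng.choice([4.0, 6.0])) for i in range(8)}
            s = st.score_sample(m, sample, "s")
            lo = math.log2(s.prob_active) - math.log2(1 - s.prob_active)
            assert lo == pytest.approx(s.log2_odds, abs=1e-9)

    @pytest.mark.parametrize("trial", range(25))
    def test_factorized_score_matches_joint_enumeration(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(1, 9))
        params = {
            f"g{i}": GeneParams(
                "up",
                5.0,
                float(rng.uniform(0.05, 0.95)),
                float(rng.uniform(0.05, 0.95)),
            )
            for i in range(n)
        }
        prior = float(rng.uniform(0.1, 0.9))
        m = st.FrozenPathwayModel("P", prior, params)
        # random evidence including unobserved genes (but never all missing)
        states = rng.choice([0, 1, 2], size=n)
        if (states == 2).all():
            states[0] = 1
        evidence = {
            f"g{i}": (None if s == 2 else bool(s)) for i, s in enumerate(states)
        }
        sample = {
            g: (6.0 if e else 4.0) for g, e in evidence.items() if e is not None
        }
        got = st.score_sample(m, sample, "s").prob_active
        want = enum_posterior(prior, params, evidence)
        assert abs(got - want) < 1e-9

    def test_monotone_in_number_of_high_genes(self):
        m = make_model(10, p_act=0.8, p_inact=0.3)
        prev = -np.inf
        for k in range(11):
            sample = {f"g{i}": (6.0 if i < k else 4.0) for i in range(10)}
            lo = st.score_sample(m, sample, "s").log2_odds
            assert lo >= prev
            prev = lo


class TestScoreCohort:
    def _cohort(self, values, ids):
        return st.ExpressionMatrix(values=pd.DataFrame(values, index=ids))

    def test_single_sample_cohort_wraps_score_sample(self):
        m = make_model(3)
        cohort = self._cohort({"s1": [6.0, 4.0, 6.0]}, ["g0", "g1", "g2"])
        [profile] = st.score_cohort([m], cohort)
        direct = st.score_sample(m, cohort.sample_values("s1"), "s1")
        assert profile.scores["P"] == direct

    def test_duplicate_pathway_names_rejected(self):
        m = make_model(2)
        cohort = self._cohort({"s1": [6.0, 4.0]}, ["g0", "g1"])
        with pytest.raises(st.ConfigError):
            st.score_cohort([m, m], cohort)

    def test_sample_order_equivariance_and_composition_independence(self):
        rng = np.random.default_rng(3)
        m = make_model(5)
        genes = [f"g{i}" for i in range(5)]
        base = {f"s{i}": rng.uniform(3, 7, size=5).tolist() for i in range(6)}
        cohort = self._cohort(base, genes)
        profiles = {p.sample_id: p for p in st.score_cohort([m], cohort)}
        # permuted sample order
        perm_ids = list(reversed(cohort.sample_ids))
        perm = {p.sample_id: p for p in st.score_cohort([m], cohort.subset_samples(perm_ids))}
        assert {s: p.scores["P"] for s, p in perm.items()} == {
            s: p.scores["P"] for s, p in profiles.items()
        }
        # appending unrelated samples leaves original scores bit-identical
        extra = dict(base)
        extra.update({f"x{i}": rng.uniform(3, 7, size=5).tolist() for i in range(10)})
        bigger = {p.sample_id: p for p in st.score_cohort([m], self._cohort(extra, genes))}
        for s in base:
            assert bigger[s].scores["P"].log2_odds == profiles[s].scores["P"].log2_odds


class TestFrozenImmutability:
    def test_model_fields_immutable(self):
        m = make_model(2)
        with pytest.raises(dataclasses.FrozenInstanceError):
            m.prior_active = 0.9
        with pytest.raises(TypeError):
            m.gene_params["g0"] = None

    def test_probabilities_must_be_interior(self):
        with pytest.raises(st.ConfigError):
            GeneParams("up", 5.0, 1.0, 0.5)


class TestPi3kInference:
    def test_activated_cell_has_high_pi3k(self):
        # FOXO -3.8 in an activated sample vs +10.3 in the naive reference
        assert st.infer_pi3k_from_foxo(-3.8, reference=10.3) == "pi3k_high"
        assert st.infer_pi3k_from_foxo(10.3, reference=-3.8) == "pi3k_low"

    def test_tie_is_indeterminate(self):
        assert st.infer_pi3k_from_foxo(1.0, reference=1.0) == "indeterminate"

    def test_oxidative_stress_blocks_the_inversion(self):
        assert (
            st.infer_pi3k_from_foxo(-5.0, reference=5.0, oxidative_stress=True)
            == "indeterminate"
        )
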