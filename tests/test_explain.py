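"""Logit-mutation impact and interaction statistics against closed-form oracles."""

import numpy as np
import pytest

from ehrisk.explain import (
    AdditiveLogitScorer, MutationSpec, NullMutationError, OverlappingMutationError,
    aggregate_impacts, impact, impact_table, interaction, rank_interactions,
)


@pytest.fixture
def linear_scorer(stub_dataset):
    return AdditiveLogitScorer(
        bias=-0.3,
        temporal_weights={"depression": 0.7, "anxiety": -0.4},
        static_weights={"lgbt_status=Yes": -0.462, "sex=Female": 0.25},
        age_per_decade=0.2,
        dataset=stub_dataset)


class TestImpact:
    def test_binary_impact_equals_coefficient(self, stub_dataset, linear_scorer):
        res = impact(linear_scorer, stub_dataset.patients[0],
                     MutationSpec.temporal("depression"), stub_dataset)
        assert res.impact == pytest.approx(0.7, abs=1e-9)
        assert res.impact_score == res.impact  # binary: denominator is 1

    def test_impact_independent_of_other_features(self, stub_dataset, linear_scorer):
        # depression weight recovered identically for two very different patients
        r0 = impact(linear_scorer, stub_dataset.patients[0],
                    MutationSpec.temporal("depression"), stub_dataset)
        r3 = impact(linear_scorer, stub_dataset.patients[3],
                    MutationSpec.temporal("depression"), stub_dataset)
        assert r0.impact == pytest.approx(r3.impact, abs=1e-9)

    def test_static_block_impact(self, stub_dataset, linear_scorer):
        res = impact(linear_scorer, stub_dataset.patients[0],
                     MutationSpec.static("lgbt_status=Yes"), stub_dataset)
        assert res.impact == pytest.approx(-0.462, abs=1e-9)

    def test_age_impact_per_decade(self, stub_dataset, linear_scorer):
        # age 71.6 vs reference 61.6 under weight 0.2 per decade
        res = impact(linear_scorer, stub_dataset.patients[0],
                     MutationSpec.age(), stub_dataset)
        assert res.impact == pytest.approx(0.2, abs=1e-9)
        assert res.impact_score == pytest.approx(0.2, abs=1e-9)

    def test_identity_mutation_zero_impact(self, stub_dataset, linear_scorer):
        # patient 1 is at the reference age: mutation changes nothing
        res = impact(linear_scorer, stub_dataset.patients[1],
                     MutationSpec.age(), stub_dataset)
        assert res.impact == 0.0 and res.p_cur == res.p_ref

    def test_null_temporal_mutation_raises(self, stub_dataset, linear_scorer):
        with pytest.raises(NullMutationError):
            impact(linear_scorer, stub_dataset.patients[4],
                   MutationSpec.temporal("depression"), stub_dataset)

    def test_mutation_is_side_effect_free(self, stub_dataset, linear_scorer):
        patient = stub_dataset.patients[0]
        before = linear_scorer.predict_proba([patient])[0]
        tokens_before = list(patient.tokens)
        static_before = patient.static.copy()
        impact(linear_scorer, patient, MutationSpec.temporal("depression"), stub_dataset)
        impact(linear_scorer, patient, MutationSpec.static("lgbt_status=Yes"), stub_dataset)
        impact(linear_scorer, patient, MutationSpec.age(), stub_dataset)
        assert patient.tokens == tokens_before
        np.testing.assert_array_equal(patient.static, static_before)
        assert linear_scorer.predict_proba([patient])[0] == before

    def test_positive_impact_means_higher_risk(self, stub_dataset, linear_scorer):
        res = impact(linear_scorer, stub_dataset.patients[0],
                     MutationSpec.temporal("anxiety"), stub_dataset)
        assert res.impact < 0  # anxiety weight is negative: protective
        assert res.p_cur < res.p_ref


class TestAggregation:
    def test_mean_impact_equals_coefficient_for_linear_scorer(self, stub_dataset, linear_scorer):
        agg = aggregate_impacts(linear_scorer, stub_dataset, MutationSpec.temporal("depression"))
        assert agg["n"] == 3
        assert agg["mean_impact"] == pytest.approx(0.7, abs=1e-9)
        assert agg["sd_impact"] == pytest.approx(0.0, abs=1e-9)
        assert agg["direction"] == "+"

    def test_feature_absent_everywhere_gives_flagged_empty_summary(self, stub_dataset):
        scorer = AdditiveLogitScorer(dataset=stub_dataset)
        ds = stub_dataset.subset([4])  # only the token-free patient
        agg = aggregate_impacts(scorer, ds, MutationSpec.temporal("pain"))
        assert agg["n"] == 0 and agg["empty"] is True

    def test_impact_table_ranks_by_magnitude(self, stub_dataset, linear_scorer):
        table = impact_table(linear_scorer, stub_dataset,
                             [MutationSpec.temporal("depression"),
                              MutationSpec.temporal("anxiety"),
                              MutationSpec.static("sex=Female")])
        assert list(table["feature"]) == ["depression", "anxiety", "sex=Female"]


class TestInteraction:
    def test_additive_scorer_zero_interaction(self, stub_dataset, linear_scorer):
        res = interaction(linear_scorer, stub_dataset.patients[0],
                          MutationSpec.temporal("depression"),
                          MutationSpec.temporal("anxiety"), stub_dataset)
        assert res.interaction == pytest.approx(0.0, abs=1e-9)

    def test_product_term_recovered_exactly(self, stub_dataset):
        scorer = AdditiveLogitScorer(
            bias=0.1, temporal_weights={"depression": 0.7, "anxiety": -0.4},
            product_terms={("depression", "anxiety"): 0.9}, dataset=stub_dataset)
        res = interaction(scorer, stub_dataset.patients[0],
                          MutationSpec.temporal("depression"),
                          MutationSpec.temporal("anxiety"), stub_dataset)
        assert res.interaction == pytest.approx(0.9, abs=1e-9)

    def test_symmetry(self, stub_dataset):
        scorer = AdditiveLogitScorer(
            bias=-0.2, temporal_weights={"depression": 0.7, "anxiety": -0.4},
            product_terms={("depression", "anxiety"): -0.6}, dataset=stub_dataset)
        ab = interaction(scorer, stub_dataset.patients[0],
                         MutationSpec.temporal("depression"),
                         MutationSpec.temporal("anxiety"), stub_dataset)
        ba = interaction(scorer, stub_dataset.patients[0],
                         MutationSpec.temporal("anxiety"),
                         MutationSpec.temporal("depression"), stub_dataset)
        assert ab.interaction == pytest.approx(ba.interaction, abs=1e-12)

    def test_mixed_static_temporal_product_term(self, stub_dataset):
        scorer = AdditiveLogitScorer(
            bias=0.0, temporal_weights={"depression": 0.5},
            static_weights={"lgbt_status=Yes": -0.4},
            product_terms={("depression", "lgbt_status=Yes"): 0.8}, dataset=stub_dataset)
        res = interaction(scorer, stub_dataset.patients[0],
                          MutationSpec.temporal("depression"),
                          MutationSpec.static("lgbt_status=Yes"), stub_dataset)
        assert res.interaction == pytest.approx(0.8, abs=1e-9)

    def test_overlapping_mutations_rejected(self, stub_dataset, linear_scorer):
        with pytest.raises(OverlappingMutationError):
            interaction(linear_scorer, stub_dataset.patients[0],
                        MutationSpec.static("lgbt_status=Yes"),
                        MutationSpec.static("lgbt_status=No"), stub_dataset)


class TestRankInteractions:
    def test_planted_pair_ranks_first_and_anchor_excluded(self, stub_dataset):
        scorer = AdditiveLogitScorer(
            bias=0.1, temporal_weights={"depression": 0.7, "anxiety": -0.4, "pain": 0.2},
            product_terms={("depression", "anxiety"): 0.9}, dataset=stub_dataset)
        anchor = MutationSpec.temporal("depression")
        cands = [MutationSpec.temporal("depression"), MutationSpec.temporal("anxiety"),
                 MutationSpec.temporal("pain")]
        table = rank_interactions(scorer, stub_dataset, anchor, cands)
        assert "depression" not in list(table["feature"])
        assert table.iloc[0]["feature"] == "anxiety"
        assert table.iloc[0]["mean_interaction"] == pytest.approx(0.9, abs=1e-9)

    def test_additive_scorer_all_zero(self, stub_dataset, linear_scorer):
        table = rank_interactions(linear_scorer, stub_dataset,
                                  MutationSpec.temporal("depression"),
                                  [MutationSpec.temporal("anxiety"),
                                   MutationSpec.temporal("pain")])
        vals = table["mean_interaction"].dropna()
        assert (vals.abs() < 1e-9).all()
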