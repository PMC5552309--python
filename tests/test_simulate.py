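"""Synthetic cohort generator: calibration, determinism, clustering, encoding."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pointbiserialr

from riskcart.cohort import CohortError, encode_predictors
from riskcart.profiles import MappingEntry, PredictorMapping
from riskcart.simulate import (
    CalibrationError,
    CohortSpec,
    PlantedSubgroup,
    SpecError,
    generate_cohort,
    make_validation_cohort,
    subgroup_membership,
)
from riskcart.tree import weighted_prevalence

GROUPS = (
    PlantedSubgroup(((60, "yes"), (65, "yes"), (70, "yes")), 0.38),
    PlantedSubgroup(((50, "yes"), (55, "yes"), (62, "no")), 0.32),
)


class TestSpecValidation:
    def test_rejects_out_of_range_proportions(self):
        with pytest.raises(SpecError):
            CohortSpec(n_individuals=10, base_prevalence=1.2)
        with pytest.raises(SpecError):
            CohortSpec(n_individuals=0)
        with pytest.raises(SpecError):
            CohortSpec(n_individuals=10, clustering_strength=-0.1)

    def test_rejects_subgroup_index_out_of_range(self):
        bad = PlantedSubgroup(((80, "yes"),), 0.4)
        with pytest.raises(SpecError):
            CohortSpec(n_individuals=10, n_predictors=75, planted_subgroups=(bad,))

    def test_rejects_duplicate_condition_indices(self):
        with pytest.raises(SpecError):
            PlantedSubgroup(((1, "yes"), (1, "no")), 0.4)

    def test_roundtrips_through_dict(self):
        spec = CohortSpec(n_individuals=100, planted_subgroups=GROUPS, seed=5)
        assert CohortSpec.from_dict(spec.to_dict()) == spec


class TestGenerateCohort:
    def test_deterministic_for_identical_spec(self):
        spec = CohortSpec(n_individuals=500, planted_subgroups=GROUPS, seed=42)
        a, b = generate_cohort(spec), generate_cohort(spec)
        pd.testing.assert_frame_equal(a.to_frame(), b.to_frame())

    def test_seed_changes_output(self):
        spec = CohortSpec(n_individuals=500, seed=42)
        a = generate_cohort(spec)
        b = generate_cohort(spec, seed=43)
        assert not np.array_equal(a.primary_outcome, b.primary_outcome)

    def test_base_prevalence_calibrated_without_plants(self):
        # weighted prevalence within Monte-Carlo error of the target
        spec = CohortSpec(n_individuals=50_000, base_prevalence=0.12, seed=1)
        cohort = generate_cohort(spec)
        se = np.sqrt(0.12 * 0.88 / 50_000)
        prev = weighted_prevalence(cohort.primary_outcome, cohort.weights)
        assert abs(prev - 0.12) < 4 * se

    def test_calibration_holds_across_seeds_with_plants(self):
        # |weighted prevalence - base| < 4 binomial SEs, 20 seeds
        n = 10_000
        se = np.sqrt(0.12 * 0.88 / n)
        for seed in range(20):
            spec = CohortSpec(n_individuals=n, planted_subgroups=GROUPS, seed=seed)
            cohort = generate_cohort(spec)
            prev = weighted_prevalence(cohort.primary_outcome, cohort.weights)
            assert abs(prev - 0.12) < 4 * se, f"seed {seed}: {prev:.4f}"

    def test_subgroup_prevalence_matches_configuration(self):
        spec = CohortSpec(n_individuals=20_000, planted_subgroups=GROUPS, seed=9)
        cohort = generate_cohort(spec)
        member = subgroup_membership(cohort.predictors.to_numpy(), GROUPS)
        for g, group in enumerate(GROUPS):
            mask = member == g
            n_g = mask.sum()
            assert n_g > 100  # plants must be realistically sized
            target = group.outcome_prevalence_in_group
            se = np.sqrt(target * (1 - target) / n_g)
            assert abs(cohort.primary_outcome[mask].mean() - target) < 4 * se

    def test_degenerate_plant_covering_all_rows(self):
        # one subgroup at prevalence ~1 matching everyone => all outcomes 1
        group = PlantedSubgroup(((0, "no"),), 0.999999)
        spec = CohortSpec(
            n_individuals=200,
            n_predictors=2,
            predictor_marginals=(0.001, 0.5),
            missingness_rates=(0.9, 0.0),
            planted_subgroups=(group,),
            seed=0,
        )
        cohort = generate_cohort(spec)
        member = subgroup_membership(cohort.predictors.to_numpy(), (group,))
        assert (member == 0).mean() > 0.99
        assert cohort.primary_outcome[member == 0].all()

    def test_infeasible_calibration_raises(self):
        # a huge high-risk plant forces a negative background rate
        group = PlantedSubgroup(((74, "no"),), 0.9)  # matches ~2/3 of rows
        spec = CohortSpec(
            n_individuals=2_000, base_prevalence=0.12, planted_subgroups=(group,), seed=0
        )
        with pytest.raises(CalibrationError):
            generate_cohort(spec)

    def test_clustering_raises_pairwise_correlation(self):
        base = dict(n_individuals=50_000, n_predictors=20, seed=4)
        flat = generate_cohort(CohortSpec(clustering_strength=0.0, **base))
        clus = generate_cohort(CohortSpec(clustering_strength=0.4, **base))

        def mean_corr(c):
            r = np.corrcoef(c.predictors.to_numpy(), rowvar=False)
            return r[np.triu_indices_from(r, k=1)].mean()

        assert mean_corr(clus) > mean_corr(flat) + 0.02

    def test_weights_nonnegative_mean_one(self):
        cohort = generate_cohort(CohortSpec(n_individuals=20_000, seed=2))
        assert (cohort.weights >= 0).all()
        assert abs(cohort.weights.mean() - 1.0) < 0.02

    def test_secondary_outcomes_elevated_in_subgroups(self):
        # multifinality: members of planted subgroups carry more of every outcome
        spec = CohortSpec(n_individuals=30_000, planted_subgroups=GROUPS, seed=6)
        cohort = generate_cohort(spec)
        member = subgroup_membership(cohort.predictors.to_numpy(), GROUPS) >= 0
        for col in cohort.secondary_outcomes.columns:
            y = cohort.secondary_outcomes[col].to_numpy()
            assert y[member].mean() > y[~member].mean()

    def test_secondary_prevalences_near_targets(self):
        spec = CohortSpec(n_individuals=50_000, planted_subgroups=GROUPS, seed=8)
        cohort = generate_cohort(spec)
        for col, target in zip(cohort.secondary_outcomes.columns, spec.secondary_prevalences):
            prev = weighted_prevalence(cohort.secondary_outcomes[col], cohort.weights)
            se = np.sqrt(target * (1 - target) / 50_000)
            assert abs(prev - target) < 4 * se


class TestEncodePredictors:
    def test_three_levels_fold_to_indicator(self):
        raw = pd.DataFrame({"a": ["yes", "no", "missing"]})
        assert encode_predictors(raw)["a"].tolist() == [1, 0, 0]

    def test_all_yes_column(self):
        raw = pd.DataFrame({"a": ["yes"] * 4})
        assert encode_predictors(raw)["a"].tolist() == [1, 1, 1, 1]

    def test_round_trip_on_two_level_table(self, rng):
        values = rng.choice(["yes", "no"], size=(30, 4))
        raw = pd.DataFrame(values, columns=list("abcd"))
        expected = (values == "yes").astype(int)
        assert np.array_equal(encode_predictors(raw).to_numpy(), expected)

    def test_unknown_level_names_row_and_column(self):
        raw = pd.DataFrame({"a": ["yes"], "b": ["maybe"]})
        with pytest.raises(CohortError, match="'b'"):
            encode_predictors(raw)


class TestValidationCohort:
    def test_identity_mapping_full_coverage(self):
        spec = CohortSpec(n_individuals=500, planted_subgroups=GROUPS, seed=3)
        mapping = PredictorMapping.identity(spec.predictor_names())
        cohort, report = make_validation_cohort(spec, mapping)
        assert report.coverage == 1.0 and not report.unmapped
        # zero noise, all mapped: identical to the discovery generator's output
        discovery = generate_cohort(spec)
        assert np.array_equal(
            cohort.predictors[spec.predictor_names()].to_numpy(),
            discovery.predictors.to_numpy(),
        )

    def test_unmapped_variable_absent_and_reported(self):
        spec = CohortSpec(n_individuals=200, seed=3)
        names = spec.predictor_names()
        entries = [MappingEntry(n, n) for n in names]
        entries[4] = MappingEntry(names[4], None)
        cohort, report = make_validation_cohort(spec, PredictorMapping(entries))
        assert names[4] not in cohort.predictors.columns
        assert report.unmapped == [names[4]]

    def test_unknown_source_rejected(self):
        spec = CohortSpec(n_individuals=50, n_predictors=3)
        with pytest.raises(SpecError):
            make_validation_cohort(spec, PredictorMapping([MappingEntry("zz", "zz")]))

    def test_heavy_proxy_noise_destroys_association(self):
        # flip prob 0.5 on a subgroup-defining variable: the observed proxy
        # becomes uninformative about latent membership
        group = PlantedSubgroup(((70, "yes"), (72, "yes")), 0.38)
        spec = CohortSpec(n_individuals=20_000, planted_subgroups=(group,), seed=12)
        names = spec.predictor_names()
        target_name = names[70]

        def association(flip):
            entries = [
                MappingEntry(n, n, flip if n == target_name else 0.0) for n in names
            ]
            cohort, _ = make_validation_cohort(spec, PredictorMapping(entries))
            latent = generate_cohort(spec)
            member = subgroup_membership(latent.predictors.to_numpy(), (group,)) >= 0
            r, _ = pointbiserialr(member, cohort.predictors[target_name].to_numpy())
            return abs(r)

        assert association(0.5) < 0.1 < association(0.0)
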