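"""Ground-truth generator: determinism, conservation and calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kpsize.errors import ConfigurationError
from kpsize.frame import stratify_units
from kpsize.synthetic import (
    SimConfig,
    generate_country,
    generate_mapping_observations,
    generate_service_data,
    simulate_all,
)

SMALL = dict(
    n_units=5,
    pop_range=(8_000, 30_000),
    kp_prevalence=0.02,
    survey_size=100,
    seed=0,
)


class TestGenerateCountry:
    def test_zero_prevalence_zero_counts(self):
        truth, census = generate_country(SimConfig(**{**SMALL, "kp_prevalence": 0.0}))
        assert truth.national_truth == 0
        assert (truth.units["kp_count"] == 0).all()

    def test_331_units_stratify_into_study_terciles(self):
        truth, census = generate_country(SimConfig(seed=4))
        sizes = stratify_units(census)["stratum"].value_counts()
        assert sizes["high"] == 110 and sizes["medium"] == 110 and sizes["low"] == 111

    def test_national_truth_within_binomial_bounds(self):
        cfg = SimConfig(n_units=40, pop_range=(50_000, 200_000), kp_prevalence=0.005, seed=9)
        truth, census = generate_country(cfg)
        base = int(census["adult_f"].sum())
        lo, hi = stats.binom.ppf([0.005, 0.995], base, 0.005)
        assert lo <= truth.national_truth <= hi

    def test_conservation_and_hidden_attend_nothing(self):
        truth, _ = generate_country(SimConfig(**SMALL))
        assert truth.unit_truth.sum() == truth.national_truth
        hidden_ids = set(truth.individuals.loc[truth.individuals["hidden"], "individual_id"])
        assert hidden_ids.isdisjoint(set(truth.attendance["individual_id"]))
        visible = truth.individuals[~truth.individuals["hidden"]]
        assert (visible["spots_attended"] >= 1).all()

    def test_invalid_probability_is_configuration_error(self):
        with pytest.raises(Exception):
            SimConfig(**{**SMALL, "hidden_prob": 1.4})
        with pytest.raises(Exception):
            SimConfig(**{**SMALL, "n_units": 2})
        with pytest.raises(Exception):
            SimConfig(**{**SMALL, "mobility_prob": 0.3, "spots_visited_mean": 1.2})

    def test_stratum_specific_prevalence(self):
        cfg = SimConfig(
            **{**SMALL, "n_units": 9, "kp_prevalence": {"high": 0.05, "medium": 0.0, "low": 0.0}}
        )
        truth, census = generate_country(cfg)
        strata = stratify_units(census).set_index("unit_id")["stratum"]
        by = truth.unit_truth.groupby(strata).sum()
        assert by.get("medium", 0) == 0 and by.get("low", 0) == 0
        assert by["high"] > 0


class TestDeterminism:
    def test_identical_config_identical_tables(self):
        a = simulate_all(SimConfig(**SMALL))
        b = simulate_all(SimConfig(**SMALL))
        pd.testing.assert_frame_equal(a.census, b.census)
        pd.testing.assert_frame_equal(a.spots, b.spots)
        pd.testing.assert_frame_equal(a.registry, b.registry)
        pd.testing.assert_frame_equal(a.survey, b.survey)
        c = simulate_all(SimConfig(**{**SMALL, "seed": 1}))
        assert not a.census.equals(c.census)


class TestMappingObservations:
    def test_zero_noise_brackets_collapse_to_truth(self):
        truth, _ = generate_country(SimConfig(**SMALL))
        obs = generate_mapping_observations(truth, noise=0.0)
        att = truth.attendance.groupby("spot_id").size()
        assert (obs["min_count"] == obs["max_count"]).all()
        merged = obs.set_index("spot_id")["min_count"]
        pd.testing.assert_series_equal(
            merged.sort_index(), att.sort_index(), check_names=False
        )

    def test_fully_hidden_population_yields_empty_table(self):
        truth, _ = generate_country(SimConfig(**{**SMALL, "hidden_prob": 1.0}))
        obs = generate_mapping_observations(truth)
        assert len(obs) == 0

    def test_noise_brackets_contain_truth(self):
        truth, _ = generate_country(SimConfig(**SMALL))
        obs = generate_mapping_observations(truth, noise=0.2, rng=np.random.default_rng(5))
        att = truth.attendance.groupby("spot_id").size()
        merged = obs.set_index("spot_id").join(att.rename("truth"))
        assert (merged["min_count"] <= merged["truth"]).all()
        assert (merged["max_count"] >= merged["truth"]).all()

    def test_symmetric_noise_midpoints_unbiased(self):
        """Mean of noisy midpoints over 500 observation replicates stays
        within 2% of the true total attendance."""
        truth, _ = generate_country(SimConfig(**SMALL))
        true_total = len(truth.attendance)
        rng = np.random.default_rng(17)
        totals = []
        for _ in range(500):
            obs = generate_mapping_observations(truth, noise=0.2, rng=rng)
            totals.append(((obs["min_count"] + obs["max_count"]) / 2).sum())
        assert np.mean(totals) == pytest.approx(true_total, rel=0.02)


class TestServiceData:
    def test_full_coverage_full_survey_recover_truth_exactly(self):
        cfg = SimConfig(
            **{**SMALL, "service_coverage": {"svc": 1.0}, "object_coverage": 1.0}
        )
        truth, _ = generate_country(cfg)
        cfg2 = cfg.model_copy(update={"survey_size": truth.national_truth})
        truth.config = cfg2
        registry, survey = generate_service_data(truth)
        counts = registry.set_index("source_name")["count"]
        assert counts["svc"] == truth.national_truth
        assert len(survey) == truth.national_truth
        assert survey["received_svc"].all()
        # multiplier n/p with p = 1 recovers N exactly
        assert counts["svc"] / survey["received_svc"].mean() == truth.national_truth

    def test_zero_object_coverage_distributes_nothing(self):
        cfg = SimConfig(**{**SMALL, "object_coverage": 0.0})
        truth, _ = generate_country(cfg)
        registry, survey = generate_service_data(truth)
        assert registry.set_index("source_name").loc["unique_object", "count"] == 0
        assert survey["received_unique_object"].sum() == 0

    def test_registry_counts_match_binomial_mean(self):
        """coverage 0.2 on ~1000 members: mean registry count over 500
        country replicates within 3% of 0.2 * mean N."""
        counts, truths = [], []
        for seed in range(500):
            cfg = SimConfig(
                n_units=4,
                pop_range=(15_000, 25_000),
                kp_prevalence=0.05,
                service_coverage={"svc": 0.2},
                survey_size=10,
                seed=seed,
            )
            truth, _ = generate_country(cfg)
            counts.append(truth.individuals["received_svc"].sum())
            truths.append(truth.national_truth)
        assert np.mean(counts) == pytest.approx(0.2 * np.mean(truths), rel=0.03)

    def test_oversized_survey_rejected(self):
        truth, _ = generate_country(SimConfig(**{**SMALL, "kp_prevalence": 0.001}))
        truth.config = truth.config.model_copy(
            update={"survey_size": truth.national_truth + 1}
        )
        with pytest.raises(ConfigurationError, match="survey_size"):
            generate_service_data(truth)

    def test_survey_is_valid_forest_with_flags(self):
        truth, _ = generate_country(SimConfig(**SMALL))
        _, survey = generate_service_data(truth)
        from kpsize.multiplier import validate_survey

        validate_survey(survey, indicators=["received_ngo_clients", "hidden"])
        assert (survey["recruiter_id"] == "").sum() == truth.config.n_seeds
        assert (survey["degree"] >= 1).all()

    def test_indicator_prevalence_approaches_coverage_in_census_survey(self):
        cfg = SimConfig(**{**SMALL, "kp_prevalence": 0.05, "seed": 2})
        truth, _ = generate_country(cfg)
        truth.config = cfg.model_copy(update={"survey_size": truth.national_truth})
        _, survey = generate_service_data(truth)
        cov = cfg.service_coverage["ngo_clients"]
        assert survey["received_ngo_clients"].mean() == pytest.approx(
            truth.individuals["received_ngo_clients"].mean()
        )
        assert survey["received_ngo_clients"].mean() == pytest.approx(cov, abs=0.03)
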