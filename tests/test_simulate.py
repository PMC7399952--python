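import numpy as np
import pandas as pd
import pytest

from meddsurvey.cognition import standardize_cognition
from meddsurvey.errors import ConfigurationError
from meddsurvey.ingest import average_recall_table, map_fped_to_components, screen_energy_outliers
from meddsurvey.scoring import ScoreCutoffs, score_components
from meddsurvey.simulate import (
    CohortConfig,
    generate_cohort,
    true_population_summary,
)


def scored_totals(cohort):
    intake, _ = average_recall_table(cohort.recalls)
    comp = map_fped_to_components(intake)
    return score_components(comp, ScoreCutoffs())


class TestConfigValidation:
    def test_too_few_psus_names_field(self):
        with pytest.raises(ConfigurationError, match="psus_per_stratum"):
            CohortConfig(psus_per_stratum=1).validate()

    def test_too_small_cohort_names_field(self):
        with pytest.raises(ConfigurationError, match="n_participants"):
            CohortConfig(n_participants=50, n_strata=14).validate()

    def test_probability_out_of_range(self):
        with pytest.raises(ConfigurationError, match="memory_complaint_rate"):
            CohortConfig(memory_complaint_rate=1.4).validate()
        with pytest.raises(ConfigurationError, match="selection_informativeness"):
            CohortConfig(selection_informativeness=1.0).validate()

    def test_unknown_component_rejected(self):
        cfg = CohortConfig()
        cfg.component_distributions["chocolate_g"] = {"family": "gamma"}
        with pytest.raises(ConfigurationError, match="chocolate_g"):
            cfg.validate()


class TestDeterminism:
    def test_same_config_and_seed_byte_identical(self):
        a = generate_cohort(CohortConfig(n_participants=200, seed=42))
        b = generate_cohort(CohortConfig(n_participants=200, seed=42))
        assert a.recalls.to_csv(index=False) == b.recalls.to_csv(index=False)
        assert a.participants.to_csv(index=False) == b.participants.to_csv(index=False)
        assert a.truth == b.truth

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortConfig(n_participants=200, seed=1))
        b = generate_cohort(CohortConfig(n_participants=200, seed=2))
        assert not a.recalls.equals(b.recalls)


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(CohortConfig(n_participants=600, seed=9))


class TestCohortStructure:

    def test_every_participant_has_two_recall_days(self, cohort):
        days = cohort.recalls.groupby("SEQN")["DAY"].agg(lambda d: sorted(d))
        assert (days.apply(lambda s: s == [1, 2])).all()

    def test_weights_strictly_positive(self, cohort):
        assert (cohort.participants["WTDRD_2DAY"] > 0).all()

    def test_two_psus_per_stratum(self, cohort):
        per = cohort.participants.groupby("SDMVSTRA")["SDMVPSU"].nunique()
        assert (per == 2).all()

    def test_truth_fields_populated(self, cohort):
        assert 0 < cohort.truth["medd_mean"] < 18
        assert cohort.truth["medd_sd"] > 0
        assert cohort.truth["score_mean_meat"] > 0

    def test_csv_roundtrip(self, cohort, tmp_path):
        paths = cohort.to_csv(tmp_path)
        back = pd.read_csv(paths["recalls"])
        assert len(back) == len(cohort.recalls)
        assert paths["config"].exists()


class TestEnergyOutlierPlanting:
    def test_planted_outliers_flagged_exactly(self):
        cohort = generate_cohort(
            CohortConfig(n_participants=400, seed=3, outlier_energy_count=3)
        )
        intake, _ = average_recall_table(cohort.recalls)
        _, flagged = screen_energy_outliers(intake)
        assert len(flagged) == 3
        planted = cohort.recalls.groupby("SEQN")["ENERGY_KCAL"].max()
        expected = set(planted.nlargest(3).index)
        assert set(flagged["SEQN"]) == expected

    def test_clean_cohort_flags_nothing(self):
        cohort = generate_cohort(CohortConfig(n_participants=400, seed=3))
        intake, _ = average_recall_table(cohort.recalls)
        _, flagged = screen_energy_outliers(intake)
        assert len(flagged) == 0


class TestLatentDietFactor:
    def test_null_effect_gives_null_score_cognition_correlation(self):
        """With diet_effect_gamma = 0 the MedD score and cognitive z-scores
        are uncorrelated; the mean correlation over replicates sits within
        its own 3-SE Monte-Carlo band around 0."""
        rng = np.random.default_rng(55)
        corrs = []
        for _ in range(30):
            cohort = generate_cohort(
                CohortConfig(
                    n_participants=500,
                    diet_effect_gamma=0.0,
                    seed=int(rng.integers(2**31 - 1)),
                )
            )
            scores = scored_totals(cohort)
            z = standardize_cognition(cohort.participants)
            merged = scores.merge(z[["SEQN", "Z_GLOBAL"]], on="SEQN").dropna()
            corrs.append(np.corrcoef(merged["SCORE_TOTAL"], merged["Z_GLOBAL"])[0, 1])
        corrs = np.array(corrs)
        assert abs(corrs.mean()) < 3 * corrs.std(ddof=1) / np.sqrt(len(corrs))

    def test_positive_effect_induces_positive_correlation(self):
        cohort = generate_cohort(
            CohortConfig(n_participants=2000, diet_effect_gamma=0.3, seed=17)
        )
        scores = scored_totals(cohort)
        z = standardize_cognition(cohort.participants)
        merged = scores.merge(z[["SEQN", "Z_GLOBAL"]], on="SEQN").dropna()
        assert np.corrcoef(merged["SCORE_TOTAL"], merged["Z_GLOBAL"])[0, 1] > 0.05


class TestTruePopulationSummary:
    def test_oracle_matches_independent_monte_carlo(self):
        """The cached census values agree with an independent MC draw within
        3 combined standard errors."""
        cfg = CohortConfig(n_participants=300)
        truth = true_population_summary(cfg, n_mc=80_000)
        indep = true_population_summary(cfg, n_mc=80_000, seed=424242)
        se = truth["medd_sd"] * np.sqrt(2 / 80_000)
        assert abs(truth["medd_mean"] - indep["medd_mean"]) < 3 * se

    def test_oracle_near_emulated_cohort_mean(self):
        """Weighted cohort estimates recover the census mean under the
        default informative design."""
        from meddsurvey.survey import SurveyDesign, four_year_weights, svy_mean

        cfg = CohortConfig(n_participants=4000, seed=101)
        cohort = generate_cohort(cfg)
        scores = scored_totals(cohort)
        df = scores.merge(cohort.participants, on="SEQN")
        d = SurveyDesign(
            df["SDMVSTRA"], df["SDMVPSU"], four_year_weights(df["WTDRD_2DAY"].to_numpy())
        )
        est = svy_mean(df["SCORE_TOTAL"].astype(float), d)
        assert abs(est.estimate - cohort.truth["medd_mean"]) < 4 * est.se

    def test_degenerate_all_max_intakes_score_18(self):
        """Forcing every component into its top band yields a census mean of 18."""
        cfg = CohortConfig(n_participants=300, day_to_day_sigma=0.0)
        for comp, dist in cfg.component_distributions.items():
            if comp == "alcohol_g":
                cfg.component_distributions[comp] = {
                    "family": "zi_lognormal", "p_any": 1.0, "median": 18.0,
                    "sigma": 1e-9, "theta": 0.0,
                }
            elif comp == "meat_g":
                cfg.component_distributions[comp] = {
                    "family": "zi_lognormal", "p_any": 1.0, "median": 1e-6,
                    "sigma": 1e-9, "theta": 0.0,
                }
            else:
                cfg.component_distributions[comp] = {
                    "family": "zi_lognormal", "p_any": 1.0, "median": 5000.0,
                    "sigma": 1e-9, "theta": 0.0,
                }
        truth = true_population_summary(cfg, n_mc=2000)
        assert truth["medd_mean"] == pytest.approx(18.0, abs=1e-9)


class TestInformativeSelection:
    def test_zero_informativeness_weighted_close_to_unweighted(self):
        from meddsurvey.survey import SurveyDesign, four_year_weights, svy_mean

        cohort = generate_cohort(
            CohortConfig(n_participants=6000, selection_informativeness=0.0, seed=77)
        )
        scores = scored_totals(cohort)
        df = scores.merge(cohort.participants, on="SEQN")
        d = SurveyDesign(
            df["SDMVSTRA"], df["SDMVPSU"], four_year_weights(df["WTDRD_2DAY"].to_numpy())
        )
        est = svy_mean(df["SCORE_TOTAL"].astype(float), d)
        assert abs(est.estimate - df["SCORE_TOTAL"].mean()) < 3 * est.se

    def test_informative_design_weights_track_diet_factor(self):
        """Higher informativeness makes weights negatively associated with the
        MedD score (high-theta participants are over-sampled, so they carry
        smaller weights)."""
        cohort = generate_cohort(
            CohortConfig(n_participants=4000, selection_informativeness=0.8, seed=31)
        )
        scores = scored_totals(cohort)
        df = scores.merge(cohort.participants, on="SEQN")
        r = np.corrcoef(df["SCORE_TOTAL"], df["WTDRD_2DAY"])[0, 1]
        assert r < -0.05  # high theta is over-sampled, so it carries low weight
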