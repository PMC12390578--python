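"""The synthetic study generator: sampling law, censoring, presets."""

import numpy as np
import pytest
import scipy.stats as stats

from bbaconcord import (
    ChemicalTreatment,
    Grade,
    PRESET_NAMES,
    StrainProfile,
    ValidationError,
    mean_curve,
    preset_scenario,
    sample_knockdown_times,
    simulate_bottle,
    simulate_field_trial,
    simulate_study,
    validate_dataset,
)

TREATMENT = ChemicalTreatment("deltamethrin", Grade.TECHNICAL, 22.0)


class TestKnockdownSampling:
    def test_fully_immune_population_never_goes_down(self, rng):
        profile = StrainProfile("x", kt50=30, shape=3, immune_fraction=1.0)
        assert np.isinf(sample_knockdown_times(100, profile, rng)).all()

    def test_half_are_down_by_the_median_time(self, rng):
        profile = StrainProfile("x", kt50=30, shape=3)
        times = sample_knockdown_times(100_000, profile, rng)
        frac = np.mean(times <= 30.0)
        se = np.sqrt(0.25 / 100_000)
        assert abs(frac - 0.5) < 3 * se

    def test_same_seed_reproduces_draws(self):
        profile = StrainProfile("x", kt50=30, shape=3, immune_fraction=0.2)
        t1 = sample_knockdown_times(1000, profile, np.random.default_rng(9))
        t2 = sample_knockdown_times(1000, profile, np.random.default_rng(9))
        assert np.array_equal(t1, t2)

    def test_empirical_cdf_matches_log_logistic_closed_form(self, rng):
        # independent cross-check against scipy's Fisk (log-logistic) distribution
        profile = StrainProfile("x", kt50=30, shape=2.5)
        times = sample_knockdown_times(100_000, profile, rng)
        ks = stats.ks_1samp(times, stats.fisk(c=2.5, scale=30).cdf).statistic
        assert ks < 0.01

    def test_weibull_law_has_the_requested_median(self, rng):
        profile = StrainProfile("x", kt50=40, shape=2.0, law="weibull")
        times = sample_knockdown_times(100_000, profile, rng)
        assert np.median(times) == pytest.approx(40.0, rel=0.02)
        scale = 40.0 / np.log(2.0) ** 0.5
        ks = stats.ks_1samp(times, stats.weibull_min(c=2.0, scale=scale).cdf).statistic
        assert ks < 0.01

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValidationError):
            StrainProfile("x", kt50=-1, shape=3)
        with pytest.raises(ValidationError):
            StrainProfile("x", kt50=30, shape=3, immune_fraction=1.5)
        with pytest.raises(ValidationError):
            StrainProfile("x", kt50=30, shape=3, control_rate=0.2)


class TestSimulateBottle:
    def test_simulated_bottles_satisfy_all_invariants(self, rng):
        # construction would raise if counts were non-monotone or out of range
        profile = StrainProfile("x", kt50=45, shape=2, immune_fraction=0.3)
        for i in range(50):
            b = simulate_bottle(profile, TREATMENT, rng, replicate_id=str(i))
            assert b.n_introduced in (24, 25)
            assert b.down_counts[0] == 0 or b.down_counts[0] >= 0

    def test_susceptible_like_profile_completes_by_15_min(self, rng):
        profile = StrainProfile("x", kt50=5, shape=8)
        assert profile.cdf(15.0) == pytest.approx(0.99985, abs=1e-4)
        b = simulate_bottle(profile, TREATMENT, rng, n_per_bottle=1000, escape_prob=0)
        assert b.down_counts[3] / b.n_introduced > 0.995  # index 3 is t=15

    def test_resistant_like_profile_plateaus_near_immune_complement(self, rng):
        profile = StrainProfile("x", kt50=60, shape=3, immune_fraction=0.45)
        b = simulate_bottle(profile, TREATMENT, rng, n_per_bottle=2000, escape_prob=0)
        plateau = 100 * b.down_counts[-1] / b.n_introduced
        expected = profile.expected_mortality_pct(180.0)
        assert plateau == pytest.approx(expected, abs=3 * 100 * np.sqrt(0.25 / 2000))


class TestFieldTrial:
    def test_total_efficacy_kills_every_cage(self):
        cfg = preset_scenario("fogg_malathion", seed=1)
        cages = simulate_field_trial(cfg, np.random.default_rng(1))
        for c in cages:
            if not c.is_control and c.strain == "Fogg Rd":
                assert c.dead_12h == c.n_introduced

    def test_partial_efficacy_matches_binomial_expectation(self):
        cfg = preset_scenario("vicfazio_malathion", seed=1, cages_per_distance=30, n_per_cage=20)
        cages = [
            c
            for c in simulate_field_trial(cfg, np.random.default_rng(4))
            if not c.is_control and c.strain == "Vic Fazio"
        ]
        total_n = sum(c.n_introduced for c in cages)
        frac = sum(c.dead_12h for c in cages) / total_n
        se = np.sqrt(0.474 * 0.526 / total_n)
        assert abs(frac - 0.474) < 3 * se

    def test_records_pass_dataset_validation(self):
        ds = simulate_study(preset_scenario("vicfazio_deltamethrin", seed=8))
        assert validate_dataset(ds).is_valid


class TestPresets:
    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_every_preset_is_a_valid_scenario(self, name):
        cfg = preset_scenario(name, seed=0)
        assert cfg.n_bottles == 4 and cfg.n_per_bottle == 25
        assert cfg.cages_per_distance == 3 and cfg.n_per_cage == 20

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValidationError):
            preset_scenario("nope")

    def test_reference_expected_complete_by_its_diagnostic_time(self):
        cfg = preset_scenario("fogg_deltamethrin")
        for arm in cfg.arms:
            ref = arm.profiles[cfg.reference_strain]
            # technical reference completes by 30 min, formulated by 15 min
            t = 30.0 if arm.treatment.grade is Grade.TECHNICAL else 15.0
            assert ref.expected_mortality_pct(t) > 99.9

    def test_vicfazio_malathion_technical_plateau_near_55(self):
        cfg = preset_scenario("vicfazio_malathion")
        technical = next(a for a in cfg.arms if a.treatment.name == "malathion")
        plateau = technical.profiles["Vic Fazio"].expected_mortality_pct(180.0)
        assert plateau == pytest.approx(55.0, abs=5.0)

    def test_immune_fraction_recovered_from_large_n_plateau(self, rng):
        # end-to-end parameter recovery at n_per_bottle = 1000
        cfg = preset_scenario("vicfazio_malathion", seed=6, n_per_bottle=1000, escape_prob=0.0)
        ds = simulate_study(cfg)
        bottles = [
            b
            for b in ds.bottles
            if b.strain == "Vic Fazio" and b.treatment.name == "malathion"
        ]
        curve = mean_curve(bottles)
        profile = next(
            a for a in cfg.arms if a.treatment.name == "malathion"
        ).profiles["Vic Fazio"]
        expected = profile.expected_mortality_pct(180.0)
        n_total = sum(b.n_introduced for b in bottles)
        binom_se = 100 * np.sqrt(0.25 / n_total)
        assert curve.mean_pct[-1] == pytest.approx(expected, abs=4 * binom_se)
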