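"""RMSE concordance statistic and the bootstrap CI on RMSE differences."""

import math

import numpy as np
import pytest

from bbaconcord import (
    ChemicalTreatment,
    Grade,
    MortalityCurve,
    ValidationError,
    bootstrap_rmse_diff,
    closest_time,
    mean_curve,
    rmse_vs_field,
)
from conftest import DELTAGARD, DELTAMETHRIN, make_bottle, make_cage


def curve_from_values(values, times=None, strain="Fogg Rd", treatment=DELTAMETHRIN):
    times = tuple(times) if times is not None else tuple(range(0, 15 * len(values), 15))
    if times[0] != 0:
        times = (0,) + times[1:]
    return MortalityCurve(
        strain=strain,
        treatment=treatment,
        times=times,
        mean_pct=tuple(float(v) for v in values),
        se_pct=tuple(0.0 for _ in values),
        n_replicates=4,
        n_total=100,
    )


def brute_force_rmse(values, field):
    # independent oracle: explicit sum, no numpy vectorization
    total = 0.0
    for v in values:
        total += (v - field) ** 2
    return math.sqrt(total / len(values))


class TestRmse:
    def test_curve_equal_to_field_has_zero_error(self):
        curve = curve_from_values([60.0] * 15)
        assert rmse_vs_field(curve, 60.0) == 0.0

    def test_three_point_hand_evaluation(self):
        curve = curve_from_values([0, 50, 100], times=(0, 60, 120))
        assert rmse_vs_field(curve, 100.0) == pytest.approx(64.5497224, abs=1e-3)

    def test_matches_brute_force_oracle_on_random_curves(self, rng):
        for _ in range(1000):
            values = np.sort(rng.uniform(0, 100, size=15))
            field = float(rng.uniform(0, 100))
            curve = curve_from_values(values)
            assert rmse_vs_field(curve, field) == pytest.approx(
                brute_force_rmse(values, field), abs=1e-9
            )

    def test_scales_linearly_in_the_deviations(self, rng):
        field = 50.0
        for k in (0.5, 0.9):
            values = np.sort(rng.uniform(0, 100, size=15))
            shrunk = field + k * (values - field)
            curve, curve_k = curve_from_values(values), curve_from_values(shrunk)
            assert rmse_vs_field(curve_k, field) == pytest.approx(
                k * rmse_vs_field(curve, field)
            )

    def test_invariant_to_schedule_order(self, rng):
        values = np.sort(rng.uniform(0, 100, size=15))
        perm = rng.permutation(15)
        assert brute_force_rmse(values[perm], 70.0) == pytest.approx(
            brute_force_rmse(values, 70.0)
        )
        assert rmse_vs_field(curve_from_values(values), 70.0) == pytest.approx(
            brute_force_rmse(values[perm], 70.0)
        )

    def test_t0_exclusion_drops_the_zero_point(self):
        curve = curve_from_values([0, 80, 80], times=(0, 60, 120))
        assert rmse_vs_field(curve, 80.0, include_t0=False) == 0.0
        assert rmse_vs_field(curve, 80.0, include_t0=True) > 0.0


class TestClosestTime:
    def test_exact_hit_returned(self):
        values = [0] * 6 + [95.0] * 9
        curve = curve_from_values(values)
        t, m = closest_time(curve, 95.0)
        assert t == 90 and m == 95.0

    def test_tie_broken_toward_earliest_time(self):
        curve = curve_from_values([0, 90, 100], times=(0, 60, 120))
        assert closest_time(curve, 95.0) == (60, 90.0)

    def test_brute_force_over_random_curves(self, rng):
        for _ in range(200):
            values = np.sort(rng.uniform(0, 100, size=15))
            field = float(rng.uniform(0, 100))
            curve = curve_from_values(values)
            t, m = closest_time(curve, field)
            best = min(abs(v - field) for v in values)
            assert abs(m - field) == pytest.approx(best)
            # earliest among minimizers
            first = next(
                tt for tt, v in zip(curve.times, values) if abs(v - field) == best
            )
            assert t == first


def _arms(rng, n_bottles=4, shift=0):
    a = [
        make_bottle(np.sort(rng.integers(0, 26, size=15)), replicate=str(i))
        for i in range(n_bottles)
    ]
    b = [
        make_bottle(
            np.minimum(25, np.sort(rng.integers(shift, 26, size=15))),
            replicate=str(i),
            treatment=DELTAGARD,
        )
        for i in range(n_bottles)
    ]
    cages = [make_cage(int(k), replicate=str(i)) for i, k in enumerate(rng.integers(10, 21, 9))]
    return a, b, cages


class TestBootstrap:
    def test_identical_arms_are_symmetric_about_zero(self, rng):
        # within-arm resampling is independent, so identical arms yield a
        # difference distribution symmetric about 0, never a significant call
        a, _, cages = _arms(rng)
        b = [
            make_bottle(bot.down_counts, n=bot.n_introduced, replicate=bot.replicate_id,
                        treatment=DELTAGARD)
            for bot in a
        ]
        res = bootstrap_rmse_diff(a, b, cages, n_boot=2000, seed=7)
        assert res.rmse_a == res.rmse_b
        assert res.boot_mean_diff == pytest.approx(0.0, abs=1.0)
        assert res.ci_low < 0 < res.ci_high
        assert not res.significant

    def test_seeded_runs_are_bit_identical(self, rng):
        a, b, cages = _arms(rng)
        r1 = bootstrap_rmse_diff(a, b, cages, n_boot=300, seed=11, keep_diffs=True)
        r2 = bootstrap_rmse_diff(a, b, cages, n_boot=300, seed=11, keep_diffs=True)
        assert r1 == r2
        assert r1.boot_diffs == r2.boot_diffs

    def test_boot_mean_approaches_plugin_difference(self, rng):
        a, b, cages = _arms(rng, shift=8)
        field = float(np.mean([c.mortality_12h_pct for c in cages]))
        plugin = rmse_vs_field(mean_curve(a), field) - rmse_vs_field(mean_curve(b), field)
        res = bootstrap_rmse_diff(a, b, cages, n_boot=10_000, seed=3)
        assert res.boot_mean_diff == pytest.approx(plugin, abs=2.0)
        assert res.rmse_a - res.rmse_b == pytest.approx(plugin, abs=1e-9)

    def test_single_replicate_warns_of_degeneracy(self, rng):
        a, b, cages = _arms(rng)
        with pytest.warns(UserWarning, match="single replicate"):
            bootstrap_rmse_diff(a[:1], b, cages, n_boot=50, seed=1)

    def test_time_point_resampling_unit(self, rng):
        a, b, cages = _arms(rng, shift=8)
        res = bootstrap_rmse_diff(a, b, cages, n_boot=500, seed=5, resample_unit="time_points")
        assert res.resample_unit == "time_points"
        assert res.ci_low <= res.ci_high

    def test_bca_interval_close_to_percentile_for_mild_skew(self, rng):
        a, b, cages = _arms(rng, shift=8)
        pct = bootstrap_rmse_diff(a, b, cages, n_boot=2000, seed=5)
        bca = bootstrap_rmse_diff(a, b, cages, n_boot=2000, seed=5, ci_method="bca")
        assert bca.ci_low <= bca.ci_high
        assert bca.ci_low == pytest.approx(pct.ci_low, abs=6.0)
        assert bca.ci_high == pytest.approx(pct.ci_high, abs=6.0)

    def test_significance_follows_zero_exclusion(self, rng):
        a, b, cages = _arms(rng, shift=15)
        res = bootstrap_rmse_diff(a, b, cages, n_boot=1000, seed=2)
        assert res.significant == (not (res.ci_low <= 0 <= res.ci_high))

    def test_mismatched_strains_rejected(self, rng):
        a, b, cages = _arms(rng)
        b = [
            make_bottle(bot.down_counts, n=bot.n_introduced, strain="Vic Fazio",
                        replicate=bot.replicate_id, treatment=DELTAGARD)
            for bot in b
        ]
        with pytest.raises(ValidationError):
            bootstrap_rmse_diff(a, b, cages, n_boot=10, seed=1)
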