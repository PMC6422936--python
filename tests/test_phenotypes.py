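"""Migration metric definitions: percentages, rates, velocities, classification."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from muc3 import (
    UNSTIMULATED,
    WrongConditionError,
    assign_regions,
    cell_velocity,
    classify_track,
    count_direction_changes,
    decision_ratio,
    percent_migrated_series,
    rate_of_accumulation,
    simulate_experiment,
    spontaneous_fraction,
)
from muc3.phenotypes import UndefinedDenominatorError, _track_path_velocity


def make_track(samples, cell_id=0, dt=2.5, regions=None):
    """Track table from a list of (x, y) per frame."""
    n = len(samples)
    df = pd.DataFrame(
        {
            "cell_id": cell_id,
            "frame": np.arange(n),
            "t_min": np.arange(n) * dt,
            "x_um": [s[0] for s in samples],
            "y_um": [s[1] for s in samples],
        }
    )
    if regions is not None:
        df["region"] = regions
    return df


def make_population(frame_regions, dt=2.5):
    """Population table from per-cell region sequences (positions dummy)."""
    rows = []
    for cid, regions in enumerate(frame_regions):
        for f, reg in enumerate(regions):
            rows.append((cid, f, f * dt, 0.0, 0.0, reg))
    return pd.DataFrame(
        rows, columns=["cell_id", "frame", "t_min", "x_um", "y_um", "region"]
    )


class TestAssignRegions:
    def test_loading_track(self, geometry):
        tr = make_track([(0, 0), (10, 5), (-20, 30)])
        out = assign_regions(tr, geometry)
        assert (out["region"] == "loading").all()

    def test_crossing_into_reservoir(self, geometry):
        row = geometry.channel_rows[3]
        tr = make_track([(940, row), (948, row), (955, row), (980, row)])
        out = assign_regions(tr, geometry)
        assert list(out["region"]) == [
            "channel_fmlp", "channel_fmlp", "reservoir_fmlp", "reservoir_fmlp",
        ]

    def test_mouth_belongs_to_channel_reservoir_mouth_to_reservoir(self, geometry):
        row = geometry.channel_rows[0]
        out = assign_regions(make_track([(50.0, row), (950.0, row)]), geometry)
        assert list(out["region"]) == ["channel_fmlp", "reservoir_fmlp"]

    def test_matches_simulator_ground_truth(self, geometry, fields):
        run = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=100,
                                  duration=150, seed=12)
        recomputed = assign_regions(run.tracks.drop(columns="region"), geometry)
        assert (recomputed["region"] == run.tracks["region"]).all()


class TestPercentMigrated:
    def test_table_formula(self):
        # 12 cells in the reservoir at the last frame, loading average 120
        pop = make_population(
            [["loading"] * 3] * 120 + [["loading", "channel_fmlp", "reservoir_fmlp"]] * 12
        )
        # loading counts per frame: 120 + 12, 120, 120 -> mean 124; adjust to
        # exactly 120 by keeping the 12 migrants out of loading throughout
        pop = make_population(
            [["loading"] * 3] * 120
            + [["channel_fmlp", "channel_fmlp", "reservoir_fmlp"]] * 12
        )
        series = percent_migrated_series(pop, "reservoir_fmlp")
        assert series["percent"].iloc[-1] == pytest.approx(100.0 * 12 / 120)

    def test_no_migration_gives_zero_series(self):
        pop = make_population([["loading"] * 5] * 10)
        series = percent_migrated_series(pop, "reservoir_fmlp")
        assert (series["percent"] == 0.0).all()

    def test_channels_selector_counts_mazes(self):
        pop = make_population(
            [["loading", "channel_fmlp", "maze_fmlp"], ["loading"] * 3]
        )
        series = percent_migrated_series(pop, "channels")
        assert series["percent"].iloc[-1] > 0

    def test_zero_denominator_rejected(self):
        pop = make_population([["channel_fmlp"] * 3] * 4)
        with pytest.raises(UndefinedDenominatorError):
            percent_migrated_series(pop, "reservoir_fmlp")

    def test_reservoir_series_non_decreasing_with_absorbing_reservoirs(
        self, geometry, fields
    ):
        run = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=150,
                                  duration=250, seed=13)
        for sel in ("reservoir_fmlp", "reservoir_ltb4"):
            p = percent_migrated_series(run.tracks, sel)["percent"].to_numpy()
            assert (np.diff(p) >= -1e-12).all()

    def test_scale_invariance_in_n_cells(self, geometry, fields):
        """Expected percentages do not depend on the number of loaded cells."""
        small = [
            percent_migrated_series(
                simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=250,
                                    duration=250, seed=s).tracks,
                "reservoir_fmlp")["percent"].iloc[-1]
            for s in range(6)
        ]
        large = [
            percent_migrated_series(
                simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=500,
                                    duration=250, seed=s).tracks,
                "reservoir_fmlp")["percent"].iloc[-1]
            for s in range(6)
        ]
        assert abs(np.mean(small) - np.mean(large)) < 2.5


class TestRateOfAccumulation:
    def test_linear_rise(self):
        t = np.arange(0, 122.5, 2.5)
        series = pd.DataFrame({"t_min": t, "percent": 20.0 * t / 120.0})
        assert rate_of_accumulation(series) == pytest.approx(10.0)

    def test_constant_series(self):
        t = np.arange(0, 122.5, 2.5)
        series = pd.DataFrame({"t_min": t, "percent": np.full(len(t), 7.0)})
        assert rate_of_accumulation(series) == pytest.approx(0.0, abs=1e-12)

    def test_picks_steepest_window(self):
        t = np.arange(0, 302.5, 2.5)
        p = np.where(t < 120, 0.0, np.where(t < 180, (t - 120) * 0.2, 12.0))
        series = pd.DataFrame({"t_min": t, "percent": p})
        assert rate_of_accumulation(series) == pytest.approx(12.0, rel=0.01)

    def test_too_short_series_rejected(self):
        series = pd.DataFrame({"t_min": [0, 10, 20], "percent": [0, 1, 2]})
        with pytest.raises(ValueError):
            rate_of_accumulation(series, window=60.0)


class TestCellVelocity:
    def test_single_step(self):
        tr = make_track([(0, 0), (25, 0)])
        assert cell_velocity(tr, scope="whole_track") == pytest.approx(10.0)

    def test_stationary(self):
        tr = make_track([(5, 5)] * 4)
        assert cell_velocity(tr, scope="whole_track") == pytest.approx(0.0)

    def test_path_length_not_displacement(self):
        tr = make_track([(0, 0), (25, 0), (0, 0)])
        assert cell_velocity(tr, scope="whole_track") == pytest.approx(10.0)

    def test_time_reversal_invariance(self):
        rng = np.random.default_rng(0)
        pts = list(zip(rng.uniform(0, 100, 20), rng.uniform(0, 100, 20)))
        fwd = cell_velocity(make_track(pts), scope="whole_track")
        rev = cell_velocity(make_track(pts[::-1]), scope="whole_track")
        assert fwd == pytest.approx(rev)

    def test_in_channel_scope_excludes_loading(self):
        regions = ["loading", "channel_fmlp", "channel_fmlp", "channel_fmlp"]
        tr = make_track([(40, 0), (60, 0), (85, 0), (110, 0)], regions=regions)
        # only the two fully in-channel segments count: both 25 um / 2.5 min
        assert cell_velocity(tr, scope="in_channel", side="fmlp") == pytest.approx(10.0)

    def test_fewer_than_two_samples_in_scope(self):
        tr = make_track([(40, 0), (60, 0)], regions=["loading", "channel_fmlp"])
        assert cell_velocity(tr, scope="in_channel") is None

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        pts = list(zip(rng.uniform(0, 50, 15), rng.uniform(0, 50, 15)))
        shifted = [(x + 321.0, y - 77.0) for x, y in pts]
        assert cell_velocity(make_track(pts), scope="whole_track") == pytest.approx(
            cell_velocity(make_track(shifted), scope="whole_track")
        )


def brute_force_direction_changes(xs, ys, threshold):
    """Independent recount: literal loop over retained per-axis steps."""
    total = 0
    for vals in (xs, ys):
        steps = [b - a for a, b in zip(vals, vals[1:])]
        kept = [s for s in steps if abs(s) >= threshold]
        for a, b in zip(kept, kept[1:]):
            if (a > 0) != (b > 0):
                total += 1
    return total


class TestDirectionChanges:
    def test_monotone_track(self):
        tr = make_track([(0, 0), (5, 0), (10, 0), (15, 0)])
        assert count_direction_changes(tr) == 0

    def test_documented_example(self):
        # x: 0 -> 5 -> 2 -> 7 -> 3 with threshold 2: three sign flips
        tr = make_track([(0, 0), (5, 0), (2, 0), (7, 0), (3, 0)])
        assert count_direction_changes(tr, jitter_threshold=2.0) == 3

    def test_jitter_below_threshold_ignored(self):
        tr = make_track([(0, 0), (1.0, 0), (0.5, 0), (1.5, 0), (0.2, 0)])
        assert count_direction_changes(tr, jitter_threshold=2.0) == 0

    def test_short_track(self):
        assert count_direction_changes(make_track([(0, 0), (5, 0)])) == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_on_random_walks(self, seed):
        rng = np.random.default_rng(seed)
        xs = np.cumsum(rng.normal(0, 4, 30))
        ys = np.cumsum(rng.normal(0, 4, 30))
        tr = make_track(list(zip(xs, ys)))
        assert count_direction_changes(tr, 2.0) == brute_force_direction_changes(
            xs, ys, 2.0
        )


class TestClassification:
    def test_straight_run_is_directional_only(self, geometry):
        row = geometry.channel_rows[5]
        pts = [(30, row), (55, row), (300, row), (600, row), (955, row)]
        tr = assign_regions(make_track(pts), geometry)
        label = classify_track(tr, geometry)
        assert label.directional and not label.non_directional and not label.oscillatory

    def test_maze_entry_is_non_directional(self, geometry):
        row = geometry.channel_rows[5]
        rung_x = geometry.rung_positions[0]
        pts = [(30, row), (rung_x, row), (rung_x, row + 40)]
        tr = assign_regions(make_track(pts), geometry)
        label = classify_track(tr, geometry)
        assert label.non_directional

    def test_oscillation_in_channel_not_non_directional(self, geometry):
        row = geometry.channel_rows[5]
        xs = [60, 100, 70, 110, 80, 120, 90]
        tr = assign_regions(make_track([(x, row) for x in xs]), geometry)
        label = classify_track(tr, geometry)
        assert label.oscillatory and not label.non_directional and not label.directional

    def test_never_leaving_loading_is_not_directional(self, geometry):
        tr = assign_regions(make_track([(0, 0)] * 5), geometry)
        assert not classify_track(tr, geometry).directional


class TestDecisionRatioAndSpontaneous:
    def test_equal_percentages(self):
        ratio, defined = decision_ratio(5.0, 5.0)
        assert defined and ratio == 1.0

    def test_zero_denominator(self):
        ratio, defined = decision_ratio(5.0, 0.0)
        assert math.isinf(ratio) and not defined

    def test_both_zero(self):
        ratio, defined = decision_ratio(0.0, 0.0)
        assert math.isnan(ratio) and not defined

    def test_requires_no_chemoattractant_condition(self, geometry, fields):
        run = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=20,
                                  duration=60, seed=1)
        with pytest.raises(WrongConditionError):
            spontaneous_fraction(run)

    def test_no_motility_gives_zero(self, geometry):
        preset = UNSTIMULATED.with_(spontaneous_fraction=0.0)
        run = simulate_experiment(preset, geometry, None, n_cells=40,
                                  duration=100, seed=2)
        assert spontaneous_fraction(run) == 0.0
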