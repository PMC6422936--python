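"""Agent-based track generator: determinism, conservation, bias response."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from muc3 import (
    ConfigurationError,
    UNSTIMULATED,
    percent_migrated_series,
    simulate_experiment,
)


def _symmetric_preset():
    return UNSTIMULATED.with_(
        bias_strength={"fmlp": 1.8, "ltb4": 1.8},
        speed_mean={"fmlp": 10.0, "ltb4": 10.0},
        speed_sd={"fmlp": 3.0, "ltb4": 3.0},
        motile_fraction=0.3,
    )


class TestContracts:
    def test_deterministic_given_preset_and_seed(self, geometry, fields):
        a = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=60,
                                duration=60, seed=42)
        b = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=60,
                                duration=60, seed=42)
        pd.testing.assert_frame_equal(a.tracks, b.tracks)

    def test_seed_changes_tracks(self, geometry, fields):
        a = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=60,
                                duration=60, seed=1)
        b = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=60,
                                duration=60, seed=2)
        assert not a.tracks[["x_um", "y_um"]].equals(b.tracks[["x_um", "y_um"]])

    def test_cell_count_conserved_every_frame(self, geometry, fields):
        run = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=80,
                                  duration=120, seed=3)
        per_frame = run.tracks.groupby("frame")["cell_id"].nunique()
        assert (per_frame == 80).all()
        # and every sample carries a valid region label
        assert run.tracks["region"].isin([
            "loading", "channel_fmlp", "channel_ltb4", "maze_fmlp",
            "maze_ltb4", "reservoir_fmlp", "reservoir_ltb4",
        ]).all()

    def test_time_grid_and_step_bound(self, geometry, fields):
        run = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=50,
                                  duration=100, seed=5)
        for _, tr in run.tracks.groupby("cell_id"):
            t = tr["t_min"].to_numpy()
            assert np.allclose(np.diff(t), 2.5)
        # consecutive positions within speed_max * dt
        sd = max(UNSTIMULATED.speed_sd.values())
        vmax = max(UNSTIMULATED.speed_mean.values()) + 6 * sd
        steps = (
            run.tracks.sort_values(["cell_id", "frame"])
            .groupby("cell_id")[["x_um", "y_um"]]
            .diff()
            .dropna()
        )
        lengths = np.hypot(steps["x_um"], steps["y_um"])
        assert lengths.max() <= vmax * 2.5 + 1e-6

    def test_positions_inside_device(self, geometry, fields):
        run = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=50,
                                  duration=100, seed=6)
        # locate_many raises if any sample falls outside every region
        geometry.locate_many(run.tracks["x_um"].to_numpy(),
                             run.tracks["y_um"].to_numpy())

    def test_invalid_inputs(self, geometry, fields):
        with pytest.raises(ValueError):
            simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=0)
        with pytest.raises(ConfigurationError):
            simulate_experiment(UNSTIMULATED, geometry, None,
                                condition="dual_gradient", n_cells=10)
        with pytest.raises(ValueError):
            simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=10,
                                duration=100, dt=3.0)


class TestPhenotypeLimits:
    def test_no_motile_cells_never_migrate(self, geometry, fields):
        preset = UNSTIMULATED.with_(motile_fraction=0.0)
        run = simulate_experiment(preset, geometry, fields, n_cells=60,
                                  duration=120, seed=7)
        assert (run.tracks["region"] == "loading").all()
        series = percent_migrated_series(run.tracks, "reservoir_fmlp")
        assert (series["percent"] == 0.0).all()

    def test_strong_bias_absorbs_all_channel_entrants(self, geometry, fields):
        preset = UNSTIMULATED.with_(
            bias_strength={"fmlp": 50.0, "ltb4": 0.0},
            reversal_probability=0.0,
            maze_entry_weight=0.0,
            motile_fraction=1.0,
            activation_rate=0.05,
        )
        run = simulate_experiment(preset, geometry, fields, n_cells=60,
                                  duration=300, seed=8)
        tr = run.tracks
        entered_early = tr[(tr["region"] == "channel_fmlp") & (tr["t_min"] < 200)][
            "cell_id"
        ].unique()
        final = tr[tr["frame"] == tr["frame"].max()].set_index("cell_id")["region"]
        assert len(entered_early) > 0
        assert (final.loc[entered_early] == "reservoir_fmlp").all()

    def test_reservoirs_absorbing(self, geometry, fields):
        run = simulate_experiment(UNSTIMULATED, geometry, fields, n_cells=120,
                                  duration=300, seed=9)
        tr = run.tracks.sort_values(["cell_id", "frame"])
        for _, t in tr.groupby("cell_id"):
            regions = t["region"].to_numpy()
            in_res = np.isin(regions, ["reservoir_fmlp", "reservoir_ltb4"])
            if in_res.any():
                first = int(np.argmax(in_res))
                assert in_res[first:].all()


class TestStatisticalBehaviour:
    def test_symmetric_device_gives_equal_sides(self, geometry):
        """With identical attractants and a symmetric preset, neither side
        is preferred beyond sampling noise (20 seeds)."""
        from muc3 import ChemoattractantSpec, solve_channel_diffusion

        spec = ChemoattractantSpec("same", 400.0, 10.0)
        f = solve_channel_diffusion(spec, geometry, t_end=180)
        sym_fields = {"fmlp": f, "ltb4": f}
        preset = _symmetric_preset()
        diffs_f, diffs_l = [], []
        for seed in range(20):
            run = simulate_experiment(preset, geometry, sym_fields, n_cells=150,
                                      duration=180, seed=seed)
            pf = percent_migrated_series(run.tracks, "reservoir_fmlp")["percent"].iloc[-1]
            pl = percent_migrated_series(run.tracks, "reservoir_ltb4")["percent"].iloc[-1]
            diffs_f.append(pf)
            diffs_l.append(pl)
        d = np.array(diffs_f) - np.array(diffs_l)
        se = d.std(ddof=1) / np.sqrt(len(d))
        assert abs(d.mean()) < 2 * se + 1e-12

    def test_percent_migrated_monotone_in_bias(self, geometry, fields):
        """Endpoint percent toward fMLP increases with fMLP bias strength
        (Spearman rho > 0.9 over a 6-point sweep, 10 seeds each)."""
        biases = [0.0, 0.4, 0.8, 1.4, 2.2, 3.5]
        means = []
        for b in biases:
            preset = UNSTIMULATED.with_(
                bias_strength={"fmlp": b, "ltb4": 1.0}, motile_fraction=0.4
            )
            vals = [
                percent_migrated_series(
                    simulate_experiment(preset, geometry, fields, n_cells=120,
                                        duration=200, seed=s).tracks,
                    "reservoir_fmlp",
                )["percent"].iloc[-1]
                for s in range(10)
            ]
            means.append(np.mean(vals))
        rho, _ = spearmanr(biases, means)
        assert rho > 0.9

    def test_maze_entry_scales_with_weight(self, geometry, fields):
        lost = []
        for w in (0.0, 2.0):
            preset = UNSTIMULATED.with_(maze_entry_weight=w, motile_fraction=0.5)
            run = simulate_experiment(preset, geometry, fields, n_cells=150,
                                      duration=200, seed=11)
            lost.append((run.tracks["region"].str.startswith("maze")).sum())
        assert lost[0] == 0
        assert lost[1] > 0
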