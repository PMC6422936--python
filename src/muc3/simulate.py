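"""Agent-based generator of single-cell migration tracks on the chip.

Each cell is a biased persistent random walker. Cells start uniformly
scattered in the central loading channel (with a small contact-exclusion
spacing); a motile cell commits to migration at a constant rate, picks a
side with odds proportional to that side's ``bias_strength`` times its
normalised gradient steepness, walks to the nearest channel mouth and moves
along the channel with speed drawn around its cell-specific base speed.
Direction persists between reorientation events (rate
``reversal_probability`` per step); at a reorientation the new heading
points toward the reservoir with probability
``1/2 (1 + tanh(bias * g))`` where ``g`` is the local normalised gradient
steepness (1 for a fully formed linear channel gradient, 10-fold smaller in
maze rungs, 0 without chemoattractant). Crossing a channel-maze junction
may divert the cell into a ladder rung; reservoirs are absorbing.

Tracks are emitted as a tidy table with one row per cell per frame at the
imaging interval (2.5 min by default, 121 frames over 5 h), with the
simulator's own ground-truth region label per sample.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DeviceGeometry
from .gradient import GradientField, gradient_slope
from .presets import PrimingPreset

TRACK_COLUMNS = ("cell_id", "frame", "t_min", "x_um", "y_um", "region")

# cell states
_IDLE, _TO_MOUTH, _CHANNEL, _MAZE, _RESERVOIR = 0, 1, 2, 3, 4


class ConfigurationError(ValueError):
    pass


@dataclass
class ExperimentRun:
    """One simulated chip experiment: a preset, a condition and its tracks."""

    preset: PrimingPreset
    geometry: DeviceGeometry
    condition: str  # "dual_gradient" | "no_chemoattractant"
    n_cells: int
    duration: float  # min
    dt: float  # min
    seed: int
    tracks: pd.DataFrame  # TRACK_COLUMNS

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt)) + 1

    def provenance(self) -> dict:
        h = hashlib.sha256(
            json.dumps(self.preset.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]
        from . import __version__

        return {
            "muc3_version": __version__,
            "preset": self.preset.label,
            "preset_hash": h,
            "condition": self.condition,
            "n_cells": self.n_cells,
            "duration_min": self.duration,
            "dt_min": self.dt,
            "seed": self.seed,
        }


def _normalised_steepness(field: GradientField, frame_times: np.ndarray) -> np.ndarray:
    """|slope| * L / c0 per frame: 1 for the fully formed linear profile."""
    c0 = field.reservoir_concentration
    if c0 == 0:
        return np.zeros_like(frame_times)
    L = field.channel_length
    tmax = field.t_grid[-1]
    out = np.empty_like(frame_times)
    for i, t in enumerate(frame_times):
        out[i] = abs(gradient_slope(field, min(t, tmax))) * L / c0
    return out


def _place_cells(
    rng: np.random.Generator,
    geometry: DeviceGeometry,
    n_cells: int,
    min_spacing: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform placement in the loading channel with contact exclusion."""
    hw = geometry.loading_half_width - 5.0
    hh = geometry.half_height - 5.0
    xs = np.empty(n_cells)
    ys = np.empty(n_cells)
    for i in range(n_cells):
        for _ in range(60):
            cx = rng.uniform(-hw, hw)
            cy = rng.uniform(-hh, hh)
            if i == 0:
                break
            d2 = (xs[:i] - cx) ** 2 + (ys[:i] - cy) ** 2
            if d2.min() >= min_spacing**2:
                break
        xs[i] = cx
        ys[i] = cy
    return xs, ys


def simulate_experiment(
    preset: PrimingPreset,
    geometry: DeviceGeometry | None = None,
    fields: dict[str, GradientField] | None = None,
    n_cells: int = 500,
    duration: float = 300.0,
    dt: float = 2.5,
    seed: int | None = None,
    condition: str | None = None,
    min_spacing: float = 8.0,
) -> ExperimentRun:
    """Simulate one chip experiment and return its track table.

    Parameters
    ----------
    preset
        Priming state; all behavioural parameters live here.
    fields
        ``{"fmlp": GradientField, "ltb4": GradientField}`` for the
        dual-gradient condition, or None for migration without
        chemoattractant.
    n_cells, duration, dt, seed
        Population size, experiment length (min), sampling interval (min,
        matching the imaging interval) and RNG seed. ``dt`` must divide
        ``duration``.

    Returns
    -------
    ExperimentRun
        With ``tracks`` holding one row per cell per frame.
    """
    geometry = geometry or DeviceGeometry()
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    n_steps = duration / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("dt must divide duration")
    n_steps = int(round(n_steps))
    if condition is None:
        condition = "dual_gradient" if fields else "no_chemoattractant"
    if condition == "dual_gradient" and not fields:
        raise ConfigurationError("dual_gradient condition requires gradient fields")
    if condition not in ("dual_gradient", "no_chemoattractant"):
        raise ValueError(f"unknown condition {condition!r}")
    if seed is None:
        seed = preset.rng_seed if preset.rng_seed is not None else 0

    rng = np.random.default_rng(seed)
    frame_times = np.arange(n_steps + 1) * dt

    # per-frame normalised gradient steepness per side
    g_norm = {s: np.zeros(n_steps + 1) for s in ("fmlp", "ltb4")}
    if condition == "dual_gradient":
        for s in ("fmlp", "ltb4"):
            if s not in fields:
                raise ConfigurationError(f"missing gradient field for side {s!r}")
            g_norm[s] = _normalised_steepness(fields[s], frame_times)

    rows = geometry.channel_rows
    n_rows = len(rows)
    hw = geometry.channel_width / 2.0
    mouth = geometry.mouth_x
    res_x = geometry.reservoir_x
    rungs = geometry.rung_positions
    atten = geometry.maze_attenuation
    q_junction = min(1.0, preset.maze_entry_weight / (1.0 + atten))

    motile_p = (
        preset.motile_fraction
        if condition == "dual_gradient"
        else preset.spontaneous_fraction
    )
    p_act = 1.0 - np.exp(-preset.activation_rate * dt)
    bias = preset.bias_strength
    cf = preset.speed_cell_fraction
    step_frac = float(np.sqrt(max(0.0, 1.0 - cf**2)))

    # state arrays
    x, y = _place_cells(rng, geometry, n_cells, min_spacing)
    motile = rng.random(n_cells) < motile_p
    state = np.full(n_cells, _IDLE, dtype=np.int8)
    side = np.zeros(n_cells, dtype=np.int8)  # +1 fmlp, -1 ltb4
    chan = np.zeros(n_cells, dtype=np.int64)
    dirn = np.ones(n_cells, dtype=np.int8)  # +1 outward (toward reservoir)
    base = np.zeros(n_cells)
    speed_sd_step = np.zeros(n_cells)
    speed_max = np.zeros(n_cells)
    # maze bookkeeping
    mz_origin = np.zeros(n_cells, dtype=np.int64)
    mz_target = np.zeros(n_cells, dtype=np.int64)
    mz_sign = np.zeros(n_cells, dtype=np.int8)  # sign of (y_target - y_origin)
    # reservoir parking
    park_x = np.zeros(n_cells)
    park_vy = np.zeros(n_cells)

    X = np.empty((n_steps + 1, n_cells))
    Y = np.empty((n_steps + 1, n_cells))
    S = np.empty((n_steps + 1, n_cells), dtype=np.int8)
    SD = np.empty((n_steps + 1, n_cells), dtype=np.int8)
    X[0], Y[0], S[0], SD[0] = x, y, state, side

    side_key = {1: "fmlp", -1: "ltb4"}

    for k in range(1, n_steps + 1):
        gk = {s: g_norm[s][k - 1] for s in ("fmlp", "ltb4")}
        p_fwd = {
            s: 0.5 * (1.0 + np.tanh(bias[s] * gk[s])) for s in ("fmlp", "ltb4")
        }
        p_maze_fwd = {
            s: 0.5 * (1.0 + np.tanh(bias[s] * gk[s] / atten)) for s in ("fmlp", "ltb4")
        }

        # -- pre-draw randomness for every cell (mask-independent) ----------
        u_act = rng.random(n_cells)
        u_side = rng.random(n_cells)
        z_base = rng.standard_normal(n_cells)
        z_step = rng.standard_normal(n_cells)
        u_reo = rng.random(n_cells)
        u_head = rng.random(n_cells)
        u_junc = rng.random(n_cells)
        u_rung = rng.random(n_cells)
        u_park = rng.random(n_cells)
        z_park = rng.standard_normal(n_cells)

        # -- activation of idle motile cells ---------------------------------
        w_f = bias["fmlp"] * gk["fmlp"]
        w_l = bias["ltb4"] * gk["ltb4"]
        if condition == "no_chemoattractant":
            p_side_f = 0.5
            any_drive = True
        else:
            tot = w_f + w_l
            p_side_f = w_f / tot if tot > 0 else 0.5
            any_drive = tot > 0
        act = (state == _IDLE) & motile & (u_act < p_act) & any_drive
        if act.any():
            new_side = np.where(u_side[act] < p_side_f, 1, -1).astype(np.int8)
            side[act] = new_side
            chan[act] = np.abs(y[act, None] - rows).argmin(axis=1)
            for s_val, s_name in ((1, "fmlp"), (-1, "ltb4")):
                m = act.copy()
                m[act] = new_side == s_val
                mu = preset.speed_mean[s_name]
                sd = preset.speed_sd[s_name]
                base[m] = np.clip(mu + cf * sd * z_base[m], 0.2, mu + 6 * sd)
                speed_sd_step[m] = step_frac * sd
                speed_max[m] = mu + 6 * sd
            state[act] = _TO_MOUTH

        step_speed = np.clip(np.abs(base + speed_sd_step * z_step), 0.0, speed_max)
        step_len = step_speed * dt

        # -- walk toward the chosen channel mouth ----------------------------
        tm = state == _TO_MOUTH
        if tm.any():
            tx = side[tm] * mouth
            ty = rows[chan[tm]]
            ddx = tx - x[tm]
            ddy = ty - y[tm]
            dist = np.hypot(ddx, ddy)
            L = step_len[tm]
            arrive = L >= dist
            frac = np.where(arrive, 1.0, np.where(dist > 0, L / np.maximum(dist, 1e-12), 1.0))
            x[tm] = x[tm] + frac * ddx
            y[tm] = y[tm] + frac * ddy
            idx = np.flatnonzero(tm)[arrive]
            state[idx] = _CHANNEL
            x[idx] = side[idx] * mouth
            y[idx] = rows[chan[idx]]
            dirn[idx] = 1

        # -- channel dynamics -------------------------------------------------
        ch = state == _CHANNEL
        if ch.any():
            # reorientation events
            for s_val, s_name in ((1, "fmlp"), (-1, "ltb4")):
                m = ch & (side == s_val) & (u_reo < preset.reversal_probability)
                dirn[m] = np.where(u_head[m] < p_fwd[s_name], 1, -1)
            a0 = np.abs(x[ch])
            a1 = a0 + dirn[ch] * step_len[ch]

            # junction crossings (before any reservoir/loading exit)
            lo = np.minimum(a0, np.minimum(a1, res_x))
            hi = np.minimum(np.maximum(a0, a1), res_x)
            crossed = (rungs[None, :] > lo[:, None]) & (rungs[None, :] <= hi[:, None])
            n_crossed = crossed.sum(axis=1)
            p_enter = 1.0 - (1.0 - q_junction) ** n_crossed
            enter = (u_junc[ch] < p_enter) & (n_crossed > 0)

            idx_ch = np.flatnonzero(ch)
            idx_mz = idx_ch[enter]
            if idx_mz.size:
                # first junction crossed in the direction of motion
                cm = crossed[enter]
                fwd = dirn[idx_mz] > 0
                first = np.where(
                    fwd,
                    cm.argmax(axis=1),
                    cm.shape[1] - 1 - cm[:, ::-1].argmax(axis=1),
                )
                jx = rungs[first]
                x[idx_mz] = side[idx_mz] * jx
                origin = chan[idx_mz]
                up_ok = origin < n_rows - 1
                down_ok = origin > 0
                go_up = np.where(
                    up_ok & down_ok, u_rung[idx_mz] < 0.5, up_ok
                )
                target = np.where(go_up, origin + 1, origin - 1)
                mz_origin[idx_mz] = origin
                mz_target[idx_mz] = target
                mz_sign[idx_mz] = np.where(go_up, 1, -1)
                y[idx_mz] = rows[origin]
                dirn[idx_mz] = 1  # progress toward target rung end
                state[idx_mz] = _MAZE

            # the rest advance / exit
            adv = enter.copy()
            np.logical_not(adv, out=adv)
            idx_adv = idx_ch[adv]
            a1_adv = a1[adv]
            absorbed = a1_adv >= res_x
            back = a1_adv < mouth
            stay = ~(absorbed | back)
            x[idx_adv[stay]] = side[idx_adv[stay]] * a1_adv[stay]
            ia = idx_adv[absorbed]
            state[ia] = _RESERVOIR
            x[ia] = side[ia] * (res_x + 5.0)
            # each arrived cell settles toward its own spot in the reservoir
            park_x[ia] = res_x + 15.0 + u_park[ia] * (geometry.reservoir_depth - 35.0)
            park_vy[ia] = 1.2 * np.tanh(z_park[ia])
            ib = idx_adv[back]
            state[ib] = _IDLE
            x[ib] = side[ib] * (mouth - 5.0)
            side[ib] = 0

        # -- reservoir settling ----------------------------------------------
        # arrived cells drift monotonically to a per-cell parking spot so
        # co-arriving cells do not pile onto one rendered pixel; motion is
        # never direction-reversing, so it cannot register as oscillation
        rs = state == _RESERVOIR
        if rs.any():
            ax_rs = np.abs(x[rs])
            adv_rs = np.minimum(3.5, np.maximum(0.0, park_x[rs] - ax_rs))
            x[rs] = side[rs] * (ax_rs + adv_rs)
            moving = adv_rs > 0
            y_rs = y[rs]
            y_rs[moving] = np.clip(
                y_rs[moving] + park_vy[rs][moving],
                -geometry.half_height + 10.0,
                geometry.half_height - 10.0,
            )
            y[rs] = y_rs

        # -- maze dynamics ----------------------------------------------------
        mz = state == _MAZE
        if mz.any():
            for s_val, s_name in ((1, "fmlp"), (-1, "ltb4")):
                m = mz & (side == s_val) & (u_reo < preset.reversal_probability)
                dirn[m] = np.where(u_head[m] < p_maze_fwd[s_name], 1, -1)
            dy = dirn[mz] * mz_sign[mz] * step_len[mz]
            y_new = y[mz] + dy
            y_t = rows[mz_target[mz]]
            y_o = rows[mz_origin[mz]]
            reach_t = np.abs(y_new - y_t) <= hw
            # moving toward the target can overshoot past its centreline
            reach_t |= mz_sign[mz] * (y_new - y_t) > 0
            reach_o = (~reach_t) & (
                (np.abs(y_new - y_o) <= hw) | (mz_sign[mz] * (y_new - y_o) < 0)
            )
            idx_mz = np.flatnonzero(mz)
            it = idx_mz[reach_t]
            y_new[reach_t] = rows[mz_target[it]]
            chan[it] = mz_target[it]
            io = idx_mz[reach_o]
            y_new[reach_o] = rows[mz_origin[io]]
            chan[io] = mz_origin[io]
            rejoin = reach_t | reach_o
            ir = idx_mz[rejoin]
            state[ir] = _CHANNEL
            for s_val, s_name in ((1, "fmlp"), (-1, "ltb4")):
                m = np.zeros(n_cells, dtype=bool)
                m[ir] = side[ir] == s_val
                dirn[m] = np.where(u_head[m] < p_fwd[s_name], 1, -1)
            y[mz] = y_new

        X[k], Y[k], S[k], SD[k] = x, y, state, side

    # -- assemble the track table --------------------------------------------
    region_code = np.empty((n_steps + 1, n_cells), dtype=object)
    region_code[(S == _IDLE) | (S == _TO_MOUTH)] = "loading"
    for s_val, s_name in ((1, "fmlp"), (-1, "ltb4")):
        region_code[(S == _CHANNEL) & (SD == s_val)] = f"channel_{s_name}"
        region_code[(S == _MAZE) & (SD == s_val)] = f"maze_{s_name}"
        region_code[(S == _RESERVOIR) & (SD == s_val)] = f"reservoir_{s_name}"

    frames = np.repeat(np.arange(n_steps + 1), n_cells)
    cells = np.tile(np.arange(n_cells), n_steps + 1)
    tracks = pd.DataFrame(
        {
            "cell_id": cells,
            "frame": frames,
            "t_min": frames * dt,
            "x_um": X.ravel(),
            "y_um": Y.ravel(),
            "region": region_code.ravel().astype(str),
        }
    ).sort_values(["cell_id", "frame"], kind="stable", ignore_index=True)

    return ExperimentRun(
        preset=preset,
        geometry=geometry,
        condition=condition,
        n_cells=n_cells,
        duration=duration,
        dt=dt,
        seed=seed,
        tracks=tracks,
    )
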