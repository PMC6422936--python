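"""Migration phenotype metrics computed from single-cell track tables.

All functions consume tidy track tables (one row per cell per frame with
columns ``cell_id, frame, t_min, x_um, y_um[, region]``) and implement the
chip's standard read-outs:

* percent migrated over time — cells in a chemoattractant reservoir (or in
  the migration channels) at each frame, divided by the time-averaged
  loading-channel count over the whole experiment, x100;
* rate of accumulation — the steepest ordinary-least-squares slope over any
  1-h sliding window of the percent-migrated series, in %/h;
* single-cell velocity — path length over elapsed time, by default over the
  in-channel (channel + maze) portion of the track;
* direction-change counting and the oscillatory (>= 3 changes in x or y),
  non-directional (entered a maze rung) and directional classifications;
* the decision ratio (endpoint percent toward fMLP over LTB4) and the
  spontaneous-migration fraction for chemoattractant-free runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import DeviceGeometry
from .simulate import ExperimentRun

RESERVOIR_SELECTORS = {
    "reservoir_fmlp": ("reservoir_fmlp",),
    "reservoir_ltb4": ("reservoir_ltb4",),
    "channels": ("channel_fmlp", "channel_ltb4", "maze_fmlp", "maze_ltb4"),
    "channels_fmlp": ("channel_fmlp", "maze_fmlp"),
    "channels_ltb4": ("channel_ltb4", "maze_ltb4"),
}

IN_CHANNEL_REGIONS = {
    "fmlp": ("channel_fmlp", "maze_fmlp"),
    "ltb4": ("channel_ltb4", "maze_ltb4"),
}


class UndefinedDenominatorError(ValueError):
    pass


class WrongConditionError(ValueError):
    pass


@dataclass(frozen=True)
class ClassificationLabel:
    """Non-exclusive per-track flags."""

    directional: bool
    non_directional: bool
    oscillatory: bool


@dataclass
class MigrationMetrics:
    """Per-condition summary of every chip read-out."""

    percent_migrated: dict[str, pd.DataFrame]  # selector -> (t_min, percent)
    rate_of_accumulation: dict[str, float]  # reservoir -> %/h
    velocities: dict[str, pd.DataFrame]  # side -> (cell_id, velocity)
    n_lost: dict[str, int]
    n_oscillatory: dict[str, int]
    decision_ratio: float
    decision_ratio_defined: bool = True
    spontaneous_percent: float | None = None

    def endpoint_percent(self, selector: str) -> float:
        s = self.percent_migrated[selector]
        return float(s["percent"].iloc[-1])


def assign_regions(tracks: pd.DataFrame, geometry: DeviceGeometry) -> pd.DataFrame:
    """Label every sample with its containing device region.

    Returns a copy with a (re)computed ``region`` column; positions outside
    the device raise :class:`~muc3.geometry.OutOfDomainError`.
    """
    out = tracks.copy()
    out["region"] = geometry.locate_many(
        out["x_um"].to_numpy(), out["y_um"].to_numpy()
    )
    return out


def _require_regions(tracks: pd.DataFrame) -> pd.DataFrame:
    if "region" not in tracks.columns:
        raise ValueError("tracks need a 'region' column; run assign_regions first")
    return tracks


def percent_migrated_series(
    tracks: pd.DataFrame, selector: str = "reservoir_fmlp"
) -> pd.DataFrame:
    """Percent-migrated time series for a region selector.

    Per frame: number of cells inside the selected regions divided by the
    *time-averaged* number of cells in the loading channel over the whole
    experiment, x100. Raises when that denominator is zero.
    """
    _require_regions(tracks)
    if selector not in RESERVOIR_SELECTORS:
        raise KeyError(f"unknown selector {selector!r}")
    if tracks.empty:
        raise ValueError("need at least one track")
    regions = RESERVOIR_SELECTORS[selector]
    by_frame = tracks.groupby("frame", sort=True)
    loading_mean = (
        tracks["region"].eq("loading").groupby(tracks["frame"]).sum().mean()
    )
    if loading_mean == 0:
        raise UndefinedDenominatorError(
            "time-averaged loading-channel count is zero"
        )
    counts = (
        tracks["region"].isin(regions).groupby(tracks["frame"]).sum().sort_index()
    )
    t = by_frame["t_min"].first().sort_index()
    return pd.DataFrame(
        {"t_min": t.to_numpy(), "percent": 100.0 * counts.to_numpy() / loading_mean}
    )


def rate_of_accumulation(series: pd.DataFrame, window: float = 60.0) -> float:
    """Steepest OLS slope over any sliding window of length ``window`` min,
    expressed in % per hour."""
    t = series["t_min"].to_numpy(dtype=float)
    p = series["percent"].to_numpy(dtype=float)
    if t[-1] - t[0] < window:
        raise ValueError(f"series spans {t[-1] - t[0]} min, shorter than window")
    best = -math.inf
    n = len(t)
    j = 0
    for i in range(n):
        # frame-aligned window [t_i, t_i + window]
        while j < n - 1 and t[j + 1] <= t[i] + window + 1e-9:
            j += 1
        if t[j] - t[i] < window - 1e-9:
            continue
        tt = t[i : j + 1]
        pp = p[i : j + 1]
        slope = np.polyfit(tt, pp, 1)[0]
        best = max(best, slope)
    return float(best * 60.0)


def _track_path_velocity(track: pd.DataFrame, scope_regions=None) -> float | None:
    """Path length / elapsed time over in-scope samples; None if < 2 samples.

    Only segments between consecutive frames with both endpoints in scope
    contribute.
    """
    tr = track.sort_values("frame")
    if scope_regions is not None:
        in_scope = tr["region"].isin(scope_regions).to_numpy()
    else:
        in_scope = np.ones(len(tr), dtype=bool)
    if in_scope.sum() < 2:
        return None
    xx = tr["x_um"].to_numpy()
    yy = tr["y_um"].to_numpy()
    ff = tr["frame"].to_numpy()
    tt = tr["t_min"].to_numpy()
    seg_ok = in_scope[:-1] & in_scope[1:] & (np.diff(ff) == 1)
    if not seg_ok.any():
        return None
    seg_len = np.hypot(np.diff(xx), np.diff(yy))[seg_ok]
    seg_dt = np.diff(tt)[seg_ok]
    return float(seg_len.sum() / seg_dt.sum())


def cell_velocity(track: pd.DataFrame, scope: str = "in_channel", side: str | None = None):
    """Velocity of one cell's track (um/min): distance travelled / time.

    ``scope="in_channel"`` restricts to samples labelled channel or maze
    (optionally on one ``side``); ``scope="whole_track"`` uses every sample.
    Returns None when fewer than two samples fall in scope (the cell is
    excluded from population summaries).
    """
    if scope == "whole_track":
        return _track_path_velocity(track)
    if scope != "in_channel":
        raise ValueError(f"unknown scope {scope!r}")
    _require_regions(track)
    if side is None:
        regions = IN_CHANNEL_REGIONS["fmlp"] + IN_CHANNEL_REGIONS["ltb4"]
    else:
        regions = IN_CHANNEL_REGIONS[side]
    return _track_path_velocity(track, regions)


def velocities_by_side(tracks: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-cell in-channel velocities pooled by attractant side."""
    _require_regions(tracks)
    out = {}
    for s in ("fmlp", "ltb4"):
        vals = []
        for cid, tr in tracks.groupby("cell_id"):
            v = cell_velocity(tr, scope="in_channel", side=s)
            if v is not None:
                vals.append((cid, v))
        out[s] = pd.DataFrame(vals, columns=["cell_id", "velocity_um_min"])
    return out


def count_direction_changes(track: pd.DataFrame, jitter_threshold: float = 2.0) -> int:
    """Direction changes in x plus direction changes in y.

    Per axis, steps smaller than ``jitter_threshold`` are ignored for that
    axis; a change is a sign flip between consecutive retained steps. Tracks
    with fewer than three samples return 0.
    """
    tr = track.sort_values("frame")
    if len(tr) < 3:
        return 0
    total = 0
    for col in ("x_um", "y_um"):
        steps = np.diff(tr[col].to_numpy())
        kept = steps[np.abs(steps) >= jitter_threshold]
        if len(kept) >= 2:
            total += int((np.sign(kept[:-1]) != np.sign(kept[1:])).sum())
    return total


def classify_track(
    track: pd.DataFrame,
    geometry: DeviceGeometry | None = None,
    jitter_threshold: float = 2.0,
) -> ClassificationLabel:
    """Directional / non-directional (maze) / oscillatory flags for a track.

    The flags are non-exclusive: a cell is *non-directional* if any sample
    lies in a maze rung, *oscillatory* if it changed direction >= 3 times,
    and *directional* if it left the loading channel and neither other flag
    is set.
    """
    _require_regions(track)
    regions = track["region"]
    non_directional = regions.str.startswith("maze").any()
    oscillatory = count_direction_changes(track, jitter_threshold) >= 3
    left_loading = (~regions.eq("loading")).any()
    directional = bool(left_loading and not non_directional and not oscillatory)
    return ClassificationLabel(
        directional=directional,
        non_directional=bool(non_directional),
        oscillatory=bool(oscillatory),
    )


def classification_counts(
    tracks: pd.DataFrame, jitter_threshold: float = 2.0
) -> dict[str, dict[str, int]]:
    """Lost (maze-entering) and oscillatory counts per attractant side.

    A track is attributed to the side whose channels/mazes/reservoir it
    visited; oscillatory counts are restricted to cells that migrated (left
    the loading channel), matching how tracks are scored on the chip.
    """
    _require_regions(tracks)
    out = {s: {"lost": 0, "oscillatory": 0} for s in ("fmlp", "ltb4")}
    for _, tr in tracks.groupby("cell_id"):
        regions = set(tr["region"])
        for s in ("fmlp", "ltb4"):
            visited = any(r.endswith(s) for r in regions)
            if not visited:
                continue
            if any(r == f"maze_{s}" for r in regions):
                out[s]["lost"] += 1
            if count_direction_changes(tr, jitter_threshold) >= 3:
                out[s]["oscillatory"] += 1
    return out


def decision_ratio(percent_fmlp: float, percent_ltb4: float) -> tuple[float, bool]:
    """Endpoint percent toward fMLP over percent toward LTB4.

    Returns ``(ratio, defined)``; an empty LTB4 reservoir yields
    ``(inf, False)`` and two empty reservoirs ``(nan, False)``.
    """
    if percent_ltb4 == 0.0:
        if percent_fmlp == 0.0:
            return (math.nan, False)
        return (math.inf, False)
    return (percent_fmlp / percent_ltb4, True)


def spontaneous_fraction(run: ExperimentRun) -> float:
    """Percent of cells that ever entered a migration channel in a
    chemoattractant-free run (percent-migrated denominator, reported at the
    end of the experiment)."""
    if run.condition != "no_chemoattractant":
        raise WrongConditionError(
            "spontaneous migration is defined for the no_chemoattractant condition"
        )
    tracks = _require_regions(run.tracks)
    loading_mean = (
        tracks["region"].eq("loading").groupby(tracks["frame"]).sum().mean()
    )
    if loading_mean == 0:
        raise UndefinedDenominatorError("time-averaged loading-channel count is zero")
    chan_regions = RESERVOIR_SELECTORS["channels"] + (
        "reservoir_fmlp",
        "reservoir_ltb4",
    )
    entered = (
        tracks["region"].isin(chan_regions).groupby(tracks["cell_id"]).any().sum()
    )
    return float(100.0 * entered / loading_mean)


def compute_metrics(
    run: ExperimentRun, window: float = 60.0, jitter_threshold: float = 2.0
) -> MigrationMetrics:
    """All chip metrics for one experiment run."""
    tracks = _require_regions(run.tracks)
    series = {
        sel: percent_migrated_series(tracks, sel)
        for sel in ("reservoir_fmlp", "reservoir_ltb4", "channels")
    }
    rates = {
        sel: rate_of_accumulation(series[sel], window)
        for sel in ("reservoir_fmlp", "reservoir_ltb4")
    }
    vels = velocities_by_side(tracks)
    counts = classification_counts(tracks, jitter_threshold)
    pf = float(series["reservoir_fmlp"]["percent"].iloc[-1])
    pl = float(series["reservoir_ltb4"]["percent"].iloc[-1])
    ratio, defined = decision_ratio(pf, pl)
    spont = None
    if run.condition == "no_chemoattractant":
        spont = spontaneous_fraction(run)
    return MigrationMetrics(
        percent_migrated=series,
        rate_of_accumulation=rates,
        velocities=vels,
        n_lost={s: counts[s]["lost"] for s in counts},
        n_oscillatory={s: counts[s]["oscillatory"] for s in counts},
        decision_ratio=ratio,
        decision_ratio_defined=defined,
        spontaneous_percent=spont,
    )
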