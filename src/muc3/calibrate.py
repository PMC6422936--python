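"""Grid-search calibration of priming presets against target metrics.

The packaged presets were produced by minimising the squared relative error
between simulated pipeline outputs and the published per-condition summary
statistics. This module exposes that machinery so the calibration is
reproducible and so users can fit presets to their own target surfaces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .geometry import DeviceGeometry
from .phenotypes import compute_metrics, spontaneous_fraction
from .presets import PrimingPreset
from .simulate import simulate_experiment


@dataclass
class CalibrationResult:
    preset: PrimingPreset
    loss: float
    achieved: dict[str, float]
    table: list[dict]


def _set_param(preset: PrimingPreset, name: str, value) -> PrimingPreset:
    """Set a (possibly dotted, e.g. ``bias_strength.fmlp``) parameter."""
    if "." in name:
        root, side = name.split(".", 1)
        d = dict(getattr(preset, root))
        d[side] = float(value)
        return preset.with_(**{root: d})
    return preset.with_(**{name: float(value)})


def simulated_metrics(
    preset: PrimingPreset,
    geometry: DeviceGeometry,
    fields,
    n_cells: int,
    duration: float,
    seeds,
    targets: dict[str, float],
) -> dict[str, float]:
    """Mean pipeline metrics over seeds, restricted to the targeted names.

    Recognised metric names: ``endpoint_percent_fmlp``,
    ``endpoint_percent_ltb4``, ``rate_fmlp``, ``rate_ltb4``,
    ``velocity_fmlp``, ``velocity_ltb4``, ``spontaneous_percent`` (the
    latter simulated without chemoattractant).
    """
    needs_gradient = [k for k in targets if k != "spontaneous_percent"]
    acc: dict[str, list[float]] = {k: [] for k in targets}
    for seed in seeds:
        if needs_gradient:
            run = simulate_experiment(
                preset, geometry, fields, n_cells=n_cells, duration=duration, seed=seed
            )
            m = compute_metrics(run)
            getters = {
                "endpoint_percent_fmlp": lambda: m.endpoint_percent("reservoir_fmlp"),
                "endpoint_percent_ltb4": lambda: m.endpoint_percent("reservoir_ltb4"),
                "rate_fmlp": lambda: m.rate_of_accumulation["reservoir_fmlp"],
                "rate_ltb4": lambda: m.rate_of_accumulation["reservoir_ltb4"],
                "velocity_fmlp": lambda: float(
                    m.velocities["fmlp"]["velocity_um_min"].mean()
                ),
                "velocity_ltb4": lambda: float(
                    m.velocities["ltb4"]["velocity_um_min"].mean()
                ),
            }
            for k in needs_gradient:
                acc[k].append(getters[k]())
        if "spontaneous_percent" in targets:
            run0 = simulate_experiment(
                preset,
                geometry,
                None,
                n_cells=n_cells,
                duration=duration,
                seed=seed + 10_000,
            )
            acc["spontaneous_percent"].append(spontaneous_fraction(run0))
    return {k: float(np.mean(v)) for k, v in acc.items()}


def calibrate_preset(
    base_preset: PrimingPreset,
    target_metrics: dict[str, float],
    free_parameters: dict[str, list[float]],
    geometry: DeviceGeometry | None = None,
    fields=None,
    n_cells: int = 200,
    duration: float = 300.0,
    n_replicates: int = 2,
    seed: int = 0,
) -> CalibrationResult:
    """Exhaustive grid search over the free parameters.

    Parameters
    ----------
    base_preset
        Starting preset; non-free parameters are kept.
    target_metrics
        Metric name -> target value (see :func:`simulated_metrics`). All
        targets must be finite.
    free_parameters
        Parameter name (dots address per-side entries) -> grid of values.
    n_replicates, seed
        Seeds ``seed .. seed + n_replicates - 1`` are averaged per grid
        point; the search is deterministic given ``seed``.

    Returns
    -------
    CalibrationResult
        Best preset by summed squared relative error, its achieved metrics
        and the full achieved-vs-target table.
    """
    geometry = geometry or DeviceGeometry()
    if not target_metrics:
        raise ValueError("target_metrics must be non-empty")
    for k, v in target_metrics.items():
        if not np.isfinite(v):
            raise ValueError(f"target {k} is not finite")
    names = list(free_parameters)
    grids = [list(free_parameters[n]) for n in names]
    if not names or any(len(g) == 0 for g in grids):
        raise ValueError("free_parameters must provide a non-empty grid")
    seeds = list(range(seed, seed + n_replicates))

    best = None
    table = []
    for values in itertools.product(*grids):
        preset = base_preset
        for n, v in zip(names, values):
            preset = _set_param(preset, n, v)
        achieved = simulated_metrics(
            preset, geometry, fields, n_cells, duration, seeds, target_metrics
        )
        loss = sum(
            ((achieved[k] - t) / t) ** 2 if t != 0 else achieved[k] ** 2
            for k, t in target_metrics.items()
        )
        row = {"params": dict(zip(names, values)), "loss": loss, **achieved}
        table.append(row)
        if best is None or loss < best[0]:
            best = (loss, preset, achieved)
    loss, preset, achieved = best
    return CalibrationResult(preset=preset, loss=loss, achieved=achieved, table=table)
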