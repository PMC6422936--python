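"""Group comparisons, velocity histograms and the report layer.

Conditions are compared with an unpaired two-sample Student's t-test
(equal-variance by default, Welch as an option) at alpha = 0.05, with no
multiple-testing correction by default; Holm correction is available as an
opt-in flag for users who compare many metrics at once.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phenotypes import MigrationMetrics, compute_metrics
from .simulate import ExperimentRun


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    metric: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    p_value: float
    significant: bool  # p < 0.05


def compare_groups(
    values_a,
    values_b,
    group_a: str = "a",
    group_b: str = "b",
    metric: str = "",
    equal_var: bool = True,
    alpha: float = 0.05,
) -> GroupComparison:
    """Two-sample Student's t-test between two groups of replicate values."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    if np.isnan(p):  # both groups constant and identical
        t, p = 0.0, 1.0
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        metric=metric,
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        t_statistic=float(t),
        p_value=float(p),
        significant=bool(p < alpha),
    )


def bin_velocities(velocities, bin_width: float = 1.0) -> pd.DataFrame:
    """Histogram of single-cell velocities with half-open bins
    [k*w, (k+1)*w); the total count equals the number of cells."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    v = np.asarray(list(velocities), dtype=float)
    if v.size == 0:
        return pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    k = np.floor(v / bin_width).astype(int)
    uniq, counts = np.unique(k, return_counts=True)
    return pd.DataFrame(
        {
            "bin_left": uniq * bin_width,
            "bin_right": (uniq + 1) * bin_width,
            "count": counts,
        }
    )


def holm_correction(comparisons: list[GroupComparison], alpha: float = 0.05):
    """Holm step-down adjusted significance flags for a comparison family."""
    order = np.argsort([c.p_value for c in comparisons])
    m = len(comparisons)
    out = [False] * m
    for rank, idx in enumerate(order):
        if comparisons[idx].p_value <= alpha / (m - rank):
            out[idx] = True
        else:
            break
    return out


def build_report(
    runs: list[ExperimentRun],
    bin_width: float = 1.0,
    equal_var: bool = True,
    holm: bool = False,
) -> dict:
    """Metrics tables and cross-condition comparisons for a set of runs.

    Runs are grouped by (preset label, condition); scalar metrics are
    compared pairwise across presets within each condition using the
    per-run replicate values. Returns a JSON-serialisable bundle with
    per-run metrics, comparison matrix, velocity histograms and provenance.
    """
    geoms = {id(r.geometry) for r in runs}
    if len({repr(r.geometry) for r in runs}) > 1:
        raise ValueError("all runs must share the same device geometry")

    per_run = []
    scalars: dict[tuple[str, str], dict[str, list[float]]] = {}
    histograms: dict[str, dict[str, list]] = {}
    for run in runs:
        m = compute_metrics(run)
        key = (run.preset.label, run.condition)
        entry = {
            "preset": run.preset.label,
            "condition": run.condition,
            "seed": run.seed,
            "endpoint_percent_fmlp": m.endpoint_percent("reservoir_fmlp"),
            "endpoint_percent_ltb4": m.endpoint_percent("reservoir_ltb4"),
            "rate_fmlp_pct_per_h": m.rate_of_accumulation["reservoir_fmlp"],
            "rate_ltb4_pct_per_h": m.rate_of_accumulation["reservoir_ltb4"],
            "mean_velocity_fmlp": (
                float(m.velocities["fmlp"]["velocity_um_min"].mean())
                if len(m.velocities["fmlp"])
                else float("nan")
            ),
            "mean_velocity_ltb4": (
                float(m.velocities["ltb4"]["velocity_um_min"].mean())
                if len(m.velocities["ltb4"])
                else float("nan")
            ),
            "n_lost_fmlp": m.n_lost["fmlp"],
            "n_lost_ltb4": m.n_lost["ltb4"],
            "n_oscillatory_fmlp": m.n_oscillatory["fmlp"],
            "n_oscillatory_ltb4": m.n_oscillatory["ltb4"],
            "decision_ratio": m.decision_ratio,
            "spontaneous_percent": m.spontaneous_percent,
            "provenance": run.provenance(),
        }
        per_run.append(entry)
        sc = scalars.setdefault(key, {})
        for name in (
            "endpoint_percent_fmlp",
            "endpoint_percent_ltb4",
            "rate_fmlp_pct_per_h",
            "rate_ltb4_pct_per_h",
            "mean_velocity_fmlp",
            "mean_velocity_ltb4",
            "spontaneous_percent",
        ):
            if entry[name] is not None and not (
                isinstance(entry[name], float) and np.isnan(entry[name])
            ):
                sc.setdefault(name, []).append(float(entry[name]))
        for s in ("fmlp", "ltb4"):
            h = histograms.setdefault(f"{run.preset.label}:{run.condition}:{s}", {})
            vals = m.velocities[s]["velocity_um_min"].tolist()
            h.setdefault("velocities", []).extend(vals)

    for k, h in histograms.items():
        tbl = bin_velocities(h["velocities"], bin_width)
        h["histogram"] = tbl.to_dict(orient="list")

    comparisons: list[GroupComparison] = []
    conditions = {c for _, c in scalars}
    for cond in sorted(conditions):
        labels = sorted(lbl for lbl, c in scalars if c == cond)
        for la, lb in itertools.combinations(labels, 2):
            sa, sb = scalars[(la, cond)], scalars[(lb, cond)]
            for name in sorted(set(sa) & set(sb)):
                if len(sa[name]) >= 2 and len(sb[name]) >= 2:
                    comparisons.append(
                        compare_groups(
                            sa[name], sb[name], la, lb, f"{cond}:{name}", equal_var
                        )
                    )
    comp_dicts = [asdict(c) for c in comparisons]
    if holm and comparisons:
        for d, sig in zip(comp_dicts, holm_correction(comparisons)):
            d["significant_holm"] = sig

    return {
        "per_run": per_run,
        "group_means": {
            f"{lbl}:{cond}": {k: float(np.mean(v)) for k, v in sc.items()}
            for (lbl, cond), sc in scalars.items()
        },
        "comparisons": comp_dicts,
        "velocity_histograms": histograms,
    }


def save_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=float)
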