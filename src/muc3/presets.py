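"""LPS-priming presets: parameter bundles for the migration simulator.

Three packaged presets encode the motility phenotypes of the three
conditioning states studied on the chip: untreated cells, cells primed
overnight with a super-low dose of LPS (1 ng/mL), and cells primed with a
high dose (100 ng/mL). The values are *calibrated*, not mechanistic: they
were fitted by grid search (see ``scripts/calibrate_presets.py``) so that
the full pipeline reproduces the published per-condition summary statistics
(endpoint percent migrated, accumulation rates, mean channel velocities,
spontaneous-migration fractions).

Parameter semantics
-------------------
motile_fraction
    Probability that a loaded cell is capable of chemotactic migration in
    the dual-gradient condition.
spontaneous_fraction
    Probability that a cell migrates when no chemoattractant is present.
speed_mean / speed_sd (per side, um/min)
    Population mean and SD of single-cell path speed toward each attractant.
bias_strength (per side, dimensionless >= 0)
    Couples the local normalised gradient steepness to directional
    persistence; also weights which side a cell commits to.
reversal_probability
    Per-step probability of a reorientation event; together with the bias it
    sets how often a cell flips direction (oscillatory phenotype).
maze_entry_weight
    Multiplier on the odds of branching into a ladder rung when crossing a
    channel-maze junction ("lost", non-directional phenotype).
activation_rate (1/min)
    Rate at which an idle motile cell commits to leaving the loading
    channel; controls accumulation kinetics.
speed_cell_fraction
    Fraction of the speed SD that is a stable cell-to-cell difference (the
    rest is per-step fluctuation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import yaml

SIDES = ("fmlp", "ltb4")


@dataclass(frozen=True)
class PrimingPreset:
    label: str
    motile_fraction: float
    spontaneous_fraction: float
    speed_mean: dict[str, float]
    speed_sd: dict[str, float]
    bias_strength: dict[str, float]
    reversal_probability: float
    maze_entry_weight: float
    activation_rate: float
    speed_cell_fraction: float = 0.7
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("motile_fraction", "spontaneous_fraction", "reversal_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for d, name in (
            (self.speed_mean, "speed_mean"),
            (self.speed_sd, "speed_sd"),
            (self.bias_strength, "bias_strength"),
        ):
            for side in SIDES:
                if side not in d:
                    raise ValueError(f"{name} needs a value for side {side!r}")
                if d[side] < 0:
                    raise ValueError(f"{name}[{side}] must be >= 0")
        if self.maze_entry_weight < 0 or self.activation_rate < 0:
            raise ValueError("maze_entry_weight and activation_rate must be >= 0")
        if not 0.0 <= self.speed_cell_fraction <= 1.0:
            raise ValueError("speed_cell_fraction must be in [0, 1]")
        # freeze the nested dicts so presets are immutable once constructed
        for d in (self.speed_mean, self.speed_sd, self.bias_strength):
            for side in SIDES:
                d[side] = float(d[side])

    def with_(self, **kwargs) -> "PrimingPreset":
        """Return a modified copy (presets themselves are immutable)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PrimingPreset":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PrimingPreset":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


UNSTIMULATED = PrimingPreset(
    label="unstimulated",
    motile_fraction=0.155,
    spontaneous_fraction=0.10,
    speed_mean={"fmlp": 10.51, "ltb4": 9.45},
    speed_sd={"fmlp": 3.91, "ltb4": 3.61},
    bias_strength={"fmlp": 2.65, "ltb4": 1.50},
    reversal_probability=0.05,
    maze_entry_weight=0.30,
    activation_rate=0.010,
    speed_cell_fraction=0.70,
)

SUPERLOW_LPS = PrimingPreset(
    label="superlow_lps",
    motile_fraction=0.28,
    spontaneous_fraction=0.25,
    speed_mean={"fmlp": 8.54, "ltb4": 9.58},
    speed_sd={"fmlp": 2.87, "ltb4": 3.36},
    bias_strength={"fmlp": 0.92, "ltb4": 1.02},
    reversal_probability=0.22,
    maze_entry_weight=1.20,
    activation_rate=0.037,
    speed_cell_fraction=0.50,
)

HIGH_LPS = PrimingPreset(
    label="high_lps",
    motile_fraction=0.185,
    spontaneous_fraction=0.25,
    speed_mean={"fmlp": 10.23, "ltb4": 8.66},
    speed_sd={"fmlp": 3.57, "ltb4": 3.14},
    bias_strength={"fmlp": 5.00, "ltb4": 0.75},
    reversal_probability=0.08,
    maze_entry_weight=0.60,
    activation_rate=0.045,
    speed_cell_fraction=0.60,
)

PACKAGED_PRESETS: dict[str, PrimingPreset] = {
    p.label: p for p in (UNSTIMULATED, SUPERLOW_LPS, HIGH_LPS)
}


def get_preset(label: str) -> PrimingPreset:
    try:
        return PACKAGED_PRESETS[label]
    except KeyError:
        raise KeyError(
            f"unknown preset {label!r}; packaged presets: {sorted(PACKAGED_PRESETS)}"
        ) from None
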