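"""Coordinate model of the dual-gradient competitive chemotaxis chip.

The device is laid out on a 2-D plane in micrometres. The origin sits at the
centre of the cell-loading channel; +x points toward the fMLP reservoir and
-x toward the LTB4 reservoir. Ten straight migration channels per side
(900 um long, 10 x 10 um cross-section) connect the loading channel to each
chemoattractant reservoir, and short vertical "maze" ladder rungs bridge
adjacent channels. The gradient inside a rung is attenuated relative to the
straight channels (10-fold by default).

Region labels used throughout the package::

    loading, channel_fmlp, channel_ltb4, maze_fmlp, maze_ltb4,
    reservoir_fmlp, reservoir_ltb4

Boundary points are resolved toward the more distal region: a channel mouth
belongs to the channel, a reservoir mouth to the reservoir.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGIONS = (
    "loading",
    "channel_fmlp",
    "channel_ltb4",
    "maze_fmlp",
    "maze_ltb4",
    "reservoir_fmlp",
    "reservoir_ltb4",
)

#: Boltzmann constant, J/K (for the Stokes-Einstein estimate).
BOLTZMANN_J_PER_K = 1.380649e-23


class OutOfDomainError(ValueError):
    """Raised when a position falls outside every device region."""


@dataclass(frozen=True)
class ChemoattractantSpec:
    """A chemoattractant loaded into one reservoir.

    Parameters
    ----------
    name
        Label, e.g. ``"fMLP"`` or ``"LTB4"``.
    molecular_weight
        Molar mass in Da; sets the diffusion coefficient when none is given.
    reservoir_concentration
        Concentration pipetted into the reservoir, nM.
    diffusion_coefficient
        um^2/s. If None, estimated by :func:`estimate_diffusion_coefficient`.
    """

    name: str
    molecular_weight: float
    reservoir_concentration: float
    diffusion_coefficient: float | None = None

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValueError("molecular_weight must be > 0")
        if self.reservoir_concentration < 0:
            raise ValueError("reservoir_concentration must be >= 0")
        if self.diffusion_coefficient is not None and self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")


def estimate_diffusion_coefficient(
    molecular_weight: float,
    temperature: float = 310.0,
    viscosity: float = 6.91e-4,
    radius_coefficient: float = 0.059,
) -> float:
    """Stokes-Einstein diffusion coefficient from molecular weight.

    D = kT / (6 pi eta r) with the hydrodynamic radius taken from the
    empirical cube-root law r = radius_coefficient * MW**(1/3). The default
    radius coefficient (0.059 nm Da^-1/3) reproduces the ~0.4-0.6 nm radii
    reported for small peptides and lipid mediators; temperature and
    viscosity default to water at 37 C.

    Parameters
    ----------
    molecular_weight : Da
    temperature : K
    viscosity : Pa s
    radius_coefficient : nm Da^-1/3

    Returns
    -------
    float
        Diffusion coefficient in um^2/s.
    """
    for name, value in (
        ("molecular_weight", molecular_weight),
        ("temperature", temperature),
        ("viscosity", viscosity),
        ("radius_coefficient", radius_coefficient),
    ):
        if value <= 0:
            raise ValueError(f"{name} must be > 0, got {value}")
    radius_m = radius_coefficient * 1e-9 * molecular_weight ** (1.0 / 3.0)
    d_m2_s = BOLTZMANN_J_PER_K * temperature / (6.0 * np.pi * viscosity * radius_m)
    return d_m2_s * 1e12  # m^2/s -> um^2/s


@dataclass(frozen=True)
class DeviceGeometry:
    """Geometry of the chip, all lengths in micrometres.

    The loading channel is the central rectangle ``|x| <= loading_half_width``.
    Migration channels run from ``|x| = loading_half_width`` (mouth) to
    ``|x| = loading_half_width + channel_length`` (reservoir mouth) at evenly
    spaced rows ``channel_rows``. Maze rungs bridge vertically between
    adjacent channel rows at the axial positions ``rung_positions`` (measured
    like channels, as distance |x| from the origin).
    """

    channel_length: float = 900.0
    channel_width: float = 10.0
    n_channels_per_side: int = 10
    channel_pitch: float = 100.0
    loading_half_width: float = 50.0
    reservoir_depth: float = 300.0
    rung_offsets: tuple[float, ...] = (150.0, 300.0, 450.0, 600.0, 750.0)
    maze_attenuation: float = 10.0

    def __post_init__(self) -> None:
        if self.channel_length <= 0:
            raise ValueError("channel_length must be > 0")
        if self.n_channels_per_side < 1:
            raise ValueError("need at least one channel per side")
        if self.maze_attenuation <= 0:
            raise ValueError("maze_attenuation must be > 0")
        for off in self.rung_offsets:
            if not 0 < off < self.channel_length:
                raise ValueError("rung offsets must lie strictly inside the channel")

    # -- derived coordinates -------------------------------------------------

    @property
    def channel_rows(self) -> np.ndarray:
        """y positions of the channel centrelines (shared by both sides)."""
        n = self.n_channels_per_side
        span = (n - 1) * self.channel_pitch
        return np.linspace(-span / 2.0, span / 2.0, n)

    @property
    def mouth_x(self) -> float:
        """|x| of the channel mouths at the loading channel."""
        return self.loading_half_width

    @property
    def reservoir_x(self) -> float:
        """|x| of the reservoir mouths."""
        return self.loading_half_width + self.channel_length

    @property
    def device_half_length(self) -> float:
        return self.reservoir_x + self.reservoir_depth

    @property
    def half_height(self) -> float:
        """Vertical half-extent of loading channel and reservoirs."""
        return self.channel_rows[-1] + 0.75 * self.channel_pitch

    @property
    def rung_positions(self) -> np.ndarray:
        """Axial |x| positions where maze rungs meet the channels."""
        return self.mouth_x + np.asarray(self.rung_offsets)

    # -- region lookup -------------------------------------------------------

    def locate(self, x: float, y: float) -> str:
        """Region label containing the point (x, y); raises if outside."""
        out = self.locate_many(np.atleast_1d(x), np.atleast_1d(y))
        return str(out[0])

    def locate_many(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised region lookup. Returns an array of region labels."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ax = np.abs(x)
        side_f = x >= 0.0
        hh = self.half_height
        hw = self.channel_width / 2.0

        in_y_band = np.abs(y) <= hh
        labels = np.full(x.shape, "", dtype=object)

        # loading channel: |x| < mouth (mouth itself belongs to the channel)
        loading = (ax < self.mouth_x) & in_y_band
        labels[loading] = "loading"

        # reservoirs: mouth inclusive
        res = (ax >= self.reservoir_x) & (ax <= self.device_half_length) & in_y_band
        labels[res & side_f] = "reservoir_fmlp"
        labels[res & ~side_f] = "reservoir_ltb4"

        # channels: mouth <= |x| < reservoir mouth, inside a channel strip
        rows = self.channel_rows
        dist_row = np.abs(y[..., None] - rows).min(axis=-1)
        chan = (ax >= self.mouth_x) & (ax < self.reservoir_x) & (dist_row <= hw)
        labels[chan & side_f] = "channel_fmlp"
        labels[chan & ~side_f] = "channel_ltb4"

        # maze rungs: vertical strips around rung_positions between channel rows
        rungs = self.rung_positions
        near_rung = np.abs(ax[..., None] - rungs).min(axis=-1) <= hw
        between_rows = (np.abs(y) <= rows[-1]) & (dist_row > hw)
        maze = (
            (labels == "")
            & near_rung
            & between_rows
            & (ax >= self.mouth_x)
            & (ax < self.reservoir_x)
        )
        labels[maze & side_f] = "maze_fmlp"
        labels[maze & ~side_f] = "maze_ltb4"

        if (labels == "").any():
            i = int(np.argmax(labels == ""))
            raise OutOfDomainError(
                f"position ({x.flat[i]:.1f}, {y.flat[i]:.1f}) um is outside the device"
            )
        return labels.astype(str)

    def contains(self, x: float, y: float) -> bool:
        try:
            self.locate(x, y)
            return True
        except OutOfDomainError:
            return False

    def axial_distance_from_reservoir(self, x: np.ndarray) -> np.ndarray:
        """Distance along the channel axis from the reservoir mouth (0 at the
        reservoir, channel_length at the loading-channel mouth)."""
        return self.reservoir_x - np.abs(np.asarray(x, dtype=float))

    def bounding_box(self, margin: float = 20.0) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) enclosing the device, with a margin."""
        return (
            -self.device_half_length - margin,
            -self.half_height - margin,
            self.device_half_length + margin,
            self.half_height + margin,
        )


DEFAULT_FMLP = ChemoattractantSpec("fMLP", molecular_weight=438.0, reservoir_concentration=10.0)
DEFAULT_LTB4 = ChemoattractantSpec("LTB4", molecular_weight=336.0, reservoir_concentration=100.0)
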