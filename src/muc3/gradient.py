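"""One-dimensional diffusion of chemoattractant along a migration channel.

A reservoir held at fixed concentration feeds a 900-um channel whose far end
opens into the cell-loading channel. Because the loading channel communicates
with a ~4 mL media bath while each reservoir holds only ~10 uL, the loading
end is treated as a perfect sink by default (a well-mixed finite bath is
available as an option). The resulting steady state is the linear profile
observed experimentally; this module quantifies how fast that profile forms
and how stable it stays over a 5-10 h experiment.

The solver is an unconditionally stable Crank-Nicolson scheme on a uniform
grid (defaults dx = 10 um, dt = 1 s), so accuracy rather than stability sets
the step sizes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .geometry import ChemoattractantSpec, DeviceGeometry, estimate_diffusion_coefficient


@dataclass(frozen=True)
class GradientField:
    """Concentration field c(x, t) along one channel.

    ``x_grid`` runs from 0 at the reservoir mouth to ``L`` at the
    loading-channel mouth (um); ``t_grid`` is in minutes; ``concentration``
    has shape (len(x_grid), len(t_grid)) in nM.
    """

    x_grid: np.ndarray
    t_grid: np.ndarray
    concentration: np.ndarray
    reservoir_concentration: float
    name: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.concentration)
        if c.shape != (len(self.x_grid), len(self.t_grid)):
            raise ValueError("concentration must have shape (n_x, n_t)")

    @property
    def channel_length(self) -> float:
        return float(self.x_grid[-1] - self.x_grid[0])

    def profile(self, t: float) -> np.ndarray:
        """Concentration profile at time t (min), linear interpolation in t."""
        t_grid = np.asarray(self.t_grid, dtype=float)
        if not (t_grid[0] <= t <= t_grid[-1]):
            raise ValueError(f"t={t} min outside field range [{t_grid[0]}, {t_grid[-1]}]")
        j = np.searchsorted(t_grid, t)
        if j == 0 or t_grid[j] == t:
            return self.concentration[:, j].copy()
        w = (t - t_grid[j - 1]) / (t_grid[j] - t_grid[j - 1])
        return (1 - w) * self.concentration[:, j - 1] + w * self.concentration[:, j]

    def steady_state(self) -> np.ndarray:
        """Analytic steady profile for the sink boundary: linear in x."""
        c0 = self.reservoir_concentration
        L = self.channel_length
        return c0 * (1.0 - (self.x_grid - self.x_grid[0]) / L)

    def to_frame(self):
        """Long-format (x_um, t_min, c_nM) table."""
        import pandas as pd

        xx, tt = np.meshgrid(self.x_grid, self.t_grid, indexing="ij")
        return pd.DataFrame(
            {"x_um": xx.ravel(), "t_min": tt.ravel(), "c_nM": self.concentration.ravel()}
        )

    def plot_kymograph(self, path=None, ax=None):
        """Space-time heat map of the field; saves a PNG when path is given."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        im = ax.pcolormesh(self.t_grid, self.x_grid, self.concentration, shading="auto")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("distance from reservoir (um)")
        ax.set_title(self.name or "gradient")
        plt.colorbar(im, ax=ax, label="c (nM)")
        if path is not None:
            ax.figure.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def solve_channel_diffusion(
    spec: ChemoattractantSpec,
    geometry: DeviceGeometry | None = None,
    boundary_model: str = "sink",
    dx: float = 10.0,
    dt: float = 1.0,
    t_end: float = 600.0,
    store_every_min: float = 1.0,
    bath_volume_ratio: float = 400.0,
) -> GradientField:
    """Integrate 1-D diffusion along the channel with a fixed reservoir end.

    Parameters
    ----------
    spec
        Chemoattractant; its diffusion coefficient is estimated from the
        molecular weight unless given explicitly.
    geometry
        Supplies the channel length (default geometry if None).
    boundary_model
        ``"sink"`` clamps the loading end at zero; ``"finite_bath"`` couples
        it to a well-mixed volume ``bath_volume_ratio`` times the channel
        volume, which accumulates the escaped attractant.
    dx, dt
        Grid steps in um and s; dx must divide the channel length.
    t_end
        Total simulated time, minutes.
    store_every_min
        Temporal resolution of the returned field.

    Returns
    -------
    GradientField
    """
    geometry = geometry or DeviceGeometry()
    L = geometry.channel_length
    n_cells = L / dx
    if abs(n_cells - round(n_cells)) > 1e-9:
        raise ValueError(f"dx={dx} does not divide channel_length={L}")
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be > 0")
    if boundary_model not in ("sink", "finite_bath"):
        raise ValueError(f"unknown boundary_model {boundary_model!r}")

    D = spec.diffusion_coefficient
    if D is None:
        D = estimate_diffusion_coefficient(spec.molecular_weight)
    c0 = spec.reservoir_concentration

    nx = int(round(n_cells)) + 1
    x = np.linspace(0.0, L, nx)
    r = D * dt / dx**2  # Crank-Nicolson is stable for any r
    n_steps = int(math.ceil(t_end * 60.0 / dt))
    store_stride = max(1, int(round(store_every_min * 60.0 / dt)))

    # interior unknowns 1..nx-2; both boundaries handled explicitly
    m = nx - 2
    ab = np.zeros((3, m))
    ab[0, 1:] = -r / 2.0
    ab[1, :] = 1.0 + r
    ab[2, :-1] = -r / 2.0

    c = np.zeros(nx)
    c[0] = c0
    bath = 0.0  # loading-end bath concentration for finite_bath

    t_store = [0.0]
    c_store = [c.copy()]
    for step in range(1, n_steps + 1):
        rhs = c[1:-1] + (r / 2.0) * (c[2:] - 2.0 * c[1:-1] + c[:-2])
        # boundary contributions at the new time level
        rhs[0] += (r / 2.0) * c0
        c_end_new = 0.0
        if boundary_model == "finite_bath":
            # explicit well-mixed bath: flux from last interior node
            flux = D * (c[-2] - bath) / dx  # nM um / s per unit area
            bath += flux * dt / (bath_volume_ratio * L)
            c_end_new = bath
        rhs[-1] += (r / 2.0) * c_end_new
        c[1:-1] = solve_banded((1, 1), ab, rhs)
        c[0] = c0
        c[-1] = c_end_new
        if step % store_stride == 0:
            t_store.append(step * dt / 60.0)
            c_store.append(c.copy())

    field = GradientField(
        x_grid=x,
        t_grid=np.asarray(t_store),
        concentration=np.asarray(c_store).T,
        reservoir_concentration=c0,
        name=spec.name,
    )
    return field


def gradient_formation_time(field: GradientField, tolerance: float = 0.05) -> float:
    """Earliest time (min) at which the profile is within ``tolerance`` of
    steady state, measured as max |c - c_ss| / reservoir concentration.

    Returns ``math.inf`` if the field never reaches the criterion. For a zero
    reservoir concentration the field is identically at steady state (0 min).
    """
    if field.concentration.size == 0 or len(field.t_grid) == 0:
        raise ValueError("empty field")
    c0 = field.reservoir_concentration
    if c0 == 0:
        return float(field.t_grid[0])
    c_ss = field.steady_state()
    dev = np.abs(field.concentration - c_ss[:, None]).max(axis=0) / c0
    ok = dev <= tolerance
    if not ok.any():
        return math.inf
    return float(field.t_grid[int(np.argmax(ok))])


def gradient_slope(field: GradientField, t: float) -> float:
    """OLS slope of c(x, t) against x over the whole channel, nM/um."""
    prof = field.profile(t)  # raises if t out of range
    A = np.vstack([field.x_grid, np.ones_like(field.x_grid)]).T
    slope, _ = np.linalg.lstsq(A, prof, rcond=None)[0]
    return float(slope)


def slope_similarity(field_a: GradientField, field_b: GradientField, t: float) -> float:
    """Percent difference between reservoir-normalised gradient slopes.

    Each profile is first normalised to its own reservoir concentration, so
    attractants loaded at different doses are compared by gradient *shape*.
    Returns 100 |sa - sb| / mean(|sa|, |sb|); 0 when both slopes vanish.
    """
    if len(field_a.x_grid) != len(field_b.x_grid) or not np.allclose(
        field_a.x_grid, field_b.x_grid
    ):
        raise ValueError("fields must share the same spatial grid")
    sa = gradient_slope(field_a, t) / field_a.reservoir_concentration \
        if field_a.reservoir_concentration else 0.0
    sb = gradient_slope(field_b, t) / field_b.reservoir_concentration \
        if field_b.reservoir_concentration else 0.0
    denom = (abs(sa) + abs(sb)) / 2.0
    if denom == 0.0:
        return 0.0
    return 100.0 * abs(sa - sb) / denom


def concentration_lookup(
    fields: dict[str, GradientField],
    geometry: DeviceGeometry,
    position: tuple[float, float],
    t: float,
) -> dict[str, float]:
    """Per-attractant concentration (nM) at a device position.

    ``fields`` maps attractant name to its channel field, keyed by the side
    it occupies: the field named like ``geometry`` sides via the keys
    ``"fmlp"`` (+x reservoir) and ``"ltb4"`` (-x reservoir). Inside a
    channel or maze the attractant feeding that side follows its 1-D
    profile (nearest axial interpolation); the opposite attractant takes its
    loading-mouth value. The loading channel returns both mouth values.
    """
    x, y = position
    region = geometry.locate(x, y)  # raises OutOfDomainError when outside
    out: dict[str, float] = {}
    for key, field in fields.items():
        own_side = ("fmlp" in region and key == "fmlp") or (
            "ltb4" in region and key == "ltb4"
        )
        if region.startswith("reservoir") and own_side:
            out[key] = field.reservoir_concentration
        elif (region.startswith("channel") or region.startswith("maze")) and own_side:
            ax = geometry.axial_distance_from_reservoir(x)
            prof = field.profile(t)
            out[key] = float(np.interp(ax, field.x_grid, prof))
        else:
            # loading channel / opposite side: loading-mouth value
            out[key] = float(field.profile(t)[-1])
    return out


def local_gradient(
    fields: dict[str, GradientField],
    geometry: DeviceGeometry,
    position: tuple[float, float],
    t: float,
) -> dict[str, float]:
    """Per-attractant gradient magnitude (nM/um) at a position, with the
    maze attenuation applied inside ladder rungs."""
    x, y = position
    region = geometry.locate(x, y)
    out: dict[str, float] = {}
    for key, field in fields.items():
        own_side = ("fmlp" in region and key == "fmlp") or (
            "ltb4" in region and key == "ltb4"
        )
        if own_side and (region.startswith("channel") or region.startswith("maze")):
            g = abs(gradient_slope(field, t))
            if region.startswith("maze"):
                g /= geometry.maze_attenuation
            out[key] = g
        else:
            out[key] = 0.0
    return out
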