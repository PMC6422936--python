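"""Synthetic nuclear-stain time-lapse rendering of simulated runs.

Each frame places a Gaussian spot (the stained nucleus) at every cell
position, on a constant background, and corrupts it with Poisson shot noise
plus Gaussian read noise — the canonical model for fluorescence microscopy
counts. The device-to-image mapping (pixel size and origin) and the
ground-truth per-frame positions are returned alongside the stack so the
tracking module can be scored against truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ExperimentRun


@dataclass(frozen=True)
class ImageMetadata:
    pixel_size: float  # um / px
    origin: tuple[float, float]  # device um coordinates of pixel (0, 0) centre
    psf_sigma: float  # px
    background: float
    amplitude: float
    read_noise: float

    def to_pixels(self, x_um, y_um):
        """Device um -> (col, row) pixel coordinates."""
        x_um = np.asarray(x_um, dtype=float)
        y_um = np.asarray(y_um, dtype=float)
        return (x_um - self.origin[0]) / self.pixel_size, (
            y_um - self.origin[1]
        ) / self.pixel_size

    def to_um(self, col, row):
        col = np.asarray(col, dtype=float)
        row = np.asarray(row, dtype=float)
        return (
            col * self.pixel_size + self.origin[0],
            row * self.pixel_size + self.origin[1],
        )


def render_frames(
    run: ExperimentRun,
    pixel_size: float = 2.0,
    psf_sigma: float = 1.5,
    background: float = 10.0,
    amplitude: float = 200.0,
    read_noise: float = 2.0,
    seed: int = 0,
    poisson: bool = True,
) -> tuple[np.ndarray, pd.DataFrame, ImageMetadata]:
    """Render a run as a grayscale image stack.

    Parameters
    ----------
    run
        Simulated experiment whose per-frame positions are imaged.
    pixel_size
        um per pixel.
    psf_sigma
        Gaussian spot width in pixels.
    background, amplitude, read_noise
        Mean background level, peak spot intensity above background, and
        Gaussian read-noise SD (all in counts).
    seed
        Noise RNG seed; noise is independent of the simulation RNG.
    poisson
        When False, render noiselessly (background + spots only).

    Returns
    -------
    (stack, ground_truth, metadata)
        ``stack`` is float32 with shape (n_frames, height, width);
        ``ground_truth`` repeats the run's track table with added pixel
        coordinates ``col_px, row_px``.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if run.tracks.empty:
        raise ValueError("run has no tracks to render")

    xmin, ymin, xmax, ymax = run.geometry.bounding_box(margin=6 * psf_sigma * pixel_size)
    width = int(np.ceil((xmax - xmin) / pixel_size))
    height = int(np.ceil((ymax - ymin) / pixel_size))
    meta = ImageMetadata(
        pixel_size=pixel_size,
        origin=(xmin, ymin),
        psf_sigma=psf_sigma,
        background=background,
        amplitude=amplitude,
        read_noise=read_noise,
    )

    rng = np.random.default_rng(seed)
    n_frames = run.n_frames
    stack = np.empty((n_frames, height, width), dtype=np.float32)
    truth = run.tracks.copy()
    cols, rows_px = meta.to_pixels(truth["x_um"].to_numpy(), truth["y_um"].to_numpy())
    truth["col_px"] = cols
    truth["row_px"] = rows_px

    half = int(np.ceil(4 * psf_sigma))
    by_frame = truth.groupby("frame")
    for f in range(n_frames):
        img = np.full((height, width), background, dtype=np.float64)
        try:
            pts = by_frame.get_group(f)
        except KeyError:
            pts = None
        if pts is not None:
            for c, r in zip(pts["col_px"].to_numpy(), pts["row_px"].to_numpy()):
                c0, r0 = int(round(c)), int(round(r))
                cs = slice(max(0, c0 - half), min(width, c0 + half + 1))
                rs = slice(max(0, r0 - half), min(height, r0 + half + 1))
                cc, rr = np.meshgrid(np.arange(cs.start, cs.stop), np.arange(rs.start, rs.stop))
                img[rs, cs] += amplitude * np.exp(
                    -((cc - c) ** 2 + (rr - r) ** 2) / (2 * psf_sigma**2)
                )
        if poisson:
            img = rng.poisson(img).astype(np.float64)
            img += rng.normal(0.0, read_noise, size=img.shape)
        stack[f] = img.astype(np.float32)
    return stack, truth, meta


def save_stack(stack: np.ndarray, path) -> None:
    """Write the stack as a multi-page TIFF."""
    import tifffile

    tifffile.imwrite(path, stack, photometric="minisblack")


def load_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
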