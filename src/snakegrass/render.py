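"""Rendering of Gabor element layouts to grayscale images.

Elements are cosine-phase (centre-symmetric) Gabor patches: a sinusoidal
carrier under a circular Gaussian envelope, composed additively onto a
mid-grey (0.5) background.  Geometry is degrees-native; ``px_per_deg``
controls rasterisation.  At the e^-2 envelope level (2 sigma radius) the
visible patch diameter is 4 sigma = 0.64 deg for the default sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import StimulusLayout


@dataclass(frozen=True)
class GaborParams:
    """Carrier/envelope parameters of one Gabor element."""

    spatial_frequency: float = 2.5  # cycles per degree
    envelope_sd_deg: float = 0.16
    polarity: int = 1  # +1 bright-centre, -1 dark-centre
    contrast: float = 1.0  # Michelson

    def __post_init__(self) -> None:
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must be in [0, 1]")
        if self.envelope_sd_deg <= 0:
            raise ValueError("envelope SD must be positive")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")


@dataclass(frozen=True)
class RenderConfig:
    px_per_deg: float = 20.0
    image_width_px: int = 1064
    image_height_px: int = 600
    background_level: float = 0.5
    envelope_support_sigma: float = 3.0  # truncation radius in SD units

    def __post_init__(self) -> None:
        if self.px_per_deg <= 0:
            raise ValueError("px_per_deg must be positive")


def visible_diameter_deg(envelope_sd_deg: float = 0.16, level_sigma: float = 2.0) -> float:
    """Visible patch diameter at the given envelope cutoff (default e^-2)."""
    return 2.0 * level_sigma * envelope_sd_deg


def gabor_patch(
    params: GaborParams, orientation_deg: float, config: RenderConfig
) -> np.ndarray:
    """Render one Gabor patch as a square tile with values in [0, 1].

    The tile is ``0.5 + 0.5 c p exp(-r^2 / 2 sigma^2) cos(2 pi f u)`` where
    ``u`` is the coordinate perpendicular to the grating stripes; outside the
    truncation radius the tile is exactly background.
    """
    ppd = config.px_per_deg
    sigma = params.envelope_sd_deg
    support = config.envelope_support_sigma * sigma
    half = int(np.ceil(support * ppd))
    ax = (np.arange(-half, half + 1)) / ppd  # degrees
    xx, yy = np.meshgrid(ax, -ax)  # row 0 at top; y upward
    theta = np.deg2rad(orientation_deg)
    # stripes run along `orientation`; modulation is perpendicular to them
    u = -np.sin(theta) * xx + np.cos(theta) * yy
    r2 = xx**2 + yy**2
    envelope = np.exp(-r2 / (2.0 * sigma**2))
    envelope[r2 > support**2] = 0.0
    carrier = np.cos(2.0 * np.pi * params.spatial_frequency * u)
    return 0.5 + 0.5 * params.contrast * params.polarity * envelope * carrier


def _draw_fixation(img: np.ndarray, config: RenderConfig) -> None:
    """Concentric fixation squares: 0.5 deg grey outline, 0.1 deg black fill."""
    ppd = config.px_per_deg
    cy, cx = img.shape[0] // 2, img.shape[1] // 2

    def square(side_deg: float, value: float, fill: bool) -> None:
        halfpx = max(1, int(round(side_deg / 2 * ppd)))
        y0, y1 = cy - halfpx, cy + halfpx + 1
        x0, x1 = cx - halfpx, cx + halfpx + 1
        if fill:
            img[y0:y1, x0:x1] = value
        else:
            img[y0:y1, x0] = value
            img[y0:y1, x1 - 1] = value
            img[y0, x0:x1] = value
            img[y1 - 1, x0:x1] = value

    square(0.5, 0.25, fill=False)
    square(0.1, 0.0, fill=True)


def render_stimulus(
    layout: StimulusLayout,
    contrast: float,
    polarity: int = 1,
    fixation_marks: bool = True,
    config: RenderConfig | None = None,
    gabor: GaborParams | None = None,
) -> np.ndarray:
    """Render a full stimulus image in [0, 1].

    Every element is drawn at the same contrast and polarity (as in the
    task, where all simultaneously shown Gabors share a randomly assigned
    polarity).  Elements whose tile would fall entirely outside the image
    are skipped with a warning.
    """
    if config is None:
        config = RenderConfig()
    base = gabor if gabor is not None else GaborParams()
    params = GaborParams(
        spatial_frequency=base.spatial_frequency,
        envelope_sd_deg=base.envelope_sd_deg,
        polarity=polarity,
        contrast=contrast,
    )
    h, w = config.image_height_px, config.image_width_px
    img = np.full((h, w), config.background_level, dtype=float)
    half = int(np.ceil(config.envelope_support_sigma * params.envelope_sd_deg * config.px_per_deg))
    cy, cx = h // 2, w // 2
    ppd = config.px_per_deg
    for e in layout.elements:
        t = gabor_patch(params, e.orientation_deg, config) - 0.5
        px = int(round(cx + e.x_deg * ppd))
        py = int(round(cy - e.y_deg * ppd))
        y0, y1 = py - half, py + half + 1
        x0, x1 = px - half, px + half + 1
        if y1 <= 0 or x1 <= 0 or y0 >= h or x0 >= w:
            warnings.warn(f"element at ({e.x_deg:.1f}, {e.y_deg:.1f}) deg outside image; clipped")
            continue
        sy0, sx0 = max(0, -y0), max(0, -x0)
        sy1 = t.shape[0] - max(0, y1 - h)
        sx1 = t.shape[1] - max(0, x1 - w)
        img[max(0, y0):min(h, y1), max(0, x0):min(w, x1)] += t[sy0:sy1, sx0:sx1]
    np.clip(img, 0.0, 1.0, out=img)
    if fixation_marks:
        _draw_fixation(img, config)
    return img


def save_png(img: np.ndarray, path: str) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    from PIL import Image

    Image.fromarray(np.round(img * 255).astype(np.uint8), mode="L").save(path)
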