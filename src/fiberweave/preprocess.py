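"""SHG stack preprocessing: intensity clipping, small-σ Gaussian blur and
rolling-ball background subtraction, applied per slice in that order.

The rolling-ball step is defined *mathematically* rather than by any one
tool's dialect: the background of a slice is its grayscale opening by a
spherical-cap structuring element of the stated radius, and the result is
slice − background.  Grayscale opening is anti-extensive, so the output
is automatically non-negative and pointwise ≤ the input, and it is
idempotent as a background estimator.  Blur and background subtraction
are 2-D per slice because the z spacing (10.62 μm by default) is about
nine times the in-plane pixel, making 3-D structuring elements
physically meaningless at these scales.

All arithmetic is floating point; quantization back to integers happens
only on export.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .core import ShgStack

DEFAULT_CLIP = (0.0, 4000.0)
DEFAULT_BLUR_SIGMA = 0.5
DEFAULT_BALL_RADIUS = 40


def clip_range(s: ShgStack, lo: float = DEFAULT_CLIP[0], hi: float = DEFAULT_CLIP[1]) -> ShgStack:
    """Clamp intensities to [lo, hi] (display-range normalization)."""
    if not lo < hi:
        raise ValueError(f"need lo < hi, got ({lo}, {hi})")
    out = np.clip(s.data, lo, hi)
    return s.with_data(out, {"op": "clip_range", "lo": lo, "hi": hi})


def gaussian_blur(s: ShgStack, sigma_px: float = DEFAULT_BLUR_SIGMA) -> ShgStack:
    """Per-slice 2-D Gaussian blur with reflective boundary handling."""
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if sigma_px == 0:
        return s.with_data(s.data.copy(), {"op": "gaussian_blur", "sigma_px": 0.0})
    out = np.empty_like(s.data)
    for k in range(s.data.shape[0]):
        out[k] = ndi.gaussian_filter(s.data[k], sigma=sigma_px, mode="reflect")
    return s.with_data(out, {"op": "gaussian_blur", "sigma_px": sigma_px})


def ball_structuring_element(radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    """Spherical-cap structuring element for grayscale opening.

    Returns ``(footprint, heights)`` where ``footprint`` marks in-plane
    offsets with d ≤ radius and ``heights`` is sqrt(r² − d²) there — the
    upper hemisphere of a ball of the stated radius.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    n = int(np.floor(radius_px))
    yy, xx = np.mgrid[-n:n + 1, -n:n + 1]
    d2 = yy * yy + xx * xx
    footprint = d2 <= radius_px * radius_px
    heights = np.zeros_like(d2, dtype=np.float64)
    heights[footprint] = np.sqrt(radius_px * radius_px - d2[footprint])
    return footprint, heights


def rolling_ball_background(slice2d: np.ndarray, radius_px: float) -> np.ndarray:
    """Background of one slice: grayscale opening by the spherical cap."""
    footprint, heights = ball_structuring_element(radius_px)
    structure = np.where(footprint, heights, -np.inf)
    eroded = ndi.grey_erosion(slice2d, structure=structure,
                              footprint=footprint, mode="nearest")
    opened = ndi.grey_dilation(eroded, structure=structure,
                               footprint=footprint, mode="nearest")
    # anti-extensivity can be violated by a fraction of an ulp; restore it
    return np.minimum(opened, slice2d)


def rolling_ball_subtract(s: ShgStack, radius_px: float = DEFAULT_BALL_RADIUS) -> ShgStack:
    """Subtract the rolling-ball background from every slice.

    The output is floored at 0 (a formality — opening is anti-extensive).
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    nz, ny, nx = s.data.shape
    n = int(np.floor(radius_px))
    if 2 * n + 1 > min(ny, nx):
        raise ValueError(
            f"ball radius {radius_px} px exceeds the slice extent {(ny, nx)}"
        )
    out = np.empty_like(s.data)
    for k in range(nz):
        bg = rolling_ball_background(s.data[k], radius_px)
        out[k] = np.maximum(s.data[k] - bg, 0.0)
    return s.with_data(out, {"op": "rolling_ball_subtract", "radius_px": radius_px})


def process_stack(
    s: ShgStack,
    clip: tuple[float, float] = DEFAULT_CLIP,
    sigma_px: float = DEFAULT_BLUR_SIGMA,
    ball_radius_px: float = DEFAULT_BALL_RADIUS,
) -> ShgStack:
    """The full preprocessing recipe: clip → blur → rolling-ball, in order."""
    out = clip_range(s, *clip)
    out = gaussian_blur(out, sigma_px)
    out = rolling_ball_subtract(out, ball_radius_px)
    return out
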