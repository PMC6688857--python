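"""Seeded deformed-terrain height fields and level-cut occlusion masks.

A terrain is a smooth, band-limited random relief map on a square pixel
grid; heights increase toward the viewer.  Slicing the relief with a
fronto-parallel plane at depth ``d`` ("level cut") partitions the image
into a visible shaded region and a homogeneous occluder.  Two polarities
exist for the same cut: a *convex* mask hides everything behind the
plane (leaving the shaded peaks, which look unambiguously like top-lit
bumps) and a *bistable* mask hides everything in front of it (leaving
the valleys, which can flip between bumps-lit-from-below and
dents-lit-from-above).  At a common depth the two masks are exact
complements.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import ndimage

Polarity = Literal["convex", "bistable"]

__all__ = [
    "HeightField",
    "LevelCutMask",
    "generate_terrain",
    "clip_and_smooth",
    "level_cut_depth_for_visibility",
    "make_level_cut_mask",
    "rotate_mask",
]


@dataclass(frozen=True)
class HeightField:
    """Gridded surface relief.  Larger height = nearer to the viewer.

    Storage is row-major with the origin at the top-left (row = screen
    down); all angle-valued outputs elsewhere use the display convention
    in which 90 deg points up on screen.
    """

    heights: np.ndarray
    pixel_pitch: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError("height grid must be square and 2-D")
        if not np.all(np.isfinite(h)):
            raise ValueError("heights must be finite everywhere")
        object.__setattr__(self, "heights", h)

    @property
    def size(self) -> int:
        return self.heights.shape[0]


@dataclass(frozen=True)
class LevelCutMask:
    """Binary occluder from thresholding a height field at ``cut_depth``.

    ``mask`` is True where the gray occluder covers the image; the
    visible fraction is ``1 - mask.mean()``.
    """

    mask: np.ndarray
    cut_depth: float
    polarity: Polarity
    rotated: bool = False

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if self.polarity not in ("convex", "bistable"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    @property
    def visible_fraction(self) -> float:
        return float(1.0 - self.mask.mean())


def generate_terrain(
    seed: int, size: int = 512, cutoff: float = 8.0, relief_amplitude: float = 1.0
) -> HeightField:
    """Generate a smooth, isotropic, band-limited random relief map.

    Gaussian white noise is low-pass filtered in the frequency domain
    with a hard isotropic cutoff at ``cutoff`` cycles per image, giving
    a zero-mean smooth field, then rescaled so the RMS relief equals
    ``relief_amplitude``.  Output is a pure function of the arguments.

    Parameters
    ----------
    seed : int
        Seed for the white-noise draw.
    size : int
        Grid side length in pixels (>= 64).
    cutoff : float
        Retained band, cycles/image; energy above this radius is zeroed.
    relief_amplitude : float
        RMS height after scaling, in length units.
    """
    if size < 64:
        raise ValueError("size must be >= 64")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if relief_amplitude <= 0:
        raise ValueError("relief_amplitude must be positive")

    rng = np.random.default_rng(seed)
    white = rng.standard_normal((size, size))
    spectrum = np.fft.fft2(white)
    fy = np.fft.fftfreq(size) * size  # cycles per image
    fx = np.fft.fftfreq(size) * size
    radius = np.hypot(fy[:, None], fx[None, :])
    spectrum[radius > cutoff] = 0.0
    spectrum[0, 0] = 0.0  # zero mean
    h = np.fft.ifft2(spectrum).real
    h *= relief_amplitude / np.sqrt(np.mean(h**2))
    return HeightField(h, seed=seed)


def clip_and_smooth(
    h: HeightField, floor: float, smooth_sigma: float = 3.0
) -> HeightField:
    """Flatten the valleys below a height quantile, then smooth.

    ``floor`` is the quantile (0..1) of the empirical height
    distribution at which the terrain is clipped from below; the abrupt
    skirts the clip creates are then rounded with a Gaussian filter of
    ``smooth_sigma`` pixels.  The result never dips below the floor
    value and is exactly flat away from bump skirts, emulating smooth
    bumps rising from a planar base.
    """
    if not 0.0 <= floor <= 1.0:
        raise ValueError("floor quantile must lie in [0, 1]")
    if smooth_sigma < 0:
        raise ValueError("smooth_sigma must be non-negative")
    floor_value = float(np.quantile(h.heights, floor))
    clipped = np.maximum(h.heights, floor_value)
    if smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(clipped, smooth_sigma, mode="reflect")
        # smoothing a field bounded below keeps the bound
        smoothed = np.maximum(smoothed, floor_value)
    else:
        smoothed = clipped
    return HeightField(smoothed, pixel_pitch=h.pixel_pitch, seed=h.seed)


def level_cut_depth_for_visibility(
    h: HeightField, fraction: float, polarity: Polarity = "convex"
) -> float:
    """Cut depth leaving ``fraction`` of the pixels visible.

    The depth is read off the exact empirical height distribution
    (sorted heights), so the achieved visible fraction is within
    1/size**2 of the request for fields without massive ties.  Convex
    polarity shows ``h >= d``; bistable shows ``h < d``.  A convex cut
    at fraction f and a bistable cut at 1 - f share the same depth,
    hence the complementary-mask construction.  Ties break toward the
    smaller depth.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly in (0, 1)")
    heights = h.heights.ravel()
    if np.ptp(heights) == 0:
        raise ValueError("constant height field admits no valid cut")
    n = heights.size
    ordered = np.sort(heights)
    if polarity == "convex":
        k = int(round(fraction * n))  # pixels with h >= d
        k = min(max(k, 1), n - 1)
        return float(ordered[n - k])
    elif polarity == "bistable":
        k = int(round(fraction * n))  # pixels with h < d
        k = min(max(k, 1), n - 1)
        return float(ordered[k])
    raise ValueError(f"unknown polarity {polarity!r}")


def make_level_cut_mask(
    h: HeightField, cut_depth: float, polarity: Polarity = "convex"
) -> LevelCutMask:
    """Threshold the relief at ``cut_depth`` into an occluder mask.

    Convex: the mask hides everything behind the cut plane
    (``h < d``); bistable hides everything in front (``h >= d``).
    The two are exact logical complements at the same depth.
    """
    if polarity == "convex":
        mask = h.heights < cut_depth
    elif polarity == "bistable":
        mask = h.heights >= cut_depth
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return LevelCutMask(mask=mask, cut_depth=float(cut_depth), polarity=polarity)


def rotate_mask(m: LevelCutMask) -> LevelCutMask:
    """Rotate the occluder 180 degrees about the image center.

    This keeps the contour geometry identical but destroys the
    orientation-intensity relationship between the contours and the
    shading they overlay.  Applying twice restores the original.
    """
    return replace(m, mask=m.mask[::-1, ::-1].copy(), rotated=not m.rotated)
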