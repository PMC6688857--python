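"""Ribbon stimuli: thin level-cut paths with parametric covariation.

A ribbon isolates the photogeometric information carried by a bounding
contour: a two-pixel-wide path traced along a level-cut contour on a
uniform gray background, shaded purely as a function of its own
orientation.  The noiseless shading rule is linear in angular
separation from the top (90 deg) azimuth,

    L = 0.8 - 0.6 * sep(theta, 90 deg) / 180 deg,

so luminance falls from 0.8 where the into-mask normal points straight
up, through 0.5 (the background gray) at exactly vertical segments, to
0.2 where the normal points straight down.  Covariation strength is
then degraded by mixing the shading with low-frequency noise whose
radially averaged Fourier amplitude spectrum matches the average
spectrum of rendered terrain shading, in a noise proportion w in [0, 1].
The 13 proportions used for paper-faithful stimulus sets are
0, .15, .30, .35, .40, .45, .50, .55, .60, .65, .70, .85, 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import contours as _contours
from . import covariation as _covariation
from .shading import ShadedImage, render_height_field
from .terrain import (
    HeightField,
    generate_terrain,
    level_cut_depth_for_visibility,
    make_level_cut_mask,
)

__all__ = [
    "NOISE_PROPORTIONS",
    "RibbonSpec",
    "NoiseTexture",
    "linear_shade_ribbon",
    "average_amplitude_spectrum",
    "default_target_spectrum",
    "spectrum_matched_noise",
    "mix_ribbon",
    "compose_ribbon_image",
    "make_ribbon_stimulus",
    "measure_ribbon",
]

#: Noise proportions used in the paired-comparison stimulus set; chosen
#: to spread the measured covariation roughly uniformly over [0, 1].
NOISE_PROPORTIONS = (
    0.0, 0.15, 0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60, 0.65, 0.70, 0.85, 1.0
)

_RIBBON_RANGE = (0.2, 0.8)
_BACKGROUND = 0.5


@dataclass
class RibbonSpec:
    """A ribbon path plus the mixing parameters that shade it."""

    positions: np.ndarray  # (n, 2) row/col path pixels
    orientations: np.ndarray  # (n,) into-mask normal, degrees [0, 360)
    width: int = 2
    noise_proportion: float = 0.0
    seed: int = 0
    background: float = _BACKGROUND

    def __post_init__(self) -> None:
        if self.width < 1:
            raise ValueError("ribbon width must be >= 1")
        if not 0.0 <= self.noise_proportion <= 1.0:
            raise ValueError("noise proportion must lie in [0, 1]")


@dataclass
class NoiseTexture:
    """Random-phase noise with a prescribed radial amplitude spectrum."""

    values: np.ndarray
    target_spectrum: np.ndarray
    seed: int


def linear_shade_ribbon(orientations) -> np.ndarray:
    """Noiseless ribbon luminance from orientation alone.

    Linear falloff from 0.8 at 90 deg (top-lit) to 0.2 at 270 deg;
    exactly vertical segments (0/180 deg) land on the 0.5 background
    gray.  The linear form approximates Lambert's cosine to r = 0.979
    over the quarter range.
    """
    sep = _covariation.angular_separation(np.asarray(orientations, float), 90.0)
    return 0.8 - 0.6 * sep / 180.0


def _radial_bins(size: int) -> np.ndarray:
    f = np.fft.fftfreq(size) * size
    return np.round(np.hypot(f[:, None], f[None, :])).astype(int)


def average_amplitude_spectrum(images: list[ShadedImage] | list[np.ndarray]) -> np.ndarray:
    """Radially averaged Fourier amplitude, averaged over images.

    Index k of the returned profile holds the mean |FFT| over all
    frequency-plane pixels whose radius rounds to k cycles/image; the
    DC bin is zeroed.  All images must share one square size.
    """
    if not images:
        raise ValueError("need at least one image")
    arrays = [im.luminance if isinstance(im, ShadedImage) else np.asarray(im, float) for im in images]
    size = arrays[0].shape[0]
    if any(a.shape != (size, size) for a in arrays):
        raise ValueError("all images must be square and of a common size")
    bins = _radial_bins(size)
    n_bins = bins.max() + 1
    counts = np.bincount(bins.ravel(), minlength=n_bins)
    profile = np.zeros(n_bins)
    for a in arrays:
        amp = np.abs(np.fft.fft2(a))
        profile += np.bincount(bins.ravel(), weights=amp.ravel(), minlength=n_bins)
    profile /= counts * len(arrays)
    profile[0] = 0.0  # exclude DC
    return profile


@lru_cache(maxsize=4)
def default_target_spectrum(size: int = 256, n_terrains: int = 16, cutoff: float = 8.0) -> np.ndarray:
    """Average shading spectrum of a standard bank of rendered terrains.

    Deterministic (terrain seeds 0..n-1); computed on first use and
    cached so ribbon generation needs no explicit rendering step.
    """
    renders = [
        render_height_field(generate_terrain(seed, size=size, cutoff=cutoff))
        for seed in range(n_terrains)
    ]
    return average_amplitude_spectrum(renders)


def spectrum_matched_noise(
    target_spectrum: np.ndarray, size: int, seed: int
) -> NoiseTexture:
    """Noise with the target radial amplitude profile and random phase.

    White Gaussian noise supplies a conjugate-symmetric random phase
    field; its Fourier amplitudes are replaced by the target profile
    interpolated at each frequency radius.  The inverse transform is
    therefore real and seeded.
    """
    target_spectrum = np.asarray(target_spectrum, float)
    if np.any(target_spectrum < 0):
        raise ValueError("target spectrum must be non-negative")
    rng = np.random.default_rng(seed)
    white = np.fft.fft2(rng.standard_normal((size, size)))
    radius = np.hypot(
        (np.fft.fftfreq(size) * size)[:, None], (np.fft.fftfreq(size) * size)[None, :]
    )
    amp = np.interp(radius, np.arange(len(target_spectrum)), target_spectrum,
                    right=0.0)
    amp[0, 0] = 0.0
    mag = np.abs(white)
    phase = np.where(mag > 0, white / np.where(mag > 0, mag, 1.0), 1.0)
    values = np.fft.ifft2(amp * phase).real
    return NoiseTexture(values=values, target_spectrum=target_spectrum, seed=seed)


def mix_ribbon(shaded: np.ndarray, noise_on_path: np.ndarray, w: float) -> np.ndarray:
    """Blend linear shading with path-sampled noise in proportion ``w``.

    The noise samples are first affinely rescaled to span the ribbon
    gamut [0.2, 0.8] along the path, so a pure-noise ribbon (w = 1)
    occupies the same luminance range as a noiseless one.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("noise proportion must lie in [0, 1]")
    shaded = np.asarray(shaded, float)
    if w == 0.0:
        return shaded.copy()
    noise = np.asarray(noise_on_path, float)
    lo, hi = noise.min(), noise.max()
    if hi > lo:
        noise = _RIBBON_RANGE[0] + (noise - lo) * (
            (_RIBBON_RANGE[1] - _RIBBON_RANGE[0]) / (hi - lo)
        )
    else:
        noise = np.full_like(noise, np.mean(_RIBBON_RANGE))
    return (1.0 - w) * shaded + w * noise


def compose_ribbon_image(
    spec: RibbonSpec, luminances: np.ndarray, size: int
) -> ShadedImage:
    """Paint the ribbon onto a uniform gray background.

    Width-2 realization: each path pixel plus its neighbour one step
    along the into-mask normal takes the path pixel's luminance; wider
    ribbons continue stepping along the normal.  Quantization to 8 bits
    is left to the caller/writer — values here stay float.
    """
    img = np.full((size, size), spec.background, dtype=float)
    pos = np.asarray(spec.positions)
    if len(pos) == 0:
        return ShadedImage(img)
    if pos.min() < 0 or pos.max() >= size:
        raise ValueError("ribbon path falls outside the image")
    lum = np.asarray(luminances, float)
    theta = np.radians(spec.orientations)
    for step in range(spec.width):
        # step along the into-mask normal: display (cos, sin) -> storage (-sin, cos)
        rr = pos[:, 0] - np.round(step * np.sin(theta)).astype(int)
        cc = pos[:, 1] + np.round(step * np.cos(theta)).astype(int)
        ok = np.isfinite(spec.orientations) & (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
        img[rr[ok], cc[ok]] = lum[ok]
    return ShadedImage(img)


def measure_ribbon(img: ShadedImage, mask) -> "_covariation.CovariationResult":
    """Re-measure a ribbon stimulus with the analysis pipeline.

    The ribbon is centered on the contour, so intensity is sampled at
    the contour pixel itself (inset 0) rather than one step into the
    gradients as for masked terrain images.
    """
    pixels = _contours.measure_contour(img, mask, inset=0)
    return _covariation.covariation_score(pixels)


def make_ribbon_stimulus(
    seed: int,
    noise_proportion: float,
    size: int = 256,
    terrain_cutoff: float = 8.0,
    visibility: float = 0.5,
    width: int = 2,
    target_spectrum: np.ndarray | None = None,
):
    """Generate one complete ribbon stimulus from a seeded terrain.

    Returns ``(image, spec, mask)``; the mask is the level-cut occluder
    whose contour defines the path, for re-measurement.

    The path is the level-cut contour of a fresh band-limited terrain at
    the requested visibility; orientations are measured with the same
    contour machinery used for analysis, shaded linearly, mixed with
    spectrum-matched noise sampled along the path, and composed on the
    0.5 gray background.
    """
    h = generate_terrain(seed, size=size, cutoff=terrain_cutoff)
    d = level_cut_depth_for_visibility(h, visibility, "convex")
    mask = make_level_cut_mask(h, d, "convex")
    positions = _contours.extract_contour_pixels(mask)
    tangents, _ = _contours.estimate_orientation_180(positions, shape=mask.mask.shape)
    orientations = _contours.disambiguate_orientation_360(mask, positions, tangents)
    ok = np.isfinite(orientations)
    positions, orientations = positions[ok], orientations[ok]

    shaded = linear_shade_ribbon(orientations)
    if target_spectrum is None:
        target_spectrum = default_target_spectrum(size, cutoff=terrain_cutoff)
    noise = spectrum_matched_noise(target_spectrum, size, seed=seed + 1_000_003)
    noise_on_path = noise.values[positions[:, 0], positions[:, 1]]
    mixed = mix_ribbon(shaded, noise_on_path, noise_proportion)

    spec = RibbonSpec(
        positions=positions,
        orientations=orientations,
        width=width,
        noise_proportion=noise_proportion,
        seed=seed,
    )
    return compose_ribbon_image(spec, mixed, size), spec, mask
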