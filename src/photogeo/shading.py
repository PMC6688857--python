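"""Lambertian shading of height fields, gray-mask compositing, defocus.

Surface attitude is expressed in observer-centric spherical coordinates:
*tilt* is the image-plane direction of the projected surface normal
(degrees, display convention: 0 deg = rightward, 90 deg = up on screen)
and *slant* is the angle between the normal and the viewing axis.  For
a Lambertian surface under a collimated source the luminance is the
clipped dot product of the unit normal and unit light vectors,

    L = max(0, r * i * (n . l)),

which, for fixed illumination, is a cosine of tilt whose amplitude
B*sin(slant) and offset A*cos(slant) depend on slant only.  At a
self-occluding rim slant -> 90 deg, the offset vanishes and the rim
luminance reduces to ``max(0, B*cos(theta_rim - C))`` with phase C equal
to the light azimuth.  These two limits are exposed directly as
:func:`lambert_luminance` and :func:`rim_luminance`; whole-image
rendering differentiates the height field and applies the same law per
pixel under an orthographic view.

Defocus is a thin-lens approximation: per-pixel blur scale grows
linearly with distance from the focal plane and inversely with the
f-number, applied as a layered, depth-binned Gaussian blur composited
far to near.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .terrain import HeightField, LevelCutMask

__all__ = [
    "SurfaceOrientation",
    "CollimatedLight",
    "Material",
    "ShadedImage",
    "CosineFalloff",
    "DefocusConfig",
    "lambert_luminance",
    "rim_luminance",
    "surface_orientation_from_heights",
    "render_height_field",
    "apply_mask",
    "defocus_sigma",
    "depth_from_heights",
    "simulate_defocus",
]


@dataclass(frozen=True)
class SurfaceOrientation:
    """Tilt/slant pair; tilt is NaN (undefined) when slant is zero."""

    tilt: float
    slant: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.slant <= 90.0:
            raise ValueError("slant must lie in [0, 90] degrees")


@dataclass(frozen=True)
class CollimatedLight:
    """Distant point source: azimuth/elevation in degrees, strength >= 0.

    Elevation is measured from the viewing direction (0 = behind the
    observer's shoulder pointing at the surface, 90 = grazing).
    """

    azimuth: float = 90.0
    elevation: float = 45.0
    strength: float = 5.0

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("light strength must be non-negative")
        if not 0.0 <= self.elevation <= 180.0:
            raise ValueError("elevation must lie in [0, 180] degrees")

    @property
    def unit_vector(self) -> np.ndarray:
        """Unit vector toward the source, display coords (x right, y up, z out)."""
        az = np.radians(self.azimuth)
        el = np.radians(self.elevation)
        return np.array(
            [np.sin(el) * np.cos(az), np.sin(el) * np.sin(az), np.cos(el)]
        )


@dataclass(frozen=True)
class Material:
    """Lambertian material; albedo in [0, 1]."""

    albedo: float = 0.3

    def __post_init__(self) -> None:
        if not 0.0 <= self.albedo <= 1.0:
            raise ValueError("albedo must lie in [0, 1]")


@dataclass(frozen=True)
class ShadedImage:
    """Relative-luminance raster in [0, 1] plus provenance metadata."""

    luminance: np.ndarray
    bit_depth: int | str = "float"
    display_scale: float = 1.0

    def __post_init__(self) -> None:
        L = np.asarray(self.luminance, dtype=float)
        object.__setattr__(self, "luminance", L)

    def quantized(self) -> np.ndarray:
        """8-bit view; quantization is always the last step."""
        return np.round(np.clip(self.luminance, 0, 1) * 255).astype(np.uint8)


@dataclass(frozen=True)
class CosineFalloff:
    """Parameters of L = A + B*cos(theta - C); B >= 0."""

    amplitude: float
    offset: float = 0.0
    phase: float = 90.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude B must be non-negative")


@dataclass(frozen=True)
class DefocusConfig:
    """Thin-lens blur model: sigma(z) = blur_gain * |z - focal| / f_number.

    ``blur_gain`` calibrates length units to blur pixels; the default is
    chosen so the strong-blur condition (f/1.4, far plane 0.6 length
    units from focus) yields sigma ~ 8 px on a 1024-pixel image.
    """

    focal_distance: float
    f_number: float
    blur_gain: float = 18.7

    def __post_init__(self) -> None:
        if self.f_number <= 0:
            raise ValueError("f_number must be positive")
        if self.blur_gain < 0:
            raise ValueError("blur_gain must be non-negative")


def lambert_luminance(
    s: SurfaceOrientation, light: CollimatedLight, m: Material
) -> float:
    """Clipped Lambertian luminance for one surface attitude.

    Equivalent to the spherical law of cosines
    ``r*i*(cos(slant)cos(el) + sin(slant)sin(el)cos(tilt - az))``
    clipped at zero.
    """
    slant = np.radians(s.slant)
    tilt = 0.0 if s.slant == 0 else np.radians(s.tilt)
    n = np.array(
        [np.sin(slant) * np.cos(tilt), np.sin(slant) * np.sin(tilt), np.cos(slant)]
    )
    return float(max(0.0, m.albedo * light.strength * n @ light.unit_vector))


def rim_luminance(theta_rim, falloff: CosineFalloff):
    """Luminance at a self-occluding rim of orientation ``theta_rim``.

    The slant-90 limit of the tilt cosine: the offset term vanishes and
    L = max(0, B*cos(theta_rim - C)).  Accepts scalars or arrays.
    """
    theta = np.asarray(theta_rim, dtype=float)
    L = falloff.offset + falloff.amplitude * np.cos(
        np.radians(theta - falloff.phase)
    )
    out = np.maximum(0.0, L)
    return float(out) if np.isscalar(theta_rim) else out


def surface_orientation_from_heights(
    h: HeightField,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (tilt, slant) arrays in degrees from central differences.

    The surface normal of relief h is proportional to (-hx, -hy, 1) in
    display coordinates (y up); rows run downward in storage, so the
    screen-vertical derivative is negated.  Tilt is NaN where the
    gradient vanishes.
    """
    d_row, d_col = np.gradient(h.heights, h.pixel_pitch)
    hx = d_col
    hy = -d_row  # storage rows run down-screen
    tilt = np.degrees(np.arctan2(-hy, -hx)) % 360.0
    tilt[(hx == 0) & (hy == 0)] = np.nan
    slant = np.degrees(np.arctan(np.hypot(hx, hy)))
    return tilt, slant


def render_height_field(
    h: HeightField,
    light: CollimatedLight | None = None,
    m: Material | None = None,
    normalize: str = "fixed-scale",
) -> ShadedImage:
    """Shade a height field under orthographic viewing.

    Per-pixel normals come from central differences; luminance follows
    the clipped Lambertian law.  ``normalize`` is one of ``"none"``,
    ``"fixed-scale"`` (divide by r*i so a fronto-parallel facet maps to
    cos(elevation) < 1) or ``"max-to-1"``; the applied scale is recorded
    on the output and values are clipped to [0, 1] afterwards.
    """
    light = light or CollimatedLight()
    m = m or Material()
    d_row, d_col = np.gradient(h.heights, h.pixel_pitch)
    hx, hy = d_col, -d_row
    norm = np.sqrt(hx**2 + hy**2 + 1.0)
    lvec = light.unit_vector
    ndotl = (-hx * lvec[0] - hy * lvec[1] + lvec[2]) / norm
    L = np.maximum(0.0, m.albedo * light.strength * ndotl)

    if normalize == "none":
        scale = 1.0
    elif normalize == "fixed-scale":
        scale = 1.0 / (m.albedo * light.strength)
    elif normalize == "max-to-1":
        peak = L.max()
        scale = 1.0 / peak if peak > 0 else 1.0
    else:
        raise ValueError(f"unknown normalization mode {normalize!r}")
    return ShadedImage(np.clip(L * scale, 0.0, 1.0), display_scale=scale)


def apply_mask(
    img: ShadedImage, m: LevelCutMask, gray: float | str = "mean"
) -> ShadedImage:
    """Composite the gray occluder over the shading.

    Masked pixels take the gray level (``"mean"``: the mean of the
    input image over all pixels, the level used for the gray occluders
    of the masking experiments); unmasked pixels are bit-identical to
    the input.
    """
    if img.luminance.shape != m.mask.shape:
        raise ValueError("image and mask shapes differ")
    level = float(img.luminance.mean()) if gray == "mean" else float(gray)
    out = img.luminance.copy()
    out[m.mask] = level
    return ShadedImage(out, img.bit_depth, img.display_scale)


def defocus_sigma(depth, cfg: DefocusConfig):
    """Blur scale (pixels) at each depth: blur_gain*|z - focal|/N."""
    return cfg.blur_gain * np.abs(np.asarray(depth, float) - cfg.focal_distance) / cfg.f_number


def depth_from_heights(h: HeightField, camera_distance: float) -> HeightField:
    """Depth map (camera distance minus relief) for defocus simulation."""
    return HeightField(camera_distance - h.heights, pixel_pitch=h.pixel_pitch, seed=h.seed)


def simulate_defocus(
    img: ShadedImage,
    depth: HeightField,
    cfg: DefocusConfig,
    n_bins: int = 12,
) -> ShadedImage:
    """Depth-of-field blur via layered, depth-binned Gaussian filtering.

    The depth map is split into ``n_bins`` (>= 8) equal-width bins; each
    layer is blurred with the sigma of its bin center and composited far
    to near with normalized (blurred) coverage, so kernels conserve
    energy and in-focus pixels pass through unchanged.  Layers whose
    sigma is below 0.05 px are copied verbatim.
    """
    if n_bins < 8:
        raise ValueError("need at least 8 depth bins")
    z = depth.heights
    if z.shape != img.luminance.shape:
        raise ValueError("depth map and image shapes differ")
    zmin, zmax = float(z.min()), float(z.max())
    if zmax == zmin:
        sigma = float(defocus_sigma(zmin, cfg))
        if sigma < 0.05:
            return ShadedImage(img.luminance.copy(), img.bit_depth, img.display_scale)
        return ShadedImage(
            ndimage.gaussian_filter(img.luminance, sigma, mode="reflect"),
            img.bit_depth,
            img.display_scale,
        )

    # bin edges include the focal plane as an edge when it lies in range,
    # so in-focus pixels fall in a bin whose center sigma is ~0
    edges = np.linspace(zmin, zmax, n_bins + 1)
    idx = np.clip(np.digitize(z, edges) - 1, 0, n_bins - 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # snap the bin containing the focal plane onto it: its layer stays sharp
    in_range = zmin <= cfg.focal_distance <= zmax
    if in_range:
        focal_bin = int(np.clip(np.digitize(cfg.focal_distance, edges) - 1, 0, n_bins - 1))
        centers[focal_bin] = cfg.focal_distance

    out = np.zeros_like(img.luminance)
    coverage = np.zeros_like(img.luminance)
    # depth = camera distance, so large values are far; composite far to near
    order = np.argsort(centers)[::-1]
    for b in order:
        layer_mask = (idx == b).astype(float)
        if not layer_mask.any():
            continue
        sigma = float(defocus_sigma(centers[b], cfg))
        if sigma < 0.05:
            blurred = img.luminance * layer_mask
            alpha = layer_mask
        else:
            blurred = ndimage.gaussian_filter(img.luminance * layer_mask, sigma, mode="reflect")
            alpha = ndimage.gaussian_filter(layer_mask, sigma, mode="reflect")
        out = blurred + (1.0 - alpha) * out
        coverage = alpha + (1.0 - alpha) * coverage
    with np.errstate(invalid="ignore", divide="ignore"):
        result = np.where(coverage > 1e-9, out / np.maximum(coverage, 1e-9), img.luminance)
    return ShadedImage(np.clip(result, 0.0, 1.0), img.bit_depth, img.display_scale)
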