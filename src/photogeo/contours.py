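"""Contour extraction, 360-degree orientation estimation, intensity sampling.

The covariation statistic needs, for every pixel along a level-cut
contour, (a) the orientation of the unit normal pointing from the
shading side into the gray mask, in the full 360-degree range, and
(b) the shading intensity immediately adjacent on the gradient side.
Orientation comes in two stages: an undirected tangent from a local
principal-component fit of contour coordinates in a square window
(default 9x9), then a side-of-contour probe that picks which of the two
candidate normals (tangent +/- 90 deg) lands inside the mask.  All
angles use the display convention (0 deg = right, 90 deg = up on
screen, counter-clockwise positive).

Contour pixels live on the *gradient* side of the boundary (non-mask
pixels with a masked 8-neighbour), so an intensity sample one pixel
inward never reads the mask gray.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .shading import ShadedImage
from .terrain import HeightField, LevelCutMask

__all__ = [
    "ContourPixelSet",
    "extract_contour_pixels",
    "estimate_orientation_180",
    "disambiguate_orientation_360",
    "sample_adjacent_intensity",
    "measure_contour",
    "ground_truth_tilt",
]

_EIGHT = np.ones((3, 3), dtype=bool)


@dataclass
class ContourPixelSet:
    """Per-pixel contour records: (row, col), into-mask normal, intensity.

    ``orientation`` is in degrees [0, 360), NaN where invalid;
    ``intensity`` is relative luminance on the gradient side, NaN where
    the probe fell off the image or the orientation is invalid.
    """

    positions: np.ndarray  # (n, 2) int, row/col storage order
    orientation: np.ndarray  # (n,) degrees [0, 360) or NaN
    intensity: np.ndarray  # (n,) luminance or NaN
    valid: np.ndarray  # (n,) bool

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def valid_fraction(self) -> float:
        return float(self.valid.mean()) if len(self) else 0.0

    def to_frame(self) -> pd.DataFrame:
        """CSV-ready table: x, y, orientation_deg, intensity, valid."""
        return pd.DataFrame(
            {
                "x": self.positions[:, 1],
                "y": self.positions[:, 0],
                "orientation_deg": self.orientation,
                "intensity": self.intensity,
                "valid": self.valid,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ContourPixelSet":
        return cls(
            positions=np.column_stack([df["y"].to_numpy(int), df["x"].to_numpy(int)]),
            orientation=df["orientation_deg"].to_numpy(float),
            intensity=df["intensity"].to_numpy(float),
            valid=df["valid"].to_numpy(bool),
        )


def extract_contour_pixels(m: LevelCutMask) -> np.ndarray:
    """Positions (row, col) of gradient-side boundary pixels.

    A contour pixel is a non-mask pixel with at least one mask pixel in
    its 8-neighbourhood.
    """
    mask = m.mask
    if mask.all() or not mask.any():
        raise ValueError("mask is uniform; no contour exists")
    ring = ndimage.binary_dilation(mask, structure=_EIGHT) & ~mask
    return np.argwhere(ring)


def estimate_orientation_180(
    positions: np.ndarray, window: int = 9, shape: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Undirected tangent angle per contour pixel, degrees [0, 180).

    For each pixel, the contour pixels inside the centered
    ``window`` x ``window`` block are fit by principal components; the
    leading axis is the local tangent.  Pixels with fewer than 3 contour
    neighbours in the window are flagged invalid (NaN tangent).

    Returns ``(tangent_deg, valid)``.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    positions = np.asarray(positions)
    n = len(positions)
    half = window // 2
    if shape is None:
        shape = tuple(positions.max(axis=0) + half + 1)
    grid = np.zeros(shape, dtype=bool)
    grid[positions[:, 0], positions[:, 1]] = True

    tangents = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for k, (r, c) in enumerate(positions):
        r0, r1 = max(0, r - half), min(shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(shape[1], c + half + 1)
        local = np.argwhere(grid[r0:r1, c0:c1])
        if len(local) < 3:
            continue
        # display coords: x = col, y = -row (screen up positive)
        xy = np.column_stack([local[:, 1], -local[:, 0]]).astype(float)
        xy -= xy.mean(axis=0)
        cov = xy.T @ xy
        # leading eigenvector of the 2x2 coordinate covariance
        evals, evecs = np.linalg.eigh(cov)
        vx, vy = evecs[:, -1]
        tangents[k] = np.degrees(np.arctan2(vy, vx)) % 180.0
        valid[k] = True
    return tangents, valid


def disambiguate_orientation_360(
    m: LevelCutMask,
    positions: np.ndarray,
    tangents: np.ndarray,
    probe_distance: int = 2,
) -> np.ndarray:
    """Resolve each tangent into the into-mask normal, degrees [0, 360).

    The two candidates are tangent +/- 90 deg; a probe ``probe_distance``
    pixels along each candidate decides which side is the mask.  A probe
    is also accepted when it lands off-image on a candidate whose twin
    clearly lands in the gradients.  Pixels where both or neither
    candidate hits the mask are NaN (invalid).
    """
    mask = m.mask
    rows, cols = mask.shape
    out = np.full(len(positions), np.nan)
    for k, (r, c) in enumerate(np.asarray(positions)):
        t = tangents[k]
        if not np.isfinite(t):
            continue
        hits = []
        for cand in ((t + 90.0) % 360.0, (t - 90.0) % 360.0):
            a = np.radians(cand)
            # display direction (cos, sin) -> storage step (-sin, cos)
            pr = r - int(round(probe_distance * np.sin(a)))
            pc = c + int(round(probe_distance * np.cos(a)))
            if 0 <= pr < rows and 0 <= pc < cols:
                hits.append(bool(mask[pr, pc]))
            else:
                hits.append(None)  # off image: inconclusive
        in_mask = [h is True for h in hits]
        if in_mask[0] != in_mask[1]:
            cand = (t + 90.0) % 360.0 if in_mask[0] else (t - 90.0) % 360.0
            out[k] = cand
    return out


def sample_adjacent_intensity(
    img: ShadedImage, positions: np.ndarray, orientations: np.ndarray, inset: int = 1
) -> np.ndarray:
    """Luminance ``inset`` pixels along the anti-normal (gradient side).

    Nearest-pixel rounding; probes that leave the image or start from an
    invalid orientation give NaN.
    """
    L = img.luminance
    rows, cols = L.shape
    out = np.full(len(positions), np.nan)
    for k, (r, c) in enumerate(np.asarray(positions)):
        theta = orientations[k]
        if not np.isfinite(theta):
            continue
        a = np.radians(theta)
        pr = r + int(round(inset * np.sin(a)))  # -N: +sin in storage rows
        pc = c - int(round(inset * np.cos(a)))
        if 0 <= pr < rows and 0 <= pc < cols:
            out[k] = L[pr, pc]
    return out


def measure_contour(
    img: ShadedImage, m: LevelCutMask, window: int = 9, inset: int = 1
) -> ContourPixelSet:
    """Full contour measurement: extract, orient, disambiguate, sample."""
    positions = extract_contour_pixels(m)
    tangents, tangent_ok = estimate_orientation_180(
        positions, window=window, shape=m.mask.shape
    )
    orientation = disambiguate_orientation_360(m, positions, tangents)
    intensity = sample_adjacent_intensity(img, positions, orientation, inset=inset)
    valid = tangent_ok & np.isfinite(orientation) & np.isfinite(intensity)
    return ContourPixelSet(positions, orientation, intensity, valid)


def ground_truth_tilt(h: HeightField) -> np.ndarray:
    """Per-pixel surface tilt in degrees [0, 360): the direction of -grad h.

    On a proximal-relief surface the image-projected normal points
    downhill, so tilt at a convex level cut equals the into-mask contour
    normal.  NaN where the gradient vanishes.
    """
    d_row, d_col = np.gradient(h.heights, h.pixel_pitch)
    gx = d_col
    gy = -d_row  # screen-up derivative
    tilt = np.degrees(np.arctan2(-gy, -gx)) % 360.0
    tilt[(gx == 0) & (gy == 0)] = np.nan
    return tilt
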