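"""The orientation-intensity covariation statistic.

Along the bounding contour of a shaded surface, Lambertian shading makes
intensity fall off as a cosine of the angular separation between the
contour-normal orientation and the illumination azimuth.  The statistic
quantifies how much of that structure an image actually contains:

1. convert each contour pixel's 360-degree orientation into an angular
   separation from a candidate illumination azimuth,
2. Pearson-correlate separation with adjacent shading intensity
   (sign-flipped so that shading-like falloff scores +1),
3. sweep 16 candidate azimuths (0 to 337.5 deg in 22.5-deg steps) and
   keep the maximum — the sweep guards against incidental correlations
   consistent with some other light direction.

A linear falloff stands in for the cosine because over the quarter
range [0, 90] deg the two are nearly collinear (Pearson r = 0.979, see
:func:`cosine_linear_correlation`).  A direct cosine fit of intensity
against orientation (:func:`cosine_fit`) recovers the amplitude/phase
parameters of the rim-shading model for plotting and diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .contours import ContourPixelSet
from .shading import CosineFalloff

__all__ = [
    "CovariationResult",
    "SWEEP_AZIMUTHS",
    "angular_separation",
    "pearson_covariation",
    "covariation_score",
    "cosine_fit",
    "cosine_linear_correlation",
]

SWEEP_AZIMUTHS = tuple(np.arange(16) * 22.5)


@dataclass(frozen=True)
class CovariationResult:
    """Outcome of the 16-azimuth sweep plus the cosine-fit diagnostics."""

    per_azimuth_r: np.ndarray  # 16 sign-adjusted Pearson values
    best_azimuth: float  # degrees, in the 22.5-deg grid
    score: float  # rho = max over azimuths
    n_pixels: int
    cosine_fit_r: float = np.nan
    cosine_fit_p: float = np.nan
    falloff: CosineFalloff | None = None

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "best_azimuth": self.best_azimuth,
            "n_pixels": self.n_pixels,
            "per_azimuth": {
                f"{a:g}": float(r) for a, r in zip(SWEEP_AZIMUTHS, self.per_azimuth_r)
            },
            "cosine_fit_r": self.cosine_fit_r,
            "cosine_fit_p": self.cosine_fit_p,
        }


def angular_separation(theta, azimuth):
    """Circular separation |theta - azimuth| folded into [0, 180] degrees."""
    d = np.abs(np.asarray(theta, float) - azimuth) % 360.0
    out = np.minimum(d, 360.0 - d)
    return float(out) if np.isscalar(theta) else out


def _valid_arrays(pixels: ContourPixelSet) -> tuple[np.ndarray, np.ndarray]:
    ok = pixels.valid & np.isfinite(pixels.orientation) & np.isfinite(pixels.intensity)
    return pixels.orientation[ok], pixels.intensity[ok]


def pearson_covariation(pixels: ContourPixelSet, azimuth: float) -> float:
    """Sign-adjusted Pearson r between angular separation and intensity.

    The raw correlation of separation with intensity is negated so a
    perfect shading-like falloff (intensity decreasing away from the
    light azimuth) scores +1.
    """
    theta, intensity = _valid_arrays(pixels)
    if len(theta) < 3:
        raise ValueError("need at least 3 valid contour pixels")
    sep = angular_separation(theta, azimuth)
    if np.ptp(sep) == 0 or np.ptp(intensity) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(-np.corrcoef(sep, intensity)[0, 1])


def covariation_score(
    pixels: ContourPixelSet, azimuths=SWEEP_AZIMUTHS, with_cosine_fit: bool = True
) -> CovariationResult:
    """Sweep candidate azimuths and keep the maximum correlation.

    Ties in the argmax break toward the smallest azimuth.  The cosine
    fit is attached when it is well posed (it can be degenerate, e.g.
    for constant fitted values, without invalidating the sweep).
    """
    rs = np.array([pearson_covariation(pixels, a) for a in azimuths])
    best = int(np.argmax(rs))  # argmax returns the first (smallest) on ties
    theta, _ = _valid_arrays(pixels)
    fit_r, fit_p, falloff = np.nan, np.nan, None
    if with_cosine_fit:
        try:
            falloff, fit_r, fit_p = cosine_fit(pixels)
        except ValueError:
            pass
    return CovariationResult(
        per_azimuth_r=rs,
        best_azimuth=float(azimuths[best]),
        score=float(rs[best]),
        n_pixels=len(theta),
        cosine_fit_r=fit_r,
        cosine_fit_p=fit_p,
        falloff=falloff,
    )


def cosine_fit(pixels: ContourPixelSet) -> tuple[CosineFalloff, float, float]:
    """Least-squares cosine of orientation: I ~ A + B*cos(theta - C).

    Linearized as I ~ A + u*cos(theta) + v*sin(theta) with
    B = hypot(u, v), C = atan2(v, u).  Returns the falloff parameters,
    the Pearson r between fitted and observed intensities, and its
    two-sided p-value (t approximation, n - 2 df).  The p-value ignores
    the spatial autocorrelation of neighbouring contour pixels and is
    descriptive, not inferential.
    """
    theta, intensity = _valid_arrays(pixels)
    if len(theta) < 4:
        raise ValueError("need at least 4 valid contour pixels")
    rad = np.radians(theta)
    design = np.column_stack([np.ones_like(rad), np.cos(rad), np.sin(rad)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design: cosine fit degenerate")
    coef, *_ = np.linalg.lstsq(design, intensity, rcond=None)
    offset, u, v = coef
    fitted = design @ coef
    if np.ptp(fitted) == 0 or np.ptp(intensity) == 0:
        raise ValueError("degenerate fit: constant fitted or observed values")
    r, p = stats.pearsonr(fitted, intensity)
    falloff = CosineFalloff(
        amplitude=float(np.hypot(u, v)),
        offset=float(offset),
        phase=float(np.degrees(np.arctan2(v, u)) % 360.0),
    )
    return falloff, float(r), float(p)


def cosine_linear_correlation(
    max_separation: float = 90.0, n: int = 100_001
) -> float:
    """|Pearson r| between a cosine and a linear falloff of separation.

    Evaluated on a dense uniform grid of angular separations in
    [0, ``max_separation``] degrees.  Over the quarter range this is
    0.979, the figure that justifies using a linear falloff in ribbon
    stimuli in place of Lambert's cosine.
    """
    sep = np.linspace(0.0, max_separation, n)
    return float(abs(np.corrcoef(sep, np.cos(np.radians(sep)))[0, 1]))
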