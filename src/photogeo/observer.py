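"""Synthetic observers: latent-score choice model and noisy gauge probes.

Human data collection is out of scope; this module generates choice and
gauge-figure data with the statistical structure the analysis layer
assumes, so every stage of that layer is testable end to end.  A
stimulus's latent "focus score" rises with the orientation-intensity
covariation of its contours and the convexity of the visible surface
and falls with defocus blur; paired choices follow a Bradley-Terry
(logistic) link on score differences with an optional lapse rate.

The default coefficients are arbitrary fixtures chosen to produce
well-separated scores for stimuli like those of the masking
experiments; they are NOT estimates of human observer parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .psychophysics import GaugeProbeSetting, PairedComparisonData

__all__ = [
    "ObserverModel",
    "focus_score_model",
    "simulate_choices",
    "simulate_gauge_settings",
    "gauge_truth_from_profile",
    "gauge_truth_from_gradient",
]

#: Fixture coefficients of the focus-score model (alpha: weight on the
#: covariation score, beta: weight on convex fraction, gamma: penalty
#: per ordinal blur level).  Not fitted to human data.
DEFAULT_COEFFICIENTS = {"alpha": 2.0, "beta": 1.0, "gamma": 0.75}


@dataclass
class ObserverModel:
    """Latent-score chooser: logistic link, decision noise tau, lapses."""

    scores: np.ndarray
    tau: float = 1.0
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.tau <= 0:
            raise ValueError("decision noise tau must be positive")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse rate must lie in [0, 0.5)")

    def choice_probability(self, i: int, j: int) -> float:
        """P(stimulus i chosen over j)."""
        from scipy.special import expit

        z = (self.scores[i] - self.scores[j]) / self.tau
        return float((1.0 - 2.0 * self.lapse) * expit(z) + self.lapse)


def focus_score_model(
    rho: float,
    convex_fraction: float,
    blur_level: float = 0.0,
    coefficients: dict | None = None,
) -> float:
    """Latent focus score of a stimulus.

    Monotone increasing in the covariation score ``rho`` and in the
    fraction of the visible surface that reads as convex, monotone
    decreasing in ordinal blur level (0 = no blur).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [-1, 1]")
    if not 0.0 <= convex_fraction <= 1.0:
        raise ValueError("convex_fraction must lie in [0, 1]")
    if blur_level < 0:
        raise ValueError("blur_level must be non-negative")
    c = coefficients or DEFAULT_COEFFICIENTS
    return c["alpha"] * rho + c["beta"] * convex_fraction - c["gamma"] * blur_level


def simulate_choices(
    model: ObserverModel,
    trials_per_pair: int = 1,
    seed: int | None = None,
    stimulus_ids: list | None = None,
) -> PairedComparisonData:
    """Seeded Bernoulli round-robin of all stimulus pairs."""
    if trials_per_pair < 1:
        raise ValueError("need at least one trial per pair")
    n = len(model.scores)
    rng = np.random.default_rng(model.seed if seed is None else seed)
    wins = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        p = model.choice_probability(i, j)
        won = rng.random(trials_per_pair) < p
        wins[i, j] = won.sum()
        wins[j, i] = trials_per_pair - won.sum()
    ids = stimulus_ids if stimulus_ids is not None else list(range(n))
    return PairedComparisonData(stimulus_ids=ids, wins=wins)


def gauge_truth_from_profile(
    heights: np.ndarray, spacing: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Exact (tilt, slant) gauge settings along a 1-D relief profile.

    Tilt is recorded as the uphill image direction along the
    (rightward, 0-degree) measurement line, so integrating
    ``tan(slant)*cos(tilt)`` recovers the relief itself; slopes are
    central differences of the profile.
    """
    g = np.gradient(np.asarray(heights, float), spacing)
    return gauge_truth_from_gradient(g)


def gauge_truth_from_gradient(gradient: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(tilt, slant) from exact along-line relief slopes.

    For analytic surfaces the closed-form derivative avoids the finite
    difference error of :func:`gauge_truth_from_profile`.
    """
    g = np.asarray(gradient, float)
    slant = np.degrees(np.arctan(np.abs(g)))
    tilt = np.where(g >= 0, 0.0, 180.0)
    return tilt, slant


def simulate_gauge_settings(
    tilt: np.ndarray,
    slant: np.ndarray,
    kappa: float = 0.0,
    seed: int = 0,
    observer: str = "sim",
    n_repeats: int = 1,
) -> list[GaugeProbeSetting]:
    """Perturb true probe attitudes with seeded angular noise.

    ``kappa`` is the dispersion (standard deviation, degrees) of
    Gaussian perturbations applied to tilt and slant; slant is clipped
    to [0, 89.9] to keep gradients bounded.  ``kappa = 0`` returns the
    exact ground truth.
    """
    if kappa < 0:
        raise ValueError("angular noise dispersion must be non-negative")
    tilt = np.asarray(tilt, float)
    slant = np.asarray(slant, float)
    if tilt.shape != slant.shape:
        raise ValueError("tilt and slant must have the same length")
    rng = np.random.default_rng(seed)
    settings: list[GaugeProbeSetting] = []
    for rep in range(n_repeats):
        t = (tilt + rng.normal(0.0, kappa, tilt.shape)) % 360.0 if kappa > 0 else tilt
        s = np.clip(slant + (rng.normal(0.0, kappa, slant.shape) if kappa > 0 else 0.0), 0.0, 89.9)
        for k in range(len(tilt)):
            settings.append(
                GaugeProbeSetting(
                    probe=k + 1,
                    slant=float(s[k]),
                    tilt=float(t[k]),
                    observer=observer,
                    repeat=rep,
                )
            )
    return settings
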