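"""Analysis layer for paired-comparison and gauge-figure data.

Covers the descriptive statistics used to summarize two-alternative
forced-choice experiments (percent-chosen tallies, binning of trials by
measured covariation, selection-slope regression), a Bradley-Terry
latent-score fit used to validate synthetic choice data, and the
reconstruction of perceived-relief cross sections from gauge-figure
slant/tilt probe settings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "PairedComparisonData",
    "GaugeProbeSetting",
    "ReliefProfile",
    "tally_choices",
    "bin_by_correlation",
    "selection_slope",
    "fit_latent_scores",
    "reconstruct_profile",
    "normalize_profiles",
]


@dataclass
class PairedComparisonData:
    """Round-robin choice counts: wins[i, j] = times i was chosen over j."""

    stimulus_ids: list
    wins: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wins, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("wins must be a square matrix")
        if w.shape[0] != len(self.stimulus_ids):
            raise ValueError("wins shape does not match number of stimuli")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal of wins must be zero")
        if np.any(w < 0):
            raise ValueError("win counts must be non-negative")
        self.wins = w

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_ids)

    @property
    def pair_totals(self) -> np.ndarray:
        return self.wins + self.wins.T


@dataclass
class GaugeProbeSetting:
    """One gauge-figure adjustment: probe index, slant/tilt, identifiers."""

    probe: int  # 1-based position along the measurement line
    slant: float  # degrees [0, 90]
    tilt: float  # degrees [0, 360)
    observer: str = "obs"
    repeat: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.slant <= 90.0:
            raise ValueError("slant must lie in [0, 90] degrees")


@dataclass
class ReliefProfile:
    """Heights at the probe positions, normalized distance units."""

    heights: np.ndarray
    observer: str = "obs"

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)


def tally_choices(d: PairedComparisonData) -> pd.Series:
    """Percent of appearances in which each stimulus was chosen.

    Requires a complete round-robin (every off-diagonal pair presented
    at least once).  Over a complete balanced design the tallies
    average exactly 50%.
    """
    totals = d.pair_totals
    off = ~np.eye(d.n_stimuli, dtype=bool)
    if np.any(totals[off] == 0):
        raise ValueError("incomplete design: some pairs were never presented")
    appearances = totals.sum(axis=1)
    percent = 100.0 * d.wins.sum(axis=1) / appearances
    return pd.Series(percent, index=d.stimulus_ids, name="percent_chosen")


def bin_by_correlation(records: pd.DataFrame) -> pd.Series:
    """Percent-chosen per covariation bin.

    ``records`` has columns ``rho`` (the measured covariation of the
    stimulus on that trial) and ``chosen`` (bool).  Bins are
    [0.9, 1.0], [0.8, 0.9), ..., [0.4, 0.5), plus a bottom bin
    collecting every trial with rho < 0.4.  Empty bins are reported as
    missing (NaN), not zero.
    """
    rho = np.asarray(records["rho"], dtype=float)
    chosen = np.asarray(records["chosen"], dtype=bool)
    if np.any(rho < -1) or np.any(rho > 1):
        raise ValueError("rho values must lie in [-1, 1]")
    labels = ["<0.4"] + [f"[{lo:.1f},{lo + 0.1:.1f})" for lo in np.arange(0.4, 0.9, 0.1)] + ["[0.9,1.0]"]
    edges = np.array([-np.inf, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, np.inf])
    idx = np.digitize(rho, edges) - 1
    out = pd.Series(np.nan, index=labels, name="percent_chosen")
    for b, label in enumerate(labels):
        sel = idx == b
        if sel.any():
            out[label] = 100.0 * chosen[sel].mean()
    return out


def selection_slope(noise_percent, percent_chosen) -> tuple[float, float]:
    """OLS slope of percent-chosen on noise percentage, with R^2.

    Returns ``(b, r_squared)``; a slope of -1 means one percentile of
    selection likelihood lost per percentile of added ribbon noise.
    """
    x = np.asarray(noise_percent, dtype=float)
    y = np.asarray(percent_chosen, dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct noise levels")
    design = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(coef[1]), r2


def fit_latent_scores(d: PairedComparisonData, tol: float = 1e-8, max_iter: int = 10_000) -> np.ndarray:
    """Bradley-Terry maximum-likelihood scores, zero-sum identified.

    P(i beats j) = logistic(s_i - s_j).  Fit by the standard MM
    iteration on the worth parameters; requires a connected comparison
    graph with no stimulus winning or losing every single trial (such
    data push scores to infinity).
    """
    wins = d.wins
    n = d.n_stimuli
    totals = d.pair_totals
    # connectivity of the comparison graph
    adj = totals > 0
    reached = np.zeros(n, dtype=bool)
    stack = [0]
    while stack:
        i = stack.pop()
        if reached[i]:
            continue
        reached[i] = True
        stack.extend(np.flatnonzero(adj[i] & ~reached))
    if not reached.all():
        raise ValueError("comparison graph is disconnected: scores not identifiable")
    w_i = wins.sum(axis=1)
    l_i = wins.sum(axis=0)
    if np.any((w_i == 0) | (l_i == 0)) and n > 1:
        # a stimulus that never wins (or never loses) has an infinite MLE
        raise ValueError("all-one-sided data: scores not identifiable")

    p = np.ones(n)
    for _ in range(max_iter):
        denom = totals / (p[:, None] + p[None, :])
        np.fill_diagonal(denom, 0.0)
        new = w_i / denom.sum(axis=1)
        new /= np.exp(np.mean(np.log(new)))  # geometric-mean identification
        if np.max(np.abs(new - p)) < tol:
            p = new
            break
        p = new
    scores = np.log(p)
    return scores - scores.mean()


def reconstruct_profile(
    settings: list[GaugeProbeSetting],
    spacing: float = 1.0,
    line_direction: float = 0.0,
    observer: str | None = None,
) -> ReliefProfile:
    """Integrate gauge-figure settings into a relief cross-section.

    The along-line depth gradient at each probe is
    ``g = tan(slant) * cos(tilt - line_direction)``; repeats are
    averaged at the gradient stage (integration is linear, so this
    equals averaging profiles but tolerates missing repeats), then the
    gradients are integrated by the trapezoid rule from zero.
    """
    if observer is not None:
        settings = [s for s in settings if s.observer == observer]
    probes = sorted({s.probe for s in settings})
    if len(probes) == 0:
        raise ValueError("no probe settings supplied")
    grads = []
    for p in probes:
        here = [s for s in settings if s.probe == p]
        g = []
        for s in here:
            if s.slant >= 90.0:
                raise ValueError("slant of 90 degrees gives an unbounded gradient")
            g.append(np.tan(np.radians(s.slant)) * np.cos(np.radians(s.tilt - line_direction)))
        grads.append(np.mean(g))
    heights = integrate.cumulative_trapezoid(grads, dx=spacing, initial=0.0)
    obs = observer if observer is not None else (settings[0].observer if settings else "obs")
    return ReliefProfile(heights=heights, observer=obs)


def normalize_profiles(
    profiles: list[ReliefProfile],
) -> tuple[list[ReliefProfile], np.ndarray, np.ndarray]:
    """Scale each observer's profile to the grand mean height, then average.

    Returns ``(normalized profiles, mean profile, per-point SEM)``.
    Profiles with zero mean cannot be rescaled multiplicatively and are
    rejected.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    means = np.array([p.heights.mean() for p in profiles])
    if np.any(means == 0):
        raise ValueError("zero-mean profile cannot be scaled to the grand mean")
    grand = means.mean()
    normalized = [
        ReliefProfile(p.heights * (grand / m), observer=p.observer)
        for p, m in zip(profiles, means)
    ]
    stack = np.vstack([p.heights for p in normalized])
    mean_profile = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(profiles)) if len(profiles) > 1 else np.zeros(stack.shape[1])
    return normalized, mean_profile, sem
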