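"""Circular statistics for directional attention read-outs.

A fish's per-frame body orientations are summarised by the mean resultant
vector r = mean(cos a_i, sin a_i); its length R in [0, 1] measures directional
focus (R -> 1: all orientations identical; R -> 0: no preferred direction) and
is inversely related to the angular standard deviation.  The projection of r
onto the stimulus direction (180 deg here) gives a linear score in [-1, 1]:
positive toward the stimulus, negative away.

A treatment group of fish is summarised by the grand vector average of the
individual resultant vectors — each fish's direction implicitly weighted by
its own focus R — and group-level departure from circular uniformity is
tested with Moore's Modified Rayleigh test, a nonparametric test on the ranks
of the individual vector lengths with a seeded Monte-Carlo null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError

#: resultant lengths below this are treated as a vanishing vector (alpha undefined)
R_UNDEFINED_TOL = 1e-12


def wrap_degrees(a):
    """Map angles to [0, 360)."""
    return np.mod(a, 360.0)


def angdiff_degrees(a, b):
    """Signed angular difference a - b wrapped to (-180, 180]."""
    d = np.mod(np.asarray(a, float) - np.asarray(b, float), 360.0)
    return np.where(d > 180.0, d - 360.0, d)


@dataclass(frozen=True)
class ResultantVector:
    """Mean direction alpha (deg, None when undefined) and length R in [0,1]."""

    alpha: float | None
    R: float
    n: int

    def __post_init__(self):
        if not 0.0 <= self.R <= 1.0 + 1e-9:
            raise ValidationError(f"resultant length {self.R} outside [0, 1]")

    @property
    def defined(self) -> bool:
        return self.alpha is not None

    def cartesian(self) -> tuple[float, float]:
        """(x, y) components; the zero vector when alpha is undefined."""
        if not self.defined:
            return (0.0, 0.0)
        a = math.radians(self.alpha)
        return (self.R * math.cos(a), self.R * math.sin(a))


@dataclass(frozen=True)
class GroupVector:
    """Length-weighted grand mean of a group's individual resultant vectors."""

    alpha_g: float | None
    R_g: float
    n_fish: int
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def defined(self) -> bool:
        return self.alpha_g is not None


@dataclass(frozen=True)
class MooreTestResult:
    R_star: float
    p: float
    n_mc: int
    seed: int


def mean_resultant_vector(angles_deg: Sequence[float]) -> ResultantVector:
    """Mean resultant vector of a sample of angles (degrees).

    r = mean over frames of the unit vectors (cos a_i, sin a_i); R = |r|;
    alpha = atan2(r_y, r_x) mapped to [0, 360), flagged undefined when R = 0.
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    if a.size == 0:
        raise ValidationError("need at least one angle")
    if np.isnan(a).any():
        raise ValidationError("angles contain NaN")
    x = float(np.mean(np.cos(a)))
    y = float(np.mean(np.sin(a)))
    R = min(math.hypot(x, y), 1.0)
    if R < R_UNDEFINED_TOL:
        return ResultantVector(alpha=None, R=0.0, n=a.size)
    alpha = math.degrees(math.atan2(y, x)) % 360.0
    return ResultantVector(alpha=alpha, R=R, n=a.size)


def project_onto_direction(rv: ResultantVector, direction_deg: float = 180.0) -> float:
    """R * cos(alpha - direction): directional focus along ``direction_deg``.

    +R means fully aligned with the direction, -R fully opposite, 0 when the
    resultant vector vanishes.
    """
    if not rv.defined:
        return 0.0
    return rv.R * math.cos(math.radians(rv.alpha - direction_deg))


def group_mean_vector(members: Sequence[ResultantVector]) -> GroupVector:
    """Vector average of individual resultant vectors.

    Each member contributes its Cartesian resultant (already scaled by its own
    R), so directions of more focused fish weigh more.  Members with an
    undefined direction contribute the zero vector.
    """
    if len(members) == 0:
        raise ValidationError("empty group")
    if not any(m.defined for m in members):
        raise ValidationError("no member has a defined mean direction")
    xy = np.array([m.cartesian() for m in members], dtype=float)
    x, y = xy.mean(axis=0)
    R_g = math.hypot(x, y)
    if R_g < R_UNDEFINED_TOL:
        return GroupVector(alpha_g=None, R_g=0.0, n_fish=len(members))
    alpha_g = math.degrees(math.atan2(y, x)) % 360.0
    return GroupVector(alpha_g=alpha_g, R_g=R_g, n_fish=len(members))


def moore_rank_statistic(alphas_deg: np.ndarray, lengths: np.ndarray) -> float:
    """Moore's rank-weighted resultant R*.

    Lengths are ranked ascending (average ranks on ties); with unit vectors at
    the member directions weighted by rank, R* = sqrt(X^2 + Y^2) / N^{3/2}.
    """
    n = len(alphas_deg)
    ranks = stats.rankdata(lengths)  # average ranks on ties
    a = np.radians(alphas_deg)
    x = float(np.sum(ranks * np.cos(a)))
    y = float(np.sum(ranks * np.sin(a)))
    return math.sqrt(x * x + y * y) / n**1.5


def moores_rayleigh_test(
    members: Sequence[ResultantVector],
    n_mc: int = 9999,
    seed: int = 0,
) -> MooreTestResult:
    """Moore's Modified Rayleigh test of circular uniformity.

    Tests whether the individual mean directions, weighted by the ranks of
    their resultant lengths, deviate from uniformity.  The p-value is Monte
    Carlo: each replicate redraws N independent uniform directions while
    keeping the observed ranks, and p = (1 + #{R*_mc >= R*}) / (n_mc + 1).
    """
    if len(members) < 4:
        raise InsufficientDataError("Moore's test needs at least 4 members")
    if n_mc < 999:
        raise ValidationError("n_mc must be at least 999")
    if not all(m.defined for m in members):
        raise ValidationError("all members must have a defined mean direction")
    alphas = np.array([m.alpha for m in members], dtype=float)
    lengths = np.array([m.R for m in members], dtype=float)
    n = len(members)
    r_star = moore_rank_statistic(alphas, lengths)

    rng = np.random.default_rng(seed)
    ranks = stats.rankdata(lengths)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_mc, n))
    x = (ranks * np.cos(theta)).sum(axis=1)
    y = (ranks * np.sin(theta)).sum(axis=1)
    r_mc = np.sqrt(x * x + y * y) / n**1.5
    p = (1.0 + int(np.count_nonzero(r_mc >= r_star))) / (n_mc + 1.0)
    return MooreTestResult(R_star=r_star, p=p, n_mc=n_mc, seed=seed)


def bootstrap_direction_ci(
    members: Sequence[ResultantVector],
    conf: float = 0.95,
    reps: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the group mean direction (degrees).

    Fish are resampled with replacement; each resample's group direction is
    expressed as a signed angular deviation from the point estimate before
    taking percentiles, avoiding the 0/360 wrap-around.  Resamples with a
    vanishing group vector are redrawn (error after 100 consecutive failures).
    Returns (ci_low, ci_high) in [0, 360); the interval may wrap through 0.
    """
    if len(members) < 5:
        raise InsufficientDataError("bootstrap CI needs at least 5 members")
    if not 0.0 <= conf < 1.0:
        raise ValidationError("conf must lie in [0, 1)")
    point = group_mean_vector(members)
    if not point.defined:
        raise ValidationError("group mean direction undefined; no CI")
    if conf == 0.0:
        return (point.alpha_g, point.alpha_g)

    rng = np.random.default_rng(seed)
    n = len(members)
    xy = np.array([m.cartesian() for m in members], dtype=float)
    devs = np.empty(reps)
    failures = 0
    i = 0
    while i < reps:
        idx = rng.integers(0, n, size=n)
        x, y = xy[idx].mean(axis=0)
        if math.hypot(x, y) < R_UNDEFINED_TOL:
            failures += 1
            if failures >= 100:
                raise ValidationError("bootstrap degenerate: 100 consecutive zero-resultant resamples")
            continue
        failures = 0
        alpha_b = math.degrees(math.atan2(y, x)) % 360.0
        devs[i] = angdiff_degrees(alpha_b, point.alpha_g)
        i += 1
    lo_q, hi_q = (1.0 - conf) / 2.0, 1.0 - (1.0 - conf) / 2.0
    lo, hi = np.quantile(devs, [lo_q, hi_q])
    return (float((point.alpha_g + lo) % 360.0), float((point.alpha_g + hi) % 360.0))


def ci_width_degrees(ci: tuple[float, float]) -> float:
    """Width of a (possibly wrapping) directional CI in degrees."""
    return float(np.mod(ci[1] - ci[0], 360.0))
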