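"""Preference priors: log probabilities of observations under the driver's goals.

In active inference, goals are encoded as prior distributions over
*observations*: the agent prefers policies whose predicted observations
score a high log probability under these priors (pragmatic value).  Four
prior families cover both driving scenarios:

* Gaussian — speed keeping (centred at the speed limit), comfortable
  acceleration and steering rate (centred at zero);
* symmetric triangular — lane keeping, peaked at the lane centre and
  vanishing at the lane boundaries;
* Bernoulli over gaze direction — the motivation to look off-road at a
  secondary task, parameterised by the log probability of an on-road
  glance;
* absolute categorical — hard aversions (conflict with a pedestrian,
  exiting the lane), assigning the preferred outcome probability ~1 and
  the forbidden outcome a large negative log probability.

All evaluations are finite: zero-density points (triangular bounds, a
degenerate Bernoulli) return a configured floor rather than -inf so that
expected-free-energy arithmetic stays finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LOG_FLOOR",
    "EXPORT_FLOOR",
    "gaussian_logpdf",
    "triangular_logpdf",
    "bernoulli_gaze_logprob",
    "categorical_logprob",
    "GaussianPrior",
    "TriangularPrior",
    "BernoulliGazePrior",
    "CategoricalAbsolutePrior",
    "PreferenceEntry",
    "PreferenceModel",
]

#: Internal log-probability floor used during planning and filtering.
LOG_FLOOR = -1000.0

#: Truncation applied when exporting value traces for plotting, where the
#: internal floor would dwarf every other feature of the curves.
EXPORT_FLOOR = -100.0

_LOG_2PI = float(np.log(2.0 * np.pi))


def gaussian_logpdf(x, mu: float, sigma: float):
    """Log density of a normal distribution, vectorised over ``x``.

    Raises ``ValueError`` for non-positive ``sigma`` (configuration error).
    """
    if sigma <= 0:
        raise ValueError(f"Gaussian prior requires sigma > 0, got {sigma}")
    x = np.asarray(x, dtype=float)
    z = (x - mu) / sigma
    return -0.5 * _LOG_2PI - np.log(sigma) - 0.5 * z * z


def triangular_logpdf(y, center: float, lower: float, upper: float, floor: float = LOG_FLOOR):
    """Log density of a symmetric triangular distribution.

    The density peaks at ``center`` with value ``2 / (upper - lower)`` and
    decays linearly to zero at the bounds.  Values at or beyond the bounds
    return ``floor`` (not -inf).
    """
    if not (lower < center < upper):
        raise ValueError(
            f"Triangular prior requires lower < center < upper, got ({lower}, {center}, {upper})"
        )
    y = np.asarray(y, dtype=float)
    peak = 2.0 / (upper - lower)
    # Linear decay on each side of the peak.
    left = (y - lower) / (center - lower)
    right = (upper - y) / (upper - center)
    frac = np.where(y <= center, left, right)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(frac > 0, np.log(peak * np.clip(frac, 1e-300, None)), floor)
    return np.maximum(out, floor)


def bernoulli_gaze_logprob(gaze_on, log_p_on: float, floor: float = LOG_FLOOR):
    """Log probability of a gaze state under a normalized Bernoulli prior.

    ``log_p_on`` is the log probability of an on-road glance; the off-road
    probability is ``1 - exp(log_p_on)`` so the distribution normalizes.
    ``gaze_on`` is truthy (1) for on-road, falsy (0) for off-road.
    """
    if log_p_on > 0:
        raise ValueError(f"log_p_on must be <= 0, got {log_p_on}")
    gaze_on = np.asarray(gaze_on)
    if log_p_on == 0.0:
        log_p_off = floor  # degenerate: off-road has probability 0
    else:
        log_p_off = float(np.log1p(-np.exp(log_p_on)))
        log_p_off = max(log_p_off, floor)
    return np.where(gaze_on.astype(bool), log_p_on, log_p_off)


def categorical_logprob(flag, forbidden_logprob: float = LOG_FLOOR):
    """Absolute categorical preference: 0 for the preferred state, a large
    negative value for the forbidden one (conflict / lane exit)."""
    flag = np.asarray(flag)
    return np.where(flag.astype(bool), forbidden_logprob, 0.0)


@dataclass(frozen=True)
class GaussianPrior:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"Gaussian prior requires sigma > 0, got {self.sigma}")

    def logpdf(self, x):
        return gaussian_logpdf(x, self.mu, self.sigma)

    @property
    def max_logpdf(self) -> float:
        return float(gaussian_logpdf(self.mu, self.mu, self.sigma))


@dataclass(frozen=True)
class TriangularPrior:
    center: float
    lower: float
    upper: float
    floor: float = LOG_FLOOR

    def __post_init__(self):
        if not (self.lower < self.center < self.upper):
            raise ValueError("Triangular prior requires lower < center < upper")

    def logpdf(self, y):
        return triangular_logpdf(y, self.center, self.lower, self.upper, self.floor)

    @property
    def max_logpdf(self) -> float:
        return float(np.log(2.0 / (self.upper - self.lower)))


@dataclass(frozen=True)
class BernoulliGazePrior:
    log_p_on: float
    floor: float = LOG_FLOOR

    def __post_init__(self):
        if self.log_p_on > 0:
            raise ValueError("log_p_on must be <= 0")

    def logpdf(self, gaze_on):
        return bernoulli_gaze_logprob(gaze_on, self.log_p_on, self.floor)

    @property
    def max_logpdf(self) -> float:
        return float(np.max(self.logpdf(np.array([0.0, 1.0]))))


@dataclass(frozen=True)
class CategoricalAbsolutePrior:
    forbidden_logprob: float = LOG_FLOOR

    def logpdf(self, flag):
        return categorical_logprob(flag, self.forbidden_logprob)

    @property
    def max_logpdf(self) -> float:
        return 0.0


@dataclass(frozen=True)
class PreferenceEntry:
    """One preference: a prior attached to an observation dimension.

    ``maskable`` marks dimensions that drop out of the pragmatic value when
    they cannot be observed (e.g. lateral position during an off-road
    glance).
    """

    name: str
    obs_index: int
    prior: object
    maskable: bool = False


@dataclass
class PreferenceModel:
    """Named collection of preference priors over observation dimensions."""

    entries: list[PreferenceEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def max_pragmatic(self) -> float:
        """Sum of peak log densities: the best attainable per-step pragmatic
        value when every observation sits at its preference mode."""
        return float(sum(e.prior.max_logpdf for e in self.entries))
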