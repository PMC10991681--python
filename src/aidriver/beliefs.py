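"""Particle-ensemble belief representation and SIR filtering.

The agent's belief Q(s) over the hidden scenario state is a weighted set
of N particles, each a full realization of the state vector.  Belief
updates use a sequential importance resampling (SIR) filter: particles
are propagated through the transition model under the executed action,
reweighted by the observation likelihood, and systematically resampled
when the effective sample size N / (1 + sum w^2) drops below N/2.

Observation likelihoods: the scenarios' observation maps are
deterministic, which would give degenerate 0/1 likelihoods.  Continuous
observation dimensions therefore use a narrow Gaussian kernel (sigma_obs,
in native units) around the predicted observation, while discrete and
null-coded dimensions use exact match with a large negative log floor on
mismatch.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np

from .priors import LOG_FLOOR

__all__ = [
    "NULL_CODE",
    "ParticleEnsemble",
    "TransitionModel",
    "ObservationModel",
    "effective_sample_size",
    "systematic_resample",
    "sir_update",
]

logger = logging.getLogger("aidriver")

#: Numeric code for "not observable" (an occluded pedestrian position, the
#: road ahead during an off-road glance): a value far away from anything
#: physical so kernel-density machinery operates on purely numeric vectors.
NULL_CODE = -1000.0

# Observation-dimension kinds, used by the likelihood.
CONT = "cont"          # continuous, Gaussian kernel
DISC = "disc"          # discrete label, exact match
NULLABLE = "nullable"  # continuous but may carry NULL_CODE


@dataclass
class ParticleEnsemble:
    """Weighted particle set representing the belief Q(s).

    ``states`` has shape (N, D); ``weights`` shape (N,), nonnegative,
    summing to 1.
    """

    states: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.states.shape[0] != self.weights.shape[0]:
            raise ValueError("states and weights must have the same length")
        if self.n < 2:
            raise ValueError("a particle ensemble needs at least 2 particles")
        self.validate()

    @property
    def n(self) -> int:
        return self.states.shape[0]

    def validate(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("particle weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"particle weights must sum to 1, got {self.weights.sum()!r}")

    def mean(self, index: int) -> float:
        return float(np.dot(self.weights, self.states[:, index]))

    def std(self, index: int) -> float:
        m = self.mean(index)
        var = float(np.dot(self.weights, (self.states[:, index] - m) ** 2))
        return float(np.sqrt(max(var, 0.0)))

    def prob(self, index: int, value: float = 1.0) -> float:
        """Posterior probability that a discrete state dimension equals ``value``."""
        return float(np.dot(self.weights, self.states[:, index] == value))

    def copy(self) -> "ParticleEnsemble":
        return ParticleEnsemble(self.states.copy(), self.weights.copy())


class TransitionModel(Protocol):
    """P(s'|s,a): vectorised state transition.

    ``step`` maps states of shape (..., D) and actions of shape (..., A)
    to next states (..., D), deterministic given the random generator state.
    """

    def step(self, states: np.ndarray, actions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        ...


class ObservationModel(Protocol):
    """P(o|s): deterministic observation map plus a likelihood kernel."""

    obs_kinds: Sequence[str]
    sigma_obs: float
    epistemic_dims: Sequence[int]

    def observe(self, states: np.ndarray) -> np.ndarray:
        ...


def effective_sample_size(weights: np.ndarray) -> float:
    """Effective sample size N / (1 + sum w_n^2) of a normalized weight set.

    This is the form used throughout this package (it differs from the
    textbook 1 / sum w^2 by an additive regularisation in the denominator;
    both reduce to ~N for uniform weights and ~N/2 at full degeneracy).
    """
    weights = np.asarray(weights, dtype=float)
    if abs(weights.sum() - 1.0) > 1e-6:
        raise ValueError("effective_sample_size expects normalized weights")
    n = weights.shape[0]
    return float(n / (1.0 + np.sum(weights**2)))


def systematic_resample(
    ensemble: ParticleEnsemble,
    rng: np.random.Generator,
    offset: float | None = None,
) -> ParticleEnsemble:
    """Systematic resampling: N equidistant points in cumulative-weight space
    with a single uniform offset; output weights exactly uniform.

    ``offset`` in [0, 1/N) may be supplied explicitly (used by tests to
    enumerate all outcomes); by default it is drawn from ``rng``.
    """
    n = ensemble.n
    if offset is None:
        offset = float(rng.uniform(0.0, 1.0 / n))
    positions = offset + np.arange(n) / n
    cumulative = np.cumsum(ensemble.weights)
    cumulative[-1] = 1.0 + 1e-12  # guard against round-off
    idx = np.searchsorted(cumulative, positions, side="right")
    return ParticleEnsemble(ensemble.states[idx], np.full(n, 1.0 / n))


def observation_log_likelihood(
    observation: np.ndarray,
    predicted: np.ndarray,
    obs_kinds: Sequence[str],
    sigma_obs: float,
    floor: float = LOG_FLOOR,
) -> np.ndarray:
    """Per-particle log likelihood of ``observation`` given each particle's
    predicted (deterministic) observation.

    Continuous dims use a Gaussian kernel of scale ``sigma_obs``; discrete
    dims use exact match with ``floor`` on mismatch; nullable dims match
    null-against-null exactly, real-against-real through the kernel, and
    null/real disagreement at the floor.  Each dimension's contribution is
    itself floored so a single wild dimension cannot drive the total below
    ``floor`` times the dimension count.
    """
    predicted = np.atleast_2d(predicted)
    total = np.zeros(predicted.shape[0])
    inv2 = 1.0 / (2.0 * sigma_obs**2)
    for d, kind in enumerate(obs_kinds):
        o = observation[d]
        p = predicted[:, d]
        if kind == DISC:
            contrib = np.where(p == o, 0.0, floor)
        elif kind == NULLABLE:
            o_null = o == NULL_CODE
            p_null = p == NULL_CODE
            if o_null:
                contrib = np.where(p_null, 0.0, floor)
            else:
                contrib = np.where(p_null, floor, np.maximum(-((p - o) ** 2) * inv2, floor))
        else:  # CONT
            contrib = np.maximum(-((p - o) ** 2) * inv2, floor)
        total = total + contrib
    return total


def low_variance_draw(
    ensemble: ParticleEnsemble, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw k particle states by weight with systematic (low-variance)
    sampling, so discrete belief fractions are represented at their
    round-proportional counts instead of with binomial noise.  Used to
    hand planning particles to the policy optimizer."""
    offset = float(rng.uniform(0.0, 1.0 / k))
    positions = offset + np.arange(k) / k
    cumulative = np.cumsum(ensemble.weights)
    cumulative[-1] = 1.0
    idx = np.searchsorted(cumulative, positions, side="right")
    return ensemble.states[idx]


def sir_update(
    ensemble: ParticleEnsemble,
    action: np.ndarray,
    observation: np.ndarray,
    transition_model: TransitionModel,
    observation_model: ObservationModel,
    rng: np.random.Generator,
) -> ParticleEnsemble:
    """One SIR step: propagate, reweight by likelihood, resample if degenerate.

    If every particle's likelihood sits at the log floor (total conflict
    between belief and observation) the weights are reset to uniform and a
    warning is logged.
    """
    n = ensemble.n
    actions = np.broadcast_to(np.asarray(action, dtype=float), (n, np.size(action)))
    next_states = transition_model.step(ensemble.states, actions, rng)
    predicted = observation_model.observe(next_states)
    loglik = observation_log_likelihood(
        observation, predicted, observation_model.obs_kinds, observation_model.sigma_obs
    )
    n_dims = len(observation_model.obs_kinds)
    if np.all(loglik <= LOG_FLOOR):
        msg = "belief-observation total conflict: all likelihoods at floor; weights reset"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        weights = np.full(n, 1.0 / n)
    else:
        # Stabilised exponentiation; relative weights are what matter.
        w = ensemble.weights * np.exp(loglik - loglik.max())
        total = w.sum()
        if not np.isfinite(total) or total <= 0.0:
            logger.warning("degenerate posterior weights; resetting to uniform")
            weights = np.full(n, 1.0 / n)
        else:
            weights = w / total
    updated = ParticleEnsemble(next_states, weights)
    # The resampling trigger uses the standard effective sample size
    # 1/sum(w^2) (range [1, N]); the regularised form N/(1+sum w^2) that
    # effective_sample_size reports has range [N/2, N] and therefore can
    # never fall below the N/2 threshold, which would leave the filter
    # stuck on a single high-weight particle.
    if 1.0 / np.sum(weights**2) < n / 2.0:
        updated = systematic_resample(updated, rng)
    return updated
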