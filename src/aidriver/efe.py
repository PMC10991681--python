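"""Expected free energy: policy rollout and pragmatic/epistemic scoring.

A policy (a length-H sequence of actions) is scored by

    G(pi) = sum_tau [ -pragmatic_tau - epistemic_tau ]

where the pragmatic value at lookahead step tau is the mean log
probability of the predicted observations under the preference priors,
and the epistemic value is the expected information gain, computed
through the entropy decomposition: posterior-predictive entropy of the
predicted observations minus the expected ambiguity.

Both terms are estimated from particles.  The predictive entropy uses a
leave-one-out Gaussian kernel density estimate (Scott's-rule bandwidth
with a floor).  With this package's deterministic observation maps the
ambiguity term is the constant entropy of a perfectly degenerate sample
set under the same estimator, so a degenerate belief scores exactly zero
epistemic value and dispersed beliefs score strictly positive values.

Scale note: differential entropy depends on the measurement units of the
observation dimensions, so the absolute magnitude of the epistemic term
is a modelling choice rather than a derived quantity.  The information
gain is therefore weighted by an explicit epistemic precision
(``epistemic_weight``), calibrated once so that resolving lane-scale
positional uncertainty is commensurate with the log-probability scale of
the gaze preference priors (around -7); only orderings of epistemic
values are treated as meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beliefs import NULL_CODE, ParticleEnsemble, low_variance_draw
from .priors import PreferenceModel

__all__ = [
    "KDE_BANDWIDTH_FLOOR",
    "EPISTEMIC_WEIGHT",
    "EFEBreakdown",
    "RolloutPrediction",
    "rollout",
    "pragmatic_value",
    "kde_entropy",
    "degenerate_entropy",
    "epistemic_value",
    "score_policy_batch",
    "expected_free_energy",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Default per-dimension bandwidth floor of the entropy estimator (native
#: units).  Acts as a perceptual resolution: belief dispersion below this
#: scale carries no distinguishable information.
KDE_BANDWIDTH_FLOOR = 0.2

#: Default precision weight on the information-gain term (see module docstring).
EPISTEMIC_WEIGHT = 10.0

#: Lower clamp on the entropy estimate, per dimension.
_ENTROPY_CLAMP_PER_DIM = -10.0


@dataclass
class RolloutPrediction:
    """Predicted particles along one policy: states (H, N, D), observations
    (H, N, O) and a per-step boolean mask of null-coded observation entries."""

    states: np.ndarray
    observations: np.ndarray

    @property
    def horizon(self) -> int:
        return self.states.shape[0]

    @property
    def null_mask(self) -> np.ndarray:
        return self.observations == NULL_CODE


@dataclass
class EFEBreakdown:
    """Per-lookahead-step pragmatic and epistemic values of one policy."""

    pragmatic: np.ndarray  # (H,)
    epistemic: np.ndarray  # (H,)

    @property
    def total(self) -> float:
        """G(pi) = -sum_tau (pragmatic_tau + epistemic_tau)."""
        return float(-(self.pragmatic + self.epistemic).sum())


def rollout(states, policy, transition_model, observation_model, rng) -> RolloutPrediction:
    """Propagate particles through a policy, sampling states and observations
    sequentially; deterministic given the generator state.

    ``states`` is (N, D) (an ensemble's states, or particles drawn from one);
    ``policy`` is (H, A).
    """
    states = np.atleast_2d(np.asarray(states, dtype=float))
    policy = np.atleast_2d(np.asarray(policy, dtype=float))
    n = states.shape[0]
    out_states, out_obs = [], []
    for a in policy:
        actions = np.broadcast_to(a, (n, a.shape[0]))
        states = transition_model.step(states, actions, rng)
        out_states.append(states)
        out_obs.append(observation_model.observe(states))
    return RolloutPrediction(np.stack(out_states), np.stack(out_obs))


def pragmatic_value(
    observation_particles: np.ndarray,
    preferences: PreferenceModel,
    observability_mask: np.ndarray | None = None,
    floor: float | None = None,
):
    """Mean over particles of the summed prior log probabilities of the
    observable preference dimensions.

    ``observation_particles`` has shape (..., N, O).  Maskable preference
    entries contribute nothing where their observation dimension is
    unobservable; by default unobservability is read off the null codes in
    the observations themselves, or an explicit boolean mask of the same
    shape may be given (True = observable).  ``floor`` optionally truncates
    each per-particle log probability from below (the -100 export
    convention for plotted value curves).
    """
    obs = np.asarray(observation_particles, dtype=float)
    total = np.zeros(obs.shape[:-2])
    for entry in preferences:
        x = obs[..., entry.obs_index]
        vals = entry.prior.logpdf(x)
        if floor is not None:
            vals = np.maximum(vals, floor)
        if entry.maskable:
            if observability_mask is not None:
                observable = observability_mask[..., entry.obs_index]
            else:
                observable = x != NULL_CODE
            vals = np.where(observable, vals, 0.0)
        total = total + vals.mean(axis=-1)
    return total if total.ndim else float(total)


def _bandwidths(samples: np.ndarray, floor: float) -> np.ndarray:
    """Per-dimension bandwidths with a floor; samples (..., N, D).

    Scott's-rule rate n^(-1/(d+4)) on a robust scale estimate
    min(std, MAD/0.6745), the normalised median absolute deviation.  The
    robust scale matters for null-coded observation mixtures (clusters
    ~1000 units apart): with a plain std the bandwidth would grow with the
    cluster separation and the entropy estimate would measure distance
    instead of cluster structure (an 80/20 present/absent mixture should
    contribute ~Bernoulli entropy, not log of the null-code offset).  The
    MAD is preferred over the interquartile range because its 50%
    breakdown point keeps the bandwidth pinned to the majority cluster
    even when a minority cluster sits exactly astride a quartile.
    """
    n, d = samples.shape[-2], samples.shape[-1]
    std = samples.std(axis=-2)  # population std per dim
    med = np.median(samples, axis=-2)
    mad = np.median(np.abs(samples - med[..., None, :]), axis=-2)
    scale = np.minimum(std, mad / 0.6745)
    return np.maximum(scale * n ** (-1.0 / (d + 4)), floor)


def kde_entropy(samples: np.ndarray, bandwidth_floor: float = KDE_BANDWIDTH_FLOOR):
    """Monte-Carlo differential entropy: minus the mean log of the
    leave-one-out Gaussian-KDE density at each sample.

    ``samples`` is (N, D) or batched (..., N, D); fewer than two samples is
    defined as entropy 0.  The estimate is clamped below at -10 per
    dimension.  For any sample set the estimate is bounded below by the
    degenerate-set entropy under the same bandwidth floor, which is what
    makes the information gain in :func:`epistemic_value` nonnegative.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n, d = samples.shape[-2], samples.shape[-1]
    if n < 2:
        return 0.0 if samples.ndim == 2 else np.zeros(samples.shape[:-2])
    h = _bandwidths(samples, bandwidth_floor)  # (..., D)
    z = (samples[..., :, None, :] - samples[..., None, :, :]) / h[..., None, None, :]
    peak = -np.log(h).sum(axis=-1)[..., None, None] - 0.5 * d * _LOG_2PI
    logk = -0.5 * (z * z).sum(axis=-1) + peak
    # Saturating kernel: an isolated sample (no neighbour within the
    # bandwidth scale) contributes at most ~2*log(n-1) above the degenerate
    # floor -- the discrete surprise of an outcome seen once in n draws --
    # instead of a squared-distance term that would make the "information
    # gain" grow without bound with the separation of null-coded clusters.
    logk = np.maximum(logk, peak - 2.0 * np.log(n - 1))
    # Leave-one-out: exclude the diagonal from the kernel sum.
    idx = np.arange(n)
    logk[..., idx, idx] = -np.inf
    m = logk.max(axis=-1, keepdims=True)
    log_density = np.squeeze(m, -1) + np.log(np.exp(logk - m).sum(axis=-1)) - np.log(n - 1)
    entropy = -log_density.mean(axis=-1)
    entropy = np.maximum(entropy, _ENTROPY_CLAMP_PER_DIM * d)
    return float(entropy) if entropy.ndim == 0 else entropy


def degenerate_entropy(n_dims: int, bandwidth_floor: float = KDE_BANDWIDTH_FLOOR) -> float:
    """Entropy the estimator assigns to a perfectly degenerate sample set:
    the analytic entropy floor of the observation kernel.  Used as the
    (constant) expected-ambiguity term."""
    return n_dims * (0.5 * _LOG_2PI + float(np.log(bandwidth_floor)))


def epistemic_value(
    observation_particles: np.ndarray,
    epistemic_dims,
    bandwidth_floor: float = KDE_BANDWIDTH_FLOOR,
    weight: float = EPISTEMIC_WEIGHT,
):
    """Expected information gain of the predicted observations at one
    lookahead step: posterior-predictive entropy (KDE over the epistemic
    observation dimensions) minus the constant ambiguity term, scaled by
    the epistemic precision.  Exactly 0 for a degenerate belief; >= 0 for
    any sample set."""
    obs = np.asarray(observation_particles, dtype=float)
    samples = obs[..., list(epistemic_dims)]
    h = kde_entropy(samples, bandwidth_floor)
    return weight * (h - degenerate_entropy(len(tuple(epistemic_dims)), bandwidth_floor))


def score_policy_batch(
    base_states: np.ndarray,
    actions: np.ndarray,
    transition_model,
    observation_model,
    preferences: PreferenceModel,
    rng: np.random.Generator,
    bandwidth_floor: float = KDE_BANDWIDTH_FLOOR,
    epistemic_weight: float = EPISTEMIC_WEIGHT,
):
    """Score a batch of policies by expected free energy.

    ``base_states`` (N, D) are the planning particles; ``actions`` is
    (M, H, A).  Returns ``(G, pragmatic, epistemic)`` with shapes (M,),
    (M, H), (M, H).
    """
    base_states = np.atleast_2d(np.asarray(base_states, dtype=float))
    actions = np.asarray(actions, dtype=float)
    if actions.ndim == 2:
        actions = actions[None]
    m, horizon, _ = actions.shape
    n = base_states.shape[0]
    states = np.broadcast_to(base_states, (m, n, base_states.shape[1])).copy()
    dims = list(observation_model.epistemic_dims)
    ambiguity = degenerate_entropy(len(dims), bandwidth_floor)
    all_obs = np.empty((m, horizon, n, states.shape[-1]))
    for tau in range(horizon):
        a = np.broadcast_to(actions[:, tau, None, :], (m, n, actions.shape[2]))
        states = transition_model.step(states, a, rng)
        all_obs[:, tau] = observation_model.observe(states)
    prag = pragmatic_value(all_obs, preferences)
    epist = epistemic_weight * (kde_entropy(all_obs[..., dims], bandwidth_floor) - ambiguity)
    g = -(prag + epist).sum(axis=1)
    return g, prag, epist


def expected_free_energy(
    ensemble: ParticleEnsemble,
    policy: np.ndarray,
    transition_model,
    observation_model,
    preferences: PreferenceModel,
    rng: np.random.Generator,
    n_planning: int | None = None,
    bandwidth_floor: float = KDE_BANDWIDTH_FLOOR,
    epistemic_weight: float = EPISTEMIC_WEIGHT,
) -> EFEBreakdown:
    """Expected free energy of a single policy under a belief ensemble.

    If ``n_planning`` is given, that many particles are drawn from the
    ensemble by weight; otherwise all particles are used (resampled by
    weight if the weights are non-uniform).
    """
    n = ensemble.n
    if n_planning is None and np.allclose(ensemble.weights, 1.0 / n):
        base = ensemble.states
    else:
        base = low_variance_draw(ensemble, n_planning or n, rng)
    policy = np.atleast_2d(np.asarray(policy, dtype=float))
    _, prag, epist = score_policy_batch(
        base, policy[None], transition_model, observation_model, preferences, rng,
        bandwidth_floor, epistemic_weight,
    )
    return EFEBreakdown(pragmatic=prag[0], epistemic=epist[0])
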