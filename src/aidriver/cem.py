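"""Cross-entropy-method model predictive control over mixed action spaces.

At every control step the planner draws N-tilde particles from the
belief by weight, then iteratively refines a distribution over action
sequences: sample M policies, score each by expected free energy,
keep the lowest-G elite fraction, and refit the distribution — Gaussian
moments for continuous action dimensions, Bernoulli frequencies for
discrete ones, fitted separately.  The executed action is drawn from the
distribution of elite first actions after the final iteration.

The sampling distribution is re-initialised at every control step (no
warm start): a zero-mean Gaussian with standard deviation equal to half
the bound range per continuous dimension, and probability 0.5 per
discrete dimension.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .beliefs import ParticleEnsemble, low_variance_draw
from .config import AgentConfig
from .efe import score_policy_batch

__all__ = ["PlannerConfig", "ActionDistribution", "refit", "plan"]

logger = logging.getLogger("aidriver")


@dataclass
class PlannerConfig:
    """CEM hyperparameters plus the scenario's action-space geometry.

    ``cont_bounds`` is (C, 2) rows of (low, high) for the continuous
    action dimensions; ``n_disc`` counts trailing binary action
    dimensions.  The action vector layout is [continuous..., discrete...].
    """

    horizon: int
    samples: int
    iters: int
    elite_frac: float
    n_planning: int
    cont_bounds: np.ndarray
    n_disc: int = 0
    #: per-continuous-dim std of the initial sampling distribution; None
    #: means half the bound range.  Narrow values turn CEM into a local
    #: optimizer around zero input, which is what short-horizon corrective
    #: control (steering) needs; wide values allow discovery of sustained
    #: inputs (braking).
    init_std: object = None
    #: AR(1) correlation of the continuous exploration noise across the
    #: horizon.  Smooth (sustained) input sequences are what give elite
    #: selection a usable signal for slow dynamics: one isolated step of
    #: steering or braking barely moves a policy's score, a sustained one
    #: does.
    noise_corr: float = 0.9
    #: per-iteration multiplicative decay of the continuous sampling std.
    #: Wide early exploration finds the right input direction; the final
    #: iteration evaluates elites under near-deterministic inputs, so the
    #: scoring is not dominated by lane excursions the exploration noise
    #: itself would cause (an effect that grows ~v^2 and otherwise drags
    #: the preferred speed down).
    std_decay: float = 0.5
    #: initial Bernoulli probability per discrete action dim.  Starting at
    #: the preference prior (rather than an uninformed 0.5) keeps floored
    #: gaze steps from dominating every sampled policy's score.
    disc_init_p: float = 0.5
    #: optional nominal-policy hook: called with the belief-mean state
    #: vector, returns an (H, C) continuous action sequence around which
    #: the first iteration samples.  Computed fresh from the current belief
    #: every control step (this is not a warm start); it gives the sampler
    #: control authority that per-step exploration noise alone cannot
    #: provide at desk-scale sample counts.
    nominal_fn: object = None
    var_floor: float = 0.002
    disc_clamp: float = 0.02
    kde_bandwidth_floor: float = 0.2
    epistemic_weight: float = 10.0

    def __post_init__(self):
        self.cont_bounds = np.atleast_2d(np.asarray(self.cont_bounds, dtype=float))
        if self.init_std is None:
            self.init_std = (self.cont_bounds[:, 1] - self.cont_bounds[:, 0]) / 2.0
        self.init_std = np.broadcast_to(
            np.asarray(self.init_std, dtype=float), (self.cont_bounds.shape[0],)
        ).copy()
        if self.n_elite < 2:
            raise ValueError("elite count M*r must be at least 2")
        if not np.all(np.isfinite(self.cont_bounds)):
            raise ValueError("continuous action bounds must be finite")

    @property
    def n_cont(self) -> int:
        return self.cont_bounds.shape[0]

    @property
    def n_elite(self) -> int:
        return int(np.ceil(self.samples * self.elite_frac))

    @classmethod
    def from_agent(
        cls, agent: AgentConfig, dt: float, cont_bounds, n_disc: int = 0, init_std=None,
        disc_init_p: float = 0.5, nominal_fn=None,
    ) -> "PlannerConfig":
        return cls(
            init_std=init_std,
            disc_init_p=disc_init_p,
            nominal_fn=nominal_fn,
            horizon=agent.horizon_steps(dt),
            samples=agent.cem_samples,
            iters=agent.cem_iters,
            elite_frac=agent.elite_frac,
            n_planning=agent.n_planning,
            cont_bounds=cont_bounds,
            n_disc=n_disc,
            var_floor=agent.var_floor,
            disc_clamp=agent.disc_clamp,
            kde_bandwidth_floor=agent.kde_bandwidth_floor,
            epistemic_weight=agent.epistemic_weight,
        )


@dataclass
class ActionDistribution:
    """Per-step sampling distribution: Gaussian (mean, std) per continuous
    dim, Bernoulli probability per discrete dim."""

    cont_mean: np.ndarray  # (H, C)
    cont_std: np.ndarray   # (H, C)
    disc_p: np.ndarray     # (H, Dd)

    @classmethod
    def initial(cls, cfg: PlannerConfig, cont_mean: np.ndarray | None = None) -> "ActionDistribution":
        h, c = cfg.horizon, cfg.n_cont
        p0 = float(np.clip(cfg.disc_init_p, cfg.disc_clamp, 1.0 - cfg.disc_clamp))
        mean = np.zeros((h, c)) if cont_mean is None else np.asarray(cont_mean, dtype=float)
        return cls(
            cont_mean=mean,
            cont_std=np.tile(cfg.init_std, (h, 1)),
            disc_p=np.full((h, cfg.n_disc), p0),
        )


def _correlated_noise(shape, rho, rng):
    """AR(1) unit-variance noise along axis 1 of (M, H, C)."""
    xi = rng.standard_normal(shape)
    if rho <= 0:
        return xi
    eps = np.empty_like(xi)
    eps[:, 0] = xi[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for t in range(1, shape[1]):
        eps[:, t] = rho * eps[:, t - 1] + c * xi[:, t]
    return eps


def sample_policies(dist: ActionDistribution, cfg: PlannerConfig, rng) -> np.ndarray:
    """Draw ``cfg.samples`` policies (M, H, A) from the current distribution:
    per-step Gaussians with AR(1)-correlated deviations for the continuous
    dims (clipped to bounds), independent Bernoullis for the discrete dims."""
    eps = _correlated_noise((cfg.samples,) + dist.cont_mean.shape, cfg.noise_corr, rng)
    cont = np.clip(
        dist.cont_mean + dist.cont_std * eps, cfg.cont_bounds[:, 0], cfg.cont_bounds[:, 1]
    )
    if cfg.n_disc:
        disc = (rng.random((cfg.samples,) + dist.disc_p.shape) < dist.disc_p).astype(float)
        return np.concatenate([cont, disc], axis=2)
    return cont


def refit(elites: np.ndarray, previous: ActionDistribution, cfg: PlannerConfig) -> ActionDistribution:
    """Refit per-step Gaussian moments and discrete frequencies to the elite
    action sequences (E, H, A); std floored, probabilities clamped."""
    if elites.shape[0] < 2:
        raise ValueError("refit needs at least 2 elite sequences")
    cont = elites[:, :, : cfg.n_cont]
    mean = cont.mean(axis=0)
    std = np.maximum(cont.std(axis=0), cfg.var_floor)
    std = np.maximum(np.minimum(std, previous.cont_std * cfg.std_decay), cfg.var_floor)
    if cfg.n_disc:
        p = elites[:, :, cfg.n_cont :].mean(axis=0)
        p = np.clip(p, cfg.disc_clamp, 1.0 - cfg.disc_clamp)
    else:
        p = previous.disc_p
    return ActionDistribution(cont_mean=mean, cont_std=std, disc_p=p)


def _sample_first_action(elites: np.ndarray, cfg: PlannerConfig, rng) -> np.ndarray:
    """Executed action from the distribution of elite first actions.

    Continuous dims execute the mean of the elite first actions (the mode
    of the fitted Gaussian): drawing them instead would inject exploration
    noise orders of magnitude above the scenarios' physical disturbances
    into the executed trajectory, making planner noise the dominant
    dynamics.  Discrete dims are sampled from the raw elite frequencies,
    unclamped — if every elite agrees, the executed discrete action is
    deterministic (the probability clamp is an exploration device for the
    CEM iterations only).
    """
    first = elites[:, 0, :]
    cont = np.clip(
        first[:, : cfg.n_cont].mean(axis=0), cfg.cont_bounds[:, 0], cfg.cont_bounds[:, 1]
    )
    if cfg.n_disc:
        p = first[:, cfg.n_cont :].mean(axis=0)
        disc = (rng.random(cfg.n_disc) < p).astype(float)
        return np.concatenate([cont, disc]), p
    return cont, None


def plan(
    ensemble: ParticleEnsemble,
    transition_model,
    observation_model,
    preferences,
    cfg: PlannerConfig,
    rng: np.random.Generator,
):
    """Select the next action by CEM over EFE-scored policies.

    Returns ``(action, diagnostics)`` where diagnostics carries the
    per-iteration best G, the elite G spread, and the pragmatic/epistemic
    breakdown of the best policy found (for tracing).
    """
    base_states = low_variance_draw(ensemble, cfg.n_planning, rng)
    nominal = None
    if cfg.nominal_fn is not None:
        mean_state = ensemble.weights @ ensemble.states
        nominal = cfg.nominal_fn(mean_state)
    dist = ActionDistribution.initial(cfg, nominal)
    diagnostics: dict = {"iter_best_g": [], "iter_elite_spread": []}
    elites = None
    for _ in range(cfg.iters):
        policies = sample_policies(dist, cfg, rng)
        g, prag, epist = score_policy_batch(
            base_states, policies, transition_model, observation_model, preferences, rng,
            cfg.kde_bandwidth_floor, cfg.epistemic_weight,
        )
        order = np.argsort(g, kind="stable")
        elite_idx = order[: cfg.n_elite]
        elites = policies[elite_idx]
        best = elite_idx[0]
        diagnostics["iter_best_g"].append(float(g[best]))
        diagnostics["iter_elite_spread"].append(float(g[elite_idx[-1]] - g[best]))
        diagnostics["best_g"] = float(g[best])
        diagnostics["best_pragmatic"] = prag[best].copy()
        diagnostics["best_epistemic"] = epist[best].copy()
        diagnostics["best_policy"] = policies[best].copy()
        if np.ptp(g) == 0.0:
            msg = "CEM: all sampled policies scored identical G; sampling unrefined distribution"
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
            action = sample_policies(dist, cfg, rng)[0, 0]
            return action, diagnostics
        dist = refit(elites, dist, cfg)
    action, first_disc_p = _sample_first_action(elites, cfg, rng)
    if first_disc_p is not None:
        diagnostics["first_disc_p"] = first_disc_p
    return action, diagnostics
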