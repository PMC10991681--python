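"""Scenario 2: visual time-sharing between lane keeping and a secondary task.

A kinematic-bicycle ego vehicle drives a straight road segment while the
driver alternates gaze between the road and an off-road secondary task.
A small stochastic steering disturbance (uneven road surface, wind
gusts) makes the lateral position drift; during off-road glances the
vehicle's x/y position and heading cannot be observed, so the belief
about lateral position disperses until an on-road glance resets it.
Lane-boundary crossings are always observable ("rumble strips").  The
same steering noise drives the agent's counterfactual rollouts, so the
generative model matches the generative process.

State vector (10 dims): x, y, heading theta, front-wheel angle delta,
speed v, acceleration a, steering rate w, gaze I (0 off-road /
1 on-road), left-crossed Cl, right-crossed Cr.  Actions: longitudinal
acceleration, steering rate, and the (deterministic) gaze action.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .beliefs import CONT, DISC, NULLABLE, NULL_CODE, ParticleEnsemble
from .cem import PlannerConfig
from .config import AgentConfig
from .efe import degenerate_entropy, kde_entropy, pragmatic_value
from .loop import run_closed_loop
from .priors import (
    EXPORT_FLOOR,
    BernoulliGazePrior,
    CategoricalAbsolutePrior,
    GaussianPrior,
    PreferenceEntry,
    PreferenceModel,
    TriangularPrior,
)

__all__ = [
    "TimesharingConfig",
    "TimesharingModel",
    "bicycle_step",
    "gaze_transition",
    "observe_timesharing",
    "initialize_belief",
    "build_timesharing_preferences",
    "run_timesharing_simulation",
    "value_curves",
    "OFF_ROAD",
    "ON_ROAD",
]

# State / observation column indices.
X, Y, TH, DELTA, V, A, W, GAZE, CL, CR = range(10)
STATE_DIM = 10

OFF_ROAD, ON_ROAD = 0.0, 1.0

TRACE_COLUMNS = [
    "t", "x", "y", "theta", "delta", "v", "a", "w", "gaze", "Cl", "Cr",
    "sigma_b_y", "pragmatic", "epistemic", "G",
]


@dataclass(frozen=True)
class TimesharingConfig:
    lane_width: float = 3.0
    wheelbase: float = 2.7
    #: steering-rate disturbance std (rad/s), applied per step in both the
    #: generative process and the agent's rollouts
    sigma_w: float = 0.001
    dt: float = 0.2
    episode_s: float = 30.0
    #: log probability of an on-road glance (0 = never look away)
    log_p_on: float = -7.0
    speed_mu: float = 10.0
    speed_sigma: float = 1.0
    accel_sigma: float = 2.0
    #: comfort scale of the steering-rate prior; lane-keeping corrections
    #: need |w| of only ~0.1 rad/s, and a firm prior here is what keeps
    #: open-loop policy samples from swamping the planner with steering
    #: noise
    steer_rate_sigma: float = 0.05
    delta_max: float = 0.5
    init_speed: float = 10.0
    #: observation kernel scale; narrow enough that a single on-road glance
    #: collapses the lateral belief well below 0.05 m
    sigma_obs: float = 0.025
    a_bounds: tuple[float, float] = (-4.0, 2.5)
    w_bounds: tuple[float, float] = (-0.25, 0.25)
    #: initial CEM sampling std per continuous action dim (accel, steering
    #: rate); the narrow steering value keeps open-loop policy samples from
    #: lane-exiting rollouts that would otherwise dominate every score
    planner_init_std: tuple[float, float] = (1.0, 0.008)

    def __post_init__(self):
        if self.lane_width <= 0:
            raise ValueError("lane width must be positive")
        if self.sigma_w < 0:
            raise ValueError("steering noise must be nonnegative")

    @property
    def lane_half_width(self) -> float:
        return self.lane_width / 2.0

    @property
    def n_steps(self) -> int:
        return int(round(self.episode_s / self.dt))


def bicycle_step(
    states: np.ndarray,
    actions: np.ndarray,
    dt: float,
    wheelbase: float,
    sigma_w: float,
    rng: np.random.Generator,
    delta_max: float = 0.5,
) -> np.ndarray:
    """Kinematic bicycle step with stochastic steering-rate disturbance.

    Sequential update: delta += (w + eta)*dt (eta ~ N(0, sigma_w), delta
    clipped to +-delta_max); theta += (v/L)*tan(delta)*dt; x += v*cos(theta)*dt;
    y += v*sin(theta)*dt; v += a*dt floored at 0.  ``states`` (..., >=7) with
    the kinematic layout [x, y, theta, delta, v, a, w]; ``actions`` (..., 2)
    = (a, w).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    states = np.asarray(states, dtype=float)
    out = states.copy()
    a_cmd = actions[..., 0]
    w_cmd = actions[..., 1]
    eta = rng.standard_normal(states.shape[:-1]) * sigma_w if sigma_w > 0 else 0.0
    delta = np.clip(states[..., DELTA] + (w_cmd + eta) * dt, -delta_max, delta_max)
    v = states[..., V]
    theta = states[..., TH] + (v / wheelbase) * np.tan(delta) * dt
    out[..., X] = states[..., X] + v * np.cos(theta) * dt
    out[..., Y] = states[..., Y] + v * np.sin(theta) * dt
    out[..., TH] = theta
    out[..., DELTA] = delta
    out[..., V] = np.maximum(v + a_cmd * dt, 0.0)
    out[..., A] = a_cmd
    out[..., W] = w_cmd
    return out


def gaze_transition(gaze, gaze_action):
    """Deterministic gaze dynamics: the gaze state becomes the gaze action."""
    return np.asarray(gaze_action, dtype=float) + 0.0 * np.asarray(gaze, dtype=float)


def observe_timesharing(states: np.ndarray, config: TimesharingConfig) -> np.ndarray:
    """Observation map: everything exact while looking at the road; during
    off-road glances x, y and theta are null-coded.  Steering angle, speed,
    control inputs, gaze and the lane-crossing flags (rumble strips) are
    always observed exactly."""
    states = np.asarray(states, dtype=float)
    obs = states.copy()
    off = states[..., GAZE] == OFF_ROAD
    for dim in (X, Y, TH):
        obs[..., dim] = np.where(off, NULL_CODE, states[..., dim])
    return obs


class TimesharingModel:
    """Transition + observation model for Scenario 2 (process and model
    share the same dynamics and the same steering noise)."""

    obs_kinds = (NULLABLE, NULLABLE, NULLABLE, CONT, CONT, CONT, CONT, DISC, DISC, DISC)
    #: dimensions carrying the epistemic value: vehicle pose, null-coded off-road
    epistemic_dims = (X, Y, TH)

    def __init__(self, config: TimesharingConfig):
        self.config = config
        self.sigma_obs = config.sigma_obs

    def step(self, states: np.ndarray, actions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        out = bicycle_step(
            states, actions[..., :2], cfg.dt, cfg.wheelbase, cfg.sigma_w, rng, cfg.delta_max
        )
        out[..., GAZE] = gaze_transition(states[..., GAZE], actions[..., 2])
        out[..., CL] = (out[..., Y] > cfg.lane_half_width).astype(float)
        out[..., CR] = (out[..., Y] < -cfg.lane_half_width).astype(float)
        return out

    def observe(self, states: np.ndarray) -> np.ndarray:
        return observe_timesharing(states, self.config)


def build_timesharing_preferences(config: TimesharingConfig) -> PreferenceModel:
    """Speed keeping, lane keeping (maskable off-road), comfortable inputs,
    gaze preference, absolute no-lane-exit priors."""
    half = config.lane_half_width
    return PreferenceModel([
        PreferenceEntry("speed", V, GaussianPrior(config.speed_mu, config.speed_sigma)),
        PreferenceEntry("lane_keeping", Y, TriangularPrior(0.0, -half, half), maskable=True),
        PreferenceEntry("accel", A, GaussianPrior(0.0, config.accel_sigma)),
        PreferenceEntry("steer_rate", W, GaussianPrior(0.0, config.steer_rate_sigma)),
        PreferenceEntry("gaze", GAZE, BernoulliGazePrior(config.log_p_on)),
        PreferenceEntry("no_exit_left", CL, CategoricalAbsolutePrior()),
        PreferenceEntry("no_exit_right", CR, CategoricalAbsolutePrior()),
    ])


def nominal_policy(mean_state: np.ndarray, config: TimesharingConfig, horizon: int) -> np.ndarray:
    """Nominal stabilising control sequence around the belief-mean state.

    A simple cascaded lane-centering law (lateral position -> desired
    heading -> desired wheel angle -> steering rate) plus proportional
    speed keeping, rolled forward deterministically for the horizon.  It
    runs on the *believed* state, so during off-road glances it keeps
    zeroing the believed heading (blind stabilisation) while the belief
    about lateral position disperses.  The CEM iterations sample around
    this sequence and are free to override it.
    """
    s = np.zeros(STATE_DIM)
    s[: len(mean_state)] = mean_state
    out = np.zeros((horizon, 2))
    for t in range(horizon):
        th_des = np.clip(-0.2 * s[Y], -0.12, 0.12)
        delta_des = np.clip(
            (config.wheelbase / max(s[V], 1.0)) * (th_des - s[TH]) / 0.6, -0.1, 0.1
        )
        w = float(np.clip((delta_des - s[DELTA]) / 0.4, *config.w_bounds))
        a = float(np.clip(0.5 * (config.speed_mu - s[V]), *config.a_bounds))
        out[t] = (a, w)
        s = bicycle_step(
            s[None, :], out[t][None, :], config.dt, config.wheelbase, 0.0,
            _NOMINAL_RNG, config.delta_max,
        )[0]
    return out


#: rng handed to the deterministic nominal rollout (sigma_w = 0, never drawn)
_NOMINAL_RNG = np.random.default_rng(0)


def _init_state(config: TimesharingConfig) -> np.ndarray:
    s = np.zeros(STATE_DIM)
    s[V] = config.init_speed
    s[GAZE] = ON_ROAD
    return s


def initialize_belief(config: TimesharingConfig, n: int) -> ParticleEnsemble:
    """The run starts looking at the road with the pose known exactly, so
    the initial belief is degenerate at the true state."""
    states = np.tile(_init_state(config), (n, 1))
    return ParticleEnsemble(states, np.full(n, 1.0 / n))


def run_timesharing_simulation(
    config: TimesharingConfig,
    agent: AgentConfig,
    seed: int,
) -> pd.DataFrame:
    """Closed-loop 30 s episode; returns the trace including the lateral
    belief dispersion sigma(b_y) per step."""
    model = TimesharingModel(config)
    preferences = build_timesharing_preferences(config)
    horizon = agent.horizon_steps(config.dt)
    planner_cfg = PlannerConfig.from_agent(
        agent, config.dt, [config.a_bounds, config.w_bounds], n_disc=1,
        init_std=config.planner_init_std,
        # start gaze sampling at the gaze preference prior
        disc_init_p=float(np.exp(config.log_p_on)),
        nominal_fn=lambda mean_state: nominal_policy(mean_state, config, horizon),
    )
    rng = np.random.default_rng(seed)
    belief = initialize_belief(config, agent.n_particles)

    def record(t, state, ensemble, action, diag):
        row = {
            "t": t * config.dt,
            "x": state[X], "y": state[Y], "theta": state[TH], "delta": state[DELTA],
            "v": state[V], "a": state[A], "w": state[W],
            "gaze": state[GAZE], "Cl": state[CL], "Cr": state[CR],
            "sigma_b_y": ensemble.std(Y),
        }
        if diag is None:
            row.update({"pragmatic": np.nan, "epistemic": np.nan, "G": np.nan})
        else:
            row.update({
                "pragmatic": float(diag["best_pragmatic"].sum()),
                "epistemic": float(diag["best_epistemic"].sum()),
                "G": diag["best_g"],
            })
        return row

    trace = run_closed_loop(
        _init_state(config), model, model, model, preferences,
        belief, config.n_steps, planner_cfg, rng, record,
    )
    trace.attrs.update({"scenario": "timesharing", "seed": seed})
    return trace


def value_curves(
    dispersion_grid,
    gaze_pref: float,
    config: TimesharingConfig,
    agent: AgentConfig | None = None,
    n_samples: int = 512,
    seed: int = 0,
):
    """Single-step pragmatic/epistemic/total value of an on-road vs an
    off-road glance as a function of lateral-belief dispersion.

    For each grid sigma, artificial belief particles y ~ N(0, sigma^2)
    (common standard-normal draws across the grid, so the curves are
    smooth and monotonicity is not drowned in sampling noise) are scored
    for both gaze states.  Pragmatic values use the -100 export
    truncation, the convention for plotted value curves.  Returns
    ``(table, sigma_star)`` where sigma_star is the smallest grid sigma at
    which the total on-road value exceeds the off-road value, or None if
    the curves never cross on the grid.
    """
    dispersion_grid = np.asarray(dispersion_grid, dtype=float)
    if np.any(np.diff(dispersion_grid) <= 0):
        raise ValueError("dispersion grid must be strictly increasing")
    agent = agent or AgentConfig.default()
    config = replace(config, log_p_on=gaze_pref)
    model = TimesharingModel(config)
    preferences = build_timesharing_preferences(config)
    z = np.random.default_rng(seed).standard_normal(n_samples)
    ambiguity = degenerate_entropy(len(model.epistemic_dims), agent.kde_bandwidth_floor)
    rows = []
    for sigma in dispersion_grid:
        y = z * sigma
        states = np.tile(_init_state(config), (n_samples, 1))
        states[:, Y] = y
        states[:, CL] = (y > config.lane_half_width).astype(float)
        states[:, CR] = (y < -config.lane_half_width).astype(float)
        on_states = states.copy()
        on_states[:, GAZE] = ON_ROAD
        off_states = states.copy()
        off_states[:, GAZE] = OFF_ROAD
        obs_on = model.observe(on_states)
        obs_off = model.observe(off_states)
        prag_on = float(pragmatic_value(obs_on, preferences, floor=EXPORT_FLOOR))
        prag_off = float(pragmatic_value(obs_off, preferences, floor=EXPORT_FLOOR))
        epi_on = agent.epistemic_weight * (
            kde_entropy(obs_on[:, list(model.epistemic_dims)], agent.kde_bandwidth_floor)
            - ambiguity
        )
        epi_off = agent.epistemic_weight * (
            kde_entropy(obs_off[:, list(model.epistemic_dims)], agent.kde_bandwidth_floor)
            - ambiguity
        )
        rows.append({
            "sigma": float(sigma),
            "pragmatic_on": prag_on, "pragmatic_off": prag_off,
            "epistemic_on": float(epi_on), "epistemic_off": float(epi_off),
            "total_on": prag_on + float(epi_on), "total_off": prag_off + float(epi_off),
        })
    table = pd.DataFrame(rows)
    crossed = table[table.total_on > table.total_off]
    sigma_star = float(crossed.sigma.iloc[0]) if len(crossed) else None
    return table, sigma_star
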