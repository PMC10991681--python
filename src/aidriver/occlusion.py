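"""Scenario 1: passing an occluding object with a possibly hidden pedestrian.

A point-mass ego vehicle drives along a straight lane past a large
occluding object (e.g. a double-parked vehicle).  A pedestrian may or
may not be present at a fixed site behind the object; the pedestrian is
visible only once the ego crosses the line of sight through the
occluder's corner.  The agent's belief starts with a configurable
probability that the pedestrian is present; the generative process never
actually contains one, so the interesting behavior (slowing down,
epistemic leftward movement, recovery) is driven purely by the belief.

State vector (10 dims): ego x, v_x, a_x, y, v_y, a_y; pedestrian-present
flag I; pedestrian x, y (null-coded when absent); conflict-or-lane-exit
flag C.  Observations share the layout with the context observation o_I
(1 = not observed, 2 = observed) in place of I; the pedestrian position
observation is null-coded whenever the site is occluded or no pedestrian
is there.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .beliefs import CONT, DISC, NULLABLE, NULL_CODE, ParticleEnsemble
from .cem import PlannerConfig
from .config import AgentConfig
from .efe import epistemic_value
from .loop import run_closed_loop
from .priors import (
    CategoricalAbsolutePrior,
    GaussianPrior,
    PreferenceEntry,
    PreferenceModel,
    TriangularPrior,
)

__all__ = [
    "OcclusionConfig",
    "OcclusionModel",
    "point_mass_step",
    "is_visible",
    "detect_conflict",
    "observe_occlusion",
    "initialize_belief",
    "build_occlusion_preferences",
    "run_occlusion_simulation",
    "epistemic_saliency_map",
    "VARIANTS",
]

# State / observation column indices.
X, VX, AX, Y, VY, AY, PRES, PX, PY, C = range(10)
O_I = PRES  # context observation occupies the presence slot in observations

#: context-observation codes (Table-style: 1 = not observed, 2 = observed)
NOT_OBSERVED, OBSERVED = 1.0, 2.0

STATE_DIM = 10
TRACE_COLUMNS = [
    "t", "x", "y", "v_x", "v_y", "a_x", "a_y", "o_I", "p_present",
    "conflict", "pragmatic", "epistemic", "G",
]


@dataclass(frozen=True)
class OcclusionConfig:
    """Scenario geometry and priors.

    The geometry (start point, sight corner, pedestrian site) is a
    canonical calibration: the corner sits 28 m ahead and 1.8 m to the
    right of the lane centre and the pedestrian site 4 m beyond it, so a
    straight approach at the speed limit reaches the line of sight at
    x = 22 m and an agent that slows under a 20% pedestrian belief
    resolves the uncertainty around t ~ 3 s.
    """

    lane_half_width: float = 1.5
    speed_limit: float = 10.0
    corner: tuple[float, float] = (28.0, -1.8)
    ped_site: tuple[float, float] = (32.0, -3.0)
    safe_distance: float = 2.0
    p_present: float = 0.2
    dt: float = 0.2
    episode_s: float = 10.0
    init_speed: float = 10.0
    sigma_obs: float = 0.1
    speed_sigma: float = 1.0
    #: comfort scale of the longitudinal acceleration prior: harsh braking
    #: within a candidate plan is penalised quadratically at this scale,
    #: which is what makes the agent shed speed early rather than schedule
    #: a hard stop at the end of the horizon
    accel_sigma: float = 1.0
    #: comfort scale of the lateral acceleration prior (a brief lane-change
    #: dart is cheap; sustained weaving is not)
    ay_sigma: float = 2.0
    #: initial CEM sampling std (longitudinal, lateral); modest values keep
    #: the clipped exploration noise from biasing the executed action
    #: toward the wider (braking) side of the asymmetric bounds
    planner_init_std: tuple[float, float] = (1.5, 0.75)
    #: epistemic precision for this scenario.  The occlusion scenario's
    #: information gain is the cluster entropy of a discrete context
    #: (pedestrian present/absent), a bounded ~0.5-nat quantity per step;
    #: weighting it onto the same preference scale as the conflict and
    #: lane-keeping priors needs a higher precision than the
    #: continuous-dispersion information of the time-sharing scenario.
    epistemic_weight: float = 18.0
    #: longitudinal acceleration bounds (m/s^2)
    ax_bounds: tuple[float, float] = (-4.0, 2.5)
    #: lateral acceleration bounds (m/s^2), used when lateral action enabled
    ay_bounds: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self):
        if self.corner[1] >= -self.lane_half_width:
            raise ValueError("sight corner must lie below the lane's right edge")
        if self.ped_site[0] <= self.corner[0]:
            raise ValueError("pedestrian site must lie beyond the sight corner")
        if self.safe_distance <= 0:
            raise ValueError("safe distance must be positive")

    @property
    def n_steps(self) -> int:
        return int(round(self.episode_s / self.dt))


#: variant -> (prior p(present), lateral action enabled)
VARIANTS = {
    "1a": (0.2, False),
    "1b": (0.0, False),
    "1c": (0.2, True),
    "1d": (0.0, True),
}


def point_mass_step(ego: np.ndarray, action: np.ndarray, dt: float) -> np.ndarray:
    """Linear point-mass kinematics: position += velocity*dt, velocity +=
    action*dt (forward speed floored at 0), stored acceleration = action.
    ``ego`` is (..., 6) = [x, v_x, a_x, y, v_y, a_y]; ``action`` (..., 2)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    ego = np.asarray(ego, dtype=float)
    out = ego.copy()
    out[..., 0] = ego[..., 0] + ego[..., 1] * dt
    out[..., 3] = ego[..., 3] + ego[..., 4] * dt
    out[..., 1] = np.maximum(ego[..., 1] + action[..., 0] * dt, 0.0)
    out[..., 4] = ego[..., 4] + action[..., 1] * dt
    out[..., 2] = action[..., 0]
    out[..., 5] = action[..., 1]
    return out


def is_visible(ego_x, ego_y, corner: tuple[float, float], point: tuple[float, float]):
    """True where ``point`` lies on the lane side of the ray from the ego
    through the occluder's corner (planar cross product >= 0; ties count
    as visible)."""
    xc, yc = corner
    xp, yp = point
    cross = (xc - ego_x) * (yp - ego_y) - (yc - ego_y) * (xp - ego_x)
    return cross >= 0


def detect_conflict(ego_x, ego_y, ped_x, present, safe_distance: float, lane_half_width: float):
    """Conflict flag: pedestrian present within the longitudinal safe
    distance, or the vehicle outside the lane."""
    close = np.abs(ego_x - ped_x) < safe_distance
    exit_lane = np.abs(ego_y) > lane_half_width
    return (np.asarray(present, dtype=bool) & close) | exit_lane


def observe_occlusion(states: np.ndarray, config: OcclusionConfig) -> np.ndarray:
    """Deterministic observation map: ego kinematics copied exactly; the
    pedestrian position is revealed only with line of sight and presence;
    o_I flags whether the site is in view; conflict is always observed."""
    states = np.asarray(states, dtype=float)
    obs = states.copy()
    vis = is_visible(states[..., X], states[..., Y], config.corner, config.ped_site)
    present = states[..., PRES] == 1.0
    obs[..., O_I] = np.where(vis, OBSERVED, NOT_OBSERVED)
    reveal = vis & present
    obs[..., PX] = np.where(reveal, states[..., PX], NULL_CODE)
    obs[..., PY] = np.where(reveal, states[..., PY], NULL_CODE)
    # observed conflict = absorbed pedestrian conflict or current lane exit
    exit_now = np.abs(states[..., Y]) > config.lane_half_width
    obs[..., C] = np.maximum(states[..., C], exit_now.astype(float))
    return obs


class OcclusionModel:
    """Transition + observation model for Scenario 1 (shared by the
    generative process and the agent's generative model: dynamics are
    deterministic and known; the only uncertainty is pedestrian presence).
    """

    obs_kinds = (CONT, CONT, CONT, CONT, CONT, CONT, DISC, NULLABLE, NULLABLE, DISC)
    #: observation dimensions whose diversity carries the scenario's
    #: epistemic value: the context observation and pedestrian position
    epistemic_dims = (O_I, PX, PY)

    def __init__(self, config: OcclusionConfig, lateral: bool):
        self.config = config
        self.lateral = lateral
        self.sigma_obs = config.sigma_obs

    def step(self, states: np.ndarray, actions: np.ndarray, rng=None) -> np.ndarray:
        states = np.asarray(states, dtype=float)
        actions = np.asarray(actions, dtype=float)
        a_x = actions[..., 0]
        a_y = actions[..., 1] if (self.lateral and actions.shape[-1] > 1) else np.zeros_like(a_x)
        out = states.copy()
        out[..., :6] = point_mass_step(states[..., :6], np.stack([a_x, a_y], axis=-1), self.config.dt)
        present = states[..., PRES] == 1.0
        ped_close = present & (
            np.abs(out[..., X] - out[..., PX]) < self.config.safe_distance
        )
        # The pedestrian conflict is absorbing: once the safe distance has
        # been violated along a trajectory, the trajectory stays
        # conflicted (a collision does not un-happen; a transient flag
        # would price driving through the pedestrian zone at a single
        # penalised step).  Lane excursions, by contrast, are recoverable
        # and are flagged per step by the observation map.
        out[..., C] = np.maximum(states[..., C], ped_close.astype(float))
        return out

    def observe(self, states: np.ndarray) -> np.ndarray:
        return observe_occlusion(states, self.config)


def build_occlusion_preferences(config: OcclusionConfig, lateral: bool) -> PreferenceModel:
    """Speed keeping at the limit, comfortable accelerations, absolute
    no-conflict; lane keeping (triangular) only when lateral movement is
    enabled."""
    entries = [
        PreferenceEntry("speed", VX, GaussianPrior(config.speed_limit, config.speed_sigma)),
        PreferenceEntry("accel_x", AX, GaussianPrior(0.0, config.accel_sigma)),
        PreferenceEntry("no_conflict", C, CategoricalAbsolutePrior()),
    ]
    if lateral:
        entries.insert(
            1,
            PreferenceEntry(
                "lane_keeping", Y,
                TriangularPrior(0.0, -config.lane_half_width, config.lane_half_width),
            ),
        )
        entries.insert(2, PreferenceEntry("accel_y", AY, GaussianPrior(0.0, config.ay_sigma)))
    return PreferenceModel(entries)


def _ego_init(config: OcclusionConfig) -> np.ndarray:
    return np.array([0.0, config.init_speed, 0.0, 0.0, 0.0, 0.0])


def initialize_belief(
    config: OcclusionConfig, p_present: float, n: int, rng: np.random.Generator
) -> ParticleEnsemble:
    """Particles drawn i.i.d. from the prior: ego state known exactly,
    presence ~ Bernoulli(p), pedestrian at the site when present else
    null-coded; weights uniform."""
    if not 0.0 <= p_present <= 1.0:
        raise ValueError("p_present must be a probability")
    states = np.tile(np.concatenate([_ego_init(config), [0.0, NULL_CODE, NULL_CODE, 0.0]]), (n, 1))
    present = rng.random(n) < p_present
    states[present, PRES] = 1.0
    states[present, PX] = config.ped_site[0]
    states[present, PY] = config.ped_site[1]
    return ParticleEnsemble(states, np.full(n, 1.0 / n))


def _true_init_state(config: OcclusionConfig) -> np.ndarray:
    # Ground truth: no pedestrian is actually present in any run.
    return np.concatenate([_ego_init(config), [0.0, NULL_CODE, NULL_CODE, 0.0]])


def run_occlusion_simulation(
    config: OcclusionConfig,
    agent: AgentConfig,
    variant: str,
    seed: int,
) -> pd.DataFrame:
    """Closed-loop run of one occlusion variant; returns the trace."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {sorted(VARIANTS)}")
    p_prior, lateral = VARIANTS[variant]
    config = replace(config, p_present=p_prior)
    model = OcclusionModel(config, lateral)
    preferences = build_occlusion_preferences(config, lateral)
    bounds = [config.ax_bounds, config.ay_bounds] if lateral else [config.ax_bounds]
    init_std = config.planner_init_std[: len(bounds)]
    planner_cfg = PlannerConfig.from_agent(agent, config.dt, bounds, n_disc=0, init_std=init_std)
    planner_cfg.epistemic_weight = config.epistemic_weight
    rng = np.random.default_rng(seed)
    belief = initialize_belief(config, p_prior, agent.n_particles, rng)

    def record(t, state, ensemble, action, diag):
        vis = is_visible(state[X], state[Y], config.corner, config.ped_site)
        row = {
            "t": t * config.dt,
            "x": state[X], "y": state[Y],
            "v_x": state[VX], "v_y": state[VY],
            "a_x": state[AX], "a_y": state[AY],
            "o_I": OBSERVED if vis else NOT_OBSERVED,
            "p_present": ensemble.prob(PRES, 1.0),
            "conflict": float(
                max(state[C], float(abs(state[Y]) > config.lane_half_width))
            ),
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
        _true_init_state(config), model, model, model, preferences,
        belief, config.n_steps, planner_cfg, rng, record,
    )
    trace.attrs.update({"scenario": "occlusion", "variant": variant, "seed": seed})
    return trace


def epistemic_saliency_map(
    y_grid,
    x_grid,
    fixed_belief_p: float,
    config: OcclusionConfig,
    agent: AgentConfig | None = None,
    n_particles: int = 200,
) -> np.ndarray:
    """Epistemic value of the observation from each (x, y) ego position
    under a fixed pedestrian-presence belief, summed over a stationary
    planning horizon.  Returns a (len(y_grid), len(x_grid)) grid.

    The belief composition is deterministic (round(p*N) present particles)
    so the map itself is deterministic.
    """
    if not 0.0 <= fixed_belief_p <= 1.0:
        raise ValueError("fixed_belief_p must be a probability")
    agent = agent or AgentConfig.default()
    horizon = agent.horizon_steps(config.dt)
    n_present = int(round(fixed_belief_p * n_particles))
    states = np.tile(
        np.concatenate([_ego_init(config), [0.0, NULL_CODE, NULL_CODE, 0.0]]), (n_particles, 1)
    )
    states[:n_present, PRES] = 1.0
    states[:n_present, PX] = config.ped_site[0]
    states[:n_present, PY] = config.ped_site[1]
    out = np.empty((len(y_grid), len(x_grid)))
    for i, y in enumerate(y_grid):
        for j, x in enumerate(x_grid):
            s = states.copy()
            s[:, X] = x
            s[:, Y] = y
            obs = observe_occlusion(s, config)
            per_step = epistemic_value(
                obs, OcclusionModel.epistemic_dims,
                agent.kde_bandwidth_floor, config.epistemic_weight,
            )
            out[i, j] = horizon * float(per_step)
    return out
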