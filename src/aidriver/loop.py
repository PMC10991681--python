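"""Closed-loop simulation driver shared by both scenarios.

Per control step: plan from the current belief, apply the first action
to the generative process (the true environment), observe, and update
the belief with the SIR filter.  The trace records one row per timestep:
row t holds the true state and belief *at* time t*dt together with the
action and planner diagnostics computed there; a final row records the
terminal state with no action.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd

from .beliefs import ParticleEnsemble, sir_update
from .cem import PlannerConfig, plan

__all__ = ["run_closed_loop"]


def run_closed_loop(
    init_state: np.ndarray,
    process_transition,
    agent_transition,
    observation_model,
    preferences,
    ensemble: ParticleEnsemble,
    n_steps: int,
    planner_cfg: PlannerConfig,
    rng: np.random.Generator,
    record: Callable[[int, np.ndarray, ParticleEnsemble, np.ndarray | None, dict | None], dict],
) -> pd.DataFrame:
    """Run a full episode and return the trace as a DataFrame.

    ``record(step, true_state, belief, action, diagnostics)`` builds one
    trace row; it is called with ``action=None`` for the terminal row.
    Separate generator streams drive the agent (planning + filtering) and
    the environment so the run is reproducible from (config, seed).
    """
    rng_agent, rng_env = rng.spawn(2)
    state = np.asarray(init_state, dtype=float).copy()
    rows = []
    for t in range(n_steps):
        action, diag = plan(
            ensemble, agent_transition, observation_model, preferences, planner_cfg, rng_agent
        )
        rows.append(record(t, state, ensemble, action, diag))
        state = process_transition.step(state[None, :], action[None, :], rng_env)[0]
        obs = observation_model.observe(state[None, :])[0]
        ensemble = sir_update(
            ensemble, action, obs, agent_transition, observation_model, rng_agent
        )
    rows.append(record(n_steps, state, ensemble, None, None))
    return pd.DataFrame(rows)
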