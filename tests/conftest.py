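"""Shared fixtures: reduced-profile agent, cached experiment batteries,
and tiny oracle systems (discrete chain, linear-Gaussian) used to check
the particle filter against exact recursions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from aidriver import AgentConfig, run_experiment
from aidriver.beliefs import CONT

N_SEEDS = 10
BASE_SEED = 0


@pytest.fixture(scope="session")
def agent() -> AgentConfig:
    return AgentConfig.test_profile()


@pytest.fixture(scope="session")
def results_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("batteries")


def _battery(name: str, results_dir, **kwargs) -> pd.DataFrame:
    out = results_dir / name
    return run_experiment(
        name, n_seeds=N_SEEDS, out_dir=out, base_seed=BASE_SEED, profile="test", **kwargs
    )


@pytest.fixture(scope="session")
def sim1a_summary(results_dir):
    return _battery("sim1a", results_dir)


@pytest.fixture(scope="session")
def sim1b_summary(results_dir):
    return _battery("sim1b", results_dir)


@pytest.fixture(scope="session")
def sim1c_summary(results_dir):
    return _battery("sim1c", results_dir)


@pytest.fixture(scope="session")
def sim1d_summary(results_dir):
    return _battery("sim1d", results_dir)


@pytest.fixture(scope="session")
def sim2a_summary(results_dir):
    return _battery("sim2a", results_dir)


@pytest.fixture(scope="session")
def sim2b_summary(results_dir):
    return _battery("sim2b", results_dir)


class TwoStateChain:
    """Two-state Markov chain with a noisy scalar readout.

    The transition matrix is known, so an exact discrete Bayes filter is
    available as the oracle; the readout is the state identity plus
    Gaussian noise, which the particle filter's Gaussian observation
    kernel matches exactly (up to a normalising constant that cancels).
    """

    obs_kinds = (CONT,)
    epistemic_dims = (0,)

    def __init__(self, transition: np.ndarray, sigma_obs: float):
        self.transition = np.asarray(transition, dtype=float)
        self.sigma_obs = sigma_obs

    def step(self, states, actions, rng):
        states = np.asarray(states, dtype=float)
        s = states[..., 0].astype(int)
        u = rng.random(s.shape)
        # next state is 1 with probability T[s, 1]
        p_one = self.transition[s, 1]
        return (u < p_one).astype(float)[..., None]

    def observe(self, states):
        return np.asarray(states, dtype=float).copy()

    def exact_filter(self, prior: np.ndarray, observations) -> list[np.ndarray]:
        """Exact Bayes recursion; returns the posterior after each update."""
        from scipy.stats import norm

        p = np.asarray(prior, dtype=float)
        out = []
        for o in observations:
            pred = self.transition.T @ p
            lik = norm.pdf(o, loc=np.array([0.0, 1.0]), scale=self.sigma_obs)
            p = pred * lik
            p = p / p.sum()
            out.append(p.copy())
        return out


class ScalarLinearGaussian:
    """1-D linear-Gaussian system x' = a x + w; Kalman filter is exact."""

    obs_kinds = (CONT,)
    epistemic_dims = (0,)

    def __init__(self, a: float, sigma_process: float, sigma_obs: float):
        self.a = a
        self.sigma_process = sigma_process
        self.sigma_obs = sigma_obs

    def step(self, states, actions, rng):
        states = np.asarray(states, dtype=float)
        noise = rng.standard_normal(states.shape[:-1]) * self.sigma_process
        return (self.a * states[..., 0] + noise)[..., None]

    def observe(self, states):
        return np.asarray(states, dtype=float).copy()

    def kalman(self, mean0, var0, observations):
        """Exact posterior means/vars after each observation."""
        m, v = mean0, var0
        means, variances = [], []
        for o in observations:
            m_pred = self.a * m
            v_pred = self.a**2 * v + self.sigma_process**2
            k = v_pred / (v_pred + self.sigma_obs**2)
            m = m_pred + k * (o - m_pred)
            v = (1 - k) * v_pred
            means.append(m)
            variances.append(v)
        return np.array(means), np.array(variances)
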