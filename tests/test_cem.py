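"""CEM planner: elite algebra, refit rules, convergence, bounds and the
preference-tracking limit."""

import numpy as np
import pytest

from aidriver import AgentConfig, OcclusionConfig, TimesharingConfig
from aidriver.beliefs import CONT, ParticleEnsemble
from aidriver.cem import ActionDistribution, PlannerConfig, plan, refit, sample_policies
from aidriver.occlusion import OcclusionModel, build_occlusion_preferences, initialize_belief
from aidriver.priors import GaussianPrior, PreferenceEntry, PreferenceModel
from aidriver.timesharing import (
    TimesharingModel,
    build_timesharing_preferences,
    initialize_belief as ts_initialize_belief,
)


def _config(**kwargs):
    defaults = dict(
        horizon=5, samples=64, iters=3, elite_frac=0.1, n_planning=8,
        cont_bounds=[(-1.0, 1.0)],
    )
    defaults.update(kwargs)
    return PlannerConfig(**defaults)


class TestConfig:
    def test_elite_count_is_ceiling(self):
        assert _config(samples=64, elite_frac=0.1).n_elite == 7
        assert _config(samples=32, elite_frac=0.25).n_elite == 8

    def test_too_few_elites_rejected(self):
        with pytest.raises(ValueError):
            _config(samples=10, elite_frac=0.05)

    def test_infinite_bounds_rejected(self):
        with pytest.raises(ValueError):
            _config(cont_bounds=[(-np.inf, 1.0)])


class TestRefit:
    def test_identical_elites_floor_the_std(self):
        cfg = _config(var_floor=0.01)
        seq = np.tile(np.linspace(-0.5, 0.5, 5)[None, :, None], (4, 1, 1))
        dist = refit(seq, ActionDistribution.initial(cfg), cfg)
        np.testing.assert_allclose(dist.cont_mean[:, 0], np.linspace(-0.5, 0.5, 5))
        assert np.all(dist.cont_std == cfg.var_floor)

    def test_population_std_of_elites(self):
        cfg = _config(var_floor=0.01, std_decay=1.0)
        elites = np.array([-1.0, 0.0, 1.0])[:, None, None] * np.ones((3, 5, 1))
        dist = refit(elites, ActionDistribution.initial(cfg), cfg)
        assert dist.cont_std[0, 0] == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-9)

    def test_discrete_frequencies_clamped(self):
        cfg = _config(n_disc=1, disc_clamp=0.02)
        elites = np.zeros((7, 5, 2))
        elites[:6, :, 1] = 1.0  # 6 of 7 elites choose "on"
        dist = refit(elites, ActionDistribution.initial(cfg), cfg)
        assert dist.disc_p[0, 0] == pytest.approx(6.0 / 7.0)
        elites[:, :, 1] = 1.0  # unanimous -> clamped
        dist = refit(elites, ActionDistribution.initial(cfg), cfg)
        assert dist.disc_p[0, 0] == pytest.approx(0.98)

    def test_needs_two_elites(self):
        cfg = _config()
        with pytest.raises(ValueError):
            refit(np.zeros((1, 5, 1)), ActionDistribution.initial(cfg), cfg)


class _ShiftModel:
    """1-D deterministic system: position += action."""

    obs_kinds = (CONT,)
    sigma_obs = 0.1
    epistemic_dims = (0,)

    def step(self, states, actions, rng):
        return np.asarray(states, dtype=float) + np.asarray(actions, dtype=float)

    def observe(self, states):
        return np.asarray(states, dtype=float).copy()


class TestPlan:
    def test_matches_grid_search_on_quadratic_objective(self):
        model = _ShiftModel()
        prefs = PreferenceModel([PreferenceEntry("pos", 0, GaussianPrior(0.7, 1.0))])
        ens = ParticleEnsemble(np.zeros((8, 1)), np.full(8, 0.125))
        cfg = _config(horizon=1, samples=64, iters=5, elite_frac=0.1,
                      epistemic_weight=0.0, noise_corr=0.0, std_decay=1.0)
        action, _ = plan(ens, model, model, prefs, cfg, np.random.default_rng(0))
        # grid-search optimum over the action interval
        grid = np.linspace(-1, 1, 2001)
        best = grid[np.argmax(prefs.entries[0].prior.logpdf(grid))]
        assert abs(action[0] - best) < 0.1 * 2.0  # within 10% of the interval

    def test_sampled_policies_respect_bounds(self):
        cfg = _config(cont_bounds=[(-2.0, 0.5), (-0.25, 0.25)], n_disc=1)
        dist = ActionDistribution.initial(cfg)
        pols = sample_policies(dist, cfg, np.random.default_rng(0))
        assert pols.shape == (64, 5, 3)
        assert np.all(pols[:, :, 0] >= -2.0) and np.all(pols[:, :, 0] <= 0.5)
        assert np.all(pols[:, :, 1] >= -0.25) and np.all(pols[:, :, 1] <= 0.25)
        assert set(np.unique(pols[:, :, 2])) <= {0.0, 1.0}

    def test_executed_action_within_bounds_on_scenarios(self, agent):
        cfg = OcclusionConfig()
        model = OcclusionModel(cfg, lateral=True)
        prefs = build_occlusion_preferences(cfg, lateral=True)
        belief = initialize_belief(cfg, 0.2, 64, np.random.default_rng(0))
        pcfg = PlannerConfig.from_agent(
            agent, cfg.dt, [cfg.ax_bounds, cfg.ay_bounds], n_disc=0,
            init_std=cfg.planner_init_std,
        )
        for seed in range(5):
            action, _ = plan(belief, model, model, prefs, pcfg, np.random.default_rng(seed))
            assert cfg.ax_bounds[0] <= action[0] <= cfg.ax_bounds[1]
            assert cfg.ay_bounds[0] <= action[1] <= cfg.ay_bounds[1]

    def test_best_g_non_increasing_across_iterations(self, agent):
        """Median (over 20 seeds) of the per-iteration best G never rises,
        on both scenario configurations."""
        diffs = {"occlusion": [], "timesharing": []}
        occ = OcclusionConfig()
        occ_model = OcclusionModel(occ, lateral=False)
        occ_prefs = build_occlusion_preferences(occ, lateral=False)
        occ_cfg = PlannerConfig.from_agent(
            agent, occ.dt, [occ.ax_bounds], init_std=occ.planner_init_std[:1]
        )
        ts = TimesharingConfig()
        ts_model = TimesharingModel(ts)
        ts_prefs = build_timesharing_preferences(ts)
        ts_cfg = PlannerConfig.from_agent(
            agent, ts.dt, [ts.a_bounds, ts.w_bounds], n_disc=1,
            init_std=ts.planner_init_std, disc_init_p=float(np.exp(ts.log_p_on)),
        )
        for seed in range(20):
            rng = np.random.default_rng(seed)
            belief = initialize_belief(occ, 0.2, agent.n_particles, rng)
            _, diag = plan(belief, occ_model, occ_model, occ_prefs, occ_cfg, rng)
            diffs["occlusion"].append(np.diff(diag["iter_best_g"]))
            belief2 = ts_initialize_belief(ts, agent.n_particles)
            _, diag2 = plan(belief2, ts_model, ts_model, ts_prefs, ts_cfg, rng)
            diffs["timesharing"].append(np.diff(diag2["iter_best_g"]))
        for name, d in diffs.items():
            med = np.median(np.array(d), axis=0)
            assert np.all(med <= 1e-9), (name, med)

    def test_identical_scores_warn_and_fall_back(self):
        model = _ShiftModel()
        prefs = PreferenceModel([])  # no preferences: every policy scores 0
        ens = ParticleEnsemble(np.zeros((4, 1)), np.full(4, 0.25))
        cfg = _config(horizon=3, epistemic_weight=0.0)
        with pytest.warns(RuntimeWarning):
            action, _ = plan(ens, model, model, prefs, cfg, np.random.default_rng(0))
        assert -1.0 <= action[0] <= 1.0

    def test_preference_tracking_limit_settles_at_speed_prior(self, agent):
        """With epistemic value zeroed, no disturbance and a certain belief,
        the planner reduces to preference tracking: speed settles within 2%
        of the speed-prior mean on an open straight road."""
        from aidriver import run_timesharing_simulation

        cfg = TimesharingConfig(log_p_on=0.0, sigma_w=0.0)
        quiet = agent.with_overrides(epistemic_weight=0.0)
        trace = run_timesharing_simulation(cfg, quiet, 0)
        settle = trace.v.tail(50).mean()
        assert abs(settle - cfg.speed_mu) < 0.02 * cfg.speed_mu
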