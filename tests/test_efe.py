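"""EFE engine: entropy estimator against closed forms, pragmatic masking,
epistemic identities, rollout kinematics and additivity."""

import numpy as np
import pytest

from aidriver import AgentConfig, OcclusionConfig, ParticleEnsemble
from aidriver.beliefs import NULL_CODE
from aidriver.efe import (
    EFEBreakdown,
    degenerate_entropy,
    epistemic_value,
    expected_free_energy,
    kde_entropy,
    pragmatic_value,
    rollout,
)
from aidriver.occlusion import (
    OcclusionModel,
    VX,
    build_occlusion_preferences,
    initialize_belief,
)
from aidriver.priors import (
    CategoricalAbsolutePrior,
    GaussianPrior,
    PreferenceEntry,
    PreferenceModel,
    TriangularPrior,
)

GAUSS_H1 = 0.5 * np.log(2 * np.pi * np.e)  # 1.4189


class TestKdeEntropy:
    def test_gaussian_1d_within_ten_percent(self):
        x = np.random.default_rng(0).standard_normal((2000, 1))
        assert abs(kde_entropy(x) - GAUSS_H1) < 0.1 * GAUSS_H1

    def test_gaussian_2d_within_ten_percent(self):
        x = np.random.default_rng(1).standard_normal((2000, 2))
        assert abs(kde_entropy(x) - 2 * GAUSS_H1) < 0.1 * 2 * GAUSS_H1

    def test_two_cluster_mixture_adds_log2(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(2000) + np.where(rng.random(2000) < 0.5, -10.0, 10.0)
        # mixture entropy = component entropy + log 2 for far-apart clusters
        expected = GAUSS_H1 + np.log(2.0)
        assert abs(kde_entropy(x[:, None]) - expected) < 0.35

    def test_degenerate_samples_hit_the_floor_constant(self):
        x = np.full((64, 3), 4.2)
        assert kde_entropy(x, 0.2) == pytest.approx(degenerate_entropy(3, 0.2), abs=1e-9)

    def test_fewer_than_two_samples_is_zero(self):
        assert kde_entropy(np.zeros((1, 2))) == 0.0

    def test_bounded_below_by_degenerate_constant(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(2, 40)
            d = rng.integers(1, 4)
            scale = 10 ** rng.uniform(-4, 2)
            x = rng.standard_normal((n, d)) * scale
            assert kde_entropy(x, 0.2) >= degenerate_entropy(d, 0.2) - 1e-9


class TestPragmaticValue:
    def _prefs(self):
        return PreferenceModel([
            PreferenceEntry("speed", 0, GaussianPrior(10.0, 1.0)),
            PreferenceEntry("lane", 1, TriangularPrior(0.0, -1.5, 1.5), maskable=True),
            PreferenceEntry("conflict", 2, CategoricalAbsolutePrior()),
        ])

    def test_all_particles_at_modes_reach_peak(self):
        prefs = self._prefs()
        obs = np.tile([10.0, 0.0, 0.0], (8, 1))
        assert pragmatic_value(obs, prefs) == pytest.approx(prefs.max_pragmatic(), abs=1e-9)

    def test_masked_dimension_contributes_nothing(self):
        prefs = self._prefs()
        visible = np.tile([10.0, 0.0, 0.0], (8, 1))
        masked = visible.copy()
        masked[:, 1] = NULL_CODE
        expected = pragmatic_value(visible, prefs) - np.log(2.0 / 3.0)
        assert pragmatic_value(masked, prefs) == pytest.approx(expected, abs=1e-9)

    def test_conflict_particle_costs_the_floor(self):
        prefs = self._prefs()
        obs = np.tile([10.0, 0.0, 0.0], (10, 1))
        obs[0, 2] = 1.0  # one conflicted particle out of ten
        clean = pragmatic_value(np.tile([10.0, 0.0, 0.0], (10, 1)), prefs)
        assert pragmatic_value(obs, prefs) == pytest.approx(clean - 100.0, abs=1e-9)

    def test_export_floor_truncation(self):
        prefs = self._prefs()
        obs = np.tile([10.0, 0.0, 1.0], (4, 1))
        val = pragmatic_value(obs, prefs, floor=-100.0)
        assert val == pytest.approx(prefs.max_pragmatic() - 100.0, abs=1e-9)


class TestEpistemicValue:
    def test_degenerate_belief_scores_exactly_zero(self):
        obs = np.tile([2.0, NULL_CODE, NULL_CODE], (16, 1))
        assert epistemic_value(obs, (0, 1, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_null_real_mixture_is_strictly_positive(self):
        obs = np.tile([2.0, NULL_CODE, NULL_CODE], (16, 1))
        obs[:3, 1] = 32.0
        obs[:3, 2] = -3.0
        assert epistemic_value(obs, (0, 1, 2)) > 0.5

    def test_mixture_tracks_cluster_entropy(self):
        # 80/20 two-cluster mixture: information gain ~ Bernoulli(0.2) entropy
        rng = np.random.default_rng(0)
        n = 500
        labels = rng.random(n) < 0.2
        obs = np.where(labels, 32.0, NULL_CODE)[:, None]
        bern = -(0.2 * np.log(0.2) + 0.8 * np.log(0.8))
        val = epistemic_value(obs, (0,), weight=1.0)
        assert val == pytest.approx(bern, abs=0.15)

    def test_never_meaningfully_negative(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            obs = rng.standard_normal((16, 3)) * 10 ** rng.uniform(-3, 1)
            assert epistemic_value(obs, (0, 1, 2)) >= -0.05


class TestRollout:
    def test_point_mass_constant_acceleration(self):
        cfg = OcclusionConfig()
        model = OcclusionModel(cfg, lateral=False)
        state = np.zeros((1, 10))
        state[0, VX] = 10.0
        policy = np.full((5, 1), 1.0)  # a_x = 1 m/s^2
        pred = rollout(state, policy, model, model, np.random.default_rng(0))
        # v = v0 + a * tau * dt = 10 + 1 * 5 * 0.2 = 11
        assert pred.states[-1, 0, VX] == pytest.approx(11.0)
        assert pred.horizon == 5

    def test_identity_transition_keeps_states(self):
        class Identity:
            obs_kinds = ("cont",)
            sigma_obs = 0.1
            epistemic_dims = (0,)

            def step(self, states, actions, rng):
                return np.asarray(states, dtype=float).copy()

            def observe(self, states):
                return np.asarray(states, dtype=float).copy()

        model = Identity()
        states = np.array([[3.0], [4.0]])
        pred = rollout(states, np.zeros((4, 1)), model, model, np.random.default_rng(0))
        assert np.all(pred.states == states[None, :, :])


class TestExpectedFreeEnergy:
    def test_breakdown_total_identity(self):
        b = EFEBreakdown(pragmatic=np.array([1.0, 2.0]), epistemic=np.array([0.5, 0.5]))
        assert b.total == pytest.approx(-4.0)

    def test_horizon_additivity(self):
        cfg = OcclusionConfig()
        model = OcclusionModel(cfg, lateral=False)
        belief = initialize_belief(cfg, 0.2, 64, np.random.default_rng(0))
        policy = np.zeros((20, 1))
        full = expected_free_energy(
            belief, policy, model, model, build_occlusion_preferences(cfg, False),
            np.random.default_rng(1), n_planning=16,
        )
        partial = -(full.pragmatic[:7] + full.epistemic[:7]).sum()
        assert full.total == pytest.approx(
            partial - (full.pragmatic[7:] + full.epistemic[7:]).sum(), abs=1e-9
        )

    def test_certain_belief_reduces_to_pure_pragmatic(self):
        cfg = OcclusionConfig()
        model = OcclusionModel(cfg, lateral=False)
        belief = initialize_belief(cfg, 0.0, 32, np.random.default_rng(0))
        b = expected_free_energy(
            belief, np.zeros((20, 1)), model, model,
            build_occlusion_preferences(cfg, False), np.random.default_rng(1),
        )
        np.testing.assert_allclose(b.epistemic, 0.0, atol=1e-9)
        assert b.total == pytest.approx(-b.pragmatic.sum())

    def test_crossing_line_of_sight_lowers_g_under_uncertainty(self):
        # two identical cruise policies; one starts close enough to cross
        # the line of sight within the horizon, the other never does
        cfg = OcclusionConfig()
        model = OcclusionModel(cfg, lateral=False)
        prefs = build_occlusion_preferences(cfg, False)
        rng = np.random.default_rng(0)
        belief = initialize_belief(cfg, 0.2, 64, rng)
        slow = np.full((20, 1), -4.0)  # stops well short of the sight line
        cruise = np.zeros((20, 1))
        g = {}
        for name, pol in {"slow": slow, "cruise": cruise}.items():
            b = expected_free_energy(
                belief, pol, model, model, prefs, np.random.default_rng(1), n_planning=16
            )
            g[name] = b.epistemic.sum()
        assert g["cruise"] > g["slow"]
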