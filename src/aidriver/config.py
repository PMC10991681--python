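"""Agent-level hyperparameters shared by both scenarios.

Two profiles are provided: ``default`` (the headline settings) and
``test`` (a reduced profile — fewer particles, CEM samples and
iterations — used by the test suite and the acceptance script so that
complete multi-seed experiment batteries run at desk scale).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .efe import EPISTEMIC_WEIGHT, KDE_BANDWIDTH_FLOOR

__all__ = ["AgentConfig"]


@dataclass(frozen=True)
class AgentConfig:
    #: belief-filter particle count N
    n_particles: int = 1024
    #: particles drawn from the belief for planning (N-tilde)
    n_planning: int = 32
    #: CEM policy samples per iteration (M)
    cem_samples: int = 64
    #: CEM refinement iterations (K)
    cem_iters: int = 3
    #: elite fraction r
    elite_frac: float = 0.1
    #: floor on the refit action standard deviation
    var_floor: float = 0.002
    #: clamp on discrete action probabilities inside CEM iterations
    disc_clamp: float = 0.02
    #: planning horizon in seconds (H = horizon_s / dt)
    horizon_s: float = 4.0
    #: KDE bandwidth floor per observation dimension (native units)
    kde_bandwidth_floor: float = KDE_BANDWIDTH_FLOOR
    #: precision weight on the information-gain term
    epistemic_weight: float = EPISTEMIC_WEIGHT

    @classmethod
    def default(cls) -> "AgentConfig":
        return cls()

    @classmethod
    def test_profile(cls) -> "AgentConfig":
        return cls(
            n_particles=256, n_planning=16, cem_samples=32, cem_iters=3, elite_frac=0.25
        )

    @classmethod
    def from_profile(cls, profile: str) -> "AgentConfig":
        if profile == "default":
            return cls.default()
        if profile == "test":
            return cls.test_profile()
        raise ValueError(f"unknown profile {profile!r} (expected 'default' or 'test')")

    def with_overrides(self, **kwargs) -> "AgentConfig":
        return replace(self, **kwargs)

    def horizon_steps(self, dt: float) -> int:
        return int(round(self.horizon_s / dt))
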