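"""The two behavioral testbeds: a two-armed bandit and the T-maze task.

T-maze
------
Four positions: the start (1), two reward arms (2 and 3, both absorbing), and
a cue location (4) whose observation reveals which arm holds the reward.  The
hidden state is the agent position crossed with the reward arm (8 states,
position-major); observations are the position crossed with four
reward-related outcomes (16, position-major):

1. reward indicated at position 2 (left arm);
2. reward indicated at position 3 (right arm);
3. reward obtained;
4. reward not obtained.

At the start position the outcome is uninformative (outcomes 1/2 with equal
probability); at the cue position it deterministically indicates the reward
arm; at an arm the reward is obtained with probability ``alpha`` if the arm is
correct and ``1 - alpha`` otherwise.  Goal priors place soft-max preference
``softmax(0, 0, c, -c)`` on the outcomes, spread evenly over positions; by
default the first move's prior is flat (freedom to explore) and later steps
are informative.

The simulated environment (the generative process) shares the ``A`` and ``B``
tables with the generative model: the agent is well-specified by construction.

Bandit
------
A single binary outcome with two levers: the ignorant lever yields either
outcome with probability one half; the informative lever always yields
outcome 0.  No goal prior -- the fixture isolates the epistemic drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

from .discrete import Categorical, direct_sum, kron, softmax
from .factor_graph import Factor, GraphError, Variable, build_graph
from .models import FutureModel, StateSpaceModel

__all__ = [
    "TMazeConfig",
    "TMazeEnvState",
    "TMazeEnv",
    "build_tmaze_model",
    "build_bandit_model",
    "BanditModel",
    "env_execute",
    "env_observe",
    "observation_matrix",
    "transition_matrices",
    "goal_prior",
    "flat_goal",
    "initial_state_prior",
    "state_index",
    "observation_index",
]

POSITIONS = (1, 2, 3, 4)
ARMS = (2, 3)
OUTCOMES = (1, 2, 3, 4)

# position-transition patterns (4x4, column = from, row = to); arms absorb
_B_PATTERNS = {
    1: [[1, 0, 0, 1], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 0]],
    2: [[0, 0, 0, 0], [1, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 0]],
    3: [[0, 0, 0, 0], [0, 1, 0, 0], [1, 0, 1, 1], [0, 0, 0, 0]],
    4: [[0, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [1, 0, 0, 1]],
}


def state_index(position: int, arm: int) -> int:
    """0-based state index for (position, reward arm), position-major."""
    return 2 * (position - 1) + (arm - 2)


def observation_index(position: int, outcome: int) -> int:
    """0-based observation index for (position, outcome), position-major."""
    return 4 * (position - 1) + (outcome - 1)


def transition_matrices() -> dict[int, np.ndarray]:
    """The four 8x8 control-indexed transition tables (pattern ⊗ I2)."""
    return {u: kron(np.array(p, dtype=float), np.eye(2)) for u, p in _B_PATTERNS.items()}


def observation_matrix(alpha: float) -> np.ndarray:
    """The 16x8 block-diagonal observation table ``A1 ⊕ A2 ⊕ A3 ⊕ A4``.

    Block columns are the reward-arm possibilities at each position.
    """
    if not 0.0 <= alpha <= 1.0:
        raise GraphError(f"reward probability alpha={alpha} outside [0, 1]")
    a1 = np.array([[0.5, 0.5], [0.5, 0.5], [0, 0], [0, 0]])
    a2 = np.array([[0, 0], [0, 0], [alpha, 1 - alpha], [1 - alpha, alpha]])
    a3 = np.array([[0, 0], [0, 0], [1 - alpha, alpha], [alpha, 1 - alpha]])
    a4 = np.array([[1, 0], [0, 1], [0, 0], [0, 0]])
    return direct_sum([a1, a2, a3, a4])


def goal_outcome_dist(c: float) -> Categorical:
    """Outcome preference ``softmax(0, 0, c, -c)`` with reward utility ``c``."""
    return softmax([0.0, 0.0, c, -c])


def goal_prior(c: float) -> Categorical:
    """Informative goal prior over the 16 observations.

    The soft-max outcome preference is spread evenly over the four positions
    and the Kronecker spread is renormalized, which shifts every policy's
    extrinsic value by the same constant and cannot change the argmin.
    """
    return Categorical(np.kron(np.ones(4), goal_outcome_dist(c).probs) / 4.0)


def flat_goal() -> Categorical:
    return Categorical(np.full(16, 1 / 16))


def initial_state_prior() -> Categorical:
    """Known start position 1, reward arm unknown: ``(1,0,0,0)ᵀ ⊗ (.5,.5)ᵀ``."""
    return kron(Categorical([1, 0, 0, 0]), Categorical([0.5, 0.5]))


@dataclass
class TMazeConfig:
    """Scenario parameters for the T-maze task.

    ``goal_mode='explore_first'`` applies the flat prior at absolute time 1
    and the informative prior afterwards; ``'all_informative'`` applies the
    informative prior at every step (the configuration under which epistemic
    agents turn greedy).
    """

    alpha: float = 0.9
    c: float = 2.0
    T: int = 2
    N: int = 2
    seed: int = 0
    goal_mode: str = "explore_first"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha={self.alpha} outside [0, 1]")
        if self.T < 1:
            raise ValueError("planning horizon T must be >= 1")
        if self.goal_mode not in ("explore_first", "all_informative"):
            raise ValueError(f"unknown goal_mode {self.goal_mode!r}")

    @classmethod
    def from_yaml(cls, text: str) -> "TMazeConfig":
        return cls(**(yaml.safe_load(text) or {}))


def build_tmaze_model(
    cfg: TMazeConfig, state_prior: Categorical | None = None
) -> StateSpaceModel:
    """Assemble the T-maze generative model for a scenario."""
    prior = state_prior if state_prior is not None else initial_state_prior()
    if prior.domain_size != 8:
        raise GraphError("T-maze state prior must cover the 8 position x arm states")
    informative = goal_prior(cfg.c)
    flat = flat_goal()

    def goal_for_step(k: int) -> Categorical:
        if cfg.goal_mode == "explore_first" and k <= 1:
            return flat
        return informative

    return StateSpaceModel(
        prior=prior,
        transitions=transition_matrices(),
        likelihood=observation_matrix(cfg.alpha),
        goal_for_step=goal_for_step,
        t0=1,
        state_labels=[f"pos{p}-arm{a}" for p in POSITIONS for a in ARMS],
        observation_labels=[f"pos{p}-out{o}" for p in POSITIONS for o in OUTCOMES],
    )


# ---------------------------------------------------------------------------
# bandit fixture
# ---------------------------------------------------------------------------

@dataclass
class BanditModel:
    """Two-armed bandit: one observation, one clamped control, no goal prior."""

    table: np.ndarray = field(
        default_factory=lambda: np.array([[0.5, 1.0], [0.5, 0.0]])
    )

    @property
    def controls(self) -> list[int]:
        return [0, 1]

    def future(self, policy: Sequence[int], t0: int | None = None) -> FutureModel:
        policy = tuple(policy)
        if len(policy) != 1 or policy[0] not in (0, 1):
            raise GraphError("bandit policies are single controls in {0, 1}")
        graph = build_graph(
            [Variable("y", 2, role="observation"), Variable("u", 2, role="control")],
            [
                Factor(
                    "lever", "conditional", self.table, ("y", "u"), conditioning=("u",)
                )
            ],
            clamps={"u": policy[0]},
        )
        return FutureModel(
            graph=graph,
            observation_vars=["y"],
            state_vars=[],
            policy=policy,
            ssm=None,
        )


def build_bandit_model() -> BanditModel:
    return BanditModel()


# ---------------------------------------------------------------------------
# simulated environment (generative process)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TMazeEnvState:
    """True world state: the agent's position and the rewarded arm."""

    agent_position: int
    reward_arm: int

    def __post_init__(self):
        if self.agent_position not in POSITIONS:
            raise ValueError(f"invalid position {self.agent_position}")
        if self.reward_arm not in ARMS:
            raise ValueError(f"invalid reward arm {self.reward_arm}")


def env_execute(env: TMazeEnvState, action: int) -> TMazeEnvState:
    """Apply a control to the process: the deterministic position pattern.

    Positions 2 and 3 absorb: no control moves the agent out of an arm.
    """
    if action not in POSITIONS:
        raise ValueError(f"invalid action {action}")
    col = np.array(_B_PATTERNS[action])[:, env.agent_position - 1]
    new_position = int(np.argmax(col)) + 1 if col.sum() > 0 else env.agent_position
    return TMazeEnvState(new_position, env.reward_arm)


def env_observe(env: TMazeEnvState, alpha: float, rng: np.random.Generator) -> int:
    """Sample an observation index from the ``A`` column of the true state."""
    col = observation_matrix(alpha)[:, state_index(env.agent_position, env.reward_arm)]
    return int(rng.choice(16, p=col))


class TMazeEnv:
    """Stateful wrapper around the process, with the protocol's interface."""

    def __init__(self, cfg: TMazeConfig, reward_arm: int = 3, start_position: int = 1):
        self.cfg = cfg
        self.state = TMazeEnvState(start_position, reward_arm)

    def execute(self, action: int) -> None:
        self.state = env_execute(self.state, action)

    def observe(self, rng: np.random.Generator) -> int:
        return env_observe(self.state, self.cfg.alpha, rng)

    def expected_reward(self) -> float:
        """Probability of obtaining the reward at the current position."""
        pos, arm = self.state.agent_position, self.state.reward_arm
        if pos == arm:
            return self.cfg.alpha
        if pos in ARMS:
            return 1.0 - self.cfg.alpha
        return 0.0
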