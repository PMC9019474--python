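"""Policy enumeration, planning, perception and the interactive protocol.

Planning evaluates a free-energy objective (BFE, CBFE or EFE) for every
candidate policy on the unrolled future model and selects the argmin.  The
protocol loop then follows the classic five steps per round: plan, act
(execute the first control of the active policy), let the environment respond,
observe, and slide -- the exact Bayes posterior over the current state becomes
the next round's state prior.  The planning horizon is refreshed every round
(receding horizon); beliefs about the future never influence the slide update.

Tie-breaking among optimal policies is lexicographic by default (reproducible,
and surfaced ties are scientifically meaningful), with a seeded uniform-random
option used by the interactive landscape experiments, where genuinely
ambivalent agents should split between tied arms rather than always take the
lowest-numbered one.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .discrete import Categorical
from .factor_graph import GraphError
from .free_energy import (
    FreeEnergyReport,
    expected_free_energy,
    minimize_bfe,
    minimize_cbfe,
    oracle_cbfe,
)
from .models import FutureModel, StateSpaceModel

__all__ = [
    "enumerate_policies",
    "Policy",
    "PlanningResult",
    "AgentState",
    "plan",
    "act",
    "slide",
    "run_protocol",
    "TrajectoryRecord",
]

Policy = tuple

OBJECTIVES = ("BFE", "CBFE", "EFE")


def enumerate_policies(controls, T: int) -> list[Policy]:
    """All ``|controls|**T`` control sequences, in lexicographic order.

    ``controls`` is either the control domain size (yielding 0-based indices)
    or an explicit sequence of control values.
    """
    if isinstance(controls, int):
        controls = range(controls)
    controls = list(controls)
    if not controls or T < 0:
        raise ValueError("need at least one control and a non-negative horizon")
    return [tuple(p) for p in itertools.product(controls, repeat=T)]


@dataclass
class PlanningResult:
    """Per-policy free energies, the optimal set, and the selected policy."""

    objective: str
    table: dict[Policy, FreeEnergyReport]
    optimal: list[Policy]
    selected: Policy

    @property
    def minimum_bits(self) -> float:
        return self.table[self.optimal[0]].total_bits

    def summary(self) -> dict:
        return {
            "objective": self.objective,
            "selected": list(self.selected),
            "optimal": [list(p) for p in self.optimal],
            "energies": {str(tuple(p)): r.total_bits for p, r in self.table.items()},
        }


@dataclass
class AgentState:
    """Perceptual state carried across protocol rounds."""

    state_prior: Categorical
    time: int = 1
    history: list[tuple] = field(default_factory=list)


def _resolve_builder(model_builder) -> Callable[[Categorical, Policy, int], FutureModel]:
    if isinstance(model_builder, StateSpaceModel):
        return lambda prior, policy, t0: model_builder.with_prior(prior).future(policy, t0=t0)
    if hasattr(model_builder, "future"):
        return lambda prior, policy, t0: model_builder.future(policy, t0=t0)
    return model_builder


def plan(
    agent: AgentState | Categorical,
    model_builder,
    objective: str,
    policies: Sequence[Policy] | None = None,
    engine: str = "auto",
    tie_break: str = "lexicographic",
    rng: np.random.Generator | None = None,
    atol: float = 1e-9,
) -> PlanningResult:
    """Evaluate the chosen objective for each candidate policy and select.

    ``model_builder`` is a :class:`StateSpaceModel` (or any callable mapping
    ``(state_prior, policy, t0)`` to a :class:`FutureModel`).  For the CBFE
    the optimized potential outcomes are reported per policy.  ``engine``
    picks the CBFE optimizer: ``'exhaustive'`` (message passing per outcome
    configuration), ``'em'`` (iterative), or ``'oracle'`` (closed-form tensor
    enumeration; exact on the tree-structured models built here and used by
    the interactive protocol for speed).  Policies whose every outcome is
    infeasible are retained in the table with ``+inf`` energy.
    """
    if objective not in OBJECTIVES:
        raise ValueError(f"unknown objective {objective!r}")
    if isinstance(agent, AgentState):
        prior, t0 = agent.state_prior, agent.time
    else:
        prior, t0 = agent, None
    build = _resolve_builder(model_builder)
    if policies is None:
        if isinstance(model_builder, StateSpaceModel):
            horizon = 2
            policies = enumerate_policies(model_builder.controls, horizon)
        else:
            raise ValueError("policies must be given for non-state-space builders")

    table: dict[Policy, FreeEnergyReport] = {}
    for policy in policies:
        policy = tuple(policy)
        fm = build(prior, policy, t0)
        if objective == "EFE":
            if fm.ssm is None:
                raise GraphError("EFE requires a state-space future model")
            ssm = fm.ssm  # prior already substituted by the builder
            goals = ssm.goals_for_policy(policy, t0)
            report = expected_free_energy(ssm, policy, goals)
        elif objective == "BFE":
            report, _ = minimize_bfe(fm.graph)
            report.policy = policy
        else:  # CBFE
            if engine == "oracle":
                report = oracle_cbfe(fm.graph, policy)
            else:
                report, _ = minimize_cbfe(fm.constrained().graph, mode=engine)
                report.policy = policy
        table[policy] = report
    finite_min = min(r.total_bits for r in table.values())
    optimal = [p for p, r in table.items() if r.total_bits <= finite_min + atol]
    if tie_break == "lexicographic":
        selected = optimal[0]
    elif tie_break == "random":
        rng = rng if rng is not None else np.random.default_rng()
        selected = optimal[int(rng.integers(len(optimal)))]
    else:
        raise ValueError(f"unknown tie_break {tie_break!r}")
    return PlanningResult(objective, table, optimal, selected)


def act(result: PlanningResult):
    """The first control of the selected policy."""
    return result.selected[0]


def slide(
    agent: AgentState, model: StateSpaceModel, action, observation: int
) -> AgentState:
    """Perception update: exact Bayes posterior becomes the next state prior.

    ``p(x_t | y_t, u_t) ∝ A[y_t, :] ⊙ (B_{u_t} d_{t-1})``; only the one-step
    sub-model is involved -- beliefs about the future play no role.  Raises an
    infeasibility error naming the observation when it has zero probability.
    """
    posterior = model.with_prior(agent.state_prior).posterior(action, observation)
    return AgentState(
        state_prior=posterior,
        time=agent.time + 1,
        history=agent.history + [(action, observation)],
    )


@dataclass
class TrajectoryRecord:
    """Outcome of one interactive episode."""

    objective: str
    actions: list
    observations: list[int]
    rounds: list[dict]
    final_prior: Categorical
    expected_reward: float | None = None

    @property
    def trajectory(self) -> tuple:
        return tuple(self.actions)

    def to_jsonl(self) -> str:
        lines = []
        for r in self.rounds:
            lines.append(json.dumps(r))
        return "\n".join(lines)


def run_protocol(
    model: StateSpaceModel,
    environment,
    objective: str,
    N: int = 2,
    T: int = 2,
    seed: int | np.random.Generator = 0,
    engine: str = "oracle",
    tie_break: str = "random",
    policies: Sequence[Policy] | None = None,
) -> TrajectoryRecord:
    """Run ``N`` rounds of the plan / act / execute / observe / slide loop.

    The environment must expose ``execute(action)`` and ``observe(rng)``; if
    it also provides ``expected_reward()`` the final value is recorded.  The
    horizon is ``T`` at every round (receding horizon), with the goal-prior
    schedule following absolute time, so a flat first-step prior applies only
    to the very first move of the episode.  All randomness (environment
    sampling and random tie-breaks) derives from ``seed``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    agent = AgentState(state_prior=model.prior, time=model.t0)
    if policies is None:
        policies = enumerate_policies(model.controls, T)
    actions, observations, rounds = [], [], []
    for _ in range(N):
        result = plan(
            agent, model, objective, policies=policies, engine=engine,
            tie_break=tie_break, rng=rng,
        )
        action = act(result)
        environment.execute(action)
        observation = int(environment.observe(rng))
        agent = slide(agent, model, action, observation)
        actions.append(action)
        observations.append(observation)
        rounds.append(
            {
                "time": agent.time - 1,
                "planned": result.summary(),
                "action": action,
                "observation": observation,
                "posterior": agent.state_prior.probs.tolist(),
            }
        )
    reward = None
    if hasattr(environment, "expected_reward"):
        reward = float(environment.expected_reward())
    return TrajectoryRecord(
        objective=objective,
        actions=actions,
        observations=observations,
        rounds=rounds,
        final_prior=agent.state_prior,
        expected_reward=reward,
    )
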