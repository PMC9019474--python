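"""State-space generative models and their unrolled planning graphs.

A :class:`StateSpaceModel` is the discrete POMDP-style engine used throughout
the package: a categorical state prior ``d``, control-indexed column-stochastic
transition tables ``B_u`` (``p(x_k = i | x_{k-1} = j, u) = B_u[i, j]``), an
observation table ``A`` (``p(y = i | x = j) = A[i, j]``), and a goal-prior
schedule mapping absolute time steps to preference distributions over
outcomes.  :meth:`StateSpaceModel.future` unrolls the engine over a candidate
policy into the factor graph of the future model used for planning: the
controls are clamped (candidate policies are given), which makes the graph a
tree and all planning objectives exactly computable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np

from .discrete import Categorical
from .factor_graph import Factor, FactorGraph, GraphError, Variable, build_graph
from .message_passing import InfeasibleError

__all__ = ["StateSpaceModel", "FutureModel"]


@dataclass
class FutureModel:
    """A planning model for one candidate policy: a factor graph plus metadata."""

    graph: FactorGraph
    observation_vars: list[str]
    state_vars: list[str]
    policy: tuple
    ssm: "StateSpaceModel | None" = None

    def constrained(self) -> "FutureModel":
        """The same model with point-mass constraints on predicted outcomes."""
        g = self.graph.with_constraints({v: "point_mass" for v in self.observation_vars})
        return FutureModel(g, self.observation_vars, self.state_vars, self.policy, self.ssm)


@dataclass
class StateSpaceModel:
    """Discrete state-space generative model engine with a goal-prior schedule.

    Parameters
    ----------
    prior :
        State prior ``d_{t-1}`` (the output of perception).
    transitions :
        Mapping from control value to an ``S x S`` column-stochastic table.
        Control values are arbitrary hashables (the T-maze uses the positions
        ``1..4`` so policies read like the field's notation, e.g. ``(4, 3)``).
    likelihood :
        ``O x S`` column-stochastic observation table.
    goal_for_step :
        Maps an *absolute* time index ``k`` to the goal prior over outcomes at
        that step.  Anchoring to absolute time matters: a flat prior at
        ``k = 1`` only frees the very first move for exploration, while later
        replanning rounds see informative priors throughout.
    t0 :
        Absolute time of the first planned step.
    """

    prior: Categorical
    transitions: Mapping[object, np.ndarray]
    likelihood: np.ndarray
    goal_for_step: Callable[[int], Categorical]
    t0: int = 1
    state_labels: Sequence[str] | None = None
    observation_labels: Sequence[str] | None = None

    def __post_init__(self):
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        self.transitions = {u: np.asarray(B, dtype=float) for u, B in self.transitions.items()}
        s = self.prior.domain_size
        for u, B in self.transitions.items():
            if B.shape != (s, s):
                raise GraphError(f"transition table for control {u!r} has shape {B.shape}")
            if np.any(np.abs(B.sum(axis=0) - 1.0) > 1e-6):
                raise GraphError(f"transition table for control {u!r} is not column-stochastic")
        if self.likelihood.shape[1] != s:
            raise GraphError(
                f"likelihood has {self.likelihood.shape[1]} state columns, expected {s}"
            )
        if np.any(np.abs(self.likelihood.sum(axis=0) - 1.0) > 1e-6):
            raise GraphError("likelihood table is not column-stochastic")

    @property
    def n_states(self) -> int:
        return self.prior.domain_size

    @property
    def n_observations(self) -> int:
        return int(self.likelihood.shape[0])

    @property
    def controls(self) -> list:
        return list(self.transitions.keys())

    def with_prior(self, prior: Categorical, t0: int | None = None) -> "StateSpaceModel":
        return replace(self, prior=prior, t0=self.t0 if t0 is None else t0)

    def goals_for_policy(self, policy: Sequence, t0: int | None = None) -> list[Categorical]:
        start = self.t0 if t0 is None else t0
        return [self.goal_for_step(start + k) for k in range(len(policy))]

    # -- future model construction ----------------------------------------

    def future(self, policy: Sequence, t0: int | None = None) -> FutureModel:
        """Unroll the engine over ``policy`` into the future factor graph.

        Variables: ``x0`` (the state prior's variable) through ``x{T}``,
        observations ``y1..y{T}``, and clamped controls ``u1..u{T}`` entering
        through mux transition factors that stack the per-control tables.
        Goal priors attach to each observation variable as ordinary priors,
        making the future model a scaled distribution.
        """
        policy = tuple(policy)
        controls = self.controls
        control_index = {u: i for i, u in enumerate(controls)}
        for u in policy:
            if u not in control_index:
                raise GraphError(f"policy control {u!r} not in the admissible control set")
        T = len(policy)
        S, O, U = self.n_states, self.n_observations, len(controls)
        mux = np.stack([self.transitions[u] for u in controls], axis=-1)  # (S, S, U)

        variables = [Variable("x0", S, role="state")]
        factors = [Factor("prior_x0", "prior", self.prior.probs, ("x0",))]
        clamps: dict[str, int] = {}
        goals = self.goals_for_policy(policy, t0)
        for k in range(1, T + 1):
            variables += [
                Variable(f"x{k}", S, role="state"),
                Variable(f"y{k}", O, role="observation"),
                Variable(f"u{k}", U, role="control"),
            ]
            factors += [
                Factor(
                    f"transition_{k}",
                    "mux_transition",
                    mux,
                    (f"x{k}", f"x{k-1}", f"u{k}"),
                    conditioning=(f"x{k-1}", f"u{k}"),
                ),
                Factor(
                    f"likelihood_{k}",
                    "conditional",
                    self.likelihood,
                    (f"y{k}", f"x{k}"),
                    conditioning=(f"x{k}",),
                ),
                Factor(f"goal_{k}", "goal_prior", goals[k - 1].probs, (f"y{k}",)),
            ]
            clamps[f"u{k}"] = control_index[policy[k - 1]]
        graph = build_graph(variables, factors, clamps)
        return FutureModel(
            graph=graph,
            observation_vars=[f"y{k}" for k in range(1, T + 1)],
            state_vars=[f"x{k}" for k in range(T + 1)],
            policy=policy,
            ssm=self,
        )

    # -- exact single-step Bayes update (perception) -----------------------

    def posterior(self, action, observation: int) -> Categorical:
        """Exact posterior over the next state after acting and observing.

        ``p(x_t | y_t, u_t) ∝ A[y_t, :] ⊙ (B_{u_t} d_{t-1})``.
        """
        if action not in self.transitions:
            raise GraphError(f"unknown control {action!r}")
        predicted = self.transitions[action] @ self.prior.probs
        post = self.likelihood[int(observation), :] * predicted
        total = post.sum()
        if total <= 0:
            raise InfeasibleError(
                f"observation {observation} has zero probability under the model"
            )
        return Categorical(post / total)
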