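"""Shared fixtures: the bandit and T-maze models, and random tree models."""

import numpy as np
import pytest

from cbfe.discrete import Categorical
from cbfe.factor_graph import Factor, Variable, build_graph
from cbfe.tmaze import TMazeConfig, build_bandit_model, build_tmaze_model

#: the three named planning scenarios (alpha, c)
SCENARIOS = [(0.9, 2.0), (0.5, 2.0), (0.9, 0.0)]

ALL_POLICIES = [(i, j) for i in (1, 2, 3, 4) for j in (1, 2, 3, 4)]


@pytest.fixture(scope="session")
def bandit():
    return build_bandit_model()


@pytest.fixture(scope="session", params=SCENARIOS, ids=lambda s: f"alpha{s[0]}-c{s[1]}")
def tmaze_scenario(request):
    alpha, c = request.param
    cfg = TMazeConfig(alpha=alpha, c=c)
    return cfg, build_tmaze_model(cfg)


@pytest.fixture(scope="session")
def tmaze_main():
    """The headline scenario: likely reward, positive utility."""
    cfg = TMazeConfig(alpha=0.9, c=2.0)
    return cfg, build_tmaze_model(cfg)


def random_chain_graph(rng: np.random.Generator, n_vars: int = 4, max_size: int = 3):
    """A random tree-structured model: a chain of conditionals with leaf priors.

    Used as the enumeration-vs-message-passing oracle fixture; guaranteed
    acyclic and connected, with strictly positive tables.
    """
    sizes = [int(rng.integers(2, max_size + 1)) for _ in range(n_vars)]
    variables = [Variable(f"v{i}", sizes[i]) for i in range(n_vars)]
    prior = rng.random(sizes[0]) + 0.1
    factors = [Factor("prior0", "prior", prior / prior.sum(), ("v0",))]
    for i in range(1, n_vars):
        t = rng.random((sizes[i], sizes[i - 1])) + 0.1
        t = t / t.sum(axis=0, keepdims=True)
        factors.append(
            Factor(
                f"cond{i}", "conditional", t, (f"v{i}", f"v{i-1}"),
                conditioning=(f"v{i-1}",),
            )
        )
    # occasionally hang an extra leaf observation off a mid-chain variable
    if n_vars >= 3 and rng.random() < 0.7:
        k = int(rng.integers(1, n_vars - 1))
        sz = int(rng.integers(2, max_size + 1))
        variables.append(Variable("leaf", sz))
        t = rng.random((sz, sizes[k])) + 0.1
        t = t / t.sum(axis=0, keepdims=True)
        factors.append(
            Factor("leaf_cond", "conditional", t, ("leaf", f"v{k}"), conditioning=(f"v{k}",))
        )
    return build_graph(variables, factors)


def random_goal_chain(rng: np.random.Generator, n_steps: int = 2):
    """A scaled future-model-like chain: engine plus goal priors on leaves."""
    g = random_chain_graph(rng, n_vars=n_steps + 1)
    variables = list(g.variables.values())
    factors = list(g.factors.values())
    # attach a goal prior to the last chain variable, making the model scaled
    last = f"v{n_steps}"
    size = g.variables[last].size
    goal = rng.random(size) + 0.05
    factors.append(Factor("goal", "goal_prior", goal / goal.sum(), (last,)))
    return build_graph(variables, factors)


def uniform_categorical(n: int) -> Categorical:
    return Categorical(np.full(n, 1.0 / n))
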