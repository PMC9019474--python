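"""Message updates, schedules, and the EM fixed-point iteration."""

import numpy as np
import pytest

from cbfe.discrete import PointMass
from cbfe.factor_graph import (
    Factor,
    GraphError,
    Variable,
    build_graph,
    example_tree_graph,
    joint_table,
)
from cbfe.free_energy import constrained_bethe_free_energy
from cbfe.message_passing import (
    InfeasibleError,
    Message,
    make_schedule,
    run_until_converged,
    sum_product_message,
    update_point_mass,
    variational_message,
)
from conftest import random_chain_graph


def chain2(prior=(0.5, 0.5), table=((0.9, 0.1), (0.1, 0.9))):
    return build_graph(
        [Variable("x0", 2), Variable("x1", 2)],
        [
            Factor("p0", "prior", list(prior), ("x0",)),
            Factor("trans", "conditional", np.array(table), ("x1", "x0"),
                   conditioning=("x0",)),
        ],
    )


class TestSumProduct:
    def test_bandit_likelihood_message_is_deterministic_column(self, bandit):
        # informative lever: the observation model's second column is one-hot
        g = bandit.future((1,)).graph
        m = sum_product_message(g, "lever", "y", {})
        assert np.allclose(m.values, [1.0, 0.0])

    def test_prior_factor_message_equals_prior(self):
        g = chain2(prior=(0.3, 0.7))
        m = sum_product_message(g, "p0", "x0", {})
        assert np.allclose(m.values, [0.3, 0.7])

    def test_permutation_transition_preserves_uniform(self):
        g = chain2(table=((0.0, 1.0), (1.0, 0.0)))
        m = sum_product_message(g, "trans", "x1", {"x0": np.array([0.5, 0.5])})
        assert np.allclose(m.values, [0.5, 0.5])

    def test_all_zero_message_is_infeasible(self):
        g = chain2()
        with pytest.raises(InfeasibleError, match="trans"):
            sum_product_message(g, "trans", "x1", {"x0": np.array([0.0, 0.0])})


class TestVariational:
    def test_one_hot_neighbors_reduce_to_sum_product(self):
        g = chain2(table=((0.8, 0.4), (0.2, 0.6)))
        onehot = np.array([0.0, 1.0])
        sp = sum_product_message(g, "trans", "x1", {"x0": onehot})
        vmp = variational_message(g, "trans", "x1", {"x0": onehot})
        assert np.allclose(sp.values, vmp.values)

    def test_prior_factor_message_equals_prior(self):
        g = chain2(prior=(0.25, 0.75))
        m = variational_message(g, "p0", "x0", {})
        assert np.allclose(m.values, [0.25, 0.75])

    def test_geometric_mean_of_columns(self):
        # E_q log A with q = (.5,.5) averages the log columns: both entries
        # become sqrt(0.9 * 0.1), i.e. the message is uniform
        g = chain2()
        m = variational_message(g, "trans", "x1", {"x0": np.array([0.5, 0.5])})
        assert np.allclose(m.values, [0.5, 0.5])


class TestPointMassUpdate:
    def setup_method(self):
        self.g = chain2().with_constraints({"x1": "point_mass"})

    def test_dominant_mode(self):
        pm = update_point_mass(self.g, "x1", np.array([0.9, 0.1]), np.array([0.5, 0.5]))
        assert pm.index == 0

    def test_tie_breaks_low(self):
        pm = update_point_mass(self.g, "x1", np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert pm.index == 0

    def test_bandit_informative_outcome(self, bandit):
        # likelihood message (1, 0) with no goal prior: the potential outcome
        # of the informative lever is y = 0
        g = bandit.future((1,)).constrained().graph
        m = sum_product_message(g, "lever", "y", {})
        assert update_point_mass(g, "y", m).index == 0

    def test_zero_product_infeasible(self):
        with pytest.raises(InfeasibleError):
            update_point_mass(self.g, "x1", np.array([1.0, 0.0]), np.array([0.0, 1.0]))

    def test_requires_constraint(self):
        with pytest.raises(GraphError):
            update_point_mass(chain2(), "x1", np.array([1.0, 0.0]))


class TestSchedule:
    def test_chain_forward_then_backward(self):
        g = chain2()
        sched = make_schedule(g)
        dirs = [(e.factor, e.target_variable) for e in sched]
        assert set(dirs) == {("p0", "x0"), ("trans", "x1"), ("trans", "x0")}
        # the forward message into x1 needs the prior message first
        assert dirs.index(("p0", "x0")) < dirs.index(("trans", "x1"))

    def test_example_model_schedule_has_seven_messages(self):
        sched = make_schedule(example_tree_graph())
        assert len(sched) == 7
        # every factor-variable direction appears exactly once
        assert len({(e.factor, e.target_variable) for e in sched}) == 7

    def test_tmaze_schedule_covers_both_sweeps(self, tmaze_main):
        _cfg, model = tmaze_main
        g = model.future((4, 3)).graph
        sched = make_schedule(g)
        # 7 factors over 5 free variables: 11 factor-variable directions
        assert len(sched) == 11
        targets = {(e.factor, e.target_variable) for e in sched}
        assert ("likelihood_2", "x2") in targets  # backward (smoothing) leg

    def test_disconnected_graph_rejected(self):
        g = build_graph(
            [Variable("a", 2), Variable("b", 2)],
            [
                Factor("fa", "prior", [0.5, 0.5], ("a",)),
                Factor("fb", "prior", [0.5, 0.5], ("b",)),
            ],
        )
        with pytest.raises(GraphError, match="disconnected"):
            make_schedule(g)


class TestConvergence:
    @pytest.mark.parametrize("seed", range(8))
    def test_tree_marginals_match_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        g = random_chain_graph(rng, n_vars=int(rng.integers(3, 7)))
        state, iters, converged = run_until_converged(g)
        assert converged and iters <= 2
        jt, order = joint_table(g)
        jt = jt / jt.sum()
        for i, v in enumerate(order):
            axes = tuple(j for j in range(len(order)) if j != i)
            assert np.allclose(
                jt.sum(axis=axes), state.variable_marginals[v].probs, atol=1e-10
            ), v

    @pytest.mark.parametrize("seed", range(4))
    def test_factor_beliefs_marginalize_consistently(self, seed):
        g = random_chain_graph(np.random.default_rng(200 + seed))
        state, _, _ = run_until_converged(g)
        for fn, q in state.factor_beliefs.items():
            args = g.free_args(fn)
            for i, a in enumerate(args):
                axes = tuple(j for j in range(len(args)) if j != i)
                marg = q.sum(axis=axes) if axes else q
                assert np.allclose(
                    marg, state.variable_marginals[a].probs, atol=1e-6
                ), (fn, a)

    def test_beliefs_normalized_every_sweep(self, tmaze_main):
        _cfg, model = tmaze_main
        g = model.future((4, 3)).constrained().graph
        state, _, converged = run_until_converged(g)
        assert converged
        for v, m in state.variable_marginals.items():
            assert m.probs.sum() == pytest.approx(1.0)
        for fn, q in state.factor_beliefs.items():
            assert q.sum() == pytest.approx(1.0)

    def test_em_iterations_do_not_increase_cbfe(self, tmaze_main):
        # run the EM loop one sweep at a time and track the objective
        _cfg, model = tmaze_main
        g = model.future((2, 3)).constrained().graph
        energies = []
        state = None
        for iters in range(1, 7):
            state, _, _ = run_until_converged(g, max_iters=iters, tol=0.0)
            energies.append(constrained_bethe_free_energy(g, state).total_bits)
        for earlier, later in zip(energies, energies[1:]):
            assert later <= earlier + 1e-9

    def test_nonconvergence_returns_flag_not_raise(self):
        # a loopy frustrated cycle may not settle in one sweep
        t = np.full((2, 2), 0.25)
        cyc = build_graph(
            [Variable(v, 2) for v in "abc"],
            [
                Factor("fab", "prior", t, ("a", "b")),
                Factor("fbc", "prior", t, ("b", "c")),
                Factor("fca", "prior", t, ("c", "a")),
            ],
        )
        state, iters, converged = run_until_converged(cyc, max_iters=3)
        assert iters <= 3
        assert set(state.variable_marginals) == {"a", "b", "c"}
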