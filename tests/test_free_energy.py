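"""Objective evaluation, decompositions, and the enumeration oracles."""

import numpy as np
import pytest

from cbfe.discrete import Categorical
from cbfe.factor_graph import Factor, Variable, build_graph
from cbfe.free_energy import (
    FreeEnergyReport,
    bethe_free_energy,
    constrained_bethe_free_energy,
    decompose_bfe,
    decompose_ccx,
    decompose_pie,
    expected_free_energy,
    minimize_bfe,
    minimize_cbfe,
    oracle_cbfe,
    oracle_log_partition,
)
from cbfe.message_passing import BeliefState, run_until_converged
from cbfe.tmaze import TMazeConfig, build_tmaze_model
from conftest import ALL_POLICIES, random_goal_chain


class TestBanditWorkedExample:
    """The two-lever model: BFE is blind to information, the CBFE is not."""

    def test_minimized_bfe_is_zero_for_both_levers(self, bandit):
        for u in (0, 1):
            report, _ = minimize_bfe(bandit.future((u,)).graph)
            assert report.total_bits == pytest.approx(0.0, abs=1e-12)

    def test_minimized_cbfe_penalizes_the_ignorant_lever(self, bandit):
        report0, _ = minimize_cbfe(bandit.future((0,)).constrained().graph, mode="exhaustive")
        report1, _ = minimize_cbfe(bandit.future((1,)).constrained().graph, mode="exhaustive")
        assert report0.total_bits == pytest.approx(1.0, abs=1e-12)
        assert report1.total_bits == pytest.approx(0.0, abs=1e-12)

    def test_cbfe_point_evaluations(self, bandit):
        # fixing the outcome by hand: -log2 p(y|u)
        from cbfe.discrete import PointMass

        g = bandit.future((1,)).constrained().graph
        b0 = BeliefState(point_assignments={"y": PointMass(2, 0)})
        b1 = BeliefState(point_assignments={"y": PointMass(2, 1)})
        assert constrained_bethe_free_energy(g, b0).total_bits == pytest.approx(0.0)
        assert constrained_bethe_free_energy(g, b1).total_bits == np.inf

    def test_log_partition_zero_without_goal_prior(self, bandit):
        for u in (0, 1):
            assert oracle_log_partition(bandit.future((u,)).graph) == pytest.approx(0.0)

    def test_bfe_invariant_to_epistemic_perturbation(self):
        # tilting the ignorant lever's outcome odds leaves minimized BFE at 0
        from cbfe.tmaze import BanditModel

        tilted = BanditModel(table=np.array([[0.7, 1.0], [0.3, 0.0]]))
        for u in (0, 1):
            report, _ = minimize_bfe(tilted.future((u,)).graph)
            assert report.total_bits == pytest.approx(0.0, abs=1e-12)


class TestBetheEvaluation:
    def test_exact_posterior_of_normalized_factor_gives_zero(self):
        g = build_graph(
            [Variable("a", 3)], [Factor("f", "prior", [0.2, 0.3, 0.5], ("a",))]
        )
        b = BeliefState(
            variable_marginals={"a": Categorical([0.2, 0.3, 0.5])},
            factor_beliefs={"f": np.array([0.2, 0.3, 0.5])},
        )
        assert bethe_free_energy(g, b).total_bits == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_minimized_bfe_on_trees_equals_negative_log_partition(self, seed):
        g = random_goal_chain(np.random.default_rng(300 + seed))
        report, _ = minimize_bfe(g)
        assert report.total_bits == pytest.approx(
            -oracle_log_partition(g), abs=1e-9
        )


class TestOracleEquivalences:
    @pytest.mark.parametrize("seed", range(4))
    def test_exhaustive_cbfe_matches_closed_form(self, seed):
        # constrain the goal-carrying chain end as the predicted outcome
        g = random_goal_chain(np.random.default_rng(400 + seed))
        last = [v for v in g.variables if v.startswith("v")][-1]
        gc = g.with_constraints({last: "point_mass"})
        report, _ = minimize_cbfe(gc, mode="exhaustive")
        orc = oracle_cbfe(gc)
        assert report.total_bits == pytest.approx(orc.total_bits, abs=1e-9)

    def test_tmaze_exhaustive_equals_oracle_all_policies(self, tmaze_main):
        _cfg, model = tmaze_main
        for policy in ALL_POLICIES:
            fm = model.future(policy)
            report, _ = minimize_cbfe(fm.constrained().graph, mode="exhaustive")
            orc = oracle_cbfe(fm.graph, policy)
            assert report.total_bits == pytest.approx(orc.total_bits, abs=1e-9), policy

    def test_em_reaches_global_optimum_on_tmaze(self, tmaze_main):
        _cfg, model = tmaze_main
        for policy in [(4, 3), (1, 1), (2, 2), (4, 4)]:
            fm = model.future(policy)
            report, _ = minimize_cbfe(fm.constrained().graph, mode="em")
            orc = oracle_cbfe(fm.graph, policy)
            assert report.total_bits == pytest.approx(orc.total_bits, abs=1e-9), policy

    def test_tmaze_log_partition_negative_with_informative_goals(self, tmaze_main):
        _cfg, model = tmaze_main
        assert oracle_log_partition(model.future((4, 3)).graph) < 0


@pytest.fixture(scope="module")
def optimized(tmaze_scenario):
    """Converged constrained beliefs for all 16 policies of a scenario."""
    _cfg, model = tmaze_scenario
    out = {}
    for policy in ALL_POLICIES:
        fm = model.future(policy)
        g = fm.constrained().graph
        report, beliefs = minimize_cbfe(g, mode="exhaustive")
        out[policy] = (fm, g, report, beliefs)
    return out


class TestDecompositions:
    def test_ccx_terms_sum_to_cbfe_total(self, optimized):
        for policy, (fm, g, report, beliefs) in optimized.items():
            d = decompose_ccx(g, beliefs, policy)
            assert d.total_bits == pytest.approx(report.total_bits, abs=1e-6), policy
            assert d.terms_total() == pytest.approx(d.total_bits, abs=1e-9)

    def test_pie_terms_sum_to_cbfe_total(self, optimized):
        for policy, (fm, g, report, beliefs) in optimized.items():
            d = decompose_pie(g, beliefs, policy)
            assert d.total_bits == pytest.approx(report.total_bits, abs=1e-6), policy
            # exact posterior on a tree at convergence
            assert d.terms["posterior_divergence"] == pytest.approx(0.0, abs=1e-6)

    def test_predicted_log_evidence_bound(self, optimized):
        # log2 p(y|u) >= confidence - complexity, for every policy
        for policy, (fm, g, report, beliefs) in optimized.items():
            ccx = decompose_ccx(g, beliefs, policy)
            pie = decompose_pie(g, beliefs, policy)
            lhs = pie.terms["intrinsic"]
            rhs = ccx.terms["confidence"] - ccx.terms["complexity"]
            assert lhs >= rhs - 1e-9, policy

    def test_bfe_decomposition_sums_to_total(self, tmaze_scenario):
        _cfg, model = tmaze_scenario
        for policy in ALL_POLICIES:
            fm = model.future(policy)
            report, beliefs = minimize_bfe(fm.graph)
            d = decompose_bfe(fm.graph, beliefs, policy)
            assert d.total_bits == pytest.approx(report.total_bits, abs=1e-6), policy
            assert d.terms["expected_posterior_divergence"] == pytest.approx(
                0.0, abs=1e-6
            )

    def test_confidence_of_stay_home_policy(self, tmaze_scenario):
        # remaining at the start rejects 1 bit of information twice
        _cfg, model = tmaze_scenario
        fm = model.future((1, 1))
        g = fm.constrained().graph
        _report, beliefs = minimize_cbfe(g, mode="exhaustive")
        d = decompose_ccx(g, beliefs, (1, 1))
        assert d.terms["confidence"] == pytest.approx(-2.0, abs=1e-9)

    def test_intrinsic_value_of_ignorant_lever(self, bandit):
        g = bandit.future((0,)).constrained().graph
        _report, beliefs = minimize_cbfe(g, mode="exhaustive")
        d = decompose_pie(g, beliefs, (0,))
        assert d.terms["intrinsic"] == pytest.approx(-1.0, abs=1e-12)


class TestEFE:
    def test_deterministic_observations_have_zero_ambiguity(self):
        from cbfe.models import StateSpaceModel

        model = StateSpaceModel(
            prior=Categorical([0.5, 0.5]),
            transitions={0: np.eye(2)},
            likelihood=np.eye(2),
            goal_for_step=lambda k: Categorical([0.5, 0.5]),
        )
        report = expected_free_energy(model, (0, 0))
        assert report.terms["ambiguity"] == pytest.approx(0.0)

    def test_tmaze_start_position_ambiguity_is_one_bit_per_step(self, tmaze_main):
        _cfg, model = tmaze_main
        report = expected_free_energy(model, (1,))
        assert report.terms["ambiguity"] == pytest.approx(1.0, abs=1e-12)

    def test_terms_sum_and_report_consistency(self, tmaze_main):
        _cfg, model = tmaze_main
        report = expected_free_energy(model, (4, 3))
        assert report.terms_total() == pytest.approx(report.total_bits, abs=1e-12)

    def test_non_state_space_model_rejected(self, bandit):
        from cbfe.factor_graph import GraphError

        with pytest.raises(GraphError):
            expected_free_energy(bandit, (0,))


def test_report_serialization_round_trip():
    import json

    r = FreeEnergyReport(
        "CBFE", 1.5, terms={"confidence": -2.0, "complexity": 0.5, "extrinsic": -3.0},
        policy=(4, 3), point_assignments={"y1": 13},
    )
    doc = json.loads(r.to_json())
    assert doc["objective"] == "CBFE"
    assert doc["policy"] == [4, 3]
    assert doc["terms"]["confidence"] == -2.0
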