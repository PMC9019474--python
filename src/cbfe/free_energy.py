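"""Free-energy objectives for planning: BFE, CBFE, EFE, and their decompositions.

Conventions
-----------
All quantities are in bits.  Decomposition *terms* are stored with the sign
conventions of the value language (a confidence, an intrinsic value, an
extrinsic value), while the free-energy total sums their *signed energy
contributions*; :meth:`FreeEnergyReport.signed_terms` exposes the latter, and
the two always satisfy ``sum(signed) == total`` up to float rounding.

The closed-form oracles in this module (``oracle_cbfe``,
``oracle_log_partition``) work by exact tensor enumeration of small joint
domains and are deliberately independent of the message-passing engine: they
serve as the reference that the iterative optimizer is tested against, and as
a fast exact evaluator for tree-structured planning models.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .discrete import Categorical, PointMass, entropy_bits, kl_bits
from .factor_graph import FactorGraph, GraphError, joint_table
from .message_passing import (
    BeliefState,
    InfeasibleError,
    make_schedule,
    run_until_converged,
)

__all__ = [
    "FreeEnergyReport",
    "bethe_free_energy",
    "constrained_bethe_free_energy",
    "minimize_bfe",
    "minimize_cbfe",
    "decompose_ccx",
    "decompose_pie",
    "decompose_bfe",
    "expected_free_energy",
    "oracle_cbfe",
    "oracle_cbfe_table",
    "oracle_log_partition",
]

_LN2 = math.log(2.0)

#: default ceiling on outcome configurations for the exhaustive CBFE mode
EXHAUSTIVE_LIMIT = 4096

#: sign of each named term's contribution to the free-energy total
TERM_SIGNS = {
    "confidence": -1.0,
    "complexity": +1.0,
    "extrinsic": -1.0,
    "intrinsic": -1.0,
    "posterior_divergence": +1.0,
    "predictive_divergence": +1.0,
    "expected_posterior_divergence": +1.0,
    "expected_extrinsic": -1.0,
    "ambiguity": +1.0,
    "risk": +1.0,
}


@dataclass
class FreeEnergyReport:
    """A free-energy total with optional named decomposition terms."""

    objective: str  # VFE | BFE | CBFE | EFE
    total_bits: float
    terms: dict[str, float] = field(default_factory=dict)
    log_partition_bits: float | None = None
    policy: tuple | None = None
    point_assignments: dict[str, int] | None = None

    def signed_terms(self) -> dict[str, float]:
        """Each term's contribution to the energy (value terms negated)."""
        return {k: TERM_SIGNS[k] * v for k, v in self.terms.items()}

    def terms_total(self) -> float:
        return float(sum(self.signed_terms().values()))

    def to_dict(self) -> dict:
        return {
            "objective": self.objective,
            "total_bits": self.total_bits,
            "terms": dict(self.terms),
            "log_partition_bits": self.log_partition_bits,
            "policy": list(self.policy) if self.policy is not None else None,
            "point_assignments": dict(self.point_assignments)
            if self.point_assignments is not None
            else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())


# ---------------------------------------------------------------------------
# Bethe evaluation from beliefs
# ---------------------------------------------------------------------------

def _tensor_energy_bits(q: np.ndarray, t: np.ndarray) -> float:
    """``-sum q log2 t`` over a belief tensor; ``+inf`` on impossible support."""
    q = np.asarray(q, dtype=float)
    t = np.asarray(t, dtype=float)
    mask = q > 0
    if np.any(t[mask] <= 0):
        return float("inf")
    return float(-np.sum(q[mask] * np.log(t[mask])) / _LN2)


def _tensor_entropy_bits(q: np.ndarray) -> float:
    q = np.asarray(q, dtype=float)
    nz = q[q > 0]
    return float(-np.sum(nz * np.log(nz)) / _LN2)


def _free_degrees(g: FactorGraph) -> dict[str, int]:
    d = {v: 0 for v in g.free_variables}
    for fn in g.factors:
        for a in g.free_args(fn):
            d[a] += 1
    return d


def bethe_free_energy(g: FactorGraph, b: BeliefState) -> FreeEnergyReport:
    """Evaluate ``B[q] = sum_a U[q_a || f_a] - H_Bethe[q]`` in bits.

    The Bethe entropy is ``sum_a H[q_a] + sum_i (1 - d_i) H[q_i]`` where the
    degree ``d_i`` counts the factor beliefs containing variable ``i``.
    Factors whose arguments are all clamped contribute ``-log2`` of their
    (scalar) reduced value to the average energy.
    """
    degrees = _free_degrees(g)
    total = 0.0
    for fn in g.factors:
        t = g.reduced_table(fn)
        args = g.free_args(fn)
        if not args:
            val = float(t)
            total += float("inf") if val <= 0 else -math.log(val) / _LN2
            continue
        if fn not in b.factor_beliefs:
            raise GraphError(f"belief state lacks factor belief for {fn!r}")
        q = b.factor_beliefs[fn]
        if q.shape != t.shape:
            raise GraphError(
                f"belief for factor {fn!r} has shape {q.shape}, expected {t.shape}"
            )
        total += _tensor_energy_bits(q, t) - _tensor_entropy_bits(q)
    for v, d in degrees.items():
        if v not in b.variable_marginals:
            raise GraphError(f"belief state lacks marginal for variable {v!r}")
        total -= (1 - d) * entropy_bits(b.variable_marginals[v])
    return FreeEnergyReport("BFE", float(total))


def _restricted_beliefs(
    g: FactorGraph, b: BeliefState, assignments: Mapping[str, PointMass]
) -> BeliefState:
    """Slice delta axes out of the beliefs; the result matches ``g.with_clamps``."""
    marginals = {
        v: m for v, m in b.variable_marginals.items() if v not in assignments
    }
    beliefs: dict[str, np.ndarray] = {}
    for fn, q in b.factor_beliefs.items():
        args = g.free_args(fn)
        idx = tuple(
            assignments[a].index if a in assignments else slice(None) for a in args
        )
        qr = np.asarray(q)[idx]
        if qr.ndim == 0:
            continue  # factor fully determined by the assignments
        total = qr.sum()
        if total > 0:
            qr = qr / total
        beliefs[fn] = qr
    return BeliefState(marginals, beliefs, {})


def constrained_bethe_free_energy(g: FactorGraph, b: BeliefState) -> FreeEnergyReport:
    """Evaluate the point-mass-constrained BFE ``B[q; u, y] = U[q(x) f(y,x|u)] - H_B[q(x)]``.

    The optimized outcomes in ``b.point_assignments`` are substituted into the
    factor tables; delta beliefs contribute zero entropy.  An assignment with
    zero likelihood yields ``+inf`` total (not an exception).
    """
    assignments = dict(b.point_assignments)
    missing = [v for v in g.point_mass_variables if v not in assignments]
    if missing:
        raise GraphError(f"missing point-mass assignments for {missing}")
    g2 = g.with_clamps({k: pm.index for k, pm in assignments.items()})
    b2 = _restricted_beliefs(g, b, assignments)
    report = bethe_free_energy(g2, b2)
    return FreeEnergyReport(
        "CBFE",
        report.total_bits,
        point_assignments={k: pm.index for k, pm in assignments.items()},
    )


# ---------------------------------------------------------------------------
# minimization drivers
# ---------------------------------------------------------------------------

def minimize_bfe(
    g: FactorGraph, max_iters: int = 50, tol: float = 1e-10
) -> tuple[FreeEnergyReport, BeliefState]:
    """Minimize the BFE by (loopy) belief propagation; exact on trees."""
    state, _iters, _conv = run_until_converged(g, max_iters=max_iters, tol=tol)
    return bethe_free_energy(g, state), state


def _clamped_run(g_c: FactorGraph, schedule) -> BeliefState:
    state, _i, _c = run_until_converged(g_c, schedule=schedule, max_iters=4, tol=1e-12)
    return state


def minimize_cbfe(
    g: FactorGraph,
    mode: str = "auto",
    max_iters: int = 50,
    tol: float = 1e-10,
    multi_start: bool = False,
    exhaustive_limit: int = EXHAUSTIVE_LIMIT,
) -> tuple[FreeEnergyReport, BeliefState]:
    """Minimize the CBFE jointly over beliefs and potential outcomes.

    ``mode='exhaustive'`` enumerates every outcome configuration, performs
    exact inference per configuration, and returns the global optimum (the
    default whenever the joint outcome domain has at most
    ``exhaustive_limit`` configurations).  ``mode='em'`` runs the iterative
    expectation-maximization scheme from a deterministic initialization; with
    ``multi_start=True`` it restarts from every outcome configuration, which
    guards against local optima at exhaustive-mode cost.

    Ties between outcome configurations are broken toward the
    lexicographically lowest configuration.
    """
    pm_vars = g.point_mass_variables
    if not pm_vars:
        raise GraphError("no point-mass-constrained variables; use minimize_bfe")
    sizes = [g.variables[v].size for v in pm_vars]
    n_configs = int(np.prod(sizes))
    if mode == "auto":
        mode = "exhaustive" if n_configs <= exhaustive_limit else "em"

    if mode == "exhaustive":
        best: tuple[float, BeliefState, dict[str, int]] | None = None
        schedule = None
        for config in np.ndindex(*sizes):
            clamp = dict(zip(pm_vars, (int(c) for c in config)))
            g_c = g.with_clamps(clamp)
            if schedule is None:
                schedule = make_schedule(g_c)
            try:
                state = _clamped_run(g_c, schedule)
                total = bethe_free_energy(g_c, state).total_bits
            except InfeasibleError:
                continue
            if best is None or total < best[0] - 1e-12:
                best = (total, state, clamp)
        if best is None:
            # every configuration infeasible
            report = FreeEnergyReport("CBFE", float("inf"), point_assignments={})
            return report, BeliefState()
        total, state, clamp = best
        assignments = {v: PointMass(g.variables[v].size, i) for v, i in clamp.items()}
        # re-express the clamped-graph beliefs in the constrained graph's
        # convention: delta axes reinstated as one-hot
        beliefs: dict[str, np.ndarray] = {}
        for fn in g.factors:
            args = g.free_args(fn)
            if not args:
                continue
            shape = tuple(g.variables[a].size for a in args)
            q = np.zeros(shape)
            idx = tuple(
                clamp[a] if a in clamp else slice(None) for a in args
            )
            inner_args = [a for a in args if a not in clamp]
            if inner_args:
                q[idx] = state.factor_beliefs[fn]
            else:
                q[idx] = 1.0
            beliefs[fn] = q
        full_state = BeliefState(
            dict(state.variable_marginals) | {v: assignments[v] for v in pm_vars},
            beliefs,
            assignments,
        )
        report = FreeEnergyReport("CBFE", total, point_assignments=dict(clamp))
        return report, full_state

    if mode == "em":
        def one_run(init: BeliefState | None):
            state, _i, _c = run_until_converged(
                g, init=init, max_iters=max_iters, tol=tol
            )
            return constrained_bethe_free_energy(g, state), state

        if not multi_start:
            return one_run(None)
        best_pair = None
        for config in np.ndindex(*sizes):
            init = BeliefState(
                point_assignments={
                    v: PointMass(g.variables[v].size, int(i))
                    for v, i in zip(pm_vars, config)
                }
            )
            try:
                rep, state = one_run(init)
            except InfeasibleError:
                continue
            if best_pair is None or rep.total_bits < best_pair[0].total_bits - 1e-12:
                best_pair = (rep, state)
        if best_pair is None:
            return FreeEnergyReport("CBFE", float("inf"), point_assignments={}), BeliefState()
        return best_pair

    raise ValueError(f"unknown CBFE mode {mode!r}")


# ---------------------------------------------------------------------------
# factor classification (decompositions)
# ---------------------------------------------------------------------------

def _observation_vars(g: FactorGraph) -> set[str]:
    obs = {v for v, var in g.variables.items() if var.role == "observation"}
    obs |= set(g.point_mass_variables)
    return obs


def _classify_factors(g: FactorGraph):
    obs = _observation_vars(g)
    likelihood, goal, state = [], [], []
    for fn, f in g.factors.items():
        if f.kind == "goal_prior":
            goal.append(fn)
        elif any(a in obs for a in f.args):
            likelihood.append(fn)
        else:
            state.append(fn)
    return likelihood, goal, state


def _bethe_joint(g: FactorGraph, b: BeliefState) -> tuple[np.ndarray, list[str]]:
    """Joint distribution implied by the Bethe beliefs (exact on trees).

    ``q(s) = prod_a q_a(s_a) * prod_i q_i(s_i)^(1 - d_i)`` -- the junction
    reconstruction.  Zero marginals are handled as zero joint mass.
    """
    order = list(g.free_variables)
    sizes = [g.variables[v].size for v in order]
    axis = {v: i for i, v in enumerate(order)}
    out = np.ones(sizes if sizes else (1,))
    for fn in g.factors:
        args = g.free_args(fn)
        if not args:
            continue
        q = np.asarray(b.factor_beliefs[fn], dtype=float)
        expand = np.moveaxis(
            q.reshape(q.shape + (1,) * (len(order) - len(args))),
            range(len(args)),
            [axis[a] for a in args],
        )
        out = out * expand
    degrees = _free_degrees(g)
    for v in order:
        d = degrees[v]
        if d == 1:
            continue
        q = b.variable_marginals[v].probs
        w = np.ones_like(q)
        nz = q > 0
        w[nz] = q[nz] ** float(1 - d)
        shape = [1] * len(order)
        shape[axis[v]] = q.size
        out = out * w.reshape(shape)
    total = out.sum()
    if total > 0:
        out = out / total
    return out, order


def _kl_tensors_bits(q: np.ndarray, p: np.ndarray) -> float:
    mask = q > 0
    if np.any(p[mask] == 0):
        return float("inf")
    return float(np.sum(q[mask] * np.log(q[mask] / p[mask])) / _LN2)


def decompose_ccx(
    g: FactorGraph, b: BeliefState, policy: tuple | None = None
) -> FreeEnergyReport:
    """Confidence / complexity / extrinsic-value decomposition of the CBFE.

    ``confidence`` is the expected log-probability the observation model
    assigns to the chosen potential outcomes, ``complexity`` the divergence of
    the state belief from the policy-conditioned state prior (its Bethe
    estimate, exact on trees), and ``extrinsic`` the goal-prior log-probability
    of those outcomes.  The total is ``-confidence + complexity - extrinsic``.
    """
    assignments = dict(b.point_assignments)
    g2 = g.with_clamps({k: pm.index for k, pm in assignments.items()})
    b2 = _restricted_beliefs(g, b, assignments)
    likelihood, goal, state_factors = _classify_factors(g)

    confidence = 0.0
    for fn in likelihood:
        t = g2.reduced_table(fn)
        args = g2.free_args(fn)
        if not args:
            val = float(t)
            confidence += float("-inf") if val <= 0 else math.log(val) / _LN2
        else:
            confidence -= _tensor_energy_bits(b2.factor_beliefs[fn], t)

    extrinsic = 0.0
    for fn in goal:
        t = g2.reduced_table(fn)
        if t.ndim == 0:
            val = float(t)
            extrinsic += float("-inf") if val <= 0 else math.log(val) / _LN2
        else:
            extrinsic -= _tensor_energy_bits(b2.factor_beliefs[fn], t)

    # complexity: energy of the state factors minus the full Bethe entropy of
    # the state beliefs (likelihood-side beliefs are duplicates of the state
    # marginals in the clamped graph, so their entropies cancel exactly)
    degrees = _free_degrees(g2)
    complexity = 0.0
    for fn in state_factors:
        t = g2.reduced_table(fn)
        args = g2.free_args(fn)
        if not args:
            val = float(t)
            complexity += float("inf") if val <= 0 else -math.log(val) / _LN2
        else:
            complexity += _tensor_energy_bits(b2.factor_beliefs[fn], t)
    for fn, q in b2.factor_beliefs.items():
        complexity -= _tensor_entropy_bits(q)
    for v, d in degrees.items():
        complexity -= (1 - d) * entropy_bits(b2.variable_marginals[v])

    total = -confidence + complexity - extrinsic
    return FreeEnergyReport(
        "CBFE",
        float(total),
        terms={
            "confidence": float(confidence),
            "complexity": float(complexity),
            "extrinsic": float(extrinsic),
        },
        policy=policy,
        point_assignments={k: pm.index for k, pm in assignments.items()},
    )


def decompose_pie(
    g: FactorGraph, b: BeliefState, policy: tuple | None = None
) -> FreeEnergyReport:
    """Posterior-divergence / intrinsic / extrinsic decomposition of the CBFE.

    ``intrinsic`` is the predicted log-evidence ``log2 p(y_hat | u_hat)``
    computed by exact enumeration of the generative engine; the posterior
    divergence compares the (Bethe-reconstructed) state belief with the exact
    posterior given the potential outcomes.  Total
    ``= posterior_divergence - intrinsic - extrinsic``.
    """
    assignments = dict(b.point_assignments)
    g2 = g.with_clamps({k: pm.index for k, pm in assignments.items()})
    b2 = _restricted_beliefs(g, b, assignments)
    likelihood, goal, state_factors = _classify_factors(g)

    engine = likelihood + state_factors
    t_engine, order = joint_table(g2, engine)
    z = float(t_engine.sum())
    intrinsic = float("-inf") if z <= 0 else math.log(z) / _LN2

    extrinsic = 0.0
    for fn in goal:
        t = g2.reduced_table(fn)
        val = float(t) if t.ndim == 0 else float("nan")
        if t.ndim != 0:
            raise GraphError(
                f"goal factor {fn!r} still has free arguments; point-mass "
                "assignments must cover all observation variables"
            )
        extrinsic += float("-inf") if val <= 0 else math.log(val) / _LN2

    if z > 0:
        q_joint, _ = _bethe_joint(g2, b2)
        posterior_divergence = _kl_tensors_bits(q_joint, t_engine / z)
    else:
        posterior_divergence = float("inf")

    total = posterior_divergence - intrinsic - extrinsic
    return FreeEnergyReport(
        "CBFE",
        float(total),
        terms={
            "posterior_divergence": float(posterior_divergence),
            "intrinsic": float(intrinsic),
            "extrinsic": float(extrinsic),
        },
        policy=policy,
        point_assignments={k: pm.index for k, pm in assignments.items()},
    )


def decompose_bfe(
    g: FactorGraph, b: BeliefState, policy: tuple | None = None
) -> FreeEnergyReport:
    """Expected-posterior-divergence / predictive-divergence / expected-extrinsic
    decomposition of the (unconstrained) BFE, by exact enumeration.

    Total ``= expected_posterior_divergence + predictive_divergence
    - expected_extrinsic``; requires marginal (not point-mass) beliefs over
    the observation variables.
    """
    if g.point_mass_variables:
        raise GraphError("BFE decomposition requires marginal observation beliefs")
    likelihood, goal, state_factors = _classify_factors(g)
    engine = likelihood + state_factors
    p_engine, order = joint_table(g, engine)
    zp = p_engine.sum()
    if zp <= 0:
        raise GraphError("generative engine sums to zero")
    p_engine = p_engine / zp
    q_joint, order_q = _bethe_joint(g, b)
    assert order == order_q

    obs = _observation_vars(g)
    obs_axes = tuple(i for i, v in enumerate(order) if v in obs)
    state_axes = tuple(i for i, v in enumerate(order) if v not in obs)
    goal_table, _ = joint_table(g, goal)

    q_y = q_joint.sum(axis=state_axes)
    p_y = p_engine.sum(axis=state_axes)
    predictive_divergence = _kl_tensors_bits(q_y, p_y)

    # expected extrinsic value: E_q(y) log2 p_tilde(y)
    gl_y = goal_table.max(axis=state_axes) if state_axes else goal_table
    mask = q_y > 0
    if np.any(gl_y[mask] <= 0):
        expected_extrinsic = float("-inf")
    else:
        expected_extrinsic = float(np.sum(q_y[mask] * np.log(gl_y[mask])) / _LN2)

    # expected posterior divergence: E_q(y) KL[q(x|y) || p(x|y,u)]
    q_y_full = np.expand_dims(q_y, axis=state_axes) if state_axes else q_y
    p_y_full = np.expand_dims(p_y, axis=state_axes) if state_axes else p_y
    mask = q_joint > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (q_joint * p_y_full) / (q_y_full * p_engine)
    if np.any(~np.isfinite(ratio[mask])) or np.any(ratio[mask] <= 0):
        epd = float("inf")
    else:
        epd = float(np.sum(q_joint[mask] * np.log(ratio[mask])) / _LN2)

    total = epd + predictive_divergence - expected_extrinsic
    return FreeEnergyReport(
        "BFE",
        float(total),
        terms={
            "expected_posterior_divergence": float(epd),
            "predictive_divergence": float(predictive_divergence),
            "expected_extrinsic": float(expected_extrinsic),
        },
        policy=policy,
    )


# ---------------------------------------------------------------------------
# expected free energy (forward-only, ambiguity + risk)
# ---------------------------------------------------------------------------

def expected_free_energy(
    model, policy: Sequence, goal_priors: Sequence[Categorical] | None = None
) -> FreeEnergyReport:
    """Forward-only EFE: ambiguity plus observation risk, summed over the horizon.

    ``model`` must be a state-space model (a prior, control-indexed transition
    tables and an observation table).  State predictions are rolled forward as
    ``q(x_k) = B_{u_k} q(x_{k-1})``, outcome predictions as
    ``q(y_k) = A q(x_k)``; per step the ambiguity is the expected entropy of
    the observation columns and the risk the divergence of ``q(y_k)`` from the
    goal prior ``c_k``.
    """
    if not hasattr(model, "transitions") or not hasattr(model, "likelihood"):
        raise GraphError("EFE evaluation requires a state-space model")
    A = np.asarray(model.likelihood, dtype=float)
    col_entropy = np.array([entropy_bits(Categorical(A[:, j])) for j in range(A.shape[1])])
    q_x = np.asarray(model.prior, dtype=float)
    goals = list(goal_priors) if goal_priors is not None else [
        model.goal_for_step(model.t0 + k) for k in range(len(policy))
    ]
    ambiguity = 0.0
    risk = 0.0
    for k, u in enumerate(policy):
        B = np.asarray(model.transitions[u], dtype=float)
        q_x = B @ q_x
        q_y = A @ q_x
        ambiguity += float(q_x @ col_entropy)
        risk += kl_bits(Categorical(q_y), goals[k])
    total = ambiguity + risk
    return FreeEnergyReport(
        "EFE",
        float(total),
        terms={"ambiguity": float(ambiguity), "risk": float(risk)},
        policy=tuple(policy),
    )


# ---------------------------------------------------------------------------
# enumeration oracles
# ---------------------------------------------------------------------------

def _resolve_graph(model, policy):
    if isinstance(model, FactorGraph):
        return model
    if hasattr(model, "future"):
        return model.future(policy).graph
    if hasattr(model, "graph"):
        return model.graph
    raise GraphError(f"cannot resolve a factor graph from {type(model).__name__}")


def oracle_cbfe_table(g: FactorGraph) -> tuple[np.ndarray, list[str]]:
    """Exact CBFE energy ``-log2[p(y_hat|u_hat) p_tilde(y_hat)]`` for every
    outcome configuration, by tensor enumeration.

    Returns the energy table indexed by the observation variables (in free
    order) -- infeasible outcomes hold ``+inf``.
    """
    likelihood, goal, state_factors = _classify_factors(g)
    obs = [v for v in g.free_variables if v in _observation_vars(g)]
    t_engine, order = joint_table(g, likelihood + state_factors)
    state_axes = tuple(i for i, v in enumerate(order) if v not in obs)
    p_obs = t_engine.sum(axis=state_axes) if state_axes else t_engine
    goal_table, _ = joint_table(g, goal, order=obs) if goal else (np.ones_like(p_obs), obs)
    obs_in_joint_order = [v for v in order if v in obs]
    # align goal table axes with p_obs axes
    perm = [obs.index(v) for v in obs_in_joint_order]
    goal_aligned = np.transpose(goal_table, perm) if goal_table.ndim else goal_table
    with np.errstate(divide="ignore"):
        energy = -np.log2(p_obs * goal_aligned)
    return energy, obs_in_joint_order


def oracle_cbfe(model, policy: tuple | None = None) -> FreeEnergyReport:
    """Closed-form global optimum of the CBFE on an enumerable future model.

    ``total = min over y_hat of -log2[ p(y_hat|u_hat) * p_tilde(y_hat) ]``
    with the marginal likelihood by exact summation; the argmin outcome
    configuration is reported (lexicographic tie-break).
    """
    g = _resolve_graph(model, policy)
    energy, obs_order = oracle_cbfe_table(g)
    flat = np.argmin(energy)  # first occurrence = lexicographic lowest
    idx = np.unravel_index(flat, energy.shape) if energy.ndim else ()
    total = float(energy[idx]) if energy.ndim else float(energy)
    return FreeEnergyReport(
        "CBFE",
        total,
        policy=tuple(policy) if policy is not None else None,
        point_assignments={v: int(i) for v, i in zip(obs_order, idx)},
    )


def oracle_log_partition(model, policy: tuple | None = None) -> float:
    """``log2 Z`` of the future model by brute-force summation.

    Refuses joint domains above the enumeration cap documented in
    :func:`cbfe.factor_graph.joint_table`.
    """
    g = _resolve_graph(model, policy)
    t, _ = joint_table(g)
    z = float(t.sum())
    return float("-inf") if z <= 0 else math.log(z) / _LN2
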