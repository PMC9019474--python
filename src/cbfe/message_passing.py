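"""Sum-product and variational message passing with point-mass updates.

The optimizer alternates message sweeps with maximum a-posteriori updates of
the point-mass-constrained variables, an expectation-maximization style
scheme: messages play the E-step, the argmax of the product of messages into
a constrained variable plays the M-step.  On acyclic (tree) graphs without
point-mass constraints a single forward-backward sweep reproduces exact
marginals, which is the regime exercised by the planning models in this
package (controls clamped, observations either marginal or point-mass).

Ties in the point-mass update are broken toward the lowest category index so
results are reproducible; genuinely tied outcomes are semantically meaningful
(for instance symmetric cue readings before any evidence) and surface in
reports as tied optima rather than being hidden by randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .discrete import Categorical, PointMass
from .factor_graph import FactorGraph, GraphError

__all__ = [
    "InfeasibleError",
    "Message",
    "ScheduleEntry",
    "BeliefState",
    "sum_product_message",
    "variational_message",
    "update_point_mass",
    "make_schedule",
    "run_until_converged",
]

DEFAULT_MAX_ITERS = 50
DEFAULT_TOL = 1e-8


class InfeasibleError(RuntimeError):
    """Raised when a message or point-mass product is identically zero."""


@dataclass
class Message:
    """A normalized factor-to-variable message."""

    source_factor: str
    target_variable: str
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        total = v.sum()
        if not np.isfinite(total) or total <= 0:
            raise InfeasibleError(
                f"all-zero message from factor {self.source_factor!r} "
                f"to variable {self.target_variable!r}"
            )
        self.values = v / total


@dataclass(frozen=True)
class ScheduleEntry:
    """One directed message computation in a schedule."""

    factor: str
    target_variable: str
    rule: str = "sum_product"  # or "variational"


@dataclass
class BeliefState:
    """Beliefs produced by message passing.

    ``variable_marginals`` holds the per-variable beliefs ``q_i``;
    ``factor_beliefs`` the per-factor joint beliefs ``q_a`` (tensors over the
    factor's unclamped arguments, in :meth:`FactorGraph.free_args` order);
    ``point_assignments`` the optimized values of point-mass-constrained
    variables.
    """

    variable_marginals: dict[str, Categorical] = field(default_factory=dict)
    factor_beliefs: dict[str, np.ndarray] = field(default_factory=dict)
    point_assignments: dict[str, PointMass] = field(default_factory=dict)

    def assignment_indices(self) -> dict[str, int]:
        return {k: pm.index for k, pm in self.point_assignments.items()}


# ---------------------------------------------------------------------------
# message update rules
# ---------------------------------------------------------------------------

def _reduced(g: FactorGraph, factor: str):
    table = g.reduced_table(factor)
    args = g.free_args(factor)
    return table, args


def sum_product_message(
    g: FactorGraph,
    factor: str,
    target: str,
    incoming: Mapping[str, np.ndarray | Categorical],
) -> Message:
    """Sum-product rule: ``m(x) ∝ Σ_{other args} f_a(args) Π incoming``.

    ``incoming`` must cover every unclamped argument of ``factor`` other than
    ``target`` (clamped arguments are already sliced out of the table).
    """
    table, args = _reduced(g, factor)
    if target not in args:
        raise GraphError(f"variable {target!r} is not a free argument of factor {factor!r}")
    # move the target axis first, then contract the remaining axes in order
    ti = args.index(target)
    rest = [a for a in args if a != target]
    t = np.moveaxis(table, ti, 0)
    for a in reversed(rest):
        m = np.asarray(incoming[a], dtype=float)
        t = t @ m if t.ndim == 2 else np.tensordot(t, m, axes=([t.ndim - 1], [0]))
    return Message(factor, target, t)


def variational_message(
    g: FactorGraph,
    factor: str,
    target: str,
    neighbor_beliefs: Mapping[str, np.ndarray | Categorical],
) -> Message:
    """Variational rule: ``m(x) ∝ exp( E_{neighbor beliefs}[ log f_a ] )``.

    Zero table entries contribute ``-inf`` log-potential; configurations with
    neighbor belief zero contribute nothing (``0 · log 0 := 0``).  Entries
    whose expected log-potential is ``-inf`` come out with zero mass.
    """
    table, args = _reduced(g, factor)
    if target not in args:
        raise GraphError(f"variable {target!r} is not a free argument of factor {factor!r}")
    with np.errstate(divide="ignore"):
        logt = np.log(table)
    ti = args.index(target)
    t = np.moveaxis(logt, ti, 0)
    rest = [a for a in args if a != target]
    for a in reversed(rest):
        q = np.asarray(neighbor_beliefs[a], dtype=float)
        with np.errstate(invalid="ignore"):
            # expectation with 0 * (-inf) := 0
            contrib = np.where(q > 0, t * q, 0.0)
        t = contrib.sum(axis=-1)
    finite = np.isfinite(t)
    if not np.any(finite):
        raise InfeasibleError(
            f"all-zero variational message from factor {factor!r} to {target!r}"
        )
    values = np.where(finite, np.exp(t - t[finite].max()), 0.0)
    return Message(factor, target, values)


def update_point_mass(
    g: FactorGraph, variable: str, *messages: Message | np.ndarray
) -> PointMass:
    """MAP update of a point-mass-constrained variable.

    The new value is the argmax of the elementwise product of the incoming
    messages (typically a likelihood-side and a prior-side message); ties are
    broken toward the lowest index.
    """
    if g.constraint(variable) != "point_mass":
        raise GraphError(f"variable {variable!r} does not carry a point-mass constraint")
    size = g.variables[variable].size
    prod = np.ones(size)
    for m in messages:
        prod = prod * (m.values if isinstance(m, Message) else np.asarray(m, dtype=float))
    if prod.sum() <= 0:
        raise InfeasibleError(f"point-mass product for {variable!r} is identically zero")
    return PointMass(size, int(np.argmax(prod)))


# ---------------------------------------------------------------------------
# scheduling
# ---------------------------------------------------------------------------

def make_schedule(
    g: FactorGraph, rules: Mapping[tuple[str, str], str] | None = None
) -> list[ScheduleEntry]:
    """Order every factor-to-variable message so dependencies come first.

    On trees this produces a leaves-inward collect pass followed by the
    outward distribute pass (a full forward sweep plus the complete backward
    smoothing sweep), so one iteration yields exact marginals.  On cyclic
    graphs the residual messages are appended in deterministic order and the
    schedule must be iterated.  ``rules`` optionally overrides the update rule
    per ``(factor, variable)`` direction; the default is sum-product, which is
    exact on the tree-structured planning models used here.
    """
    free = set(g.free_variables)
    dirs: list[tuple[str, str]] = []
    fargs: dict[str, list[str]] = {}
    nbrs: dict[str, list[str]] = {v: [] for v in free}
    for fn in g.factors:
        fa = [a for a in g.factors[fn].args if a in free]
        if not fa:
            continue
        fargs[fn] = fa
        for a in fa:
            dirs.append((fn, a))
            nbrs[a].append(fn)
    if not dirs:
        return []
    # connectivity check over factors-with-free-args and free variables
    bip = g.bipartite(free_only=True)
    import networkx as nx

    active = [n for n in bip.nodes if bip.degree(n) > 0 or n[0] == "v"]
    if active and not nx.is_connected(bip.subgraph(active)):
        raise GraphError("disconnected factor graph; schedule undefined")

    # Kahn-style topological ordering of directed messages:
    # (f -> v) depends on (f' -> v') for every other argument v' of f and
    # every other factor f' attached to v'.
    deps = {
        (fn, v): {
            (fp, vp)
            for vp in fargs[fn]
            if vp != v
            for fp in nbrs[vp]
            if fp != fn
        }
        for fn, v in dirs
    }
    ordered: list[tuple[str, str]] = []
    done: set[tuple[str, str]] = set()
    remaining = list(dirs)
    progress = True
    while remaining and progress:
        progress = False
        still = []
        for d in remaining:
            if deps[d] <= done:
                ordered.append(d)
                done.add(d)
                progress = True
            else:
                still.append(d)
        remaining = still
    ordered.extend(remaining)  # loopy residue: fixed deterministic order
    rules = rules or {}
    return [ScheduleEntry(fn, v, rules.get((fn, v), "sum_product")) for fn, v in ordered]


# ---------------------------------------------------------------------------
# fixed-point iteration
# ---------------------------------------------------------------------------

def _initial_assignments(
    g: FactorGraph, schedule: Sequence[ScheduleEntry], init: BeliefState | None
) -> dict[str, PointMass]:
    """Default initialization of potential outcomes.

    Runs one unconstrained sum-product sweep and takes the argmax of each
    constrained variable's predictive marginal (ties toward the lowest
    index).  Deterministic and reproducible; a caller can override through
    ``init.point_assignments``.
    """
    pm_vars = g.point_mass_variables
    out: dict[str, PointMass] = {}
    if init is not None:
        out.update(init.point_assignments)
    missing = [v for v in pm_vars if v not in out]
    if not missing:
        return out
    msgs = _sweep(g, schedule, assignments={}, msgs={})
    for v in missing:
        prod = np.ones(g.variables[v].size)
        for fn in g.neighbor_factors(v):
            if (fn, v) in msgs:
                prod = prod * msgs[(fn, v)]
        if prod.sum() <= 0:
            raise InfeasibleError(f"no feasible initial value for {v!r}")
        out[v] = PointMass(g.variables[v].size, int(np.argmax(prod)))
    return out


def _var_to_factor(
    g: FactorGraph,
    var: str,
    factor: str,
    msgs: Mapping[tuple[str, str], np.ndarray],
    assignments: Mapping[str, PointMass],
) -> np.ndarray:
    if var in assignments:
        return assignments[var].probs
    prod = np.ones(g.variables[var].size)
    for fn in g.neighbor_factors(var):
        if fn != factor and (fn, var) in msgs:
            prod = prod * msgs[(fn, var)]
    total = prod.sum()
    if total <= 0:
        raise InfeasibleError(f"zero cavity message from {var!r} toward {factor!r}")
    return prod / total


def _sweep(g, schedule, assignments, msgs):
    msgs = dict(msgs)
    for entry in schedule:
        table_args = g.free_args(entry.factor)
        others = [a for a in table_args if a != entry.target_variable]
        if entry.rule == "variational":
            nb = {}
            for a in others:
                if a in assignments:
                    nb[a] = assignments[a].probs
                else:
                    prod = np.ones(g.variables[a].size)
                    for fn in g.neighbor_factors(a):
                        if (fn, a) in msgs:
                            prod = prod * msgs[(fn, a)]
                    nb[a] = prod / prod.sum() if prod.sum() > 0 else prod
            m = variational_message(g, entry.factor, entry.target_variable, nb)
        else:
            incoming = {
                a: _var_to_factor(g, a, entry.factor, msgs, assignments) for a in others
            }
            m = sum_product_message(g, entry.factor, entry.target_variable, incoming)
        msgs[(entry.factor, entry.target_variable)] = m.values
    return msgs


def _beliefs(g, msgs, assignments) -> BeliefState:
    marginals: dict[str, Categorical] = {}
    for v in g.free_variables:
        if v in assignments:
            marginals[v] = assignments[v]
            continue
        prod = np.ones(g.variables[v].size)
        for fn in g.neighbor_factors(v):
            if (fn, v) in msgs:
                prod = prod * msgs[(fn, v)]
        total = prod.sum()
        if total <= 0:
            raise InfeasibleError(f"zero marginal for variable {v!r}")
        marginals[v] = Categorical(prod / total)
    beliefs: dict[str, np.ndarray] = {}
    for fn in g.factors:
        args = g.free_args(fn)
        if not args:
            continue
        b = np.array(g.reduced_table(fn), dtype=float)
        for i, a in enumerate(args):
            m = _var_to_factor(g, a, fn, msgs, assignments)
            shape = [1] * b.ndim
            shape[i] = m.size
            b = b * m.reshape(shape)
        total = b.sum()
        if total <= 0:
            raise InfeasibleError(f"zero belief for factor {fn!r}")
        beliefs[fn] = b / total
    return BeliefState(marginals, beliefs, dict(assignments))


def run_until_converged(
    g: FactorGraph,
    schedule: Sequence[ScheduleEntry] | None = None,
    init: BeliefState | None = None,
    max_iters: int = DEFAULT_MAX_ITERS,
    tol: float = DEFAULT_TOL,
) -> tuple[BeliefState, int, bool]:
    """Iterate message sweeps and point-mass updates to a fixed point.

    Convergence requires all point assignments unchanged across a sweep and
    the largest absolute marginal change at most ``tol``.  Never raises on
    slow convergence: after ``max_iters`` sweeps the best state is returned
    with ``converged=False``.
    """
    if max_iters < 1:
        raise ValueError("max_iters must be at least 1")
    if schedule is None:
        schedule = make_schedule(g)
    assignments = _initial_assignments(g, schedule, init)
    msgs: dict[tuple[str, str], np.ndarray] = {}
    prev_marg: dict[str, np.ndarray] | None = None
    converged = False
    iters = 0
    state = None
    for iters in range(1, max_iters + 1):
        msgs = _sweep(g, schedule, assignments, msgs)
        # EM M-step: MAP update of each constrained variable
        new_assignments = dict(assignments)
        for v in g.point_mass_variables:
            prod = np.ones(g.variables[v].size)
            for fn in g.neighbor_factors(v):
                if (fn, v) in msgs:
                    prod = prod * msgs[(fn, v)]
            if prod.sum() <= 0:
                raise InfeasibleError(f"point-mass product for {v!r} is identically zero")
            new_assignments[v] = PointMass(g.variables[v].size, int(np.argmax(prod)))
        same_assign = all(
            new_assignments[v].index == assignments[v].index for v in new_assignments
        )
        assignments = new_assignments
        state = _beliefs(g, msgs, assignments)
        marg = {v: state.variable_marginals[v].probs for v in state.variable_marginals}
        if prev_marg is not None and same_assign:
            delta = max(
                (np.max(np.abs(marg[v] - prev_marg[v])) for v in marg), default=0.0
            )
            if delta <= tol:
                converged = True
                break
        prev_marg = marg
    assert state is not None
    return state, iters, converged
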