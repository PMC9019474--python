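"""Discrete factor graphs with Bethe counting numbers.

A generative model ``f(s) = prod_a f_a(s_a)`` is represented as a bipartite
structure of named variables and factors.  Edges of the field's Forney-style
notation are not reproduced literally; the bipartite factor-variable view is
equivalent for all the Bethe free-energy bookkeeping done here (the degree of
a variable counts the factor beliefs that contain it).

Clamped variables (given values: executed actions, observed outcomes, the
controls of a candidate policy) are excluded from the variational
distribution; their axes are sliced out of the factor tables.  Constraint
kinds (``marginal`` vs ``point_mass``) record how the remaining free
variables are treated by the optimizer in :mod:`cbfe.message_passing`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
import yaml

__all__ = [
    "GraphError",
    "Variable",
    "Factor",
    "FactorGraph",
    "build_graph",
    "variable_degree",
    "is_tree",
    "joint_table",
]

#: validation tolerance for table normalization
NORM_ATOL = 1e-9

#: refuse joint enumeration above this many configurations
ENUMERATION_CAP = 2**24

VARIABLE_ROLES = ("state", "observation", "control", "generic")
FACTOR_KINDS = ("prior", "conditional", "mux_transition", "goal_prior")
CONSTRAINT_KINDS = ("marginal", "point_mass")


class GraphError(ValueError):
    """Raised for malformed graph specifications or unsupported queries."""


@dataclass(frozen=True)
class Variable:
    """A named discrete variable with a finite domain."""

    name: str
    size: int
    role: str = "generic"

    def __post_init__(self):
        if self.size < 1:
            raise GraphError(f"variable {self.name!r} must have positive domain size")
        if self.role not in VARIABLE_ROLES:
            raise GraphError(f"unknown role {self.role!r} for variable {self.name!r}")


@dataclass(frozen=True)
class Factor:
    """A non-negative table over an ordered list of argument variables.

    ``conditioning`` names the argument(s) the table is conditioned on
    (the "columns"): for those, every slice of the table obtained by fixing
    the conditioning arguments sums to one.  A ``mux_transition`` is a
    transition table with a control argument among the conditioners; once the
    control is clamped it collapses to an ordinary conditional table.
    """

    name: str
    kind: str
    table: np.ndarray
    args: tuple[str, ...]
    conditioning: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "table", np.asarray(self.table, dtype=float))
        object.__setattr__(self, "args", tuple(self.args))
        object.__setattr__(self, "conditioning", tuple(self.conditioning))
        if self.kind not in FACTOR_KINDS:
            raise GraphError(f"unknown factor kind {self.kind!r} for factor {self.name!r}")
        if len(set(self.args)) != len(self.args):
            raise GraphError(f"factor {self.name!r} repeats an argument")
        for c in self.conditioning:
            if c not in self.args:
                raise GraphError(f"factor {self.name!r}: conditioning on non-argument {c!r}")
        if np.any(self.table < 0) or not np.all(np.isfinite(self.table)):
            raise GraphError(f"factor {self.name!r} table must be finite and non-negative")


class FactorGraph:
    """A validated collection of variables, factors, clamps and constraints."""

    def __init__(
        self,
        variables: Mapping[str, Variable],
        factors: Mapping[str, Factor],
        clamps: Mapping[str, int],
        constraints: Mapping[str, str],
    ):
        self.variables = dict(variables)
        self.factors = dict(factors)
        self.clamps = dict(clamps)
        self.constraints = dict(constraints)

    # -- structure queries -------------------------------------------------

    def degree(self, name: str) -> int:
        """Number of factors whose arguments include ``name``."""
        if name not in self.variables:
            raise GraphError(f"unknown variable {name!r}")
        return sum(name in f.args for f in self.factors.values())

    @property
    def free_variables(self) -> list[str]:
        """Variables not clamped, i.e. those in the variational distribution."""
        return [v for v in self.variables if v not in self.clamps]

    def constraint(self, name: str) -> str:
        return self.constraints.get(name, "marginal")

    @property
    def point_mass_variables(self) -> list[str]:
        return [v for v in self.free_variables if self.constraint(v) == "point_mass"]

    def free_args(self, factor: str) -> tuple[str, ...]:
        return tuple(a for a in self.factors[factor].args if a not in self.clamps)

    def reduced_table(self, factor: str) -> np.ndarray:
        """Factor table with clamped axes sliced at their given values.

        The result is indexed by :meth:`free_args` order; with every argument
        clamped it is a 0-d array (a scalar potential).
        """
        f = self.factors[factor]
        index = tuple(
            self.clamps[a] if a in self.clamps else slice(None) for a in f.args
        )
        return f.table[index]

    def neighbor_factors(self, name: str) -> list[str]:
        return [fn for fn, f in self.factors.items() if name in f.args]

    def bipartite(self, free_only: bool = True) -> nx.Graph:
        """The factor-variable bipartite graph (factor nodes prefixed ``f:``)."""
        g = nx.Graph()
        varset = set(self.free_variables) if free_only else set(self.variables)
        for v in varset:
            g.add_node(("v", v))
        for fn in self.factors:
            args = [a for a in self.factors[fn].args if a in varset]
            if not args and free_only:
                continue
            g.add_node(("f", fn))
            for a in args:
                g.add_edge(("f", fn), ("v", a))
        return g

    def is_tree(self) -> bool:
        """True iff the bipartite graph is acyclic after removing clamps."""
        g = self.bipartite(free_only=True)
        if g.number_of_nodes() == 0:
            return True
        return nx.is_forest(g)

    # -- derived graphs ----------------------------------------------------

    def with_clamps(self, extra: Mapping[str, int]) -> "FactorGraph":
        clamps = dict(self.clamps)
        for k, v in extra.items():
            if k not in self.variables:
                raise GraphError(f"cannot clamp unknown variable {k!r}")
            clamps[k] = int(v)
        constraints = {k: v for k, v in self.constraints.items() if k not in clamps}
        return FactorGraph(self.variables, self.factors, clamps, constraints)

    def with_constraints(self, constraints: Mapping[str, str]) -> "FactorGraph":
        merged = dict(self.constraints)
        for k, v in constraints.items():
            if k not in self.variables:
                raise GraphError(f"cannot constrain unknown variable {k!r}")
            if v not in CONSTRAINT_KINDS:
                raise GraphError(f"unknown constraint kind {v!r}")
            merged[k] = v
        return FactorGraph(self.variables, self.factors, self.clamps, merged)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "variables": [
                {"name": v.name, "size": v.size, "role": v.role}
                for v in self.variables.values()
            ],
            "factors": [
                {
                    "name": f.name,
                    "kind": f.kind,
                    "args": list(f.args),
                    "conditioning": list(f.conditioning),
                    "table": f.table.tolist(),
                }
                for f in self.factors.values()
            ],
            "clamps": dict(self.clamps),
            "constraints": dict(self.constraints),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "FactorGraph":
        variables = [Variable(d["name"], int(d["size"]), d.get("role", "generic"))
                     for d in doc.get("variables", [])]
        factors = [
            Factor(
                d["name"],
                d["kind"],
                np.asarray(d["table"], dtype=float),
                tuple(d["args"]),
                tuple(d.get("conditioning", ())),
            )
            for d in doc.get("factors", [])
        ]
        return build_graph(variables, factors, doc.get("clamps"), doc.get("constraints"))

    @classmethod
    def from_yaml(cls, text: str) -> "FactorGraph":
        return cls.from_dict(yaml.safe_load(text))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _validate_factor(f: Factor, variables: Mapping[str, Variable]) -> Factor:
    shape = tuple(variables[a].size for a in f.args)
    if f.table.shape != shape:
        raise GraphError(
            f"factor {f.name!r}: table shape {f.table.shape} does not match "
            f"argument domains {shape}"
        )
    if f.kind in ("prior", "goal_prior"):
        if f.conditioning:
            raise GraphError(f"prior factor {f.name!r} cannot have conditioning arguments")
        total = f.table.sum()
        if abs(total - 1.0) > 1e-6:
            raise GraphError(f"prior factor {f.name!r} sums to {total!r}, expected 1")
        table = f.table / total
    else:  # conditional / mux_transition
        cond_axes = tuple(f.args.index(c) for c in f.conditioning)
        free_axes = tuple(i for i in range(len(f.args)) if i not in cond_axes)
        if not free_axes:
            raise GraphError(f"conditional factor {f.name!r} has no output argument")
        sums = f.table.sum(axis=free_axes)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise GraphError(
                f"conditional factor {f.name!r}: slices sum to "
                f"{np.unique(np.round(sums, 6))}, expected 1 per conditioning value"
            )
        # exact column normalization
        table = f.table / np.expand_dims(sums, axis=free_axes)
    return Factor(f.name, f.kind, table, f.args, f.conditioning)


def build_graph(
    variables: Iterable[Variable],
    factors: Iterable[Factor],
    clamps: Mapping[str, int] | None = None,
    constraints: Mapping[str, str] | None = None,
) -> FactorGraph:
    """Validate and assemble a :class:`FactorGraph`.

    Checks: unique variable names, every factor argument names an existing
    variable, table shapes match argument domains, priors sum to one and
    conditional tables are column-normalized (normalization is exact after a
    1e-6 tolerance check), clamp values lie in the clamped variable's domain.
    """
    vmap: dict[str, Variable] = {}
    for v in variables:
        if v.name in vmap:
            raise GraphError(f"duplicate variable name {v.name!r}")
        vmap[v.name] = v
    fmap: dict[str, Factor] = {}
    for f in factors:
        if f.name in fmap:
            raise GraphError(f"duplicate factor name {f.name!r}")
        for a in f.args:
            if a not in vmap:
                raise GraphError(f"factor {f.name!r} references unknown variable {a!r}")
        fmap[f.name] = _validate_factor(f, vmap)
    cmap: dict[str, int] = {}
    for k, val in (clamps or {}).items():
        if k not in vmap:
            raise GraphError(f"cannot clamp unknown variable {k!r}")
        val = int(val)
        if not 0 <= val < vmap[k].size:
            raise GraphError(f"clamp value {val} outside domain of {k!r}")
        cmap[k] = val
    kmap: dict[str, str] = {}
    for k, kind in (constraints or {}).items():
        if k not in vmap:
            raise GraphError(f"cannot constrain unknown variable {k!r}")
        if kind not in CONSTRAINT_KINDS:
            raise GraphError(f"unknown constraint kind {kind!r} for {k!r}")
        if k not in cmap:
            kmap[k] = kind
    return FactorGraph(vmap, fmap, cmap, kmap)


def variable_degree(g: FactorGraph, name: str) -> int:
    """Bethe counting number input: how many factors touch ``name``."""
    return g.degree(name)


def is_tree(g: FactorGraph) -> bool:
    return g.is_tree()


def joint_table(
    g: FactorGraph,
    factor_names: Sequence[str] | None = None,
    cap: int = ENUMERATION_CAP,
    order: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Dense joint potential over the free variables, by brute-force expansion.

    Returns ``(tensor, order)`` where ``tensor`` is indexed by the free
    variables in ``order`` (all free variables by default; a caller may pass a
    subset covering the free arguments of the selected factors) and equals the
    product of the (clamp-reduced) factor tables.  Scalar factors (all
    arguments clamped) multiply in as constants.  Refuses domains larger than
    ``cap`` configurations.
    """
    order = list(order) if order is not None else list(g.free_variables)
    sizes = [g.variables[v].size for v in order]
    n = int(np.prod(sizes)) if sizes else 1
    if n > cap:
        raise GraphError(f"joint enumeration of {n} configurations exceeds cap {cap}")
    axis = {v: i for i, v in enumerate(order)}
    out = np.ones(sizes if sizes else (1,))
    names = list(factor_names) if factor_names is not None else list(g.factors)
    for fn in names:
        t = g.reduced_table(fn)
        fargs = g.free_args(fn)
        if not fargs:
            out = out * float(t)
            continue
        if any(a not in axis for a in fargs):
            raise GraphError(
                f"factor {fn!r} has free arguments outside the requested order"
            )
        # broadcast the reduced table into the full joint shape
        perm_axes = [axis[a] for a in fargs]
        expand = np.moveaxis(
            t.reshape(t.shape + (1,) * (len(order) - len(fargs))),
            range(len(fargs)),
            perm_axes,
        )
        out = out * expand
    return out, order


def example_tree_graph() -> FactorGraph:
    """The four-factor example model ``f_a(s1) f_b(s1,s2,s3) f_c(s3) f_d(s2,s4)``.

    A small acyclic fixture used in tests and docs; all variables binary.
    """
    rng = np.random.default_rng(7)

    def norm(x):
        return x / x.sum()

    fa = norm(rng.random(2))
    fb = rng.random((2, 2, 2))
    fb = fb / fb.sum(axis=(1, 2), keepdims=True)
    fc = norm(rng.random(2))
    fd = rng.random((2, 2))
    fd = fd / fd.sum(axis=1, keepdims=True)
    variables = [Variable(f"s{i}", 2) for i in range(1, 5)]
    factors = [
        Factor("fa", "prior", fa, ("s1",)),
        Factor("fb", "conditional", fb, ("s1", "s2", "s3"), conditioning=("s1",)),
        Factor("fc", "prior", fc, ("s3",)),
        Factor("fd", "conditional", fd, ("s2", "s4"), conditioning=("s2",)),
    ]
    return build_graph(variables, factors)


def enumerate_configurations(sizes: Sequence[int]):
    """Lexicographic iterator over joint index tuples (first axis major)."""
    return itertools.product(*(range(s) for s in sizes))
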