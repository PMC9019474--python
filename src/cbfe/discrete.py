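"""Exact discrete probability primitives and information measures, in bits.

All information quantities in this package are reported in bits (log base 2).
Internally computations may use natural logs; the conversion happens at the
boundary of each function.  Zero probabilities are never clipped: ``0 log 0``
is defined as 0, and putting belief mass on an impossible configuration
yields ``+inf`` energy, which downstream code interprets as an infeasible
policy or outcome rather than masking it with an epsilon.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "DistributionError",
    "Categorical",
    "PointMass",
    "entropy_bits",
    "kl_bits",
    "average_energy_bits",
    "kron",
    "direct_sum",
    "softmax",
]

#: construction-time tolerance on the sum of a probability vector
SUM_ATOL = 1e-9

_LN2 = np.log(2.0)


class DistributionError(ValueError):
    """Raised when a vector fails to validate as a probability distribution."""


class Categorical:
    """A probability vector over a labeled finite domain.

    Parameters
    ----------
    probs :
        Non-negative entries summing to 1 within ``SUM_ATOL``.  The vector is
        renormalized exactly on construction, so tiny floating-point drift is
        absorbed but genuinely unnormalized input raises ``DistributionError``.
    labels :
        Optional category names, one per entry (used for display only;
        categories are 0-based internally).
    """

    __slots__ = ("probs", "labels")

    def __init__(self, probs: Sequence[float] | np.ndarray, labels: Sequence[str] | None = None):
        p = np.asarray(probs, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise DistributionError(f"expected a non-empty 1-d probability vector, got shape {p.shape}")
        if not np.all(np.isfinite(p)):
            raise DistributionError("probability vector contains non-finite entries")
        if np.any(p < -SUM_ATOL):
            raise DistributionError(f"negative probability entry: min={p.min()}")
        p = np.clip(p, 0.0, None)
        total = p.sum()
        if abs(total - 1.0) > SUM_ATOL:
            raise DistributionError(f"probabilities sum to {total!r}, expected 1 within {SUM_ATOL}")
        self.probs = p / total
        if labels is not None:
            labels = list(labels)
            if len(labels) != p.size:
                raise DistributionError("number of labels does not match domain size")
        self.labels = labels

    @property
    def domain_size(self) -> int:
        return self.probs.size

    def __len__(self) -> int:
        return self.probs.size

    def __getitem__(self, i: int) -> float:
        return float(self.probs[i])

    def __array__(self, dtype=None, copy=None):
        return np.array(self.probs, dtype=dtype)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Categorical({np.array2string(self.probs, precision=4)})"

    def isclose(self, other: "Categorical", atol: float = 1e-9) -> bool:
        return self.domain_size == other.domain_size and np.allclose(
            self.probs, other.probs, atol=atol
        )


class PointMass(Categorical):
    """A one-hot categorical: all mass on a single category.

    Used both for clamped (observed) values and for the optimized potential
    outcomes of point-mass (delta) constraints.
    """

    __slots__ = ("index",)

    def __init__(self, domain_size: int, index: int, labels: Sequence[str] | None = None):
        if not 0 <= index < domain_size:
            raise DistributionError(f"index {index} outside domain of size {domain_size}")
        probs = np.zeros(domain_size)
        probs[index] = 1.0
        super().__init__(probs, labels=labels)
        self.index = int(index)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PointMass({self.domain_size}, index={self.index})"


def _as_probs(p) -> np.ndarray:
    if isinstance(p, Categorical):
        return p.probs
    return Categorical(p).probs


def entropy_bits(p: Categorical | Sequence[float]) -> float:
    """Shannon entropy ``-sum p_i log2 p_i`` with ``0 log 0 := 0``.

    Bounded by ``[0, log2(domain_size)]``; zero exactly for a point mass.
    """
    probs = _as_probs(p)
    nz = probs[probs > 0]
    return float(-np.sum(nz * np.log(nz)) / _LN2)


def kl_bits(q: Categorical | Sequence[float], p: Categorical | Sequence[float]) -> float:
    """Kullback-Leibler divergence ``sum q_i log2(q_i / p_i)`` in bits.

    Returns ``+inf`` when ``q`` puts mass where ``p`` has none.  Domains must
    match.  Non-negative by Gibbs' inequality; zero iff ``q == p``.
    """
    qa, pa = _as_probs(q), _as_probs(p)
    if qa.size != pa.size:
        raise DistributionError(f"domain mismatch: {qa.size} vs {pa.size}")
    mask = qa > 0
    if np.any(pa[mask] == 0):
        return float("inf")
    return float(np.sum(qa[mask] * np.log(qa[mask] / pa[mask])) / _LN2)


def average_energy_bits(q: Categorical | Sequence[float], f: Sequence[float] | np.ndarray) -> float:
    """Average energy ``-sum q_i log2 f_i`` of belief ``q`` under potential ``f``.

    ``f`` is a non-negative vector (it need not normalize; factors of a
    generative model generally do not).  The result is ``+inf`` when ``q``
    places mass where ``f`` vanishes -- an infeasible configuration.
    """
    qa = _as_probs(q)
    fa = np.asarray(f, dtype=float)
    if fa.ndim != 1 or fa.size != qa.size:
        raise DistributionError(f"length mismatch: q has {qa.size} entries, f has shape {fa.shape}")
    if np.any(fa < 0):
        raise DistributionError("potential f has negative entries")
    mask = qa > 0
    if np.any(fa[mask] == 0):
        return float("inf")
    return float(-np.sum(qa[mask] * np.log(fa[mask])) / _LN2)


def kron(a, b):
    """Kronecker product of two matrices or two categoricals.

    For two :class:`Categorical` operands the result is the (independent)
    product distribution, renormalized.  For arrays the standard Kronecker
    product is returned.
    """
    if isinstance(a, Categorical) and isinstance(b, Categorical):
        return Categorical(np.kron(a.probs, b.probs))
    return np.kron(np.asarray(a, dtype=float), np.asarray(b, dtype=float))


def direct_sum(blocks: Sequence[np.ndarray]) -> np.ndarray:
    """Block-diagonal concatenation of rectangular matrices.

    Output rows/columns are the sums of the block rows/columns.
    """
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks]
    if not blocks:
        raise ValueError("direct_sum of an empty list is undefined")
    return scipy.linalg.block_diag(*blocks)


def softmax(s: Sequence[float] | np.ndarray) -> Categorical:
    """Soft-max ``exp(s_i) / sum_j exp(s_j)`` as a :class:`Categorical`.

    Invariant under adding a constant to ``s`` (computed in shifted form for
    numerical stability).
    """
    sa = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(sa)):
        raise DistributionError("softmax requires finite scores")
    e = np.exp(sa - sa.max())
    return Categorical(e / e.sum())
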