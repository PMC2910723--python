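"""Co-occurrence statistic and the hybrid method's pool partition.

The statistic for an assignment (set A, set B) of pool records to the two
tested factors is

    S = sum over i in A, j in B of c_ij

— every pairwise combination of an A-record with a B-record, read off the
co-occurrence matrix.  The sum includes the diagonal term c_ii when a
record is assigned to both factors (possible under the independent and
hybrid schemes), and counts (i, j) and (j, i) separately when both records
carry both labels: a fully dually-assigned overlapped pair therefore scores
4 under the binary policy (two off-diagonal terms plus two self terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .intervals import CooccurrenceMatrix

__all__ = ["Assignment", "PoolPartition", "statistic", "observed_statistic", "partition_pool"]


@dataclass(frozen=True)
class Assignment:
    """Assignment of joint-pool indices to the two tested factors.

    Within each set assignment is without replacement (no repeated index);
    the sets may intersect only under schemes that permit dual assignment.
    """

    setA: frozenset[int]
    setB: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "setA", frozenset(self.setA))
        object.__setattr__(self, "setB", frozenset(self.setB))


@dataclass(frozen=True)
class PoolPartition:
    """Split of the joint pool into heterogeneously overlapped (O) and singleton (S) sets."""

    overlapped: frozenset[int]
    singleton: frozenset[int]


def _membership(indices, n: int) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    idx = np.fromiter(indices, dtype=np.intp) if not isinstance(indices, np.ndarray) else indices
    if idx.size:
        if idx.min() < 0 or idx.max() >= n:
            raise IndexError("assignment index outside joint pool")
        mask[idx] = True
    return mask


def statistic(matrix: CooccurrenceMatrix, assignment: Assignment) -> float:
    """Evaluate the co-occurrence statistic for an arbitrary assignment."""
    a = _membership(np.fromiter(assignment.setA, dtype=np.intp), matrix.n)
    b = _membership(np.fromiter(assignment.setB, dtype=np.intp), matrix.n)
    return score_masks(matrix, a, b)


def score_masks(matrix: CooccurrenceMatrix, a: np.ndarray, b: np.ndarray) -> float:
    """Statistic from boolean membership masks over the pool (vectorised form).

    Each stored unordered pair {i, j} contributes c_ij once per ordered
    (A-member, B-member) combination; the diagonal contributes c_ii for
    dually assigned records.
    """
    ii, jj, ww = matrix.pair_i, matrix.pair_j, matrix.pair_w
    off = ww @ (a[ii] & b[jj]) + ww @ (a[jj] & b[ii])
    dual = a & b
    return float(off + matrix.diag @ dual)


def observed_statistic(matrix: CooccurrenceMatrix, factorA: str, factorB: str) -> float:
    """Statistic at the identity assignment: each record kept on its factor of origin."""
    a = np.zeros(matrix.n, dtype=bool)
    b = np.zeros(matrix.n, dtype=bool)
    a[matrix.factor_indices(factorA)] = True
    b[matrix.factor_indices(factorB)] = True
    return score_masks(matrix, a, b)


def heterogeneous_mask(matrix: CooccurrenceMatrix, factorA: str, factorB: str) -> np.ndarray:
    """Boolean mask of records involved in >= 1 observed A-vs-B overlap."""
    a = matrix.origins == factorA
    b = matrix.origins == factorB
    ii, jj = matrix.pair_i, matrix.pair_j
    het = (a[ii] & b[jj]) | (b[ii] & a[jj])
    mask = np.zeros(matrix.n, dtype=bool)
    mask[ii[het]] = True
    mask[jj[het]] = True
    return mask


def partition_pool(matrix: CooccurrenceMatrix, factorA: str, factorB: str) -> PoolPartition:
    """Partition the pair's joint pool for the hybrid sampling scheme.

    A record belongs to the overlapped set O iff it participates in at
    least one heterogeneous overlap — an off-diagonal weight against a
    record of the *other* tested factor.  Overlaps between two records of
    the same factor do not qualify.  Everything else in the pair's pool is
    a singleton (set S).
    """
    a = np.zeros(matrix.n, dtype=bool)
    b = np.zeros(matrix.n, dtype=bool)
    a[matrix.factor_indices(factorA)] = True
    b[matrix.factor_indices(factorB)] = True
    het = heterogeneous_mask(matrix, factorA, factorB)
    pool = a | b
    overlapped = frozenset(np.flatnonzero(het & pool).tolist())
    singleton = frozenset(np.flatnonzero(pool & ~het).tolist())
    return PoolPartition(overlapped, singleton)
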