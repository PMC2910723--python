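"""Monte-Carlo null distributions for co-occurrence significance.

Four resampling schemes are implemented, differing only in how the joint
pool of locations is re-assigned to the two tested factors at each
iteration:

* ``permutation`` — the pool of the two profiles is split exhaustively:
  n_A records to A, the remainder to B.  No record is unassigned or dually
  assigned, so overlaps can only re-form where they were observed.
* ``independent`` — A and B are two independent without-replacement draws
  from the pool; the same record may be assigned to both factors, and a
  fully dually-assigned overlapped pair scores 4.
* ``hybrid`` — the pool is partitioned into heterogeneously overlapped
  records (O) and singletons (S).  A draws n_A records from O u S; B draws
  n_B from (O minus A's overlapped picks) u S.  Overlapped records go to at
  most one factor; singletons may serve both.  With S empty the scheme
  reduces to the permutation test; with O empty, to two independent draws
  whose intersection follows a hypergeometric law.
* ``fl`` — the pool contains the records of *every* factor in the dataset,
  not just the tested pair; n_A records are drawn for A, then n_B from the
  remainder.  Its p-values therefore depend on which other factors are
  present.

Every scheme scores each resampled assignment through the co-occurrence
matrix and estimates the p-value as the fraction of resamples whose score
is at least the observed one (ties count as exceedance; no +1 correction).
A result with zero exceedances is reported as "< 1/iterations".

All engines draw assignments in vectorised batches: per iteration a row of
uniform keys ranks the pool, and taking the k smallest keys is a uniform
without-replacement draw of size k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from . import core
from .intervals import CooccurrenceMatrix, LocationRecord

__all__ = [
    "TestResult",
    "FLPool",
    "InfeasibleConfigurationError",
    "permutation_test",
    "independent_test",
    "hybrid_test",
    "fl_test",
    "survey_then_full",
    "merge_results",
    "run_partitioned",
    "ci_index",
    "ci_distribution",
    "METHODS",
]


class InfeasibleConfigurationError(RuntimeError):
    """A resampling draw cannot be completed under the scheme's constraints."""


@dataclass
class TestResult:
    """Outcome of one Monte-Carlo significance test.

    ``p_hat = exceed / iterations``; when ``exceed`` is 0 the p-value is
    only bounded above and ``format_p`` renders it as ``< 1/iterations``.
    """

    method: str
    observed: float
    iterations: int
    exceed: int
    p_hat: float
    seed: object
    screened: bool = False
    null_sample: np.ndarray | None = field(default=None, repr=False)

    @property
    def below_resolution(self) -> bool:
        return self.exceed == 0

    @property
    def p_conservative(self) -> float:
        """(exceed + 1) / (iterations + 1), the add-one upper estimate."""
        return (self.exceed + 1) / (self.iterations + 1)

    def format_p(self) -> str:
        if self.below_resolution:
            return f"< {1.0 / self.iterations:.0e}"
        return f"{self.p_hat:g}"


@dataclass
class FLPool:
    """The FL scheme's sampling pool: every record of every factor in the dataset."""

    records: list[LocationRecord]
    pair: tuple[str, str]

    @classmethod
    def from_matrix(cls, matrix: CooccurrenceMatrix, factorA: str, factorB: str) -> "FLPool":
        for name in (factorA, factorB):
            if name not in matrix.factors:
                raise KeyError(f"tested factor {name!r} absent from dataset")
        return cls(list(matrix.records), (factorA, factorB))


class _SubProblem:
    """Matrix entries restricted to a pool of record indices, re-indexed densely."""

    def __init__(self, matrix: CooccurrenceMatrix, pool: np.ndarray) -> None:
        pool = np.asarray(pool, dtype=np.intp)
        self.pool = pool
        self.n = pool.size
        pos = np.full(matrix.n, -1, dtype=np.intp)
        pos[pool] = np.arange(pool.size)
        keep = (pos[matrix.pair_i] >= 0) & (pos[matrix.pair_j] >= 0)
        self.ii = pos[matrix.pair_i[keep]]
        self.jj = pos[matrix.pair_j[keep]]
        self.ww = matrix.pair_w[keep]
        self.diag = matrix.diag[pool]

    def score(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Statistic for each row of the boolean membership matrices a, b."""
        het = (a[:, self.ii] & b[:, self.jj]).astype(np.float64) @ self.ww
        het += (a[:, self.jj] & b[:, self.ii]).astype(np.float64) @ self.ww
        dual = (a & b).astype(np.float64) @ self.diag
        return het + dual


def _smallest_k_mask(keys: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of the k smallest entries per row (uniform w/o-replacement draw)."""
    b, n = keys.shape
    mask = np.zeros((b, n), dtype=bool)
    if k == 0:
        return mask
    if k >= n:
        mask[:] = True
        return mask
    sel = np.argpartition(keys, k - 1, axis=1)[:, :k]
    np.put_along_axis(mask, sel, True, axis=1)
    return mask


def _batch_sizes(iterations: int, npool: int) -> list[int]:
    per = int(max(64, min(iterations, 2_000_000 // max(npool, 1))))
    sizes = [per] * (iterations // per)
    if iterations % per:
        sizes.append(iterations % per)
    return sizes


def _pair_pool(matrix: CooccurrenceMatrix, factorA: str, factorB: str) -> np.ndarray:
    a = matrix.factor_indices(factorA)
    b = matrix.factor_indices(factorB)
    if a.size + b.size == 0:
        raise ValueError("both profiles are empty; no pool to resample")
    return np.concatenate([a, b])


def _run(
    matrix: CooccurrenceMatrix,
    pool: np.ndarray,
    observed: float,
    sampler: Callable[[np.random.Generator, "_SubProblem", int], tuple[np.ndarray, np.ndarray]],
    method: str,
    iterations: int,
    seed,
    keep_null: bool,
) -> TestResult:
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    sub = _SubProblem(matrix, pool)
    rng = np.random.default_rng(seed)
    exceed = 0
    retained: list[np.ndarray] = []
    for b in _batch_sizes(iterations, sub.n):
        a_mask, b_mask = sampler(rng, sub, b)
        scores = sub.score(a_mask, b_mask)
        exceed += int(np.count_nonzero(scores >= observed))
        if keep_null:
            retained.append(scores)
    null = np.concatenate(retained) if keep_null else None
    return TestResult(
        method=method,
        observed=observed,
        iterations=iterations,
        exceed=exceed,
        p_hat=exceed / iterations,
        seed=seed,
        null_sample=null,
    )


def permutation_test(
    matrix: CooccurrenceMatrix,
    factorA: str,
    factorB: str,
    iterations: int = 5000,
    seed=0,
    keep_null: bool = False,
) -> TestResult:
    """Permutation null: the pair's pool split exhaustively into A and B."""
    pool = _pair_pool(matrix, factorA, factorB)
    n_a = matrix.factor_indices(factorA).size
    observed = core.observed_statistic(matrix, factorA, factorB)

    def sampler(rng, sub, b):
        keys = rng.random((b, sub.n))
        a_mask = _smallest_k_mask(keys, n_a)
        return a_mask, ~a_mask

    return _run(matrix, pool, observed, sampler, "permutation", iterations, seed, keep_null)


def independent_test(
    matrix: CooccurrenceMatrix,
    factorA: str,
    factorB: str,
    iterations: int = 5000,
    seed=0,
    keep_null: bool = False,
) -> TestResult:
    """Independent-resampling null: A and B redrawn independently; dual assignment allowed."""
    pool = _pair_pool(matrix, factorA, factorB)
    n_a = matrix.factor_indices(factorA).size
    n_b = matrix.factor_indices(factorB).size
    observed = core.observed_statistic(matrix, factorA, factorB)

    def sampler(rng, sub, b):
        a_mask = _smallest_k_mask(rng.random((b, sub.n)), n_a)
        b_mask = _smallest_k_mask(rng.random((b, sub.n)), n_b)
        return a_mask, b_mask

    return _run(matrix, pool, observed, sampler, "independent", iterations, seed, keep_null)


def hybrid_test(
    matrix: CooccurrenceMatrix,
    factorA: str,
    factorB: str,
    iterations: int = 5000,
    seed=0,
    keep_null: bool = False,
) -> TestResult:
    """Hybrid null: overlapped records single-use, singletons freely dual.

    A is drawn first (n_A from the whole pool); B then draws n_B from the
    pool minus the overlapped records already taken by A.  If some draw
    leaves fewer than n_B eligible records the configuration is infeasible
    and an error is raised rather than silently retrying.
    """
    pool = _pair_pool(matrix, factorA, factorB)
    n_a = matrix.factor_indices(factorA).size
    n_b = matrix.factor_indices(factorB).size
    observed = core.observed_statistic(matrix, factorA, factorB)
    partition = core.partition_pool(matrix, factorA, factorB)
    overlapped = np.fromiter(partition.overlapped, dtype=np.intp, count=len(partition.overlapped))

    o_mask = np.zeros(matrix.n, dtype=bool)
    o_mask[overlapped] = True
    o_pool = o_mask[pool]  # overlapped membership in pool coordinates

    def sampler(rng, sub, b):
        a_mask = _smallest_k_mask(rng.random((b, sub.n)), n_a)
        blocked = a_mask & o_pool
        eligible = sub.n - blocked.sum(axis=1)
        if np.any(eligible < n_b):
            raise InfeasibleConfigurationError(
                f"hybrid draw infeasible: need {n_b} records for B but only "
                f"{int(eligible.min())} remain eligible"
            )
        keys_b = rng.random((b, sub.n))
        keys_b[blocked] = np.inf
        b_mask = _smallest_k_mask(keys_b, n_b)
        return a_mask, b_mask

    return _run(matrix, pool, observed, sampler, "hybrid", iterations, seed, keep_null)


def fl_test(
    matrix: CooccurrenceMatrix,
    factorA: str,
    factorB: str,
    iterations: int = 5000,
    seed=0,
    keep_null: bool = False,
    pool: FLPool | None = None,
) -> TestResult:
    """FL null: A then B drawn without replacement from all factors' records.

    ``matrix`` must cover the whole dataset; by default the pool is every
    record in it.  On a two-factor dataset the procedure coincides with the
    permutation test (all records are assigned, none dually).
    """
    if pool is None:
        pool = FLPool.from_matrix(matrix, factorA, factorB)
    pool_idx = np.array([r.index for r in pool.records], dtype=np.intp)
    n_a = matrix.factor_indices(factorA).size
    n_b = matrix.factor_indices(factorB).size
    if n_a + n_b > pool_idx.size:
        raise ValueError("tested profiles larger than the FL pool")
    if n_a + n_b == 0:
        raise ValueError("both tested profiles are empty")
    observed = core.observed_statistic(matrix, factorA, factorB)

    total = n_a + n_b

    def sampler(rng, sub, b):
        # Ranking the pool by uniform keys gives a uniform random permutation:
        # the n_a smallest keys form A's draw, the next n_b form B's.
        keys = rng.random((b, sub.n))
        kth = sorted({n_a - 1, total - 1} - {-1})
        sel = np.argpartition(keys, kth, axis=1)
        a_mask = np.zeros((b, sub.n), dtype=bool)
        b_mask = np.zeros((b, sub.n), dtype=bool)
        np.put_along_axis(a_mask, sel[:, :n_a], True, axis=1)
        np.put_along_axis(b_mask, sel[:, n_a:total], True, axis=1)
        return a_mask, b_mask

    return _run(matrix, pool_idx, observed, sampler, "fl", iterations, seed, keep_null)


METHODS: dict[str, Callable] = {
    "permutation": permutation_test,
    "independent": independent_test,
    "hybrid": hybrid_test,
    "fl": fl_test,
}


def survey_then_full(
    test: Callable,
    matrix: CooccurrenceMatrix,
    factorA: str,
    factorB: str,
    survey_iters: int = 100,
    cutoff: float = 0.1,
    full_iters: int = 5000,
    seed=0,
    **kwargs,
) -> TestResult:
    """Two-stage runtime optimisation: a cheap survey run screens out pairs
    that clearly do not co-occur before the expensive full run.

    If the survey p-value exceeds ``cutoff`` the survey result is returned
    flagged ``screened=True``; otherwise a fresh full run (independent
    random stream) is performed and returned.
    """
    if survey_iters < 1:
        raise ValueError("survey_iters must be >= 1")
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must lie in (0, 1]")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    survey_seed, full_seed = ss.spawn(2)
    survey = test(matrix, factorA, factorB, iterations=survey_iters, seed=survey_seed, **kwargs)
    if survey.p_hat > cutoff:
        survey.screened = True
        survey.seed = seed
        return survey
    result = test(matrix, factorA, factorB, iterations=full_iters, seed=full_seed, **kwargs)
    result.seed = seed
    return result


def merge_results(results: list[TestResult]) -> TestResult:
    """Combine independent partitions of one test's iteration budget.

    Because iterations are mutually independent, summing exceedance counts
    over partitions yields the same estimator as a single long run — the
    basis of the method's embarrassing parallelism.
    """
    if not results:
        raise ValueError("nothing to merge")
    first = results[0]
    if any(r.method != first.method or r.observed != first.observed for r in results):
        raise ValueError("cannot merge results of different tests")
    iterations = sum(r.iterations for r in results)
    exceed = sum(r.exceed for r in results)
    nulls = [r.null_sample for r in results]
    null = np.concatenate(nulls) if all(s is not None for s in nulls) else None
    return TestResult(
        method=first.method,
        observed=first.observed,
        iterations=iterations,
        exceed=exceed,
        p_hat=exceed / iterations,
        seed=[r.seed for r in results],
        null_sample=null,
    )


def run_partitioned(
    test: Callable,
    matrix: CooccurrenceMatrix,
    factorA: str,
    factorB: str,
    iterations: int,
    partitions: int,
    seed=0,
    **kwargs,
) -> TestResult:
    """Split the iteration budget over ``partitions`` independent streams and merge.

    Stream k derives its seed deterministically from (seed, k), so the
    partitioned run is reproducible regardless of execution order.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(partitions)
    base, extra = divmod(iterations, partitions)
    parts = []
    for k, child in enumerate(children):
        n_k = base + (1 if k < extra else 0)
        if n_k:
            parts.append(test(matrix, factorA, factorB, iterations=n_k, seed=child, **kwargs))
    return merge_results(parts)


def ci_index(n_obs: float, n_resampled: float, mode: str = "ratio") -> float:
    """Co-localization index: observed over resampled co-occurrence count.

    ``ratio`` returns N/R; ``log-ratio`` its natural logarithm.  The index
    depends on a single resampled value R, whose sampling variability this
    quantity inherits.
    """
    if mode not in ("ratio", "log-ratio"):
        raise ValueError(f"unknown CI mode {mode!r}")
    if n_resampled <= 0:
        raise ZeroDivisionError("co-localization index undefined for zero resampled count")
    ratio = n_obs / n_resampled
    return float(np.log(ratio)) if mode == "log-ratio" else float(ratio)


def ci_distribution(
    matrix: CooccurrenceMatrix,
    factorA: str,
    factorB: str,
    iterations: int = 5000,
    seed=0,
    mode: str = "ratio",
) -> np.ndarray:
    """Distribution of the co-localization index over permutation resamples.

    Runs the permutation test retaining the null sample and returns one CI
    value per iteration (observed / resampled score).  Iterations with a
    zero resampled score yield ``inf`` (ratio) or are undefined
    (log-ratio → ``inf``).
    """
    if mode not in ("ratio", "log-ratio"):
        raise ValueError(f"unknown CI mode {mode!r}")
    res = permutation_test(matrix, factorA, factorB, iterations=iterations, seed=seed, keep_null=True)
    null = res.null_sample
    with np.errstate(divide="ignore"):
        ratio = np.where(null > 0, res.observed / np.where(null > 0, null, 1.0), np.inf)
        return np.log(ratio) if mode == "log-ratio" else ratio
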