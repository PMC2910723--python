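"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's vectorised code paths:
matrices are checked against a naive all-pairs overlap scan, statistics
against a double loop over weight lookups, and null distributions against
exhaustive enumeration of every possible assignment on tiny pools.
"""

from __future__ import annotations

import itertools
from collections import Counter
from math import comb

import numpy as np
import pytest

from cooccur import (
    BindingProfile,
    GenomicInterval,
    SimpleModelSpec,
    build_matrix,
    make_simple_model,
)


# ---------------------------------------------------------------- oracles


def brute_force_weights(matrix):
    """All-pairs O(n^2) overlap scan over the matrix's records.

    Returns {(i, j): weight} with i < j, computed directly from coordinates
    without any contig grouping or sweep.
    """
    out = {}
    recs = matrix.records
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, b = recs[i].interval, recs[j].interval
            if a.contig != b.contig:
                continue
            shared = min(a.end, b.end) - max(a.start, b.start)
            if shared <= 0:
                continue
            out[(i, j)] = 1.0 if matrix.policy == "binary" else float(shared)
    return out


def brute_statistic(matrix, setA, setB):
    """Double-loop statistic: sum of weight(i, j) over i in A, j in B."""
    return sum(matrix.weight(i, j) for i in setA for j in setB)


def enumerate_permutation_null(matrix, pool, n_a):
    """Exact permutation null pmf: every split of the pool into A (size n_a) and B."""
    pool = list(pool)
    counts = Counter()
    for setA in itertools.combinations(pool, n_a):
        setB = [i for i in pool if i not in setA]
        counts[brute_statistic(matrix, setA, setB)] += 1
    total = comb(len(pool), n_a)
    return {s: c / total for s, c in counts.items()}


def enumerate_independent_null(matrix, pool, n_a, n_b):
    """Exact independent-resampling null pmf: every (A-draw, B-draw) combination."""
    pool = list(pool)
    counts = Counter()
    for setA in itertools.combinations(pool, n_a):
        for setB in itertools.combinations(pool, n_b):
            counts[brute_statistic(matrix, setA, setB)] += 1
    total = comb(len(pool), n_a) * comb(len(pool), n_b)
    return {s: c / total for s, c in counts.items()}


def enumerate_hybrid_null(matrix, pool, overlapped, n_a, n_b):
    """Exact hybrid null pmf: A from the pool, B from pool minus A's overlapped picks."""
    pool = list(pool)
    overlapped = set(overlapped)
    # every A-draw is equally likely; each B-draw uniform within its A-draw
    pmf = Counter()
    for setA in itertools.combinations(pool, n_a):
        blocked = overlapped & set(setA)
        eligible = [i for i in pool if i not in blocked]
        nb_ways = comb(len(eligible), n_b)
        for setB in itertools.combinations(eligible, n_b):
            pmf[brute_statistic(matrix, setA, setB)] += 1.0 / nb_ways
    total = comb(len(pool), n_a)
    return {s: p / total for s, p in pmf.items()}


def exceedance(pmf: dict, threshold: float) -> float:
    return sum(p for s, p in pmf.items() if s >= threshold)


def empirical_pmf(samples: np.ndarray) -> dict:
    vals, counts = np.unique(samples, return_counts=True)
    return dict(zip(vals.tolist(), (counts / samples.size).tolist()))


def assert_pmfs_close(empirical: dict, exact: dict, n: int, z: float = 4.0):
    """Each category frequency within z binomial SEs of its exact probability."""
    support = set(empirical) | set(exact)
    for s in support:
        p = exact.get(s, 0.0)
        f = empirical.get(s, 0.0)
        se = np.sqrt(max(p * (1 - p), 1e-12) / n)
        assert abs(f - p) <= z * se + 1e-12, (
            f"score {s}: frequency {f:.5f} vs exact {p:.5f} (z={z}, se={se:.5f})"
        )


def mc_se(p: float, n: int) -> float:
    return float(np.sqrt(p * (1 - p) / n))


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def pair_matrix():
    """Two overlapped pairs plus one singleton per factor, binary policy."""
    prof_a, prof_b = make_simple_model(SimpleModelSpec(m=2, singletons_A=1, singletons_B=1))
    return build_matrix([prof_a, prof_b])


@pytest.fixture
def pairs_only_matrix():
    """m = 2 fully paired model (4 records, no singletons)."""
    prof_a, prof_b = make_simple_model(SimpleModelSpec(m=2))
    return build_matrix([prof_a, prof_b])


def random_profiles(rng: np.random.Generator, n_factors=2, n_intervals=10, contigs=("chr1", "chr2")):
    """Random small binding profiles with frequent overlaps for oracle tests."""
    profiles = []
    for k in range(n_factors):
        ivs = []
        for _ in range(n_intervals):
            contig = contigs[rng.integers(len(contigs))]
            start = int(rng.integers(0, 500))
            length = int(rng.integers(1, 120))
            ivs.append(GenomicInterval(contig, start, start + length))
        profiles.append(BindingProfile(f"F{k}", ivs))
    return profiles
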