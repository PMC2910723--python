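"""Closed-form results for the paired co-occurrence model.

The *simple model* consists of m overlapped pairs (one location of factor A
overlapping one location of factor B) plus per-factor singleton locations,
for profile totals n_A and n_B.  Under the permutation null the observed
statistic m is maximal — no permutation can create an overlap at a
singleton — so the permutation p-value is exactly the probability of
re-creating all m pairs:

    p = P_m * P_pair

where P_m is the hypergeometric probability that exactly m of the 2m
overlapped locations receive an A label when n_A of the n_A + n_B pool
locations are assigned to A,

    P_m = C(2m, m) * C(n_A + n_B - 2m, n_A - m) / C(n_A + n_B, n_A),

and P_pair = 2^m (m!)^2 / (2m)! is the probability that m A labels and m B
labels on the 2m overlapped locations form a perfect heterogeneous pairing.
P_pair is independent of the totals, which is why the permutation test is
dominated by the absolute number of overlaps rather than the overlapped
fraction.

Also provided is the limiting null pmf of the hybrid statistic when every
location is a singleton (two independent without-replacement draws; the
statistic is the size of the intersection), again hypergeometric.

All combinatorics are evaluated in log space (log-gamma), so profile sizes
in the tens of thousands do not overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "SimpleModelParams",
    "p_m",
    "p_pair",
    "perm_pvalue_simple",
    "hybrid_limit_pmf",
    "hybrid_limit_mean",
]


@dataclass(frozen=True)
class SimpleModelParams:
    """m overlapped pairs out of n_A and n_B total sites per factor."""

    m: int
    n_A: int
    n_B: int

    def __post_init__(self) -> None:
        if min(self.m, self.n_A, self.n_B) < 0:
            raise ValueError("counts must be non-negative")
        if self.m > min(self.n_A, self.n_B):
            raise ValueError(
                f"m={self.m} exceeds a profile size (n_A={self.n_A}, n_B={self.n_B})"
            )

    @property
    def singletons_A(self) -> int:
        return self.n_A - self.m

    @property
    def singletons_B(self) -> int:
        return self.n_B - self.m


def _log_comb(n, k):
    n = np.asarray(n, dtype=np.float64)
    k = np.asarray(k, dtype=np.float64)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where((k < 0) | (k > n), -np.inf, out)


def p_m(params: SimpleModelParams) -> float:
    """Hypergeometric probability of assigning exactly m pool locations per
    factor to the 2m overlapped positions under permutation."""
    m, na, nb = params.m, params.n_A, params.n_B
    if m == 0:
        return 1.0
    log_p = (
        _log_comb(2 * m, m)
        + _log_comb(na + nb - 2 * m, na - m)
        - _log_comb(na + nb, na)
    )
    return float(np.exp(log_p))


def p_pair(m: int) -> float:
    """Probability that m A labels and m B labels on 2m overlapped locations
    pair up perfectly: 2^m (m!)^2 / (2m)!.  Independent of profile totals."""
    if m < 0:
        raise ValueError("m must be non-negative")
    if m == 0:
        return 1.0
    log_p = m * np.log(2.0) + 2.0 * gammaln(m + 1) - gammaln(2 * m + 1)
    return float(np.exp(log_p))


def perm_pvalue_simple(params: SimpleModelParams) -> float:
    """Exact permutation-test p-value for the simple model (P_m * P_pair).

    Valid because the observed statistic m is the maximum attainable, so
    the exceedance event is exactly "all m pairs re-formed".
    """
    return p_m(params) * p_pair(params.m)


def hybrid_limit_pmf(n_A: int, n_B: int, k) -> float | np.ndarray:
    """Null pmf of the hybrid statistic when the overlapped pool is empty.

    With h = n_A + n_B singleton locations and two independent
    without-replacement draws, the statistic counts dually-assigned
    locations: P(k) = C(n_A, k) C(h - n_A, n_B - k) / C(h, n_B) for
    0 <= k <= min(n_A, n_B); 0 outside that range.
    """
    if n_A < 0 or n_B < 0:
        raise ValueError("profile sizes must be non-negative")
    h = n_A + n_B
    k = np.asarray(k)
    log_p = _log_comb(n_A, k) + _log_comb(h - n_A, n_B - k) - _log_comb(h, n_B)
    out = np.exp(log_p)
    return float(out) if out.ndim == 0 else out


def hybrid_limit_mean(n_A: int, n_B: int) -> float:
    """Mean of the all-singleton hybrid null: n_A n_B / (n_A + n_B).

    Significance under the hybrid test requires the observed overlap count
    to exceed this baseline substantially.
    """
    if n_A + n_B == 0:
        return 0.0
    return n_A * n_B / (n_A + n_B)
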