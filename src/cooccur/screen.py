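"""Synthetic binding-profile generators, all-pairs screening and reporting.

The generators emit the two families of synthetic datasets on which the
resampling schemes have analytically known or well-characterised
behaviour:

* the *simple model* — m overlapped A/B pairs plus per-factor singleton
  sites, the analytically tractable configuration behind the closed forms
  in :mod:`cooccur.analytic`;
* *FL scenarios* — a tested pair of factors co-occurring at ``base_pairs``
  sites, optionally joined by replicate factor pairs binding the identical
  coordinates and by one factor with entirely disjoint sites, the
  configurations that expose the FL null's sensitivity to dataset
  composition.

Under the binary scoring policy only the overlap topology matters, so the
generators' geometry (interval length, overlap extent, inter-cluster
spacing) is fixed and arbitrary; a rescaled geometry yields identical
statistics.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import core, resampling
from .intervals import BindingProfile, CooccurrenceMatrix, GenomicInterval, build_matrix

__all__ = [
    "SimpleModelSpec",
    "FLScenarioSpec",
    "PairSummary",
    "make_simple_model",
    "make_fl_scenario",
    "screen_all_pairs",
    "write_report",
    "format_fraction",
    "significance_flag",
]


@dataclass(frozen=True)
class SimpleModelSpec:
    """Layout of a simple paired model: m overlapped pairs + singletons.

    Geometry defaults: 100-base sites overlapping by 50 bases, clusters
    spaced 1000 bases apart.  Irrelevant under binary scoring.
    """

    m: int
    singletons_A: int = 0
    singletons_B: int = 0
    interval_length: int = 100
    spacing: int = 1000
    overlap_shift: int = 50
    contig: str = "chr1"
    factorA: str = "A"
    factorB: str = "B"

    def __post_init__(self) -> None:
        if min(self.m, self.singletons_A, self.singletons_B) < 0:
            raise ValueError("counts must be non-negative")
        if not (0 < self.overlap_shift < self.interval_length):
            raise ValueError("paired intervals must overlap partially")
        if self.spacing < 2 * self.interval_length:
            raise ValueError("spacing too small: clusters would collide")


@dataclass(frozen=True)
class FLScenarioSpec:
    """An FL-method scenario: tested pair + replicate pairs + a disjoint factor."""

    base_pairs: int = 40
    replicates: int = 0
    disjoint_sites: int = 0

    def __post_init__(self) -> None:
        if min(self.base_pairs, self.replicates, self.disjoint_sites) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PairSummary:
    """One screened factor pair: per-factor overlap tallies and per-method p-values."""

    factor1: str
    factor2: str
    overlapped1: int
    total1: int
    overlapped2: int
    total2: int
    results: dict[str, resampling.TestResult] = field(default_factory=dict)

    @property
    def p_values(self) -> dict[str, float]:
        return {m: r.p_hat for m, r in self.results.items()}

    def significant(self, alpha: float) -> bool:
        return any(r.p_hat < alpha for r in self.results.values())


def make_simple_model(
    spec: SimpleModelSpec, seed: int = 0
) -> tuple[BindingProfile, BindingProfile]:
    """Generate the two binding profiles of a simple paired model.

    The layout is deterministic: m overlapped clusters followed by A's
    singletons then B's singletons, every cluster ``spacing`` bases apart
    so no two clusters interact.  ``seed`` is accepted for interface
    uniformity with the stochastic drivers; the layout does not depend on
    it.  The generated pair has observed statistic m under binary scoring
    and a hybrid partition of 2m overlapped and
    ``singletons_A + singletons_B`` singleton records.
    """
    length, shift, spacing = spec.interval_length, spec.overlap_shift, spec.spacing
    a_ivs: list[GenomicInterval] = []
    b_ivs: list[GenomicInterval] = []
    cursor = 0
    for _ in range(spec.m):
        a_ivs.append(GenomicInterval(spec.contig, cursor, cursor + length))
        start_b = cursor + length - shift
        b_ivs.append(GenomicInterval(spec.contig, start_b, start_b + length))
        cursor += spacing
    for _ in range(spec.singletons_A):
        a_ivs.append(GenomicInterval(spec.contig, cursor, cursor + length))
        cursor += spacing
    for _ in range(spec.singletons_B):
        b_ivs.append(GenomicInterval(spec.contig, cursor, cursor + length))
        cursor += spacing
    return BindingProfile(spec.factorA, a_ivs), BindingProfile(spec.factorB, b_ivs)


def make_fl_scenario(spec: FLScenarioSpec, seed: int = 0) -> list[BindingProfile]:
    """Generate the profiles of an FL scenario.

    Returns the tested pair (factors ``A``, ``B``) co-occurring at
    ``base_pairs`` sites, plus ``replicates`` additional factor pairs
    (``A_rep1``/``B_rep1``, ...) binding coordinates identical to the
    tested pair's, plus — when ``disjoint_sites > 0`` — one factor
    ``disjoint`` whose sites overlap nothing else in the dataset.
    """
    base = SimpleModelSpec(m=spec.base_pairs)
    prof_a, prof_b = make_simple_model(base, seed)
    profiles = [prof_a, prof_b]
    for r in range(1, spec.replicates + 1):
        profiles.append(BindingProfile(f"A_rep{r}", list(prof_a.intervals)))
        profiles.append(BindingProfile(f"B_rep{r}", list(prof_b.intervals)))
    if spec.disjoint_sites > 0:
        length, spacing = base.interval_length, base.spacing
        cursor = (spec.base_pairs + 1) * spacing
        ivs = []
        for _ in range(spec.disjoint_sites):
            ivs.append(GenomicInterval("chr1", cursor, cursor + length))
            cursor += spacing
        profiles.append(BindingProfile("disjoint", ivs))
    return profiles


def _pair_seed(seed: int, factor1: str, factor2: str, method: str) -> int:
    """Stable per-(pair, method) seed, independent of dataset composition.

    Derived by hashing the factor names so that adding or removing an
    unrelated factor never changes the random stream of a surviving pair —
    pair-pool p-values are then bitwise reproducible across such edits.
    """
    tag = f"{min(factor1, factor2)}|{max(factor1, factor2)}|{method}"
    return (int(seed) ^ zlib.crc32(tag.encode())) & 0x7FFFFFFF


def _overlap_counts(
    matrix: CooccurrenceMatrix, factor1: str, factor2: str
) -> tuple[int, int, int, int]:
    het = core.heterogeneous_mask(matrix, factor1, factor2)
    m1 = matrix.origins == factor1
    m2 = matrix.origins == factor2
    return (
        int(np.count_nonzero(het & m1)),
        int(np.count_nonzero(m1)),
        int(np.count_nonzero(het & m2)),
        int(np.count_nonzero(m2)),
    )


def screen_all_pairs(
    profiles: list[BindingProfile],
    methods: list[str] | None = None,
    iterations: int = 5000,
    alpha: float = 0.05,
    seed: int = 0,
    survey_iters: int = 100,
    cutoff: float = 0.1,
    policy: str = "binary",
) -> list[PairSummary]:
    """Screen every unordered factor pair for significant co-occurrence.

    The whole-dataset co-occurrence matrix is built once; each pair is then
    tested with every requested method through the two-stage
    survey-then-full optimisation.  A site is counted as *overlapped* for a
    factor when it has at least one heterogeneous overlap with the partner
    factor, which is the tally rendered by :func:`write_report`.
    """
    if methods is None:
        methods = ["hybrid"]
    unknown = [m for m in methods if m not in resampling.METHODS]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}; choose from {sorted(resampling.METHODS)}")
    names = [p.factor for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names: {names}")
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to screen")

    matrix = build_matrix(profiles, policy=policy)
    summaries: list[PairSummary] = []
    for i, f1 in enumerate(sorted(names)):
        for f2 in sorted(names)[i + 1 :]:
            o1, t1, o2, t2 = _overlap_counts(matrix, f1, f2)
            summary = PairSummary(f1, f2, o1, t1, o2, t2)
            for method in methods:
                result = resampling.survey_then_full(
                    resampling.METHODS[method],
                    matrix,
                    f1,
                    f2,
                    survey_iters=survey_iters,
                    cutoff=cutoff,
                    full_iters=iterations,
                    seed=_pair_seed(seed, f1, f2, method),
                )
                summary.results[method] = result
            summaries.append(summary)
    return summaries


def format_fraction(overlapped: int, total: int) -> str:
    """Render an overlap tally as ``overlapped/total (pct%)`` with 3 significant figures."""
    pct = 100.0 * overlapped / total if total else 0.0
    return f"{overlapped}/{total} ({pct:.3g}%)"


def significance_flag(p: float) -> str:
    """Tiered significance marker: *** < 0.001, ** < 0.05, * < 0.1."""
    if p < 0.001:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def write_report(
    summaries: list[PairSummary],
    path,
    bh_correction: bool = False,
) -> None:
    """Write a tab-separated screening report.

    One row per factor pair: the two per-factor overlap tallies, one
    p-value column per method (zero-exceedance results rendered as
    ``< 1/iterations``), and a tiered significance flag on the smallest
    p-value.  ``bh_correction`` appends Benjamini–Hochberg adjusted
    p-values per method (raw p-values are the default, and remain
    reported either way).
    """
    methods: list[str] = []
    for s in summaries:
        for m in s.results:
            if m not in methods:
                methods.append(m)
    header = ["factor1", "factor2", "overlapped1/total1", "overlapped2/total2"]
    header += [f"p_{m}" for m in methods]
    if bh_correction:
        header += [f"q_{m}" for m in methods]
    header.append("flag")

    bh: dict[str, dict[tuple[str, str], float]] = {}
    if bh_correction:
        for m in methods:
            pairs = [(s.factor1, s.factor2) for s in summaries if m in s.results]
            ps = np.array([s.results[m].p_hat for s in summaries if m in s.results])
            bh[m] = dict(zip(pairs, _bh_adjust(ps)))

    lines = ["\t".join(header)]
    for s in summaries:
        row = [
            s.factor1,
            s.factor2,
            format_fraction(s.overlapped1, s.total1),
            format_fraction(s.overlapped2, s.total2),
        ]
        for m in methods:
            row.append(s.results[m].format_p() if m in s.results else "NA")
        if bh_correction:
            for m in methods:
                q = bh.get(m, {}).get((s.factor1, s.factor2))
                row.append(f"{q:g}" if q is not None else "NA")
        p_min = min((r.p_hat for r in s.results.values()), default=1.0)
        row.append(significance_flag(p_min))
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    n = p.size
    if n == 0:
        return p
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out
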