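"""Genomic intervals, BED input and co-occurrence matrix construction.

A *binding profile* is the list of genomic locations bound by one
DNA-associated factor (DAF) — a transcription factor, chromatin protein or
histone mark mapped by ChIP-chip, ChIP-seq or DamID.  Given the profiles of
two factors A and B, every location of either factor becomes a record in a
joint pool, and the co-occurrence matrix C holds a score ``c_ij`` for every
pair of records whose intervals overlap.  The matrix completely determines
the co-occurrence statistic for any assignment of pool records to the two
factors, so the resampling engines never need to look at base coordinates.

Coordinates follow the BED convention: 0-based, half-open.  Strand is
ignored.  Two scoring policies are supported: ``binary`` (1 per overlapping
pair of locations) and ``bases`` (number of shared bases).
"""

from __future__ import annotations

import heapq
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomicInterval",
    "BindingProfile",
    "LocationRecord",
    "CooccurrenceMatrix",
    "read_bed",
    "read_bed_tracks",
    "overlaps",
    "build_matrix",
    "BedParseError",
]

POLICIES = ("binary", "bases")


class BedParseError(ValueError):
    """Raised for a malformed BED line; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (isinstance(self.start, (int, np.integer)) and isinstance(self.end, (int, np.integer))):
            raise TypeError(f"coordinates must be integers, got {self.start!r}, {self.end!r}")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class BindingProfile:
    """Named factor together with its bound locations.

    Duplicate coordinates are permitted: each entry is an independent
    location (replicate experiments, or a region bound in two conditions,
    contribute separate records to the joint pool).
    """

    factor: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class LocationRecord:
    """One entry of the joint location pool: (dense index, origin factor, interval)."""

    index: int
    origin: str
    interval: GenomicInterval


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two intervals are on the same contig and share >= 1 base.

    Half-open semantics: abutting intervals ([0,100) vs [100,150)) do not
    overlap.
    """
    return a.contig == b.contig and a.start < b.end and b.start < a.end


def shared_bases(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases common to both intervals (0 if disjoint or on different contigs)."""
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _parse_bed_lines(lines: Iterable[str]) -> Iterator[tuple[int, str, int, int, list[str]]]:
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#") or line.startswith(("track", "browser")):
            continue
        cols = line.split()
        if len(cols) < 3:
            raise BedParseError(f"line {lineno}: expected >=3 columns, got {len(cols)}")
        contig = cols[0]
        try:
            start, end = int(cols[1]), int(cols[2])
        except ValueError:
            raise BedParseError(
                f"line {lineno}: non-integer coordinates {cols[1]!r}, {cols[2]!r}"
            ) from None
        if start < 0 or start >= end:
            raise BedParseError(f"line {lineno}: invalid interval [{start}, {end})")
        yield lineno, contig, start, end, cols


def read_bed(path: str | Path, factor: str | None = None) -> BindingProfile:
    """Read a BED3+ file as the binding profile of a single factor.

    Track/browser lines and ``#`` comments are skipped; columns beyond the
    third are ignored.  The factor name defaults to the filename stem.
    """
    path = Path(path)
    name = factor if factor is not None else path.stem
    with open(path) as fh:
        intervals = [
            GenomicInterval(contig, start, end)
            for _, contig, start, end, _ in _parse_bed_lines(fh)
        ]
    return BindingProfile(name, intervals)


def read_bed_tracks(path: str | Path) -> list[BindingProfile]:
    """Read a multi-factor BED file with the factor name in column 4.

    Returns one profile per distinct name, in order of first appearance.
    """
    path = Path(path)
    by_factor: dict[str, list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, contig, start, end, cols in _parse_bed_lines(fh):
            if len(cols) < 4:
                raise BedParseError(f"line {lineno}: factor name (column 4) missing")
            by_factor.setdefault(cols[3], []).append(GenomicInterval(contig, start, end))
    return [BindingProfile(name, ivs) for name, ivs in by_factor.items()]


class CooccurrenceMatrix:
    """Symmetric sparse co-occurrence matrix over a joint location pool.

    Stores, for a pool of ``n`` location records:

    * ``pair_i, pair_j, pair_w`` — parallel arrays of the off-diagonal
      entries, one row per unordered overlapping pair (``pair_i < pair_j``,
      all weights > 0);
    * ``diag`` — the self-overlap score of each record (1 under the binary
      policy, interval length under the bases policy);
    * ``origins`` — the factor each record came from.

    Only same-contig overlapping pairs are stored; ``weight(i, j)`` returns
    0 for everything else.
    """

    def __init__(
        self,
        records: list[LocationRecord],
        pair_i: np.ndarray,
        pair_j: np.ndarray,
        pair_w: np.ndarray,
        diag: np.ndarray,
        policy: str,
        factor_names: list[str] | None = None,
    ) -> None:
        self.records = records
        self.n = len(records)
        self.pair_i = np.asarray(pair_i, dtype=np.intp)
        self.pair_j = np.asarray(pair_j, dtype=np.intp)
        self.pair_w = np.asarray(pair_w, dtype=np.float64)
        self.diag = np.asarray(diag, dtype=np.float64)
        self.policy = policy
        self.origins = np.array([r.origin for r in records], dtype=object)
        if factor_names is None:
            seen: dict[str, None] = {}
            for r in records:
                seen.setdefault(r.origin, None)
            factor_names = list(seen)
        self._factor_names = list(factor_names)
        self._lookup: dict[tuple[int, int], float] | None = None

    @property
    def sizes(self) -> dict[str, int]:
        """Record count per factor (zero-record factors included)."""
        counts = {name: 0 for name in self._factor_names}
        for r in self.records:
            counts[r.origin] = counts.get(r.origin, 0) + 1
        return counts

    @property
    def factors(self) -> list[str]:
        return list(self._factor_names)

    def factor_indices(self, factor: str) -> np.ndarray:
        """Pool indices of the records originating from ``factor``."""
        if factor not in self._factor_names:
            raise KeyError(f"unknown factor: {factor!r}")
        return np.flatnonzero(self.origins == factor)

    def weight(self, i: int, j: int) -> float:
        """Score c_ij (symmetric; 0 when absent)."""
        if i == j:
            return float(self.diag[i])
        if self._lookup is None:
            self._lookup = {
                (int(a), int(b)): float(w)
                for a, b, w in zip(self.pair_i, self.pair_j, self.pair_w)
            }
        a, b = (i, j) if i < j else (j, i)
        return self._lookup.get((a, b), 0.0)

    def items(self) -> Iterator[tuple[int, int, float]]:
        """Iterate stored off-diagonal entries as (i, j, weight) with i < j."""
        for a, b, w in zip(self.pair_i, self.pair_j, self.pair_w):
            yield int(a), int(b), float(w)


def _contig_overlap_pairs(
    entries: list[tuple[int, GenomicInterval]], policy: str
) -> Iterator[tuple[int, int, float]]:
    """Sweep one contig's records by start coordinate, yielding overlapping pairs.

    A min-heap of active (end, index) prunes records that can no longer
    overlap, so clustered data stays near O(n log n + k) for k overlaps.
    """
    entries = sorted(entries, key=lambda e: (e[1].start, e[1].end, e[0]))
    active: list[tuple[int, int, GenomicInterval]] = []  # (end, index, interval)
    for idx, iv in entries:
        while active and active[0][0] <= iv.start:
            heapq.heappop(active)
        for _, other_idx, other_iv in active:
            w = 1.0 if policy == "binary" else float(shared_bases(iv, other_iv))
            a, b = (other_idx, idx) if other_idx < idx else (idx, other_idx)
            yield a, b, w
        heapq.heappush(active, (iv.end, idx, iv))


def build_matrix(
    profiles: list[BindingProfile], policy: str = "binary"
) -> CooccurrenceMatrix:
    """Assemble the co-occurrence matrix for a set of binding profiles.

    The joint pool is the concatenation of all profiles' locations, indexed
    densely in input order; a location bound by k factors appears as k
    independent records.  Overlap detection runs one contig at a time —
    records on different contigs can never overlap, so the result equals a
    whole-genome all-pairs scan.

    All overlapping same-contig pairs are stored, including pairs within a
    single factor: under a resampled assignment any record may land on
    either factor, so homogeneous overlaps can score even though they never
    contribute to the observed statistic.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown scoring policy {policy!r}; expected one of {POLICIES}")
    if not profiles:
        raise ValueError("at least one binding profile is required")
    names = [p.factor for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate factor names in input: {names}")

    records: list[LocationRecord] = []
    for profile in profiles:
        for iv in profile.intervals:
            records.append(LocationRecord(len(records), profile.factor, iv))

    by_contig: dict[str, list[tuple[int, GenomicInterval]]] = defaultdict(list)
    for rec in records:
        by_contig[rec.interval.contig].append((rec.index, rec.interval))

    ii: list[int] = []
    jj: list[int] = []
    ww: list[float] = []
    for contig in sorted(by_contig):
        for a, b, w in _contig_overlap_pairs(by_contig[contig], policy):
            if w > 0:
                ii.append(a)
                jj.append(b)
                ww.append(w)

    if policy == "binary":
        diag = np.ones(len(records))
    else:
        diag = np.array([float(len(r.interval)) for r in records])
    return CooccurrenceMatrix(
        records,
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(ww),
        diag,
        policy,
        factor_names=names,
    )
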