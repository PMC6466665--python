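"""Assembly contiguity and composition statistics (N50, L50, N-fraction).

The modern convention is used throughout: N50 is a *length* (the length of
the contig at which the cumulative sum of descending-sorted lengths first
reaches half the assembly size) and L50 is a *count* (that contig's 1-based
rank). Some older tools and texts swap the two names; this package does not.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .seqio import Assembly


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50_length: int
    l50_count: int
    max_length: int
    n_fraction: float = 0.0

    def __post_init__(self) -> None:
        assert 1 <= self.l50_count <= self.n_contigs
        assert self.n50_length <= self.max_length
        assert 0.0 <= self.n_fraction <= 1.0


def contig_stats(lengths: Iterable[int]) -> AssemblyStats:
    """Compute N50/L50 and basic counts from contig lengths.

    "First reaches" uses >= total/2: a cumulative sum landing exactly on
    half the assembly counts as reached, so e.g. lengths [5,5,5,5] give
    N50 = 5 and L50 = 2.
    """
    arr = np.asarray(sorted(lengths, reverse=True), dtype=np.int64)
    if arr.size == 0 or arr[-1] <= 0:
        raise ValueError("invalid lengths")
    total = int(arr.sum())
    cumulative = np.cumsum(arr)
    idx = int(np.argmax(cumulative >= total / 2))
    return AssemblyStats(
        n_contigs=int(arr.size),
        total_length=total,
        n50_length=int(arr[idx]),
        l50_count=idx + 1,
        max_length=int(arr[0]),
    )


def n_fraction(assembly: Assembly) -> float:
    """Fraction of bases that are N, over the whole assembly."""
    n_bases = sum(rec.sequence.count("N") for rec in assembly)
    return n_bases / assembly.total_length


def assembly_stats(assembly: Assembly) -> AssemblyStats:
    """Full stats for an assembly, including the N fraction."""
    stats = contig_stats([len(r) for r in assembly])
    return replace(stats, n_fraction=n_fraction(assembly))
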