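"""Genomic intervals and masks.

All interval arithmetic in this package is 0-based, half-open — the BED
convention. VCF positions (1-based) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end} (need end > start)"
            )
        if self.start < 0:
            raise ValueError(f"negative coordinate {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> tuple[float, float]:
    """Overlap of ``a`` and ``b`` as a fraction of each interval's length.

    Returns ``(overlap/len(a), overlap/len(b))``; ``(0.0, 0.0)`` when the
    intervals sit on different chromosomes. Two intervals pass a reciprocal
    overlap threshold t when *both* returned fractions are >= t.
    """
    if a.chrom != b.chrom:
        return (0.0, 0.0)
    ov = max(0, min(a.end, b.end) - max(a.start, b.start))
    return (ov / a.length, ov / b.length)


def _merge_sorted(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of intervals given start-sorted arrays: merged, disjoint, sorted."""
    if len(starts) == 0:
        return starts, ends
    out_s, out_e = [starts[0]], [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= out_e[-1]:
            if e > out_e[-1]:
                out_e[-1] = e
        else:
            out_s.append(s)
            out_e.append(e)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class GenomeMask:
    """A named set of genomic intervals used for inclusion/exclusion filters.

    Intervals are stored per chromosome as merged, sorted numpy arrays, so
    membership and union-coverage queries are exact and O(log n).
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.name = name
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            s = np.array([i[0] for i in ivs], dtype=np.int64)
            e = np.array([i[1] for i in ivs], dtype=np.int64)
            self._starts[chrom], self._ends[chrom] = _merge_sorted(s, e)

    @classmethod
    def from_bed(cls, name: str, path: str | Path) -> "GenomeMask":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"], dtype={0: str},
        )
        return cls(
            name,
            (GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()),
        )

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._starts):
                for s, e in zip(self._starts[chrom], self._ends[chrom]):
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(chrom, int(s), int(e))
            for chrom in sorted(self._starts)
            for s, e in zip(self._starts[chrom], self._ends[chrom])
        ]

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def overlapped_bases(self, iv: GenomicInterval) -> int:
        """Number of bases of ``iv`` covered by the mask union."""
        if iv.chrom not in self._starts:
            return 0
        s, e = self._starts[iv.chrom], self._ends[iv.chrom]
        lo = int(np.searchsorted(e, iv.start, side="right"))
        hi = int(np.searchsorted(s, iv.end, side="left"))
        if hi <= lo:
            return 0
        cov = np.minimum(e[lo:hi], iv.end) - np.maximum(s[lo:hi], iv.start)
        return int(cov.sum())

    def overlaps(self, iv: GenomicInterval) -> bool:
        """True if any mask interval shares >= 1 bp with ``iv``."""
        return self.overlapped_bases(iv) > 0

    def contains_positions(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Vectorised membership test for 0-based positions on one chromosome."""
        pos0 = np.asarray(pos0)
        if chrom not in self._starts:
            return np.zeros(pos0.shape, dtype=bool)
        s, e = self._starts[chrom], self._ends[chrom]
        idx = np.searchsorted(s, pos0, side="right") - 1
        inside = idx >= 0
        inside[inside] = pos0[inside] < e[idx[inside]]
        return inside

    def padded(self, pad: int) -> "GenomeMask":
        """A copy with every interval widened by ``pad`` bases on each side."""
        return GenomeMask(
            f"{self.name}+{pad}",
            (
                GenomicInterval(iv.chrom, max(0, iv.start - pad), iv.end + pad)
                for iv in self.intervals()
            ),
        )


def mask_overlap_fraction(iv: GenomicInterval, mask: GenomeMask) -> float:
    """Fraction of ``iv`` covered by the union of mask intervals, in [0, 1]."""
    return mask.overlapped_bases(iv) / iv.length
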