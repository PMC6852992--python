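"""Per-sample and per-population summary statistics.

Covers heterozygosity proportion, Ti/Tv, novelty rates against a known-
variant set, 1-Mb variant-hotspot scanning, and set-level classification
of inherited novel insertions against archaic hominin genomes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .denovo import DenovoCriteria
from .intervals import GenomeMask, GenomicInterval
from .pedigree import TrioPedigree

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

MB = 1_000_000


def heterozygosity_proportion(n_het: int, n_homalt: int) -> float:
    """Heterozygous calls over heterozygous plus homozygous-alternative calls."""
    if n_het < 0 or n_homalt < 0:
        raise ValueError("counts must be >= 0")
    denom = n_het + n_homalt
    if denom == 0:
        raise ValueError("no variant calls: heterozygosity proportion undefined")
    return n_het / denom


def titv_ratio(substitutions: Iterable[tuple[str, str]]) -> float:
    """Transitions (A<->G, C<->T) over transversions; ~2.1 genome-wide."""
    ti = tv = 0
    for ref, alt in substitutions:
        if (ref.upper(), alt.upper()) in TRANSITIONS:
            ti += 1
        else:
            tv += 1
    if tv == 0:
        raise ValueError("no transversions: Ti/Tv undefined")
    return ti / tv


def novelty_rate(
    variants: Iterable[tuple[str, int, str, str]],
    known_set: set[tuple[str, int, str, str]],
) -> float:
    """Fraction of variant keys (chrom, pos, ref, alt) absent from a known set."""
    n = novel = 0
    for key in variants:
        n += 1
        if key not in known_set:
            novel += 1
    if n == 0:
        raise ValueError("no variants supplied")
    return novel / n


def read_known_variants(path: str | Path) -> set[tuple[str, int, str, str]]:
    """Known-variant table: 4-column TSV (chrom, pos, ref, alt), 1-based."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return {(str(r.chrom), int(r.pos), str(r.ref), str(r.alt)) for r in df.itertuples()}


@dataclass(frozen=True)
class WindowCount:
    """One 1-Mb window of the hotspot scan with its QC-passing variant count."""

    interval: GenomicInterval
    n_pass: int


def tile_windows(
    chrom_sizes: Mapping[str, int],
    telo_centro: GenomeMask | None = None,
    window: int = MB,
    flank: int = MB,
    min_partial: int = MB // 2,
) -> list[GenomicInterval]:
    """Non-overlapping windows tiling each chromosome from position 0.

    Windows overlapping a telomere/centromere interval padded by ``flank``
    are excluded; a final partial window is kept only if >= ``min_partial``.
    """
    excl = telo_centro.padded(flank) if telo_centro is not None else None
    out = []
    for chrom, size in chrom_sizes.items():
        start = 0
        while start < size:
            end = min(start + window, size)
            if end - start >= min_partial or end - start == window:
                iv = GenomicInterval(chrom, start, end)
                if excl is None or not excl.overlaps(iv):
                    out.append(iv)
            start += window
    return out


def hotspot_scan(
    variants: Iterable[tuple[str, int, int, int, int, float]],
    chrom_sizes: Mapping[str, int],
    telo_centro: GenomeMask | None = None,
    qc: DenovoCriteria = DenovoCriteria(),
    top_frac: float = 0.01,
    window: int = MB,
) -> list[WindowCount]:
    """Top-1% 1-Mb windows by QC-passing variant count.

    ``variants`` yields (chrom, pos [1-based], dp, gq, ad_ref, ad_alt) per
    genotype observation; QC requires GQ >= 50, DP in [10, 120] and allele
    balance in [0.3, 0.7]. The top ceil(top_frac * n_windows) windows are
    returned, extended through ties at the cutoff count. SNVs and indels
    are expected to be scanned in separate calls.
    """
    windows = tile_windows(chrom_sizes, telo_centro, window=window)
    index: dict[tuple[str, int], int] = {}
    for i, w in enumerate(windows):
        index[(w.chrom, w.start // window)] = i
    counts = [0] * len(windows)
    for chrom, pos, dp, gq, ad_ref, ad_alt in variants:
        if gq < qc.gq_min or not (qc.dp_min <= dp <= qc.dp_max):
            continue
        reads = ad_ref + ad_alt
        if reads == 0:
            continue
        ab = ad_alt / reads
        if not (qc.ab_min - 1e-12 <= ab <= qc.ab_max + 1e-12):
            continue
        i = index.get((chrom, (pos - 1) // window))
        if i is not None:
            counts[i] += 1
    if not windows:
        return []
    k = math.ceil(top_frac * len(windows))
    order = sorted(range(len(windows)), key=lambda i: (-counts[i], windows[i].chrom, windows[i].start))
    cutoff = counts[order[k - 1]]
    top = [i for i in order if counts[i] >= cutoff]
    return [WindowCount(windows[i], counts[i]) for i in top]


# ---------------------------------------------------------------------------
# novel insertions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NiRecord:
    """Presence flags for one novel-insertion contig across samples and
    archaic genomes."""

    ni_id: str
    presence: Mapping[str, bool]
    in_neanderthal: bool
    in_denisovan: bool


@dataclass(frozen=True)
class NiClass:
    inherited: bool
    archaic: str  # none | neanderthal_specific | denisovan_specific | both

    @property
    def archaic_like(self) -> bool:
        return self.archaic != "none"


def classify_ni(rec: NiRecord, trio: TrioPedigree) -> NiClass:
    """Inheritance and archaic-sharing class of one novel insertion.

    Inherited means present in the offspring and in at least one parent
    (offspring-only presence is treated as a likely artefact). The archaic
    category splits into Neanderthal-specific, Denisovan-specific and
    shared-with-both; archaic-like is their union.
    """
    for sid in trio.sample_ids:
        if sid not in rec.presence:
            raise KeyError(f"NI {rec.ni_id}: no presence flag for sample {sid}")
    inherited = rec.presence[trio.offspring_id] and (
        rec.presence[trio.father_id] or rec.presence[trio.mother_id]
    )
    archaic = {
        (True, False): "neanderthal_specific",
        (False, True): "denisovan_specific",
        (True, True): "both",
        (False, False): "none",
    }[(rec.in_neanderthal, rec.in_denisovan)]
    return NiClass(inherited, archaic)


def ni_summary(records: Sequence[NiRecord], trio: TrioPedigree) -> dict[str, int]:
    """Per-trio tallies of inherited NIs by archaic category."""
    out = {"total_inherited": 0, "archaic_like": 0,
           "neanderthal_specific": 0, "denisovan_specific": 0, "both": 0}
    for rec in records:
        cls = classify_ni(rec, trio)
        if not cls.inherited:
            continue
        out["total_inherited"] += 1
        if cls.archaic_like:
            out["archaic_like"] += 1
            out[cls.archaic] += 1
    return out


def read_ni_table(path: str | Path, sample_ids: Sequence[str]) -> list[NiRecord]:
    """NI presence table: TSV with ni_id, one 0/1 column per sample, and
    in_neanderthal / in_denisovan flag columns."""
    df = pd.read_csv(path, sep="\t")
    return [
        NiRecord(
            str(r.ni_id),
            {sid: bool(getattr(r, sid)) for sid in sample_ids},
            bool(r.in_neanderthal),
            bool(r.in_denisovan),
        )
        for r in df.itertuples()
    ]
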