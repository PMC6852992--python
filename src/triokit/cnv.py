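"""CNV ensemble merging, novelty and de novo detection, and sharing classes.

CNVs here are autosomal deletions or duplications > 100 bp called per
sample by two independent read-depth callers. A per-sample filtered set
keeps a call only if

  i.   the other caller reports a same-type call at >= 50% reciprocal
       overlap (single-caller calls are discarded);
  ii.  it does not touch any repetitive / low-complexity region;
  iii. less than 50% of its span falls in assembly gaps or segmental
       duplications (union coverage).

De novo status in an offspring is established in three steps: absence of a
same-type parental call at 50% reciprocal overlap, depth-based
re-genotyping of the interval in both parents, and emission of a per-call
review report.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomeMask, GenomicInterval, reciprocal_overlap
from .pedigree import NEGRITO_POPULATIONS, TrioPedigree

log = logging.getLogger(__name__)

DEL, DUP = "DEL", "DUP"

#: calls at or below this length are indel territory and dropped at load
MIN_CNV_LEN = 100


@dataclass(frozen=True)
class CnvCall:
    sample_id: str
    interval: GenomicInterval
    svtype: str  # DEL or DUP
    copy_number: int | None = None
    caller: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in (DEL, DUP):
            raise ValueError(f"svtype must be DEL or DUP, got {self.svtype!r}")
        if self.copy_number is not None:
            if self.svtype == DEL and self.copy_number >= 2:
                raise ValueError(f"DEL with copy number {self.copy_number}")
            if self.svtype == DUP and self.copy_number <= 2:
                raise ValueError(f"DUP with copy number {self.copy_number}")


@dataclass
class CnvRegion:
    """A cross-sample CNV region with per-trio presence and sharing class."""

    interval: GenomicInterval
    svtype: str
    carriers: frozenset[str]
    trio_presence: frozenset[str]
    sharing_class: str | None = None


def read_cnv_calls(path: str | Path, min_len: int = MIN_CNV_LEN) -> list[CnvCall]:
    """Read a per-caller CNV table (TSV: sample, chrom, start, end, svtype,
    copy_number, caller; BED-convention coordinates). Calls with length
    <= min_len bp are dropped."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    calls = []
    n_short = 0
    for r in df.itertuples():
        iv = GenomicInterval(r.chrom, int(r.start), int(r.end))
        if iv.length <= min_len:
            n_short += 1
            continue
        cn = None if pd.isna(r.copy_number) else int(r.copy_number)
        calls.append(CnvCall(str(r.sample), iv, str(r.svtype), cn, str(r.caller)))
    if n_short:
        log.info("dropped %d calls <= %d bp", n_short, min_len)
    return calls


def write_cnv_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    rows = [
        dict(sample=c.sample_id, chrom=c.interval.chrom, start=c.interval.start,
             end=c.interval.end, svtype=c.svtype,
             copy_number="" if c.copy_number is None else c.copy_number, caller=c.caller)
        for c in calls
    ]
    pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "svtype", "copy_number", "caller"]).to_csv(
        path, sep="\t", index=False
    )


def _has_reciprocal_match(
    call: CnvCall, others: Sequence[CnvCall], threshold: float = 0.5, same_type: bool = True
) -> bool:
    for o in others:
        if same_type and o.svtype != call.svtype:
            continue
        fa, fb = reciprocal_overlap(call.interval, o.interval)
        if fa >= threshold and fb >= threshold:
            return True
    return False


def merge_callsets(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    repeat_masks: Sequence[GenomeMask] = (),
    gap_segdup_masks: Sequence[GenomeMask] = (),
    threshold: float = 0.5,
) -> list[CnvCall]:
    """Two-caller concordance merge with mask filters for one sample.

    A call survives iff (i) the other caller has a same-type call at
    >= ``threshold`` reciprocal overlap, (ii) it overlaps no repeat /
    low-complexity interval by even 1 bp, and (iii) the union of gap and
    segmental-duplication intervals covers < 50% of its span. Concordant
    pairs are represented once, by the caller-A interval.
    """
    samples = {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    if len(samples) > 1:
        raise ValueError(f"merge_callsets expects a single sample, got {sorted(samples)}")
    merged: list[CnvCall] = []
    for call in calls_a:
        if not _has_reciprocal_match(call, calls_b, threshold):
            continue
        if any(m.overlaps(call.interval) for m in repeat_masks):
            continue
        if gap_segdup_masks:
            union = GenomeMask(
                "gap+segdup",
                (iv for m in gap_segdup_masks for iv in m.intervals()
                 if iv.chrom == call.interval.chrom),
            )
            frac = union.overlapped_bases(call.interval) / call.interval.length
            if frac >= 0.5:
                continue
        merged.append(call)
    return merged


def is_novel_cnv(
    region: GenomicInterval,
    database: Sequence[tuple[GenomicInterval, str]],
    svtype: str | None = None,
    match_svtype: bool = False,
    threshold: float = 0.5,
) -> bool:
    """True iff no database record reaches 50% reciprocal overlap.

    By default records of any svtype can match (``match_svtype=True``
    restricts matching to same-type records).
    """
    for db_iv, db_type in database:
        if match_svtype and svtype is not None and db_type != svtype:
            continue
        fa, fb = reciprocal_overlap(region, db_iv)
        if fa >= threshold and fb >= threshold:
            return False
    return True


class DepthProfile:
    """Windowed read-depth track for one sample.

    Stores mean depth per fixed-size window per chromosome; used to
    re-genotype CNV intervals from depth ratios.
    """

    def __init__(self, sample_id: str, window: int, depths: Mapping[str, np.ndarray]) -> None:
        self.sample_id = sample_id
        self.window = window
        self.depths = {c: np.asarray(d, dtype=float) for c, d in depths.items()}

    @property
    def autosomal_mean(self) -> float:
        return float(np.mean(np.concatenate(list(self.depths.values()))))

    def mean_depth(self, iv: GenomicInterval) -> float:
        d = self.depths.get(iv.chrom)
        if d is None:
            raise KeyError(f"no depth track for {iv.chrom}")
        lo = iv.start // self.window
        hi = (iv.end - 1) // self.window + 1
        # weight windows by their overlap with the interval
        idx = np.arange(lo, min(hi, len(d)))
        w_start = np.maximum(idx * self.window, iv.start)
        w_end = np.minimum((idx + 1) * self.window, iv.end)
        weights = (w_end - w_start).astype(float)
        return float(np.average(d[idx], weights=weights))

    def copy_number(self, iv: GenomicInterval) -> int:
        """Estimated integer copy number: round(2 * depth_ratio)."""
        return int(round(2.0 * self.mean_depth(iv) / self.autosomal_mean))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, d in self.depths.items():
            for i, v in enumerate(d):
                rows.append((self.sample_id, chrom, i * self.window, (i + 1) * self.window, v))
        return pd.DataFrame(rows, columns=["sample", "chrom", "start", "end", "depth"])

    @classmethod
    def read_tsv(cls, path: str | Path) -> dict[str, "DepthProfile"]:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        out = {}
        for sid, sub in df.groupby("sample"):
            window = int(sub.iloc[0].end - sub.iloc[0].start)
            depths = {
                str(chrom): grp.sort_values("start").depth.to_numpy()
                for chrom, grp in sub.groupby("chrom")
            }
            out[str(sid)] = cls(str(sid), window, depths)
        return out


@dataclass
class DenovoCnvReport:
    """Per-call review evidence mirroring a manual confirmation step."""

    call: CnvCall
    status: str  # "de_novo", "parental_overlap", "parental_cn", "unverified"
    father_cn: int | None = None
    mother_cn: int | None = None
    father_depth_ratio: float | None = None
    mother_depth_ratio: float | None = None


def detect_denovo_cnv(
    offspring_calls: Sequence[CnvCall],
    father_calls: Sequence[CnvCall],
    mother_calls: Sequence[CnvCall],
    depth_profiles: Mapping[str, DepthProfile] | None,
    father_id: str = "",
    mother_id: str = "",
    threshold: float = 0.5,
) -> tuple[list[CnvCall], list[DenovoCnvReport]]:
    """Three-step de novo CNV detection in one offspring.

    (i) drop offspring calls with a same-type parental call at >= 50%
    reciprocal overlap; (ii) re-genotype survivors in both parents from
    windowed depth (CN = round(2 * mean interval depth / autosomal mean))
    and drop calls where a parental CN is consistent with the offspring
    svtype (CN < 2 for DEL, CN > 2 for DUP); (iii) emit survivors with a
    per-call evidence report. Missing depth profiles skip step (ii) with a
    warning and mark the call "unverified".
    """
    denovo: list[CnvCall] = []
    reports: list[DenovoCnvReport] = []
    profiles = depth_profiles or {}
    for call in offspring_calls:
        if _has_reciprocal_match(call, list(father_calls) + list(mother_calls), threshold):
            reports.append(DenovoCnvReport(call, "parental_overlap"))
            continue
        fp, mp = profiles.get(father_id), profiles.get(mother_id)
        if fp is None or mp is None:
            log.warning("no parental depth profile for %s; call %s unverified",
                        call.sample_id, call.interval)
            denovo.append(call)
            reports.append(DenovoCnvReport(call, "unverified"))
            continue
        f_cn, m_cn = fp.copy_number(call.interval), mp.copy_number(call.interval)
        f_ratio = fp.mean_depth(call.interval) / fp.autosomal_mean
        m_ratio = mp.mean_depth(call.interval) / mp.autosomal_mean
        consistent = (
            (call.svtype == DEL and (f_cn < 2 or m_cn < 2))
            or (call.svtype == DUP and (f_cn > 2 or m_cn > 2))
        )
        status = "parental_cn" if consistent else "de_novo"
        reports.append(DenovoCnvReport(call, status, f_cn, m_cn, f_ratio, m_ratio))
        if not consistent:
            denovo.append(call)
    return denovo, reports


def estimate_cnv_rate(n_denovo: int, n_total: int) -> tuple[float, float]:
    """De novo CNV rate: de novo count over total count in the offspring.

    Returns (exact rate, rate rounded to one significant digit — the
    precision used for reporting).
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_denovo <= n_total):
        raise ValueError("need 0 <= n_denovo <= n_total")
    rate = n_denovo / n_total
    if rate == 0.0:
        return 0.0, 0.0
    import math

    digits = -int(math.floor(math.log10(abs(rate))))
    return rate, round(rate, digits)


def build_cnv_regions(
    calls_by_trio: Mapping[str, Sequence[CnvCall]],
    threshold: float = 0.5,
) -> list[CnvRegion]:
    """Cluster same-type calls across trios into regions.

    Single-linkage clustering at >= 50% reciprocal overlap; the region
    interval is the longest member call's. Per-trio presence means any
    sample of the trio carries a member call.
    """
    flat: list[tuple[str, CnvCall]] = [
        (trio_id, c) for trio_id, calls in calls_by_trio.items() for c in calls
    ]
    n = len(flat)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            ci, cj = flat[i][1], flat[j][1]
            if ci.svtype != cj.svtype:
                continue
            fa, fb = reciprocal_overlap(ci.interval, cj.interval)
            if fa >= threshold and fb >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    regions = []
    for members in clusters.values():
        calls = [flat[i][1] for i in members]
        rep = max(calls, key=lambda c: c.interval.length)
        regions.append(
            CnvRegion(
                interval=rep.interval,
                svtype=rep.svtype,
                carriers=frozenset(c.sample_id for c in calls),
                trio_presence=frozenset(flat[i][0] for i in members),
            )
        )
    regions.sort(key=lambda r: (r.interval.chrom, r.interval.start, r.svtype))
    return regions


def classify_sharing(region: CnvRegion, trios: Sequence[TrioPedigree]) -> str:
    """Sharing class of a CNV region across the five study populations.

    MLS (Malaysian) if present in at least one OA and one NB trio; OA if
    present in all of BTQ, MDQ and SMI; NGO (Negrito) if present in BTQ
    and MDQ; NB if present in DSN and MRT; private if in exactly one
    trio; other otherwise.
    """
    pops = {t.population for t in trios if t.trio_id in region.trio_presence}
    groups = {t.group for t in trios if t.trio_id in region.trio_presence}
    if "OA" in groups and "NB" in groups:
        cls = "MLS"
    elif pops >= {"BTQ", "MDQ", "SMI"}:
        cls = "OA"
    elif pops >= NEGRITO_POPULATIONS:
        cls = "NGO"
    elif pops >= {"DSN", "MRT"}:
        cls = "NB"
    elif len(region.trio_presence) == 1:
        cls = "private"
    else:
        cls = "other"
    region.sharing_class = cls
    return cls
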