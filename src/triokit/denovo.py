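"""De novo SNV/indel identification and callability-based mutation rates.

A candidate de novo mutation in an offspring must survive a five-criterion
cascade:

  i.   the locus lies outside all exclusion masks (poor mappability,
       low complexity, aberrant-SNP regions);
  ii.  offspring read depth is within [10, 120] and the allele balance
       (alt reads / informative reads) is within [0.3, 0.7];
  iii. genotype quality >= 50 in the offspring and both parents;
  iv.  zero reads support the alternative allele in either parent;
  v.   both parents are homozygous reference and the offspring carries
       the alternative allele.

The per-family mutation rate is estimated with a callability denominator:

    mu_k = n_DNM(k) / (2 * sum_s C_k(s))

where C_k(s) is the probability that a true de novo mutation at site s in
family k would survive the cascade. C_k(s) is modelled as the deterministic
pass-indicator of criteria i, iii and iv times the exact Binomial(d, 1/2)
probability that a true heterozygote at the offspring's observed depth d
shows a passing allele balance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.stats import binom

from .intervals import GenomeMask
from .pedigree import TrioPedigree
from .variants import (
    HET,
    HOMALT,
    HOMREF,
    MISSING,
    SiteGenotype,
    VariantSite,
    allele_balance,
)

CRITERIA = ("i", "ii", "iii", "iv", "v")

#: rejection-reason codes for the vectorised path
REASON_PASS, REASON_MISSING = 0, 6
REASON_BY_CRITERION = {c: i + 1 for i, c in enumerate(CRITERIA)}


@dataclass(frozen=True)
class DenovoCriteria:
    """Filter thresholds of the de novo cascade (study defaults)."""

    dp_min: int = 10
    dp_max: int = 120
    ab_min: float = 0.3
    ab_max: float = 0.7
    gq_min: int = 50
    masks: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.ab_min < self.ab_max <= 1):
            raise ValueError("need 0 <= ab_min < ab_max <= 1")
        if self.dp_min >= self.dp_max:
            raise ValueError("need dp_min < dp_max")


@dataclass
class DenovoCall:
    trio_id: str
    site: VariantSite
    vtype: str
    child_ab: float
    audit: dict[str, bool]


@dataclass
class DenovoRejection:
    trio_id: str
    site: VariantSite
    reason: str  # "missing" or the first failed criterion "i".."v"
    audit: dict[str, bool] = field(default_factory=dict)


@dataclass
class RateEstimate:
    """Callability-based mutation-rate estimate for one trio and vtype."""

    trio_id: str
    vtype: str
    n_dnm: int
    callability_sum: float
    mu: float


def _site_masked(site_chrom: str, pos0: int, masks: Mapping[str, GenomeMask], names: Iterable[str]) -> bool:
    for name in names:
        m = masks.get(name)
        if m is not None and m.contains_positions(site_chrom, np.array([pos0]))[0]:
            return True
    return False


def classify_denovo(
    site: VariantSite,
    trio: TrioPedigree,
    crit: DenovoCriteria = DenovoCriteria(),
    masks: Mapping[str, GenomeMask] | None = None,
) -> DenovoCall | DenovoRejection:
    """Apply the five-criterion cascade to one site in one trio.

    Returns a DenovoCall if every criterion passes, otherwise a rejection
    with a reason ("missing" if any member lacks a genotype; criterion v
    when the trio genotype pattern itself is not a de novo candidate; else
    the first failed QC criterion in the order i -> iv). The audit dict
    records every criterion's outcome.
    """
    masks = masks or {}
    f = site.genotypes.get(trio.father_id)
    m = site.genotypes.get(trio.mother_id)
    c = site.genotypes.get(trio.offspring_id)
    if f is None or m is None or c is None or MISSING in (f.gt, m.gt, c.gt):
        return DenovoRejection(trio.trio_id, site, "missing")

    audit: dict[str, bool] = {}
    mask_names = crit.masks or tuple(masks)
    audit["i"] = not _site_masked(site.chrom, site.pos0, masks, mask_names)

    dp_ok = crit.dp_min <= c.dp <= crit.dp_max
    if c.ad_ref + c.ad_alt > 0:
        ab = allele_balance(c)
        ab_ok = crit.ab_min - 1e-12 <= ab <= crit.ab_max + 1e-12
    else:
        ab, ab_ok = math.nan, False
    audit["ii"] = dp_ok and ab_ok
    audit["iii"] = all(g.gq >= crit.gq_min for g in (c, f, m))
    audit["iv"] = f.ad_alt == 0 and m.ad_alt == 0
    audit["v"] = f.gt == HOMREF and m.gt == HOMREF and c.gt in (HET, HOMALT)

    # criterion v defines the candidate pattern and gates the QC criteria
    for criterion in ("v", "i", "ii", "iii", "iv"):
        if not audit[criterion]:
            return DenovoRejection(trio.trio_id, site, criterion, audit)
    return DenovoCall(trio.trio_id, site, site.vtype, ab, audit)


def ab_band_probability(depth: int, ab_min: float = 0.3, ab_max: float = 0.7) -> float:
    """P(ab_min <= X/d <= ab_max) for X ~ Binomial(d, 1/2), inclusive bounds."""
    if depth <= 0:
        return 0.0
    lo = math.ceil(ab_min * depth - 1e-9)
    hi = math.floor(ab_max * depth + 1e-9)
    if hi < lo:
        return 0.0
    return float(binom.cdf(hi, depth, 0.5) - binom.cdf(lo - 1, depth, 0.5))


def callability_table(crit: DenovoCriteria, max_dp: int = 200) -> np.ndarray:
    """ab-band probability for every offspring depth 0..max_dp.

    Depths outside [dp_min, dp_max] get probability 0, folding the depth
    part of criterion ii into the table.
    """
    table = np.zeros(max_dp + 1)
    for d in range(crit.dp_min, min(crit.dp_max, max_dp) + 1):
        table[d] = ab_band_probability(d, crit.ab_min, crit.ab_max)
    return table


def site_callability(
    father: SiteGenotype,
    mother: SiteGenotype,
    child_dp: int,
    site_pos0: int | None = None,
    site_chrom: str | None = None,
    crit: DenovoCriteria = DenovoCriteria(),
    masks: Mapping[str, GenomeMask] | None = None,
    child_gq: int | None = None,
) -> float:
    """Probability C_k(s) of calling a true de novo mutation at this site.

    Zero if the site is masked, any member's depth is outside
    [dp_min, dp_max], a genotype quality is below gq_min (the offspring's
    only when ``child_gq`` is supplied), or a parent shows any alt-allele
    read; otherwise the exact binomial probability of a passing allele
    balance for a true heterozygote at depth ``child_dp``.
    """
    masks = masks or {}
    if site_pos0 is not None and site_chrom is not None:
        if _site_masked(site_chrom, site_pos0, masks, crit.masks or tuple(masks)):
            return 0.0
    for g in (father, mother):
        if not (crit.dp_min <= g.dp <= crit.dp_max) or g.gq < crit.gq_min:
            return 0.0
        if g.ad_alt > 0:
            return 0.0
    if not (crit.dp_min <= child_dp <= crit.dp_max):
        return 0.0
    if child_gq is not None and child_gq < crit.gq_min:
        return 0.0
    return ab_band_probability(child_dp, crit.ab_min, crit.ab_max)


def estimate_snv_rate(n_dnm: int, callability_sum: float, trio_id: str = "", vtype: str = "snv") -> RateEstimate:
    """mu_k = n_DNM / (2 * sum of per-site callabilities)."""
    if callability_sum <= 0:
        raise ValueError("callability_sum must be > 0")
    if n_dnm < 0:
        raise ValueError("n_dnm must be >= 0")
    return RateEstimate(trio_id, vtype, n_dnm, callability_sum, n_dnm / (2.0 * callability_sum))


# ---------------------------------------------------------------------------
# vectorised path (used on large simulated site arrays)
# ---------------------------------------------------------------------------

def classify_denovo_arrays(
    gt: np.ndarray,
    dp: np.ndarray,
    ad_alt: np.ndarray,
    gq: np.ndarray,
    masked: np.ndarray | None = None,
    crit: DenovoCriteria = DenovoCriteria(),
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised cascade over n sites for one trio.

    Arrays are shaped (3, n) with rows father, mother, offspring. Returns
    (called boolean, first-failure reason codes: 0 pass, 1..5 criteria
    i..v, 6 missing). Allele balance uses alt/(ref+alt) with ref+alt == dp
    by the simulator's construction.
    """
    n = gt.shape[1]
    if masked is None:
        masked = np.zeros(n, dtype=bool)
    fails = np.zeros((6, n), dtype=bool)
    fails[0] = (gt == MISSING).any(axis=0)
    fails[1] = ~((gt[0] == HOMREF) & (gt[1] == HOMREF) & ((gt[2] == HET) | (gt[2] == HOMALT)))
    fails[2] = masked
    cdp, cad = dp[2], ad_alt[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        ab = np.where(cdp > 0, cad / np.maximum(cdp, 1), np.nan)
    ab_ok = (ab >= crit.ab_min - 1e-12) & (ab <= crit.ab_max + 1e-12)
    fails[3] = ~((cdp >= crit.dp_min) & (cdp <= crit.dp_max) & ab_ok)
    fails[4] = (gq < crit.gq_min).any(axis=0)
    fails[5] = (ad_alt[:2] > 0).any(axis=0)
    called = ~fails.any(axis=0)
    # first-failure code in evaluation order: missing, v (pattern gate), i..iv
    order = np.array([REASON_MISSING, 5, 1, 2, 3, 4], dtype=np.int8)
    first = np.argmax(fails, axis=0)
    reason = np.where(called, np.int8(REASON_PASS), order[first])
    return called, reason


def callability_arrays(
    gt: np.ndarray,
    dp: np.ndarray,
    ad_alt: np.ndarray,
    gq: np.ndarray,
    masked: np.ndarray | None = None,
    crit: DenovoCriteria = DenovoCriteria(),
) -> np.ndarray:
    """Per-site callability C_k(s) over n sites for one trio (vectorised)."""
    n = gt.shape[1]
    if masked is None:
        masked = np.zeros(n, dtype=bool)
    table = callability_table(crit, max_dp=int(dp[2].max(initial=0)) + 1)
    ok = ~masked
    for parent in (0, 1):
        ok &= (dp[parent] >= crit.dp_min) & (dp[parent] <= crit.dp_max)
        ok &= gq[parent] >= crit.gq_min
        ok &= ad_alt[parent] == 0
    ok &= gq[2] >= crit.gq_min
    return np.where(ok, table[dp[2]], 0.0)


def denovo_scan(
    sites: Iterable[VariantSite],
    trios: list[TrioPedigree],
    crit: DenovoCriteria = DenovoCriteria(),
    masks: Mapping[str, GenomeMask] | None = None,
) -> tuple[list[DenovoCall], list[RateEstimate]]:
    """Run the cascade and accumulate callability over a stream of sites.

    Returns the de novo calls plus one RateEstimate per trio per vtype
    (snv, indel). The callability denominator for each vtype sums C_k(s)
    over the sites of that vtype, so rates are per analysed site per
    generation.
    """
    calls: list[DenovoCall] = []
    n_dnm: dict[tuple[str, str], int] = {}
    csum: dict[tuple[str, str], float] = {}
    for site in sites:
        vt = site.vtype
        for trio in trios:
            res = classify_denovo(site, trio, crit, masks)
            if isinstance(res, DenovoCall):
                calls.append(res)
                n_dnm[(trio.trio_id, vt)] = n_dnm.get((trio.trio_id, vt), 0) + 1
            f = site.genotypes.get(trio.father_id)
            m = site.genotypes.get(trio.mother_id)
            c = site.genotypes.get(trio.offspring_id)
            if f is None or m is None or c is None:
                continue
            ck = site_callability(
                f, m, c.dp, site.pos0, site.chrom, crit, masks, child_gq=c.gq
            )
            csum[(trio.trio_id, vt)] = csum.get((trio.trio_id, vt), 0.0) + ck
    rates = [
        estimate_snv_rate(n_dnm.get((t.trio_id, vt), 0), csum[(t.trio_id, vt)], t.trio_id, vt)
        for t in trios
        for vt in ("snv", "indel")
        if csum.get((t.trio_id, vt), 0.0) > 0
    ]
    return calls, rates
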