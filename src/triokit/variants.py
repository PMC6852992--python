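"""Variant sites, per-sample genotypes, and Mendelian-consistency logic.

Genotypes are unphased autosomal biallelic calls encoded as the count of
alternative alleles (0 = homref, 1 = het, 2 = homalt, -1 = missing).
VCF records are 1-based; they are converted to the package's internal
0-based half-open convention only where interval arithmetic needs it.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from cyvcf2 import VCF

log = logging.getLogger(__name__)

HOMREF, HET, HOMALT, MISSING = 0, 1, 2, -1

_GT_NAMES = {HOMREF: "homref", HET: "het", HOMALT: "homalt", MISSING: "missing"}

_AUTOSOME_RE = re.compile(r"^(chr)?([1-9]|1[0-9]|2[0-2])$")

SNV, INDEL = "snv", "indel"

#: maximum allele length for a call to count as a small indel (larger is SV territory)
MAX_INDEL_LEN = 100


def is_autosome(chrom: str) -> bool:
    return bool(_AUTOSOME_RE.match(chrom))


class UndefinedAlleleBalance(ValueError):
    """Raised when a site has zero informative reads."""


@dataclass
class SiteGenotype:
    """One sample's call at one site."""

    sample_id: str
    gt: int  # alt-allele count, or MISSING
    ad_ref: int = 0
    ad_alt: int = 0
    dp: int | None = None  # total depth; falls back to ad_ref + ad_alt
    gq: int = 0

    def __post_init__(self) -> None:
        if self.dp is None:
            self.dp = self.ad_ref + self.ad_alt
        for name in ("ad_ref", "ad_alt", "dp", "gq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def gt_name(self) -> str:
        return _GT_NAMES[self.gt]


def allele_balance(g: SiteGenotype) -> float:
    """Fraction of informative reads supporting the alternative allele.

    A true heterozygote is expected near 0.5; the de novo filters require
    this to lie in [0.3, 0.7].
    """
    n = g.ad_ref + g.ad_alt
    if n <= 0:
        raise UndefinedAlleleBalance(f"sample {g.sample_id}: no informative reads")
    return g.ad_alt / n


def mendelian_consistent(father: int, mother: int, child: int) -> bool | None:
    """Whether the child genotype is reachable by biparental transmission.

    Each parent transmits one of their two alleles; a het parent can
    transmit either. Returns None (not evaluable) if any member is missing.
    """
    if MISSING in (father, mother, child):
        return None
    paternal = {0} if father == HOMREF else {1} if father == HOMALT else {0, 1}
    maternal = {0} if mother == HOMREF else {1} if mother == HOMALT else {0, 1}
    return any(a + b == child for a in paternal for b in maternal)


@dataclass
class VariantSite:
    """A biallelic site with per-sample genotype calls.

    ``pos`` is 1-based (VCF convention); ``pos0`` gives the 0-based
    coordinate used by interval arithmetic.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: dict[str, SiteGenotype] = field(default_factory=dict)

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def vtype(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SNV
        if len(self.ref) != len(self.alt):
            return INDEL
        return "other"

    @property
    def is_small_biallelic(self) -> bool:
        vt = self.vtype
        if vt == SNV:
            return True
        return vt == INDEL and len(self.ref) < MAX_INDEL_LEN and len(self.alt) < MAX_INDEL_LEN


def _split_record(v, samples: list[str]) -> Iterator[VariantSite]:
    """Split a (possibly multiallelic) cyvcf2 record into biallelic sites.

    For each alternative allele a per-alt record is emitted whose genotypes
    count copies of that allele alone; alleles belonging to a different alt
    therefore count as reference, the usual multiallelic-split semantics.
    """
    def _fmt(key: str):
        try:
            return v.format(key)
        except KeyError:
            return None

    ad, gq, dp = _fmt("AD"), _fmt("GQ"), _fmt("DP")
    gts = v.genotypes  # [a1, a2, phased] per sample
    for k, alt in enumerate(v.ALT):
        if alt in (".", "*", "<NON_REF>"):
            continue
        site = VariantSite(chrom=v.CHROM, pos=v.POS, ref=v.REF, alt=alt)
        for i, sid in enumerate(samples):
            a1, a2 = gts[i][0], gts[i][1]
            if a1 < 0 or a2 < 0:
                g = MISSING
            else:
                g = int(a1 == k + 1) + int(a2 == k + 1)
            ad_ref = int(ad[i][0]) if ad is not None and ad[i][0] >= 0 else 0
            ad_alt = int(ad[i][k + 1]) if ad is not None and len(ad[i]) > k + 1 and ad[i][k + 1] >= 0 else 0
            dp_i = int(dp[i][0]) if dp is not None and dp[i][0] >= 0 else None
            gq_i = int(gq[i][0]) if gq is not None and gq[i][0] >= 0 else 0
            site.genotypes[sid] = SiteGenotype(sid, g, ad_ref, ad_alt, dp_i, gq_i)
        yield site


def read_vcf(
    path: str | Path,
    autosomes_only: bool = True,
    small_biallelic_only: bool = True,
) -> Iterator[VariantSite]:
    """Iterate biallelic VariantSites from a multi-sample VCF (plain or bgzip).

    Multiallelic records are split per alternative allele; sites that are
    not SNVs or small (< 100 bp) indels are dropped with a warning counter.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    n_dropped = 0
    for v in vcf:
        if autosomes_only and not is_autosome(v.CHROM):
            continue
        for site in _split_record(v, samples):
            if small_biallelic_only and not site.is_small_biallelic:
                n_dropped += 1
                continue
            yield site
    if n_dropped:
        log.warning("dropped %d non-SNV/non-small-indel records", n_dropped)


def vcf_samples(path: str | Path) -> list[str]:
    return list(VCF(str(path)).samples)


def write_vcf(
    path: str | Path,
    samples: list[str],
    sites: Iterable[VariantSite],
    contigs: dict[str, int] | None = None,
    phased_gts: dict | None = None,
) -> None:
    """Write a multi-sample VCF with GT:AD:DP:GQ fields.

    ``phased_gts`` may map (chrom, pos, sample_id) -> (paternal, maternal)
    allele indices; those genotypes are written phased (``|``, paternal
    first), everything else unphased.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=triokit\n")
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        gt_str = {HOMREF: "0/0", HET: "0/1", HOMALT: "1/1", MISSING: "./."}
        for site in sites:
            cols = [site.chrom, str(site.pos), ".", site.ref, site.alt, ".", "PASS", ".", "GT:AD:DP:GQ"]
            for sid in samples:
                g = site.genotypes.get(sid)
                if g is None:
                    cols.append("./.:.:.:.")
                    continue
                key = (site.chrom, site.pos, sid)
                if phased_gts and key in phased_gts:
                    pat, mat = phased_gts[key]
                    gt = f"{pat}|{mat}"
                else:
                    gt = gt_str[g.gt]
                cols.append(f"{gt}:{g.ad_ref},{g.ad_alt}:{g.dp}:{g.gq}")
            fh.write("\t".join(cols) + "\n")
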