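"""Pre-phasing quality filters and deterministic trio transmission phasing.

With both parents genotyped, every Mendelian-consistent site that is not
heterozygous in all three members phases deterministically: a homozygous
parent's transmitted allele is forced, which pins the origin of the
offspring's alleles. Triply heterozygous sites are the irreducible
residue and are emitted unphased (resolving them needs a population
haplotype model, which is outside this package).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .pedigree import TrioPedigree
from .variants import HOMALT, HOMREF, MISSING, VariantSite, mendelian_consistent


@dataclass(frozen=True)
class PhasedGenotype:
    """Offspring genotype with parental origin: allele indices 0 (ref) or
    1 (alt), paternal first. ``phased`` is False for the triple-het residue."""

    paternal_allele: int
    maternal_allele: int
    phased: bool

    @property
    def gt(self) -> int:
        return self.paternal_allele + self.maternal_allele


class MendelianInconsistencyError(ValueError):
    """Phasing was asked for a trio genotype impossible under transmission."""


def phase_trio_site(father: int, mother: int, child: int) -> PhasedGenotype:
    """Deterministic transmission phasing of one offspring genotype.

    Homozygous children phase trivially; a heterozygous child phases
    whenever at least one parent is homozygous. Input must be
    Mendelian-consistent (filter first).
    """
    if mendelian_consistent(father, mother, child) is not True:
        raise MendelianInconsistencyError(
            f"cannot phase trio genotype ({father}, {mother}, {child})"
        )
    if child == HOMREF:
        return PhasedGenotype(0, 0, True)
    if child == HOMALT:
        return PhasedGenotype(1, 1, True)
    # heterozygous child: a homozygous parent forces its transmitted allele
    if father == HOMREF or mother == HOMALT:
        return PhasedGenotype(0, 1, True)
    if father == HOMALT or mother == HOMREF:
        return PhasedGenotype(1, 0, True)
    return PhasedGenotype(0, 1, False)  # triply heterozygous: arbitrary order, unphased


@dataclass
class PrephaseLog:
    """Removal log of the pre-phasing filters, one entry per removed site."""

    removed: list[tuple[VariantSite, str]] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out = {"missing_rate": 0, "mendelian_error": 0}
        for _, rule in self.removed:
            out[rule] += 1
        return out


def prephase_filter(
    sites: Iterable[VariantSite],
    trios: Sequence[TrioPedigree],
    max_missing_rate: float = 0.10,
    max_mendel_trios: int = 1,
) -> tuple[list[VariantSite], PrephaseLog]:
    """Drop sites unfit for phasing.

    A site is removed when the missing-genotype fraction across all trio
    samples exceeds ``max_missing_rate``, or when it shows a Mendelian
    error in more than ``max_mendel_trios`` trios (default: two or more
    trios). The log records the triggering rule per removed site.
    """
    sample_ids = [sid for t in trios for sid in t.sample_ids]
    kept: list[VariantSite] = []
    log = PrephaseLog()
    for site in sites:
        n_missing = sum(
            1
            for sid in sample_ids
            if site.genotypes.get(sid) is None or site.genotypes[sid].gt == MISSING
        )
        if n_missing / len(sample_ids) > max_missing_rate:
            log.removed.append((site, "missing_rate"))
            continue
        n_errors = 0
        for t in trios:
            gts = [
                site.genotypes[sid].gt if sid in site.genotypes else MISSING
                for sid in t.sample_ids
            ]
            if mendelian_consistent(*gts) is False:
                n_errors += 1
        if n_errors > max_mendel_trios:
            log.removed.append((site, "mendelian_error"))
            continue
        kept.append(site)
    return kept, log


@dataclass
class PhasingReport:
    n_phased: int = 0
    n_unphased: int = 0
    n_skipped: int = 0  # missing or Mendelian-inconsistent in the trio
    removed_by_rule: dict[str, int] = field(default_factory=dict)


def phase_sites(
    sites: Sequence[VariantSite],
    trio: TrioPedigree,
) -> tuple[dict[tuple[str, int, str], tuple[int, int]], PhasingReport]:
    """Phase all phaseable offspring genotypes for one trio.

    Returns {(chrom, pos, offspring_id) -> (paternal, maternal)} for
    phased sites, plus a report. Missing or Mendelian-inconsistent sites
    are skipped (the pre-phasing filter should already have removed the
    recurrent ones).
    """
    phased: dict[tuple[str, int, str], tuple[int, int]] = {}
    report = PhasingReport()
    for site in sites:
        gts = [
            site.genotypes[sid].gt if sid in site.genotypes else MISSING
            for sid in trio.sample_ids
        ]
        if mendelian_consistent(*gts) is not True:
            report.n_skipped += 1
            continue
        pg = phase_trio_site(*gts)
        if pg.phased:
            phased[(site.chrom, site.pos, trio.offspring_id)] = (
                pg.paternal_allele,
                pg.maternal_allele,
            )
            report.n_phased += 1
        else:
            report.n_unphased += 1
    return phased, report
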