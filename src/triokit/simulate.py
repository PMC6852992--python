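"""Synthetic trio datasets with known ground truth.

Emulates the study design at desk scale: five father-mother-offspring
trios sequenced to ~30x mean depth, with Hardy-Weinberg parental
genotypes at polymorphic sites, Mendelian transmission, planted de novo
SNVs/indels on transmitted reference alleles, per-site Poisson depth,
binomial allele-balance noise, a depth-driven genotype-quality surrogate,
inherited and de novo CNVs, and two noisy pseudo-caller CNV call sets
with matched windowed depth profiles.

The simulated panel stands in for the callable autosome: per-site de novo
rates are scaled up so the per-offspring event counts match the study's,
while the estimator recovers whatever rate was planted.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .cnv import DEL, DUP, CnvCall, DepthProfile
from .intervals import GenomeMask, GenomicInterval
from .pedigree import TrioPedigree, write_ped
from .variants import SiteGenotype, VariantSite, write_vcf

_BASES = "ACGT"
_DEFAULT_POPULATIONS = ("BTQ", "MDQ", "SMI", "DSN", "MRT")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults emulate the study conditions."""

    n_trios: int = 5
    n_sites: int = 1_000_000
    chrom: str = "1"
    chrom_length: int = 100_000_000
    af_min: float = 0.05
    af_max: float = 0.95
    frac_indel: float = 0.15
    # per transmitted-allele, per-site rates on the scaled panel
    dnm_rate_snv: float = 2.0e-4
    dnm_rate_indel: float = 1.5e-4
    depth_mean: float = 30.0
    error_rate: float = 0.001  # stray alt reads on a homref background
    gq_per_depth: float = 3.3
    gq_low_dp: int = 8
    gq_floor: int = 20
    ti_fraction: float = 2.1 / 3.1  # transition share among SNVs
    mask_fraction: float = 0.0
    # CNV model
    n_cnv_per_sample: int = 40
    cnv_denovo_fraction: float = 0.05
    cnv_del_fraction: float = 0.8
    cnv_len_min: int = 2_000
    cnv_len_max: int = 50_000
    cnv_jitter_frac: float = 0.05
    cnv_dropout: float = 0.05
    depth_window: int = 1_000
    # novelty against the synthetic known-variant table (dbSNP stand-in)
    novel_fraction_snv: float = 0.027
    novel_fraction_indel: float = 0.023
    # novel-insertion presence model (proportions follow the study's tallies)
    n_ni: int = 2_000
    ni_inherited_fraction: float = 0.95
    ni_archaic_fraction: float = 0.462
    ni_nea_specific_fraction: float = 0.678
    ni_den_specific_fraction: float = 0.017
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dnm_rate_snv", "dnm_rate_indel", "frac_indel",
                     "cnv_denovo_fraction", "cnv_dropout", "mask_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be > 0")


def default_trios(cfg: SimConfig) -> list[TrioPedigree]:
    trios = []
    for i in range(cfg.n_trios):
        pop = _DEFAULT_POPULATIONS[i % len(_DEFAULT_POPULATIONS)]
        tag = pop if i < len(_DEFAULT_POPULATIONS) else f"{pop}{i}"
        trios.append(
            TrioPedigree(
                trio_id=tag,
                father_id=f"{tag}_fa",
                mother_id=f"{tag}_mo",
                offspring_id=f"{tag}_ch",
                population=pop,
            )
        )
    return trios


@dataclass
class TrioSiteArrays:
    """Per-trio site-level arrays, rows ordered (father, mother, offspring)."""

    trio: TrioPedigree
    gt: np.ndarray  # (3, n) int8
    dp: np.ndarray  # (3, n) int16
    ad_alt: np.ndarray  # (3, n) int16
    gq: np.ndarray  # (3, n) int8
    transmitted: np.ndarray  # (2, n) int8 true (paternal, maternal) child alleles
    dnm_paternal: np.ndarray  # (n,) bool
    dnm_maternal: np.ndarray  # (n,) bool

    @property
    def ad_ref(self) -> np.ndarray:
        return self.dp - self.ad_alt

    @property
    def dnm(self) -> np.ndarray:
        return self.dnm_paternal | self.dnm_maternal


@dataclass
class SimDataset:
    cfg: SimConfig
    trios: list[TrioPedigree]
    pos: np.ndarray  # (n,) 1-based positions, strictly increasing
    is_indel: np.ndarray  # (n,) bool
    ref: np.ndarray  # (n,) base codes 0..3
    alt: np.ndarray  # (n,) base codes (SNV partner; indels append an A)
    af: np.ndarray  # (n,) population allele frequency
    per_trio: list[TrioSiteArrays] = field(default_factory=list)
    mask: GenomeMask | None = None
    rng: np.random.Generator | None = field(default=None, repr=False)

    @property
    def masked(self) -> np.ndarray:
        if self.mask is None:
            return np.zeros(len(self.pos), dtype=bool)
        return self.mask.contains_positions(self.cfg.chrom, self.pos - 1)

    def ref_str(self, i: int) -> str:
        b = _BASES[self.ref[i]]
        return b

    def alt_str(self, i: int) -> str:
        if self.is_indel[i]:
            return _BASES[self.ref[i]] + "A"
        return _BASES[self.alt[i]]


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n strictly increasing 1-based positions <= length."""
    if n >= length:
        raise ValueError("n_sites must be smaller than chrom_length")
    base = np.sort(rng.integers(1, length - n + 1, size=n))
    return base + np.arange(n, dtype=np.int64)


def _rng(seed) -> np.random.Generator:
    """Package RNG: SFC64 keeps the huge simulated panels fast; streams are
    fully determined by the seed."""
    return np.random.Generator(np.random.SFC64(seed))


def _vose_alias(pmf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vose alias tables for an arbitrary finite pmf (exact sampling)."""
    pmf = np.asarray(pmf, dtype=float)
    pmf = pmf / pmf.sum()
    k = len(pmf)
    prob = np.ones(k)
    alias = np.arange(k, dtype=np.int32)
    scaled = list(pmf * k)
    small = [i for i in range(k) if scaled[i] < 1.0]
    large = [i for i in range(k) if scaled[i] >= 1.0]
    while small and large:
        s, l = small.pop(), large.pop()
        prob[s] = scaled[s]
        alias[s] = l
        scaled[l] -= 1.0 - scaled[s]
        (small if scaled[l] < 1.0 else large).append(l)
    return prob, alias


_POISSON_TABLES: dict[float, tuple[np.ndarray, np.ndarray]] = {}
_BINOM_TABLES: dict[tuple[float, int], tuple[np.ndarray, np.ndarray]] = {}


def _poisson_support(lam: float) -> int:
    return int(lam + 12.0 * lam ** 0.5) + 2


def _poisson_depths(rng: np.random.Generator, lam: float, size) -> np.ndarray:
    """Poisson(lam) read depths truncated below at 1.

    Sampled by the alias method over the (numerically complete) support;
    orders of magnitude faster than the generic sampler at panel scale.
    """
    tables = _POISSON_TABLES.get(lam)
    if tables is None:
        from scipy.stats import poisson as _pois

        tables = _vose_alias(_pois.pmf(np.arange(_poisson_support(lam)), lam))
        _POISSON_TABLES[lam] = tables
    prob, alias = tables
    k = len(prob)
    idx = (rng.random(size) * k).astype(np.int32)
    out = np.where(rng.random(size) < prob[idx], idx, alias[idx]).astype(np.int16)
    return np.maximum(out, 1)


def _binomial_class_tables(error_rate: float, dmax: int) -> tuple[np.ndarray, np.ndarray]:
    """Flattened alias tables for Binomial(d, p) with p per genotype class.

    Class c in (0, 1, 2) maps to p = error_rate, 1/2, 1 - error_rate; rows
    are indexed by (c, d) and padded to a common width of dmax + 1.
    """
    key = (error_rate, dmax)
    tables = _BINOM_TABLES.get(key)
    if tables is None:
        from scipy.stats import binom as _binom

        width = dmax + 1
        prob = np.ones((3, width, width))
        alias = np.zeros((3, width, width), dtype=np.int32)
        for c, p in enumerate((error_rate, 0.5, 1.0 - error_rate)):
            for d in range(width):
                pr, al = _vose_alias(_binom.pmf(np.arange(d + 1), d, p))
                prob[c, d, : d + 1] = pr
                alias[c, d, : d + 1] = al
        tables = (prob.reshape(-1), alias.reshape(-1))
        _BINOM_TABLES[key] = tables
    return tables


def _binomial_reads(rng: np.random.Generator, gt: np.ndarray, dp: np.ndarray,
                    error_rate: float, dmax: int) -> np.ndarray:
    """Alt-read counts ~ Binomial(dp, p[gt]) via per-(class, depth) alias tables."""
    prob, alias = _binomial_class_tables(error_rate, dmax)
    width = dmax + 1
    kk = (rng.random(gt.shape) * (dp + 1)).astype(np.int32)
    flat = (gt.astype(np.int32) * width + dp) * width + kk
    out = np.where(rng.random(gt.shape) < prob[flat], kk, alias[flat])
    return out.astype(np.int16)


def _genotype_quality(cfg: SimConfig, dp: np.ndarray) -> np.ndarray:
    depths = np.arange(int(dp.max()) + 1)
    table = np.minimum(99, np.rint(cfg.gq_per_depth * depths)).astype(np.int8)
    low = depths < cfg.gq_low_dp
    table[low] = np.maximum(table[low], cfg.gq_floor)
    return table[dp]


def _simulate_trio(cfg: SimConfig, trio: TrioPedigree, af: np.ndarray,
                   is_indel: np.ndarray, rng: np.random.Generator) -> TrioSiteArrays:
    n = len(af)
    gt = np.empty((3, n), dtype=np.int8)
    for parent in (0, 1):
        gt[parent] = (rng.random(n) < af).astype(np.int8) + (rng.random(n) < af).astype(np.int8)
    transmitted = np.empty((2, n), dtype=np.int8)
    rate = np.where(is_indel, cfg.dnm_rate_indel, cfg.dnm_rate_snv)
    dnm = []
    for parent in (0, 1):
        g = gt[parent]
        allele = np.where(g == 1, rng.integers(0, 2, n).astype(np.int8), (g // 2).astype(np.int8))
        mut = (rng.random(n) < rate) & (allele == 0)
        allele = allele | mut.astype(np.int8)
        transmitted[parent] = allele
        dnm.append(mut)
    gt[2] = transmitted.sum(axis=0)
    dp = _poisson_depths(rng, cfg.depth_mean, (3, n))
    ad_alt = _binomial_reads(rng, gt, dp, cfg.error_rate,
                             _poisson_support(cfg.depth_mean) - 1)
    gq = _genotype_quality(cfg, dp)
    return TrioSiteArrays(trio, gt, dp, ad_alt, gq, transmitted, dnm[0], dnm[1])


def simulate_mask(cfg: SimConfig, rng: np.random.Generator) -> GenomeMask | None:
    """Random exclusion mask covering ~mask_fraction of the chromosome."""
    if cfg.mask_fraction <= 0:
        return None
    n_iv = 50
    iv_len = int(cfg.mask_fraction * cfg.chrom_length / n_iv)
    starts = rng.integers(0, cfg.chrom_length - iv_len, size=n_iv)
    return GenomeMask(
        "exclude",
        (GenomicInterval(cfg.chrom, int(s), int(s) + iv_len) for s in starts),
    )


def simulate_panel(cfg: SimConfig, trios: list[TrioPedigree] | None = None) -> SimDataset:
    """Simulate the dataset-level arrays (sites, alleles, frequencies, mask).

    Per-trio genotype arrays are generated lazily by ``iter_trio_arrays``
    so large panels can be processed one trio at a time.
    """
    rng = _rng(cfg.seed)
    trios = trios if trios is not None else default_trios(cfg)
    n = cfg.n_sites
    pos = _draw_positions(rng, n, cfg.chrom_length)
    is_indel = rng.random(n) < cfg.frac_indel
    ref = rng.integers(0, 4, n).astype(np.uint8)
    # transition partner is ref XOR 2 under the ACGT encoding
    is_ti = rng.random(n) < cfg.ti_fraction
    tv_pick = rng.integers(0, 2, n).astype(np.uint8)
    alt = np.where(is_ti, ref ^ 2, np.where(tv_pick == 0, ref ^ 1, ref ^ 3)).astype(np.uint8)
    af = rng.uniform(cfg.af_min, cfg.af_max, n)
    mask = simulate_mask(cfg, rng)
    return SimDataset(cfg, trios, pos, is_indel, ref, alt, af, mask=mask, rng=rng)


def iter_trio_arrays(ds: SimDataset):
    """Yield per-trio genotype arrays one at a time (streaming)."""
    for trio in ds.trios:
        yield _simulate_trio(ds.cfg, trio, ds.af, ds.is_indel, ds.rng)


def simulate_sites(cfg: SimConfig, trios: list[TrioPedigree] | None = None) -> SimDataset:
    """Simulate the full multi-trio genotype panel (arrays in memory)."""
    ds = simulate_panel(cfg, trios)
    ds.per_trio = list(iter_trio_arrays(ds))
    return ds


def dataset_to_sites(ds: SimDataset) -> Iterator[VariantSite]:
    """Materialise VariantSite objects (small-n object pipeline and VCF I/O)."""
    cfg = ds.cfg
    for i in range(len(ds.pos)):
        site = VariantSite(cfg.chrom, int(ds.pos[i]), ds.ref_str(i), ds.alt_str(i))
        for arr in ds.per_trio:
            for row, sid in enumerate(arr.trio.sample_ids):
                site.genotypes[sid] = SiteGenotype(
                    sid,
                    int(arr.gt[row, i]),
                    int(arr.dp[row, i] - arr.ad_alt[row, i]),
                    int(arr.ad_alt[row, i]),
                    int(arr.dp[row, i]),
                    int(arr.gq[row, i]),
                )
        yield site


def truth_frame(ds: SimDataset) -> pd.DataFrame:
    """Planted de novo events: one row per (trio, site, parental channel)."""
    rows = []
    for arr in ds.per_trio:
        for channel, flags in (("paternal", arr.dnm_paternal), ("maternal", arr.dnm_maternal)):
            for i in np.nonzero(flags)[0]:
                rows.append(
                    (arr.trio.trio_id, ds.cfg.chrom, int(ds.pos[i]),
                     "indel" if ds.is_indel[i] else "snv", channel)
                )
    df = pd.DataFrame(rows, columns=["trio", "chrom", "pos", "vtype", "channel"])
    return df.sort_values(["trio", "pos"]).reset_index(drop=True)


def write_dataset(ds: SimDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write VCF, PED, truth table and (if present) the mask BED."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "trios.vcf",
        "ped": out / "trios.ped",
        "truth": out / "truth_dnm.tsv",
    }
    samples = [sid for arr in ds.per_trio for sid in arr.trio.sample_ids]
    write_vcf(paths["vcf"], samples, dataset_to_sites(ds),
              contigs={ds.cfg.chrom: ds.cfg.chrom_length})
    write_ped(ds.trios, paths["ped"])
    truth_frame(ds).to_csv(paths["truth"], sep="\t", index=False)
    if ds.mask is not None:
        paths["mask"] = out / "mask_exclude.bed"
        ds.mask.to_bed(paths["mask"])
    return paths


def simulate_trio_vcf(cfg: SimConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate and write the trio genotype panel; returns output paths."""
    return write_dataset(simulate_sites(cfg), out_dir)


def known_variant_keys(ds: SimDataset) -> set[tuple[str, int, str, str]]:
    """Synthetic known-variant table: every site except a ``novel_fraction``
    share, drawn independently per vtype (the dbSNP stand-in)."""
    cfg = ds.cfg
    rng = _rng([cfg.seed, 303])
    novel = np.where(
        ds.is_indel,
        rng.random(len(ds.pos)) < cfg.novel_fraction_indel,
        rng.random(len(ds.pos)) < cfg.novel_fraction_snv,
    )
    # the second rng.random stream above is consumed for both branches of the
    # np.where, so novelty flags stay reproducible but vtype-dependent
    return {
        (cfg.chrom, int(ds.pos[i]), ds.ref_str(i), ds.alt_str(i))
        for i in np.nonzero(~novel)[0]
    }


def simulate_ni_records(cfg: SimConfig, trios: list[TrioPedigree] | None = None):
    """Synthetic novel-insertion presence tables, one list per trio.

    Most insertions are inherited (offspring plus at least one parent); a
    small remainder is offspring-only or parent-only. Archaic-sharing flags
    follow the configured Neanderthal/Denisovan-specific and shared-with-
    both proportions.
    """
    from .summaries import NiRecord

    rng = _rng([cfg.seed, 404])
    trios = trios if trios is not None else default_trios(cfg)
    per_trio: dict[str, list[NiRecord]] = {}
    for trio in trios:
        records = []
        for i in range(cfg.n_ni):
            u = rng.random()
            if u < cfg.ni_inherited_fraction:
                parents = ["father", "mother", "both"][int(rng.integers(0, 3))]
                presence = {
                    trio.offspring_id: True,
                    trio.father_id: parents in ("father", "both"),
                    trio.mother_id: parents in ("mother", "both"),
                }
            elif u < cfg.ni_inherited_fraction + 0.03:
                presence = {trio.offspring_id: True, trio.father_id: False,
                            trio.mother_id: False}
            else:
                presence = {trio.offspring_id: False, trio.father_id: True,
                            trio.mother_id: rng.random() < 0.5}
            nea = den = False
            if rng.random() < cfg.ni_archaic_fraction:
                v = rng.random()
                if v < cfg.ni_nea_specific_fraction:
                    nea = True
                elif v < cfg.ni_nea_specific_fraction + cfg.ni_den_specific_fraction:
                    den = True
                else:
                    nea = den = True
            records.append(NiRecord(f"{trio.trio_id}_NI{i:05d}", presence, nea, den))
        per_trio[trio.trio_id] = records
    return per_trio


def write_ni_tables(per_trio, trios: list[TrioPedigree], out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for trio in trios:
        rows = [
            {
                "ni_id": r.ni_id,
                **{sid: int(r.presence[sid]) for sid in trio.sample_ids},
                "in_neanderthal": int(r.in_neanderthal),
                "in_denisovan": int(r.in_denisovan),
            }
            for r in per_trio[trio.trio_id]
        ]
        p = out / f"ni_{trio.trio_id}.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths[trio.trio_id] = p
    return paths


# ---------------------------------------------------------------------------
# CNV simulation
# ---------------------------------------------------------------------------

@dataclass
class CnvSim:
    cfg: SimConfig
    trios: list[TrioPedigree]
    truth: list[CnvCall]  # true per-sample events (caller field: "truth")
    truth_denovo: list[CnvCall]  # offspring-only planted events
    calls_a: dict[str, list[CnvCall]]  # sample -> caller A calls
    calls_b: dict[str, list[CnvCall]]
    depth_profiles: dict[str, DepthProfile]


def _jitter(iv: GenomicInterval, frac: float, rng: np.random.Generator,
            chrom_length: int) -> GenomicInterval:
    if frac <= 0:
        return iv
    j = max(1, int(frac * iv.length))
    s = iv.start + int(rng.integers(-j, j + 1))
    e = iv.end + int(rng.integers(-j, j + 1))
    s = max(0, s)
    e = min(chrom_length, max(e, s + 2))
    return GenomicInterval(iv.chrom, s, e)


def simulate_cnv_callsets(cfg: SimConfig, trios: list[TrioPedigree] | None = None) -> CnvSim:
    """Plant inherited and de novo CNVs; emit two noisy pseudo-caller sets.

    Inherited CNV alleles segregate at population loci and transmit by
    Mendelian rules on presence; de novo CNVs are offspring-only deletions.
    Each caller observes every true event minus dropout, with breakpoint
    jitter proportional to event length. Windowed depth profiles reflect
    true copy number, so depth-based re-genotyping is exercisable.
    """
    rng = _rng([cfg.seed, 202])
    trios = trios if trios is not None else default_trios(cfg)
    carrier_p = 0.47  # P(sample carries a locus) at freq ~ U(0.05, 0.5)
    n_loci = max(1, round(cfg.n_cnv_per_sample / carrier_p))
    n_denovo_slots = cfg.n_trios * 8
    slots = n_loci + n_denovo_slots
    slot_len = cfg.chrom_length // slots
    if slot_len <= cfg.cnv_len_max * 2:
        raise ValueError("chrom_length too small for the requested CNV density")
    order = rng.permutation(slots)
    loci_slots, denovo_slots = order[:n_loci], order[n_loci:]

    def make_interval(slot: int) -> GenomicInterval:
        length = int(np.exp(rng.uniform(np.log(cfg.cnv_len_min), np.log(cfg.cnv_len_max))))
        start = slot * slot_len + int(rng.integers(0, slot_len - length))
        return GenomicInterval(cfg.chrom, start, start + length)

    loci = []
    for slot in loci_slots:
        iv = make_interval(int(slot))
        svtype = DEL if rng.random() < cfg.cnv_del_fraction else DUP
        freq = rng.uniform(0.05, 0.5)
        loci.append((iv, svtype, freq))

    truth: list[CnvCall] = []
    truth_denovo: list[CnvCall] = []
    events: dict[str, list[tuple[GenomicInterval, str, int]]] = {}
    for trio in trios:
        f_alleles, m_alleles = [], []
        for iv, svtype, freq in loci:
            fg = int(rng.random() < freq) + int(rng.random() < freq)
            mg = int(rng.random() < freq) + int(rng.random() < freq)
            f_alleles.append(fg)
            m_alleles.append(mg)
        c_alleles = []
        for fg, mg in zip(f_alleles, m_alleles):
            pat = fg // 2 if fg != 1 else int(rng.integers(0, 2))
            mat = mg // 2 if mg != 1 else int(rng.integers(0, 2))
            c_alleles.append(pat + mat)
        for sid, alleles in zip(trio.sample_ids, (f_alleles, m_alleles, c_alleles)):
            for (iv, svtype, _), k in zip(loci, alleles):
                if k == 0:
                    continue
                cn = 2 - k if svtype == DEL else 2 + k
                call = CnvCall(sid, iv, svtype, cn, "truth")
                truth.append(call)
                events.setdefault(sid, []).append((iv, svtype, cn))
        n_dn = rng.poisson(cfg.n_cnv_per_sample * cfg.cnv_denovo_fraction)
        for _ in range(int(n_dn)):
            slot = int(denovo_slots[rng.integers(0, len(denovo_slots))])
            iv = make_interval(slot)
            call = CnvCall(trio.offspring_id, iv, DEL, 1, "truth")
            truth.append(call)
            truth_denovo.append(call)
            events.setdefault(trio.offspring_id, []).append((iv, DEL, 1))

    calls_a: dict[str, list[CnvCall]] = {}
    calls_b: dict[str, list[CnvCall]] = {}
    all_samples = [sid for t in trios for sid in t.sample_ids]
    for sid in all_samples:
        for caller, store in (("caller_A", calls_a), ("caller_B", calls_b)):
            store[sid] = []
            for iv, svtype, cn in events.get(sid, []):
                if rng.random() < cfg.cnv_dropout:
                    continue
                jv = _jitter(iv, cfg.cnv_jitter_frac, rng, cfg.chrom_length)
                store[sid].append(CnvCall(sid, jv, svtype, cn, caller))

    n_windows = cfg.chrom_length // cfg.depth_window
    profiles = {}
    for sid in all_samples:
        depth = rng.normal(cfg.depth_mean, 0.5, n_windows)
        for iv, svtype, cn in events.get(sid, []):
            lo = iv.start // cfg.depth_window
            hi = (iv.end - 1) // cfg.depth_window + 1
            idx = np.arange(lo, min(hi, n_windows))
            w_start = np.maximum(idx * cfg.depth_window, iv.start)
            w_end = np.minimum((idx + 1) * cfg.depth_window, iv.end)
            frac = (w_end - w_start) / cfg.depth_window
            depth[idx] *= 1.0 - frac * (1.0 - cn / 2.0)
        profiles[sid] = DepthProfile(sid, cfg.depth_window, {cfg.chrom: depth})
    return CnvSim(cfg, trios, truth, truth_denovo, calls_a, calls_b, profiles)


def write_cnv_sim(sim: CnvSim, out_dir: str | Path) -> dict[str, Path]:
    from .cnv import write_cnv_calls

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "calls_a": out / "cnv_caller_A.tsv",
        "calls_b": out / "cnv_caller_B.tsv",
        "truth": out / "truth_cnv.tsv",
        "depth": out / "depth_profiles.tsv",
    }
    write_cnv_calls([c for cs in sim.calls_a.values() for c in cs], paths["calls_a"])
    write_cnv_calls([c for cs in sim.calls_b.values() for c in cs], paths["calls_b"])
    denovo_ids = {id(c) for c in sim.truth_denovo}
    rows = [
        dict(sample=c.sample_id, chrom=c.interval.chrom, start=c.interval.start,
             end=c.interval.end, svtype=c.svtype, copy_number=c.copy_number,
             denovo=id(c) in denovo_ids)
        for c in sim.truth
    ]
    pd.DataFrame(rows).to_csv(paths["truth"], sep="\t", index=False)
    pd.concat([p.to_frame() for p in sim.depth_profiles.values()]).to_csv(
        paths["depth"], sep="\t", index=False
    )
    return paths
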