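"""End-to-end orchestration: simulate/load -> filter -> estimate -> report.

Runs the de novo SNV/indel cascade, the CNV ensemble pipeline, the genome
summaries and trio phasing in order, and writes per-trio TSV reports in
the layout of the study's three summary tables plus a machine-readable
run manifest.
"""
from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .cnv import (
    DEL,
    DUP,
    DepthProfile,
    build_cnv_regions,
    classify_sharing,
    detect_denovo_cnv,
    estimate_cnv_rate,
    merge_callsets,
    read_cnv_calls,
)
from .denovo import DenovoCall, DenovoCriteria, denovo_scan
from .intervals import GenomeMask
from .pedigree import TrioPedigree, read_ped
from .phasing import phase_sites, prephase_filter
from .simulate import (
    SimConfig,
    dataset_to_sites,
    known_variant_keys,
    simulate_cnv_callsets,
    simulate_ni_records,
    simulate_sites,
)
from .summaries import (
    heterozygosity_proportion,
    hotspot_scan,
    ni_summary,
    novelty_rate,
    read_known_variants,
    read_ni_table,
    titv_ratio,
)
from .variants import HET, HOMALT, SNV, read_vcf, write_vcf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and the output directory for one pipeline run.

    When ``vcf`` is unset the synthetic generator provides every input.
    Threshold defaults are the study's: DP 10-120, AB 0.3-0.7, GQ >= 50,
    50% reciprocal overlap for CNV concordance.
    """

    out_dir: str = "triokit_run"
    seed: int = 0
    # inputs (all optional; simulated when absent)
    vcf: str | None = None
    ped: str | None = None
    masks: dict[str, str] = field(default_factory=dict)  # name -> BED path
    cnv_calls_a: str | None = None
    cnv_calls_b: str | None = None
    depth_profiles: str | None = None
    known_variants: str | None = None
    ni_tables: dict[str, str] = field(default_factory=dict)  # trio -> TSV path
    telo_centro_bed: str | None = None
    # thresholds (study defaults)
    dp_min: int = 10
    dp_max: int = 120
    ab_min: float = 0.3
    ab_max: float = 0.7
    gq_min: int = 50
    reciprocal_threshold: float = 0.5
    hotspot_top_frac: float = 0.01
    prephase_max_missing: float = 0.10
    match_svtype: bool = False
    # simulation size (used only when no VCF is supplied)
    sim_n_sites: int = 50_000
    sim_n_trios: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def criteria(self) -> DenovoCriteria:
        return DenovoCriteria(self.dp_min, self.dp_max, self.ab_min,
                              self.ab_max, self.gq_min)


@dataclass
class RunResult:
    trios: list[TrioPedigree]
    denovo_calls: list[DenovoCall]
    table1: pd.DataFrame  # per-sample summary stats
    table2: pd.DataFrame  # per-trio de novo counts and rates
    table3: pd.DataFrame  # per-trio NI tallies
    cnv_summary: dict[str, Any]
    hotspots: pd.DataFrame
    phasing: pd.DataFrame
    manifest: dict[str, Any]


def _thresholds_dict(cfg: RunConfig) -> dict[str, Any]:
    return {
        "dp_min": cfg.dp_min, "dp_max": cfg.dp_max,
        "ab_min": cfg.ab_min, "ab_max": cfg.ab_max, "gq_min": cfg.gq_min,
        "reciprocal_threshold": cfg.reciprocal_threshold,
        "hotspot_top_frac": cfg.hotspot_top_frac,
        "prephase_max_missing": cfg.prephase_max_missing,
        "cnv_min_len": 100,
    }


def run_pipeline(cfg: RunConfig) -> RunResult:
    """Execute the full analysis and write the report bundle.

    Missing required inputs fail fast with the offending path; with no VCF
    configured, all inputs come from the synthetic generator under
    ``cfg.seed``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    crit = cfg.criteria
    for path in [cfg.vcf, cfg.ped, cfg.cnv_calls_a, cfg.cnv_calls_b,
                 cfg.depth_profiles, cfg.known_variants, cfg.telo_centro_bed,
                 *cfg.masks.values(), *cfg.ni_tables.values()]:
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"configured input does not exist: {path}")

    masks = {name: GenomeMask.from_bed(name, p) for name, p in cfg.masks.items()}

    # --- inputs -----------------------------------------------------------
    simulated = cfg.vcf is None
    if simulated:
        sim_cfg = SimConfig(n_trios=cfg.sim_n_trios, n_sites=cfg.sim_n_sites,
                            seed=cfg.seed)
        ds = simulate_sites(sim_cfg)
        trios = ds.trios
        sites = list(dataset_to_sites(ds))
        known = known_variant_keys(ds)
        cnv_sim = simulate_cnv_callsets(sim_cfg, trios)
        calls_a, calls_b = cnv_sim.calls_a, cnv_sim.calls_b
        profiles = cnv_sim.depth_profiles
        ni_per_trio = simulate_ni_records(sim_cfg, trios)
        chrom_sizes = {sim_cfg.chrom: sim_cfg.chrom_length}
    else:
        if cfg.ped is None:
            raise FileNotFoundError("a PED file is required alongside the VCF")
        trios = read_ped(cfg.ped)
        sites = list(read_vcf(cfg.vcf))
        known = read_known_variants(cfg.known_variants) if cfg.known_variants else set()
        calls_a, calls_b = {}, {}
        for src, store in ((cfg.cnv_calls_a, calls_a), (cfg.cnv_calls_b, calls_b)):
            if src:
                for c in read_cnv_calls(src):
                    store.setdefault(c.sample_id, []).append(c)
        profiles = DepthProfile.read_tsv(cfg.depth_profiles) if cfg.depth_profiles else {}
        ni_per_trio = {
            tid: read_ni_table(p, next(t.sample_ids for t in trios if t.trio_id == tid))
            for tid, p in cfg.ni_tables.items()
        }
        chrom_sizes = {}
        for s in sites:
            chrom_sizes[s.chrom] = max(chrom_sizes.get(s.chrom, 0), s.pos)

    telo_centro = (GenomeMask.from_bed("telo_centro", cfg.telo_centro_bed)
                   if cfg.telo_centro_bed else None)

    # --- de novo SNV/indel ------------------------------------------------
    calls, rates = denovo_scan(sites, trios, crit, masks)
    rate_lookup = {(r.trio_id, r.vtype): r for r in rates}

    # --- CNV pipeline -----------------------------------------------------
    merged: dict[str, list] = {}
    for sid in {c.sample_id for cs in (*calls_a.values(), *calls_b.values()) for c in cs}:
        merged[sid] = merge_callsets(
            calls_a.get(sid, []), calls_b.get(sid, []),
            repeat_masks=[m for n, m in masks.items() if "repeat" in n or "lowcomplex" in n],
            gap_segdup_masks=[m for n, m in masks.items() if "gap" in n or "segdup" in n],
            threshold=cfg.reciprocal_threshold,
        )
    cnv_denovo: dict[str, list] = {}
    cnv_rows = []
    for trio in trios:
        dn, _reports = detect_denovo_cnv(
            merged.get(trio.offspring_id, []),
            merged.get(trio.father_id, []),
            merged.get(trio.mother_id, []),
            profiles, trio.father_id, trio.mother_id,
            threshold=cfg.reciprocal_threshold,
        )
        cnv_denovo[trio.trio_id] = dn
        n_total = sum(len(merged.get(sid, [])) for sid in trio.sample_ids)
        rate, rate_rounded = (estimate_cnv_rate(len(dn), n_total)
                              if n_total else (float("nan"), float("nan")))
        cnv_rows.append((trio.trio_id, len(dn), n_total, rate, rate_rounded))

    all_merged = [c for cs in merged.values() for c in cs]
    n_del = sum(1 for c in all_merged if c.svtype == DEL)
    n_dup = sum(1 for c in all_merged if c.svtype == DUP)
    regions = build_cnv_regions(
        {t.trio_id: [c for sid in t.sample_ids for c in merged.get(sid, [])] for t in trios},
        threshold=cfg.reciprocal_threshold,
    )
    sharing_counts: dict[str, int] = {}
    for region in regions:
        sharing_counts[classify_sharing(region, trios)] = (
            sharing_counts.get(region.sharing_class, 0) + 1
        )
    cnv_summary = {
        "n_total": len(all_merged),
        "n_deletions": n_del,
        "n_duplications": n_dup,
        "n_regions": len(regions),
        "sharing": sharing_counts,
        "n_denovo_total": sum(len(v) for v in cnv_denovo.values()),
    }

    # --- summaries --------------------------------------------------------
    t1_rows = []
    for trio in trios:
        for sid in trio.sample_ids:
            counts = {"snv": [0, 0], "indel": [0, 0]}  # [het, homalt]
            subs, keys_snv, keys_indel = [], [], []
            for s in sites:
                g = s.genotypes.get(sid)
                if g is None or g.gt not in (HET, HOMALT):
                    continue
                vt = s.vtype
                counts[vt][0 if g.gt == HET else 1] += 1
                key = (s.chrom, s.pos, s.ref, s.alt)
                if vt == SNV:
                    subs.append((s.ref, s.alt))
                    keys_snv.append(key)
                else:
                    keys_indel.append(key)
            t1_rows.append({
                "trio": trio.trio_id, "sample": sid,
                "n_snv": len(keys_snv), "n_indel": len(keys_indel),
                "titv": titv_ratio(subs) if subs else float("nan"),
                "het_prop_snv": heterozygosity_proportion(*counts["snv"])
                if sum(counts["snv"]) else float("nan"),
                "het_prop_indel": heterozygosity_proportion(*counts["indel"])
                if sum(counts["indel"]) else float("nan"),
                "novelty_snv": novelty_rate(keys_snv, known) if keys_snv else float("nan"),
                "novelty_indel": novelty_rate(keys_indel, known) if keys_indel else float("nan"),
            })
    table1 = pd.DataFrame(t1_rows)

    def _qc_stream(vtype: str):
        for s in sites:
            if s.vtype != vtype:
                continue
            for g in s.genotypes.values():
                if g.gt in (HET, HOMALT):
                    yield (s.chrom, s.pos, g.dp, g.gq, g.ad_ref, g.ad_alt)

    hotspot_rows = []
    for vtype in (SNV, "indel"):
        for wc in hotspot_scan(_qc_stream(vtype), chrom_sizes, telo_centro,
                               crit, cfg.hotspot_top_frac):
            hotspot_rows.append({"vtype": vtype, "chrom": wc.interval.chrom,
                                 "start": wc.interval.start, "end": wc.interval.end,
                                 "n_pass": wc.n_pass})
    hotspots = pd.DataFrame(hotspot_rows)

    table3_rows = []
    for trio in trios:
        if trio.trio_id not in ni_per_trio:
            continue
        s = ni_summary(ni_per_trio[trio.trio_id], trio)
        table3_rows.append({"trio": trio.trio_id, **s})
    table3 = pd.DataFrame(table3_rows)

    # --- phasing ----------------------------------------------------------
    kept, prelog = prephase_filter(sites, trios, cfg.prephase_max_missing)
    phased_all: dict = {}
    phase_rows = []
    for trio in trios:
        phased, report = phase_sites(kept, trio)
        phased_all.update(phased)
        phase_rows.append({
            "trio": trio.trio_id, "n_phased": report.n_phased,
            "n_unphased_triple_het": report.n_unphased, "n_skipped": report.n_skipped,
        })
    phasing = pd.DataFrame(phase_rows)
    pre_counts = prelog.counts()

    # --- table 2 ----------------------------------------------------------
    t2_rows = []
    for trio, (tid, n_dn_cnv, n_tot_cnv, rate, rate_r) in zip(trios, cnv_rows):
        row = {"trio": tid, "population": trio.population, "group": trio.group}
        for vt in ("snv", "indel"):
            r = rate_lookup.get((tid, vt))
            row[f"n_denovo_{vt}"] = r.n_dnm if r else 0
            row[f"mu_{vt}"] = r.mu if r else float("nan")
            row[f"callability_{vt}"] = r.callability_sum if r else 0.0
        row.update({"n_denovo_cnv": n_dn_cnv, "n_total_cnv": n_tot_cnv,
                    "cnv_rate": rate, "cnv_rate_reported": rate_r})
        t2_rows.append(row)
    table2 = pd.DataFrame(t2_rows)

    manifest = {
        "triokit_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "simulated_inputs": simulated,
        "n_sites": len(sites),
        "thresholds": _thresholds_dict(cfg),
        "prephase_removed": pre_counts,
    }

    # --- outputs ----------------------------------------------------------
    table1.to_csv(out / "table1_sample_summary.tsv", sep="\t", index=False)
    table2.to_csv(out / "table2_denovo_rates.tsv", sep="\t", index=False)
    table3.to_csv(out / "table3_novel_insertions.tsv", sep="\t", index=False)
    hotspots.to_csv(out / "hotspots.tsv", sep="\t", index=False)
    phasing.to_csv(out / "phasing_report.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"trio": c.trio_id, "chrom": c.site.chrom, "pos": c.site.pos,
          "ref": c.site.ref, "alt": c.site.alt, "vtype": c.vtype,
          "child_gt": c.site.genotypes[
              next(t for t in trios if t.trio_id == c.trio_id).offspring_id].gt_name,
          "child_ab": round(c.child_ab, 4),
          "criteria_passed": ",".join(k for k, v in c.audit.items() if v)}
         for c in calls]
    ).to_csv(out / "denovo_small.tsv", sep="\t", index=False)
    with open(out / "cnv_summary.json", "w") as fh:
        json.dump(cnv_summary, fh, indent=2)
    samples = [sid for t in trios for sid in t.sample_ids]
    write_vcf(out / "phased.vcf", samples, kept,
              contigs=chrom_sizes, phased_gts=phased_all)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)

    return RunResult(trios, calls, table1, table2, table3, cnv_summary,
                     hotspots, phasing, manifest)
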