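"""Reusable validation experiments on synthetic data.

These drive the generator and the de novo machinery at scale and return
summary numbers; both the test suite and the reproduction script build on
them.
"""
from __future__ import annotations

import numpy as np

from .denovo import (
    DenovoCriteria,
    callability_arrays,
    classify_denovo_arrays,
    estimate_snv_rate,
)
from .simulate import SimConfig, iter_trio_arrays, simulate_panel


def estimate_rate_from_panel(
    cfg: SimConfig, crit: DenovoCriteria = DenovoCriteria()
) -> tuple[float, int, float]:
    """Simulate one panel and estimate the pooled SNV mutation rate.

    Streams trios to bound memory. Returns (mu, n_called, callability_sum)
    pooled over all trios: mu = total calls / (2 * total callability).
    """
    ds = simulate_panel(cfg)
    masked = ds.masked
    n_called, csum = 0, 0.0
    for arr in iter_trio_arrays(ds):
        called, _ = classify_denovo_arrays(arr.gt, arr.dp, arr.ad_alt, arr.gq, masked, crit)
        n_called += int(called.sum())
        csum += float(callability_arrays(arr.gt, arr.dp, arr.ad_alt, arr.gq, masked, crit).sum())
        del arr
    return estimate_snv_rate(n_called, csum).mu, n_called, csum


def snv_rate_recovery(
    true_rate: float = 1.0e-6,
    n_trios: int = 5,
    n_sites: int = 10_000_000,
    n_seeds: int = 20,
    base_seed: int = 0,
    crit: DenovoCriteria = DenovoCriteria(),
) -> np.ndarray:
    """Per-seed pooled mutation-rate estimates on panels with a planted rate.

    Each seed simulates ``n_trios`` trios at ``n_sites`` sites with de novo
    SNVs planted at ``true_rate`` per transmitted allele per site, then runs
    the full cascade and the callability-based estimator.
    """
    mus = []
    for s in range(n_seeds):
        cfg = SimConfig(
            n_trios=n_trios,
            n_sites=n_sites,
            dnm_rate_snv=true_rate,
            dnm_rate_indel=0.0,
            frac_indel=0.0,
            seed=base_seed + s,
        )
        mu, _, _ = estimate_rate_from_panel(cfg, crit)
        mus.append(mu)
    return np.asarray(mus)
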