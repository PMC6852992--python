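import math

import numpy as np
import pytest

from triokit.denovo import (
    DenovoCall,
    DenovoCriteria,
    DenovoRejection,
    ab_band_probability,
    callability_arrays,
    classify_denovo,
    classify_denovo_arrays,
    estimate_snv_rate,
    site_callability,
)
from triokit.intervals import GenomeMask, GenomicInterval
from triokit.pedigree import TrioPedigree
from triokit.simulate import SimConfig, simulate_sites
from triokit.variants import HET, HOMALT, HOMREF, SiteGenotype, VariantSite

TRIO = TrioPedigree("BTQ", "fa", "mo", "ch", "BTQ")


def make_site(child, father=None, mother=None, pos=1000):
    father = father or SiteGenotype("fa", HOMREF, 30, 0, 30, 99)
    mother = mother or SiteGenotype("mo", HOMREF, 30, 0, 30, 99)
    s = VariantSite("1", pos, "A", "G")
    s.genotypes = {"fa": father, "mo": mother, "ch": child}
    return s


class TestClassifyDenovo:
    def test_clean_candidate_is_called(self):
        site = make_site(SiteGenotype("ch", HET, 15, 15, 30, 99))
        res = classify_denovo(site, TRIO)
        assert isinstance(res, DenovoCall)
        assert res.child_ab == 0.5
        assert all(res.audit.values())

    def test_single_parental_alt_read_fails_criterion_iv(self):
        site = make_site(
            SiteGenotype("ch", HET, 15, 15, 30, 99),
            father=SiteGenotype("fa", HOMREF, 28, 2, 30, 99),
        )
        res = classify_denovo(site, TRIO)
        assert isinstance(res, DenovoRejection)
        assert res.reason == "iv"

    def test_homref_child_fails_criterion_v(self):
        site = make_site(SiteGenotype("ch", HOMREF, 30, 0, 30, 99))
        res = classify_denovo(site, TRIO)
        assert res.reason == "v"

    def test_low_allele_balance_fails_criterion_ii(self):
        site = make_site(SiteGenotype("ch", HET, 22, 8, 30, 99))
        res = classify_denovo(site, TRIO)
        assert res.reason == "ii"
        assert 8 / 30 < 0.3

    def test_masked_site_fails_criterion_i(self):
        masks = {"repeats": GenomeMask("repeats", [GenomicInterval("1", 900, 1100)])}
        site = make_site(SiteGenotype("ch", HET, 15, 15, 30, 99))
        res = classify_denovo(site, TRIO, masks=masks)
        assert res.reason == "i"

    def test_low_parent_gq_fails_criterion_iii(self):
        site = make_site(
            SiteGenotype("ch", HET, 15, 15, 30, 99),
            mother=SiteGenotype("mo", HOMREF, 30, 0, 30, 49),
        )
        assert classify_denovo(site, TRIO).reason == "iii"

    def test_missing_genotype_is_reported_as_missing(self):
        site = make_site(SiteGenotype("ch", -1, 0, 0, 30, 0))
        assert classify_denovo(site, TRIO).reason == "missing"

    def test_ab_bounds_are_inclusive(self):
        # 3 alt of 10 reads = 0.30 exactly -> inside the closed interval
        site = make_site(SiteGenotype("ch", HET, 35, 15, 50, 99))
        assert isinstance(classify_denovo(site, TRIO), DenovoCall)

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            DenovoCriteria(ab_min=0.8, ab_max=0.3)
        with pytest.raises(ValueError):
            DenovoCriteria(dp_min=120, dp_max=10)


def brute_ab_band(d, lo=0.3, hi=0.7):
    """Independent oracle: direct sum of binomial pmf terms."""
    return sum(
        math.comb(d, x) * 0.5 ** d
        for x in range(d + 1)
        if lo <= x / d <= hi or math.isclose(x / d, lo) or math.isclose(x / d, hi)
    )


class TestSiteCallability:
    def test_depth_10_exact_enumeration(self):
        f = SiteGenotype("fa", HOMREF, 30, 0, 30, 99)
        m = SiteGenotype("mo", HOMREF, 30, 0, 30, 99)
        assert site_callability(f, m, 10) == pytest.approx(0.890625, abs=1e-12)

    def test_depth_30_matches_binomial_sum(self):
        f = SiteGenotype("fa", HOMREF, 30, 0, 30, 99)
        m = SiteGenotype("mo", HOMREF, 30, 0, 30, 99)
        expected = sum(math.comb(30, x) * 0.5 ** 30 for x in range(9, 22))
        assert site_callability(f, m, 30) == pytest.approx(expected, abs=1e-12)

    def test_masked_site_has_zero_callability(self):
        f = SiteGenotype("fa", HOMREF, 30, 0, 30, 99)
        m = SiteGenotype("mo", HOMREF, 30, 0, 30, 99)
        masks = {"repeats": GenomeMask("repeats", [GenomicInterval("1", 0, 5000)])}
        assert site_callability(f, m, 30, 1000, "1", masks=masks) == 0.0

    @pytest.mark.parametrize(
        "father, mother, child_dp",
        [
            (SiteGenotype("fa", HOMREF, 8, 0, 8, 99), None, 30),  # parent dp < 10
            (SiteGenotype("fa", HOMREF, 30, 0, 30, 40), None, 30),  # parent gq < 50
            (SiteGenotype("fa", HOMREF, 29, 1, 30, 99), None, 30),  # parent alt read
            (None, None, 5),  # child dp < 10
            (None, None, 130),  # child dp > 120
        ],
    )
    def test_fail_conditions_zero_out(self, father, mother, child_dp):
        f = father or SiteGenotype("fa", HOMREF, 30, 0, 30, 99)
        m = mother or SiteGenotype("mo", HOMREF, 30, 0, 30, 99)
        assert site_callability(f, m, child_dp) == 0.0

    def test_matches_enumeration_for_all_depths_to_20(self):
        for d in range(1, 21):
            expected = brute_ab_band(d) if 10 <= d <= 120 else 0.0
            got = ab_band_probability(d) if 10 <= d else None
            if 10 <= d:
                assert got == pytest.approx(brute_ab_band(d), abs=1e-12), d

    def test_probability_bounds(self):
        for d in range(1, 150):
            p = ab_band_probability(d)
            assert 0.0 <= p <= 1.0


class TestEstimateRate:
    def test_zero_numerator(self):
        assert estimate_snv_rate(0, 2.0e9).mu == 0.0

    def test_study_scale_arithmetic(self):
        # callability sum back-solved so 49 calls give a rate of 1.08e-8
        assert estimate_snv_rate(49, 2.268519e9).mu == pytest.approx(1.08e-8, rel=1e-4)
        assert estimate_snv_rate(10, 1.724e9).mu == pytest.approx(2.9e-9, rel=1e-3)

    def test_invalid_denominator(self):
        with pytest.raises(ValueError):
            estimate_snv_rate(5, 0.0)
        with pytest.raises(ValueError):
            estimate_snv_rate(-1, 1.0)


class TestVectorisedCascade:
    def test_agrees_with_scalar_classifier(self, small_dataset):
        """The array path and the per-site object path are the same cascade."""
        ds = small_dataset
        arr = ds.per_trio[0]
        called, reason = classify_denovo_arrays(arr.gt, arr.dp, arr.ad_alt, arr.gq)
        idx = np.random.default_rng(0).choice(len(ds.pos), 400, replace=False)
        idx = np.concatenate([idx, np.nonzero(called)[0]])
        for i in idx:
            site = VariantSite(ds.cfg.chrom, int(ds.pos[i]), "A", "G")
            for row, sid in enumerate(arr.trio.sample_ids):
                site.genotypes[sid] = SiteGenotype(
                    sid, int(arr.gt[row, i]),
                    int(arr.dp[row, i] - arr.ad_alt[row, i]),
                    int(arr.ad_alt[row, i]), int(arr.dp[row, i]),
                    int(arr.gq[row, i]))
            res = classify_denovo(site, arr.trio)
            assert isinstance(res, DenovoCall) == bool(called[i])

    def test_callability_matches_scalar(self, small_dataset):
        ds = small_dataset
        arr = ds.per_trio[1]
        c = callability_arrays(arr.gt, arr.dp, arr.ad_alt, arr.gq)
        for i in range(0, len(ds.pos), 997):
            f = SiteGenotype("fa", int(arr.gt[0, i]),
                             int(arr.dp[0, i] - arr.ad_alt[0, i]),
                             int(arr.ad_alt[0, i]), int(arr.dp[0, i]), int(arr.gq[0, i]))
            m = SiteGenotype("mo", int(arr.gt[1, i]),
                             int(arr.dp[1, i] - arr.ad_alt[1, i]),
                             int(arr.ad_alt[1, i]), int(arr.dp[1, i]), int(arr.gq[1, i]))
            expected = site_callability(f, m, int(arr.dp[2, i]),
                                        child_gq=int(arr.gq[2, i]))
            assert c[i] == pytest.approx(expected, abs=1e-12)


class TestFilterBehaviourOnSyntheticTrios:
    def test_no_calls_without_mutations_or_errors(self):
        """Specificity: error-free Mendelian data yields zero de novo calls."""
        cfg = SimConfig(n_sites=200_000, dnm_rate_snv=0.0, dnm_rate_indel=0.0,
                        error_rate=0.0, seed=23)
        ds = simulate_sites(cfg)
        for arr in ds.per_trio:
            called, _ = classify_denovo_arrays(arr.gt, arr.dp, arr.ad_alt, arr.gq)
            assert called.sum() == 0

    def test_planted_events_passing_upstream_criteria_are_called(self):
        """Sensitivity: planted sites surviving criteria i-iii are called iff
        they also satisfy iv-v (parents homref, no stray parental reads)."""
        cfg = SimConfig(n_sites=300_000, dnm_rate_snv=5e-5, dnm_rate_indel=0.0,
                        frac_indel=0.0, error_rate=0.0, seed=29)
        ds = simulate_sites(cfg)
        total_planted = 0
        for arr in ds.per_trio:
            called, reason = classify_denovo_arrays(arr.gt, arr.dp, arr.ad_alt, arr.gq)
            planted = arr.dnm
            total_planted += int(planted.sum())
            # every call is a planted event (no false positives without noise)
            assert planted[called].all()
            # planted events with homref parents and passing ii-iii are all called
            eligible = (
                planted
                & (arr.gt[0] == HOMREF) & (arr.gt[1] == HOMREF)
                & (arr.dp[2] >= 10) & (arr.dp[2] <= 120)
                & (arr.gq >= 50).all(axis=0)
                & (arr.ad_alt[2] / arr.dp[2] >= 0.3)
                & (arr.ad_alt[2] / arr.dp[2] <= 0.7)
                & (arr.ad_alt[0] == 0) & (arr.ad_alt[1] == 0)
            )
            assert called[eligible].all()
            # nothing violating criterion v is called
            non_homref_parents = planted & ((arr.gt[0] != HOMREF) | (arr.gt[1] != HOMREF))
            assert not called[non_homref_parents].any()
        assert total_planted > 50
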