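import pytest

from triokit.cnv import (
    DEL,
    DUP,
    CnvCall,
    CnvRegion,
    DepthProfile,
    build_cnv_regions,
    classify_sharing,
    detect_denovo_cnv,
    estimate_cnv_rate,
    is_novel_cnv,
    merge_callsets,
    read_cnv_calls,
    write_cnv_calls,
)
from triokit.intervals import GenomeMask, GenomicInterval
from triokit.simulate import SimConfig, simulate_cnv_callsets

import numpy as np


def iv(start, end, chrom="1"):
    return GenomicInterval(chrom, start, end)


def call(start, end, svtype=DEL, sample="s1", caller="caller_A", cn=None):
    if cn is None:
        cn = 1 if svtype == DEL else 3
    return CnvCall(sample, iv(start, end), svtype, cn, caller)


class TestCnvCall:
    def test_copy_number_must_match_svtype(self):
        with pytest.raises(ValueError):
            CnvCall("s", iv(0, 500), DEL, 3)
        with pytest.raises(ValueError):
            CnvCall("s", iv(0, 500), DUP, 1)

    def test_tsv_round_trip_drops_short_calls(self, tmp_path):
        p = tmp_path / "c.tsv"
        calls = [call(0, 500), call(1000, 1100), call(2000, 9000, DUP)]
        write_cnv_calls(calls, p)
        back = read_cnv_calls(p)
        # the 100 bp call is indel territory and dropped at load
        assert [c.interval for c in back] == [iv(0, 500), iv(2000, 9000)]


class TestMergeCallsets:
    def test_identical_call_in_both_sets_is_retained(self):
        a, b = [call(0, 1000)], [call(0, 1000, caller="caller_B")]
        assert merge_callsets(a, b) == a

    def test_single_caller_call_is_removed(self):
        assert merge_callsets([call(0, 1000)], []) == []

    def test_segdup_coverage_at_half_removes_call(self):
        a = [call(0, 1000)]
        b = [call(400, 1400, caller="caller_B")]
        segdup = GenomeMask("segdup", [iv(0, 600)])
        # reciprocal overlap 0.6/0.6 passes, but 60% segdup coverage >= 50%
        assert merge_callsets(a, b, gap_segdup_masks=[segdup]) == []
        assert merge_callsets(a, b) == a

    def test_any_repeat_overlap_removes_call(self):
        a, b = [call(0, 1000)], [call(0, 1000, caller="caller_B")]
        repeat = GenomeMask("repeat", [iv(999, 1001)])
        assert merge_callsets(a, b, repeat_masks=[repeat]) == []

    def test_svtype_must_match_for_concordance(self):
        assert merge_callsets([call(0, 1000, DEL)], [call(0, 1000, DUP, caller="caller_B")]) == []

    def test_mixed_samples_rejected(self):
        with pytest.raises(ValueError):
            merge_callsets([call(0, 1000, sample="s1")], [call(0, 1000, sample="s2")])

    def test_merge_is_idempotent_on_its_own_output(self, rng):
        for _ in range(20):
            calls_a = [call(int(s), int(s) + int(l), DEL if rng.random() < 0.7 else DUP)
                       for s, l in zip(rng.integers(0, 50_000, 10), rng.integers(150, 5000, 10))]
            calls_b = [CnvCall("s1", c.interval, c.svtype, c.copy_number, "caller_B")
                       for c in calls_a if rng.random() > 0.4]
            merged = merge_callsets(calls_a, calls_b)
            again = merge_callsets(merged, merged)
            assert again == merged


class TestIsNovel:
    def test_identical_database_record_is_known(self):
        assert not is_novel_cnv(iv(0, 1000), [(iv(0, 1000), DEL)])

    def test_absent_chromosome_is_novel(self):
        assert is_novel_cnv(iv(0, 1000, "5"), [(iv(0, 1000), DEL)])

    def test_forty_percent_overlap_is_novel(self):
        assert is_novel_cnv(iv(0, 1000), [(iv(600, 1600), DEL)])

    def test_svtype_matching_flag(self):
        db = [(iv(0, 1000), DUP)]
        assert not is_novel_cnv(iv(0, 1000), db, svtype=DEL)  # any-type default
        assert is_novel_cnv(iv(0, 1000), db, svtype=DEL, match_svtype=True)


def flat_profile(sample, depth=30.0, window=1000, n=200, override=()):
    d = np.full(n, depth)
    for lo, hi, val in override:
        d[lo:hi] = val
    return DepthProfile(sample, window, {"1": d})


class TestDetectDenovoCnv:
    def test_parental_overlap_drops_call(self):
        offspring = [call(10_000, 20_000, sample="ch")]
        father = [call(10_000, 20_000, sample="fa")]
        profiles = {s: flat_profile(s) for s in ("fa", "mo")}
        dn, reports = detect_denovo_cnv(offspring, father, [], profiles, "fa", "mo")
        assert dn == []
        assert reports[0].status == "parental_overlap"

    def test_clean_parental_depth_confirms_de_novo(self):
        offspring = [call(10_000, 20_000, sample="ch")]
        profiles = {s: flat_profile(s) for s in ("fa", "mo")}
        dn, reports = detect_denovo_cnv(offspring, [], [], profiles, "fa", "mo")
        assert dn == offspring
        r = reports[0]
        assert r.status == "de_novo" and r.father_cn == 2 and r.mother_cn == 2

    def test_parental_depth_ratio_half_drops_deletion(self):
        offspring = [call(10_000, 20_000, sample="ch")]
        profiles = {
            "fa": flat_profile("fa"),
            "mo": flat_profile("mo", override=[(10, 20, 15.0)]),  # CN 1 over the call
        }
        dn, reports = detect_denovo_cnv(offspring, [], [], profiles, "fa", "mo")
        assert dn == []
        assert reports[0].status == "parental_cn" and reports[0].mother_cn == 1

    def test_missing_profiles_mark_unverified(self):
        offspring = [call(10_000, 20_000, sample="ch")]
        dn, reports = detect_denovo_cnv(offspring, [], [], {}, "fa", "mo")
        assert dn == offspring
        assert reports[0].status == "unverified"

    def test_no_emitted_call_has_a_parental_match(self, rng):
        """Brute-force re-check of the step (i) guarantee on random inputs."""
        for _ in range(25):
            mk = lambda sid: [call(int(s), int(s) + int(l), sample=sid)
                              for s, l in zip(rng.integers(0, 100_000, 8),
                                              rng.integers(150, 8000, 8))]
            off, fa, mo = mk("ch"), mk("fa"), mk("mo")
            profiles = {s: flat_profile(s) for s in ("fa", "mo")}
            dn, _ = detect_denovo_cnv(off, fa, mo, profiles, "fa", "mo")
            for c in dn:
                for p in fa + mo:
                    if p.svtype != c.svtype:
                        continue
                    ov = max(0, min(c.interval.end, p.interval.end)
                             - max(c.interval.start, p.interval.start))
                    assert not (ov >= 0.5 * c.interval.length
                                and ov >= 0.5 * p.interval.length)


class TestEstimateCnvRate:
    @pytest.mark.parametrize(
        "n_denovo, n_total, reported",
        [(2, 1754, 0.001), (1, 2172, 0.0005), (3, 1722, 0.002), (2, 1777, 0.001)],
    )
    def test_reported_rate_rounds_to_one_significant_digit(self, n_denovo, n_total, reported):
        exact, rounded = estimate_cnv_rate(n_denovo, n_total)
        assert exact == pytest.approx(n_denovo / n_total)
        assert rounded == reported

    def test_zero_denovo(self):
        assert estimate_cnv_rate(0, 1000) == (0.0, 0.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            estimate_cnv_rate(1, 0)
        with pytest.raises(ValueError):
            estimate_cnv_rate(5, 4)


def region(trio_ids, svtype=DEL):
    return CnvRegion(iv(0, 1000), svtype, frozenset({"x"}), frozenset(trio_ids))


class TestClassifySharing:
    @pytest.mark.parametrize(
        "present_in, expected",
        [
            (("BTQ", "MDQ", "SMI"), "OA"),
            (("BTQ", "DSN"), "MLS"),
            (("MDQ",), "private"),
            (("BTQ", "MDQ"), "NGO"),
            (("DSN", "MRT"), "NB"),
            (("BTQ", "SMI"), "other"),
            (("BTQ", "MDQ", "SMI", "DSN", "MRT"), "MLS"),
        ],
    )
    def test_sharing_definitions(self, trios5, present_in, expected):
        assert classify_sharing(region(present_in), trios5) == expected

    def test_partitions_every_presence_pattern(self, trios5):
        """Each nonempty presence pattern maps to exactly one class."""
        import itertools

        ids = [t.trio_id for t in trios5]
        classes = {"OA": 0, "NGO": 0, "NB": 0, "MLS": 0, "private": 0, "other": 0}
        n_patterns = 0
        for r in range(1, 6):
            for combo in itertools.combinations(ids, r):
                classes[classify_sharing(region(combo), trios5)] += 1
                n_patterns += 1
        assert sum(classes.values()) == n_patterns == 31


class TestBuildRegions:
    def test_clusters_same_type_calls_across_trios(self, trios5):
        calls = {
            "BTQ": [call(0, 1000, sample="BTQ_ch")],
            "MDQ": [call(100, 1100, sample="MDQ_fa")],  # 90% reciprocal with BTQ
            "DSN": [call(5000, 6000, sample="DSN_mo")],
            "MRT": [call(0, 1000, DUP, sample="MRT_ch")],  # same span, other type
        }
        regions = build_cnv_regions(calls)
        keys = {(r.interval.start, r.svtype): r for r in regions}
        assert len(regions) == 3
        assert keys[(0, DEL)].trio_presence == {"BTQ", "MDQ"}
        assert keys[(5000, DEL)].trio_presence == {"DSN"}
        assert keys[(0, DUP)].trio_presence == {"MRT"}


class TestSimulatedCnvPipeline:
    def test_noise_free_merge_recovers_planted_calls(self, clean_cnv_sim):
        sim = clean_cnv_sim
        for sid in sim.calls_a:
            merged = merge_callsets(sim.calls_a[sid], sim.calls_b[sid])
            planted = {(c.interval.start, c.interval.end, c.svtype)
                       for c in sim.truth if c.sample_id == sid}
            got = {(c.interval.start, c.interval.end, c.svtype) for c in merged}
            assert got == planted

    def test_noise_free_denovo_detection_is_exact(self, clean_cnv_sim):
        """Precision = recall = 1 on planted de novo CNVs without noise."""
        sim = clean_cnv_sim
        merged = {sid: merge_callsets(sim.calls_a[sid], sim.calls_b[sid])
                  for sid in sim.calls_a}
        found = set()
        for trio in sim.trios:
            dn, _ = detect_denovo_cnv(
                merged.get(trio.offspring_id, []),
                merged.get(trio.father_id, []),
                merged.get(trio.mother_id, []),
                sim.depth_profiles, trio.father_id, trio.mother_id)
            found |= {(c.sample_id, c.interval.start, c.interval.end) for c in dn}
        planted = {(c.sample_id, c.interval.start, c.interval.end)
                   for c in sim.truth_denovo}
        assert found == planted
        assert len(planted) > 0

    def test_total_dropout_of_one_caller_empties_the_merge(self):
        cfg = SimConfig(n_sites=1_000, cnv_dropout=1.0, seed=13)
        sim = simulate_cnv_callsets(cfg)
        assert all(len(v) == 0 for v in sim.calls_b.values())

    def test_large_jitter_breaks_concordance(self):
        cfg = SimConfig(n_sites=1_000, cnv_jitter_frac=0.6, cnv_dropout=0.0, seed=13)
        sim = simulate_cnv_callsets(cfg)
        n_merged = sum(len(merge_callsets(sim.calls_a[s], sim.calls_b[s]))
                       for s in sim.calls_a)
        n_truth = len(sim.truth)
        assert n_merged < n_truth  # some pairs fall below 50% reciprocal overlap

    def test_depth_profile_tsv_round_trip(self, clean_cnv_sim, tmp_path):
        p = tmp_path / "depth.tsv"
        prof = next(iter(clean_cnv_sim.depth_profiles.values()))
        prof.to_frame().to_csv(p, sep="\t", index=False)
        back = DepthProfile.read_tsv(p)[prof.sample_id]
        assert back.window == prof.window
        assert np.allclose(back.depths["1"], prof.depths["1"])
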