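"""Hard-filter rules, MAF/missingness, and LD pruning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import filters
from sweepscan.model import MISSING

from conftest import make_genotype_matrix


def info_passing(n):
    return {
        "QD": np.full(n, 20.0),
        "FS": np.full(n, 5.0),
        "MQ": np.full(n, 60.0),
        "MQRankSum": np.zeros(n),
        "ReadPosRankSum": np.zeros(n),
        "SOR": np.full(n, 1.0),
    }


class TestHardFilter:
    def test_low_qd_removed_with_reason(self, rng):
        info = info_passing(2)
        info["QD"] = np.array([1.5, 20.0])
        g = make_genotype_matrix(rng.integers(0, 3, (2, 6)), site_info=info)
        out, report = filters.hard_filter(g)
        assert out.n_sites == 1
        assert report.fail_reasons.tolist() == ["QD", ""]

    def test_exact_threshold_values_pass(self, rng):
        # removal conditions are strict inequalities: QD=2, FS=60, SOR=3 stay
        info = info_passing(1)
        info["QD"][0], info["FS"][0], info["SOR"][0] = 2.0, 60.0, 3.0
        info["MQRankSum"][0], info["ReadPosRankSum"][0] = -12.5, -8.0
        info["MQ"][0] = 40.0
        g = make_genotype_matrix([[0, 1, 2]], site_info=info)
        out, _ = filters.hard_filter(g)
        assert out.n_sites == 1

    def test_planted_violations_all_caught(self, rng):
        n = 10
        info = info_passing(n)
        info["FS"][2] = 75.0          # strand bias
        info["MQ"][5] = 30.0          # low mapping quality
        info["MQRankSum"][8] = -13.0  # rank-sum failure
        g = make_genotype_matrix(rng.integers(0, 3, (n, 6)), site_info=info)
        out, report = filters.hard_filter(g)
        assert out.n_sites == 7
        failed = report[report.fail_reasons != ""]
        assert dict(zip(failed.index, failed.fail_reasons)) == {
            2: "FS", 5: "MQ", 8: "MQRankSum"
        }

    def test_missing_annotation_skips_rule(self, rng):
        info = info_passing(1)
        info["MQRankSum"] = np.array([np.nan])  # hom-alt-only site, no rank sum
        g = make_genotype_matrix([[2, 2, 2]], site_info=info)
        out, _ = filters.hard_filter(g)
        assert out.n_sites == 1

    def test_depth_rule_relative_to_mean(self):
        n = 10
        dp = np.full((n, 4), 10.0)
        dp[0] = 200.0  # way above 3x the mean depth
        dp[1] = 1.0    # below 1/3x
        g = make_genotype_matrix(
            np.ones((n, 4), dtype=np.int8), site_info=info_passing(n), dp=dp
        )
        out, report = filters.hard_filter(g)
        assert "DP" in report.fail_reasons[0] and "DP" in report.fail_reasons[1]
        assert out.n_sites == n - 2

    def test_missing_rate_and_non_snp(self, rng):
        gt = np.zeros((2, 10), dtype=np.int8)
        gt[0, :2] = MISSING  # 20% missing > 10%
        g = make_genotype_matrix(gt, site_info=info_passing(2))
        g.is_biallelic_snp[1] = False
        out, report = filters.hard_filter(g)
        assert out.n_sites == 0
        assert report.fail_reasons.tolist() == ["missing_rate", "not_biallelic_snp"]

    def test_idempotent(self, rng):
        info = info_passing(20)
        info["QD"][3] = 0.5
        g = make_genotype_matrix(rng.integers(0, 3, (20, 8)), site_info=info)
        once, _ = filters.hard_filter(g)
        twice, _ = filters.hard_filter(once)
        np.testing.assert_array_equal(once.pos, twice.pos)

    def test_survivors_violate_no_rule(self, rng):
        cfg = filters.FilterConfig()
        n = 200
        info = {
            "QD": rng.uniform(0, 40, n),
            "FS": rng.uniform(0, 100, n),
            "MQ": rng.uniform(20, 60, n),
            "MQRankSum": rng.normal(0, 8, n),
            "ReadPosRankSum": rng.normal(0, 5, n),
            "SOR": rng.uniform(0, 5, n),
        }
        g = make_genotype_matrix(rng.integers(0, 3, (n, 6)), site_info=info)
        out, _ = filters.hard_filter(g, cfg)
        assert (out.site_info["QD"] >= cfg.qd_min).all()
        assert (out.site_info["FS"] <= cfg.fs_max).all()
        assert (out.site_info["MQ"] >= cfg.mq_min).all()
        assert (out.site_info["MQRankSum"] >= cfg.mqranksum_min).all()
        assert (out.site_info["ReadPosRankSum"] >= cfg.readposranksum_min).all()
        assert (out.site_info["SOR"] <= cfg.sor_max).all()


class TestMafMissing:
    def test_rare_allele_removed(self):
        # 27 diploids, alt count 2 of 54 alleles: MAF 0.037 < 0.05
        gt = np.zeros((1, 27), dtype=np.int8)
        gt[0, 0] = 2
        g = make_genotype_matrix(gt)
        assert filters.maf_missing_filter(g).n_sites == 0

    def test_half_frequency_retained(self):
        gt = np.zeros((1, 27), dtype=np.int8)
        gt[0, :13] = 2
        gt[0, 13] = 1  # alt count 27/54 = 0.5
        g = make_genotype_matrix(gt)
        assert filters.maf_missing_filter(g).n_sites == 1

    def test_low_call_rate_removed(self):
        # 4 of 27 samples missing: call rate 23/27 = 0.852 < 0.90
        gt = np.ones((1, 27), dtype=np.int8)
        gt[0, :4] = MISSING
        g = make_genotype_matrix(gt)
        assert filters.maf_missing_filter(g).n_sites == 0

    def test_all_missing_site_removed(self):
        gt = np.full((1, 5), MISSING, dtype=np.int8)
        assert filters.maf_missing_filter(make_genotype_matrix(gt)).n_sites == 0

    def test_maf_counts_both_populations_pooled(self):
        # common overall but absent in the first 20 samples
        gt = np.zeros((1, 27), dtype=np.int8)
        gt[0, 20:] = 2
        g = make_genotype_matrix(gt)
        assert filters.maf_missing_filter(g).n_sites == 1


class TestLdPrune:
    def test_duplicate_site_loses_later_copy(self, rng):
        base = rng.integers(0, 3, (1, 20)).astype(np.int8)
        gt = np.vstack([base, base, rng.integers(0, 3, (1, 20)).astype(np.int8)])
        g = make_genotype_matrix(gt)
        out = filters.ld_prune(g)
        assert out.n_sites == 2
        assert out.pos[0] == g.pos[0]  # first of the pair kept

    def test_uncorrelated_sites_all_kept(self, rng):
        gt = rng.integers(0, 3, (30, 400)).astype(np.int8)  # many samples: r2 tiny
        g = make_genotype_matrix(gt)
        assert filters.ld_prune(g).n_sites == 30

    def test_planted_pairs_match_bruteforce(self, rng):
        n_samples = 40
        cols = [rng.integers(0, 3, n_samples).astype(np.int8) for _ in range(7)]
        # plant 3 strongly correlated partners
        for src in (0, 2, 4):
            dup = cols[src].copy()
            flip = rng.random(n_samples) < 0.05
            dup[flip] = rng.integers(0, 3, flip.sum())
            cols.insert(src + 1, dup)
        gt = np.stack(cols)
        g = make_genotype_matrix(gt)
        dup_pos = set(g.pos[[1, 3, 5]].tolist())  # the inserted partners
        out = filters.ld_prune(g)
        # brute force: surviving set must contain no offending pair ...
        surv = out.gt.astype(float)
        for a in range(out.n_sites):
            for b in range(a + 1, out.n_sites):
                if surv[a].std() == 0 or surv[b].std() == 0:
                    continue
                r2 = np.corrcoef(surv[a], surv[b])[0, 1] ** 2
                assert r2 <= 0.2 + 1e-12
        # ... and the three planted near-duplicates are gone (keeping the
        # earlier member of each pair)
        assert dup_pos.isdisjoint(out.pos.tolist())
        assert out.n_sites >= 5

    def test_idempotent(self, rng):
        gt = rng.integers(0, 3, (60, 12)).astype(np.int8)
        g = make_genotype_matrix(gt)
        once = filters.ld_prune(g)
        twice = filters.ld_prune(once)
        np.testing.assert_array_equal(once.pos, twice.pos)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_ld_prune_leaves_no_offending_pair_in_window(seed):
    rng = np.random.default_rng(seed)
    gt = rng.integers(0, 3, (40, 10)).astype(np.int8)
    g = make_genotype_matrix(gt)
    out = filters.ld_prune(g, window=10, step=2, r2_max=0.3)
    x = out.gt.astype(float)
    # pairs further apart than window - step can straddle two anchors and
    # are not guaranteed to have been co-examined (plink window semantics)
    for a in range(out.n_sites):
        for b in range(a + 1, min(a + (10 - 2) + 1, out.n_sites)):
            if x[a].std() == 0 or x[b].std() == 0:
                continue
            assert np.corrcoef(x[a], x[b])[0, 1] ** 2 <= 0.3 + 1e-12
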