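"""Allele-frequency statistics: Weir-Cockerham Fst against a literal
transcription of the 1984 formulas, Hp and pi worked examples, and the
Z/P-value machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sweepscan import freq
from sweepscan.model import MISSING, Window
from sweepscan.windows import assign_snps, make_windows

from conftest import make_genotype_matrix, random_two_pop_matrix


def wc84_reference(n_i, p_i, h_i):
    """Independent oracle: scalar transcription of the Weir & Cockerham
    (1984) estimator for r populations, written directly from the
    published equations (n_bar, n_c, p_bar, s2, h_bar -> a, b, c)."""
    r = len(n_i)
    nbar = sum(n_i) / r
    nc = (r * nbar - sum(n ** 2 for n in n_i) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(n_i, p_i)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(n_i, h_i)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def tally(gt_pop):
    """Per-site (n called, alt freq, het proportion) by direct counting."""
    out = []
    for row in gt_pop:
        called = [x for x in row if x != MISSING]
        n = len(called)
        if n == 0:
            out.append((0, 0.0, 0.0))
            continue
        out.append(
            (n, sum(called) / (2 * n), sum(1 for x in called if x == 1) / n)
        )
    return out


class TestWcFst:
    def test_fixed_difference_components(self):
        comp = freq.wc_fst_site(10, 10, 1.0, 0.0, 0.0, 0.0)
        assert comp.a[0] == pytest.approx(0.5)
        assert comp.b[0] == pytest.approx(0.0)
        assert comp.c[0] == pytest.approx(0.0)
        assert comp.per_site_fst()[0] == pytest.approx(1.0)

    def test_pooled_monomorphic_excluded(self):
        comp = freq.wc_fst_site(10, 10, 0.0, 0.0, 0.0, 0.0)
        assert comp.excluded[0]
        assert np.isnan(comp.a[0])

    def test_matches_wc84_transcription_on_random_fixtures(self, rng):
        for _ in range(5):
            g, pm = random_two_pop_matrix(rng)
            ti = g.sample_indices(pm.target_samples)
            ri = g.sample_indices(pm.reference_samples)
            comp = freq.wc_components(g, ti, ri)
            tal_t = tally(g.gt[:, ti])
            tal_r = tally(g.gt[:, ri])
            for i in range(g.n_sites):
                (n1, p1, h1), (n2, p2, h2) = tal_t[i], tal_r[i]
                pbar = (n1 * p1 + n2 * p2) / (n1 + n2) if n1 + n2 else 0
                if n1 == 0 or n2 == 0 or pbar in (0.0, 1.0):
                    assert comp.excluded[i]
                    continue
                a, b, c = wc84_reference([n1, n2], [p1, p2], [h1, h2])
                assert comp.a[i] == pytest.approx(a, abs=1e-10)
                assert comp.b[i] == pytest.approx(b, abs=1e-10)
                assert comp.c[i] == pytest.approx(c, abs=1e-10)

    def test_windowed_ratio_of_sums(self, rng):
        g, pm = random_two_pop_matrix(rng, n_sites=120)
        ti = g.sample_indices(pm.target_samples)
        ri = g.sample_indices(pm.reference_samples)
        comp = freq.wc_components(g, ti, ri)
        w = Window("chr1", 1, int(g.pos[-1]), np.arange(g.n_sites))
        got = freq.fst_window(comp, w)
        inc = ~comp.excluded
        expect = comp.a[inc].sum() / (comp.a + comp.b + comp.c)[inc].sum()
        assert got == pytest.approx(expect, abs=1e-12)

    def test_identical_populations_nonpositive(self, rng):
        # same genotype table in both populations: no among-pop variance
        gt_half = rng.integers(0, 3, (40, 10)).astype(np.int8)
        g = make_genotype_matrix(np.hstack([gt_half, gt_half]))
        ti = np.arange(10)
        ri = np.arange(10, 20)
        comp = freq.wc_components(g, ti, ri)
        w = Window("chr1", 1, int(g.pos[-1]), np.arange(g.n_sites))
        assert freq.fst_window(comp, w) <= 0

    def test_single_site_window_equals_per_site_ratio(self):
        comp = freq.wc_fst_site(
            np.array([10.0]), np.array([8.0]), np.array([0.9]),
            np.array([0.2]), np.array([0.2]), np.array([0.3])
        )
        w = Window("chr1", 1, 100, np.array([0]))
        assert freq.fst_window(comp, w) == pytest.approx(comp.per_site_fst()[0])


class TestHp:
    def test_worked_example(self):
        # major (27,25,20), minor (3,5,10): 2*72*18/90^2 = 0.32
        w = Window("chr1", 1, 1000, np.arange(3))
        hp = freq.hp_window(np.array([27, 25, 20]), np.array([3, 5, 10]), w)
        assert hp == pytest.approx(0.32)

    def test_fixed_windows_are_zero(self):
        w = Window("chr1", 1, 1000, np.arange(3))
        assert freq.hp_window(np.array([10, 10, 10]), np.zeros(3, int), w) == 0.0

    def test_balanced_counts_hit_maximum(self):
        w = Window("chr1", 1, 1000, np.arange(4))
        assert freq.hp_window(np.full(4, 15), np.full(4, 15), w) == pytest.approx(0.5)

    def test_invariant_to_ref_alt_labels(self, rng):
        g, pm = random_two_pop_matrix(rng, n_sites=50)
        ti = g.sample_indices(pm.target_samples)
        maj, mino = freq.major_minor_counts(g, ti)
        # relabel: swap ref/alt at every site by inverting dosage
        gt2 = g.gt.copy()
        ok = gt2 != MISSING
        gt2[ok] = 2 - gt2[ok]
        g2 = make_genotype_matrix(gt2)
        maj2, min2 = freq.major_minor_counts(g2, ti)
        np.testing.assert_array_equal(maj, maj2)
        np.testing.assert_array_equal(mino, min2)


class TestPi:
    def test_worked_example_single_site(self):
        # n=30 alleles, j=15: 2*15*15/(30*29) = 450/870
        gt = np.zeros((1, 15), dtype=np.int8)
        gt[0, :7] = 2
        gt[0, 7] = 1
        g = make_genotype_matrix(gt)
        site = freq.pi_sites(g, np.arange(15))
        assert site[0] == pytest.approx(450 / 870)
        w = Window("chr1", 1, 50_000, np.array([0]))
        assert freq.pi_window(site, w) == pytest.approx(1.034483e-5, rel=1e-6)

    def test_monomorphic_window_zero(self):
        g = make_genotype_matrix(np.zeros((5, 10), dtype=np.int8))
        site = freq.pi_sites(g, np.arange(10))
        w = Window("chr1", 1, 1000, np.arange(5))
        assert freq.pi_window(site, w) == 0.0

    def test_doubling_length_halves_pi(self, rng):
        g, _ = random_two_pop_matrix(rng, n_sites=30, missing_rate=0)
        site = freq.pi_sites(g, np.arange(27))
        w1 = Window("chr1", 1, 10_000, np.arange(30))
        w2 = Window("chr1", 1, 20_000, np.arange(30))
        assert freq.pi_window(site, w1) == pytest.approx(
            2 * freq.pi_window(site, w2)
        )

    def test_sample_order_invariant(self, rng):
        g, _ = random_two_pop_matrix(rng, n_sites=40)
        idx = np.arange(27)
        shuffled = rng.permutation(idx)
        np.testing.assert_allclose(
            freq.pi_sites(g, idx), freq.pi_sites(g, shuffled)
        )


class TestPiRatio:
    def test_equal_diversity_is_zero(self):
        assert freq.pi_ratio_window(1e-4, 1e-4) == pytest.approx(0.0)

    def test_log2_identity(self):
        assert freq.pi_ratio_window(2e-4, 1e-4) == pytest.approx(1.0)

    def test_zero_target_is_masked(self):
        assert np.isnan(freq.pi_ratio_window(1e-4, 0.0))
        assert np.isnan(freq.pi_ratio_window(0.0, 0.0))

    def test_raw_form(self):
        assert freq.pi_ratio_window(3e-4, 1e-4, form="raw") == pytest.approx(3.0)


class TestZandP:
    def test_three_values(self):
        z = freq.z_transform(np.array([1.0, 2.0, 3.0]))
        sd = np.array([1.0, 2.0, 3.0]).std()
        np.testing.assert_allclose(z, np.array([-1, 0, 1]) / sd)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            freq.z_transform(np.full(10, 3.3))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(3, 200))
    def test_output_moments(self, seed, n):
        x = np.random.default_rng(seed).normal(5, 3, n)
        z = freq.z_transform(x)
        assert abs(z.mean()) < 1e-12
        assert abs(z.std() - 1) < 1e-12

    def test_pvalue_at_2576(self):
        assert freq.normal_pvalue(2.576, "upper") == pytest.approx(0.005, abs=1e-5)
        assert freq.normal_pvalue(-2.576, "lower") == pytest.approx(0.005, abs=1e-5)
        assert freq.normal_pvalue(0.0, "upper") == 0.5

    def test_critical_value_round_trips(self):
        z = freq.critical_z(0.005)
        assert round(z, 3) == 2.576
        assert freq.normal_pvalue(z, "upper") == pytest.approx(0.005, rel=1e-12)
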