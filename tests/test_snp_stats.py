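import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan import simulate as sim
from poolscan import snp_stats
from conftest import make_table


class TestMafFilter:
    @pytest.mark.parametrize("p, kept", [(0.5, True), (0.9, False), (0.8, True),
                                         (0.2, True), (0.19, False)])
    def test_examples(self, p, kept):
        assert snp_stats.maf_filter(np.array([p]), 0.2)[0] == kept

    def test_pool_mean_example(self):
        # pool frequencies (1, 1, 0.6, 0.6): mean 0.8, MAF exactly 0.2, kept
        mean = np.mean([1.0, 1.0, 0.6, 0.6])
        assert snp_stats.maf_filter(np.array([mean]), 0.2)[0]

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50),
           st.floats(0, 0.5), st.floats(0, 0.5))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, freqs, t1, t2):
        lo, hi = sorted((t1, t2))
        f = np.array(freqs)
        assert not np.any(snp_stats.maf_filter(f, hi) & ~snp_stats.maf_filter(f, lo))


class TestPoolFst:
    def test_fixed_difference_is_one(self, two_pools):
        t = make_table(two_pools, [[0, 30]], [[30, 0]])
        r = snp_stats.pool_fst(t, "a", "b")
        assert r.per_locus[0] == pytest.approx(1.0)

    def test_balanced_locus_value(self, two_pools):
        # both pools 15/30 at haploid size 60: h = 0.5*(60/59)*(30/29),
        # Q1 = 1 - h, Q2 = 0.5 -> FST = -0.0520
        t = make_table(two_pools, [[15, 15]], [[15, 15]])
        r = snp_stats.pool_fst(t, "a", "b")
        h = 0.5 * (60 / 59) * (30 / 29)
        assert r.per_locus[0] == pytest.approx((1 - h - 0.5) / 0.5, abs=1e-12)
        assert r.per_locus[0] == pytest.approx(-0.0520, abs=1e-4)

    def test_matches_direct_formula_on_random_counts(self, two_pools):
        rng = np.random.default_rng(0)
        cov = rng.integers(2, 60, size=(1000, 2))
        alt = rng.integers(0, cov + 1)
        t = make_table(two_pools, cov - alt, alt)
        r = snp_stats.pool_fst(t, "a", "b")
        # independent evaluation of the stated Q1/Q2 formulas
        for l in rng.choice(1000, 200, replace=False):
            pa, pb = alt[l, 0] / cov[l, 0], alt[l, 1] / cov[l, 1]
            ha = 2 * pa * (1 - pa) * (60 / 59) * (cov[l, 0] / (cov[l, 0] - 1))
            hb = 2 * pb * (1 - pb) * (60 / 59) * (cov[l, 1] / (cov[l, 1] - 1))
            q1, q2 = 1 - (ha + hb) / 2, pa * pb + (1 - pa) * (1 - pb)
            if q2 >= 1:
                assert np.isnan(r.per_locus[l])
            else:
                assert r.per_locus[l] == pytest.approx((q1 - q2) / (1 - q2), abs=1e-12)

    def test_symmetry_exact(self, two_pools):
        rng = np.random.default_rng(1)
        cov = rng.integers(10, 50, size=(200, 2))
        alt = rng.integers(0, cov + 1)
        t = make_table(two_pools, cov - alt, alt)
        assert (snp_stats.pool_fst(t, "a", "b").global_fst
                == snp_stats.pool_fst(t, "b", "a").global_fst)

    def test_fixed_same_allele_excluded(self, two_pools):
        t = make_table(two_pools, [[0, 0], [15, 15]], [[30, 30], [15, 15]])
        r = snp_stats.pool_fst(t, "a", "b")
        assert np.isnan(r.per_locus[0]) and r.n_excluded == 1

    def test_infinite_coverage_limit_matches_identity_estimator(self, two_pools):
        # at read depth >> pool size the estimator converges to the
        # individual-based identity-probability (Hudson-type) estimator
        rng = np.random.default_rng(2)
        k = rng.integers(1, 60, size=(500, 2))  # allele counts among 60
        scale = 10**6
        t = make_table(two_pools, (60 - k) * scale, k * scale)
        r = snp_stats.pool_fst(t, "a", "b")
        p = k / 60
        h = 2 * p * (1 - p) * (60 / 59)
        q1 = 1 - h.mean(axis=1)
        q2 = p[:, 0] * p[:, 1] + (1 - p[:, 0]) * (1 - p[:, 1])
        expected = (q1 - q2) / (1 - q2)
        assert np.allclose(r.per_locus, expected, atol=1e-4)

    def test_null_unbiased(self, two_pools):
        # identical latent frequencies: mean per-locus FST within 0.005 of 0
        rng = np.random.default_rng(3)
        L = 10_000
        pi = rng.uniform(0.05, 0.95, L)
        cov = np.maximum(rng.poisson(30, size=(L, 2)), 2)
        k = rng.binomial(60, pi[:, None], size=(L, 2))
        alt = rng.binomial(cov, k / 60)
        t = make_table(two_pools, cov - alt, alt)
        r = snp_stats.pool_fst(t, "a", "b")
        assert abs(np.nanmean(r.per_locus)) < 0.005

    def test_island_model_calibration(self, two_pools):
        t = sim.sim_island_snps(20_000, fst=0.05, seed=4)
        g = snp_stats.pool_fst(t, "fieldA", "labB").global_fst
        assert abs(g - 0.05) < 0.01


class TestNucleotideDiversity:
    def test_single_snp_window(self, two_pools):
        t = make_table(two_pools, [[15, 15]], [[15, 15]], positions=[500])
        rec = snp_stats.nucleotide_diversity(t, "a", window=1000)
        h = 0.5 * (60 / 59) * (30 / 29)
        assert rec["pi"][0] == pytest.approx(h / 1000)

    def test_no_snps_zero(self, two_pools):
        t = make_table(two_pools, [[15, 15]], [[15, 15]], positions=[5000])
        rec = snp_stats.nucleotide_diversity(t, "a", window=1000, step=1000)
        assert rec["pi"][0] == 0.0 and rec["n_snps"][0] == 0

    def test_recovers_expected_heterozygosity(self, two_pools):
        # binomial read sampling at fixed true frequencies: mean pi over
        # windows approaches the true mean heterozygosity
        rng = np.random.default_rng(5)
        L, C = 2000, 30
        p = rng.uniform(0.2, 0.8, L)
        cov = np.maximum(rng.poisson(C, size=(L, 2)), 2)
        alt = rng.binomial(cov, np.column_stack([p, p]))
        t = make_table(two_pools, cov - alt, alt,
                       positions=np.arange(1, L + 1) * 10)
        rec = snp_stats.nucleotide_diversity(t, "a", window=20_000, step=20_000)
        total_pi = np.nansum(rec["pi"] * 20_000)
        truth = (2 * p * (1 - p) * 60 / 59).sum()
        assert abs(total_pi - truth) / truth < 0.1


class TestPca:
    def test_identical_pools_distance_zero(self, four_pools):
        f = np.tile(np.linspace(0.1, 0.9, 50)[:, None], (1, 4))
        coords, frac = snp_stats.pca_pools(f, [p.name for p in four_pools])
        assert np.allclose(coords, 0, atol=1e-9)

    def test_variance_fractions_sum_to_one(self, four_pools):
        rng = np.random.default_rng(6)
        f = rng.uniform(0, 1, size=(500, 4))
        _, frac = snp_stats.pca_pools(f, [p.name for p in four_pools])
        assert frac.sum() == pytest.approx(1.0)
        assert (frac[:3] > 1e-6).all()

    def test_shared_history_pools_cluster(self, four_pools):
        # high fieldA-labA covariance puts those two pools closest, as for
        # same-origin field and lab strains
        cfg = sim.SimConfig(seed=7, n_loci=20_000)
        t, _ = sim.sim_pool_snps(cfg)
        coords, _ = snp_stats.pca_pools(t.alt_freq, [p.name for p in cfg.pools])
        d = np.linalg.norm(coords[:, None, :2] - coords[None, :, :2], axis=2)
        np.fill_diagonal(d, np.inf)
        i, j = sorted(np.unravel_index(np.argmin(d), d.shape))
        assert (cfg.pools[i].name, cfg.pools[j].name) == ("fieldA", "labA")

    def test_single_pool_rejected(self):
        with pytest.raises(ValueError):
            snp_stats.pca_pools(np.zeros((10, 1)), ["a"])


class TestSlidingWindows:
    def test_no_outliers_all_zero(self):
        rec, q99 = snp_stats.sliding_outlier_counts({}, {"s1": 300_000})
        assert (rec["count"] == 0).all() and q99 == 0

    def test_membership(self):
        rec, _ = snp_stats.sliding_outlier_counts(
            {"s1": np.array([5000, 95_000])}, {"s1": 200_000})
        first = rec[(rec["scaffold"] == "s1") & (rec["start"] == 1)]
        assert first["count"][0] == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(8)
        pos = {"s1": np.sort(rng.integers(1, 500_000, 300))}
        rec, _ = snp_stats.sliding_outlier_counts(pos, {"s1": 500_000})
        for row in rec[rng.choice(len(rec), 50)]:
            brute = int(((pos["s1"] >= row["start"]) & (pos["s1"] <= row["end"])).sum())
            assert row["count"] == brute
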