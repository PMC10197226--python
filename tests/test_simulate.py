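import numpy as np
import pytest
from scipy import stats

from poolscan import simulate as sim
from poolscan.io import ConfigError


class TestSimPoolSnps:
    def test_same_seed_identical(self):
        cfg = sim.SimConfig(seed=4, n_loci=500)
        t1, tr1 = sim.sim_pool_snps(cfg)
        t2, tr2 = sim.sim_pool_snps(sim.SimConfig(seed=4, n_loci=500))
        assert np.array_equal(t1.alt_counts, t2.alt_counts)
        assert tr1.equals(tr2)

    def test_selection_clipping(self):
        blk = sim.SelectedBlock("scaf1", 1, 3_000_000, n_selected=50,
                                delta=0.95, pi_range=(0.2, 0.25))
        cfg = sim.SimConfig(seed=1, n_loci=2000, selected=blk)
        _, truth = sim.sim_pool_snps(cfg)
        sel = truth[truth["selected"]]
        # 0.2 + 0.95 clips to exactly 1 in every resistant pool
        assert (sel["p_fieldA"] == 1.0).all() and (sel["p_fieldB"] == 1.0).all()

    def test_omega_recovered_from_true_frequencies(self):
        omega = 0.01 * np.eye(4)
        cfg = sim.SimConfig(seed=2, n_loci=40_000, omega_true=omega)
        _, truth = sim.sim_pool_snps(cfg)
        pi = truth["pi"].to_numpy()
        p = truth[[f"p_{q.name}" for q in cfg.pools]].to_numpy()
        a = (p - pi[:, None]) / np.sqrt(pi * (1 - pi))[:, None]
        est = a.T @ a / len(a)
        L = len(a)
        se = np.sqrt((np.outer(np.diag(omega), np.diag(omega)) + omega**2) / L)
        se += 0.01 * np.abs(omega) + 2e-4  # clipping bias allowance at extreme pi
        assert np.all(np.abs(est - omega) < 3 * se + 3e-4)

    def test_mean_frequency_unbiased_for_pi(self):
        cfg = sim.SimConfig(seed=3, n_loci=20_000)
        t, truth = sim.sim_pool_snps(cfg)
        mean_f = t.alt_freq.mean(axis=1)
        slope = np.polyfit(truth["pi"], mean_f, 1)[0]
        assert abs(slope - 1.0) < 0.02

    def test_non_pd_omega_rejected(self):
        with pytest.raises(ConfigError):
            sim.SimConfig(seed=0, omega_true=np.zeros((4, 4)))


class TestSimGenome:
    def test_gene_length_median(self):
        cfg = sim.SimConfig(seed=5, n_genes=400,
                            scaffold_lengths={"s1": 8_000_000, "s2": 8_000_000})
        ann = sim.sim_genome(cfg)
        lengths = [g.end - g.start + 1 for g in ann.genes]
        assert 6000 <= np.median(lengths) <= 8000

    def test_genes_do_not_overlap_and_fit(self):
        cfg = sim.SimConfig(seed=5, n_genes=200)
        ann = sim.sim_genome(cfg)
        for scaf in cfg.scaffold_lengths:
            spans = sorted((g.start, g.end) for g in ann.genes if g.scaffold == scaf)
            assert all(b[0] > a[1] for a, b in zip(spans, spans[1:]))
            assert all(1 <= s <= e <= cfg.scaffold_lengths[scaf] for s, e in spans)

    def test_cds_codable_with_sequence(self):
        ann = sim.sim_genome(sim.SimConfig(seed=6, n_genes=50))
        for g in ann.genes:
            assert g.codable and len(g.cds_seq) == g.cds_length

    def test_te_fraction_zero_empty_mask(self):
        ann = sim.sim_genome(sim.SimConfig(seed=6, n_genes=20, te_fraction=0.0))
        assert ann.te_mask == {}

    def test_resistance_category_count(self):
        ann = sim.sim_genome(sim.SimConfig(seed=6, n_genes=300))
        expected = round(sim.RESISTANCE_GENE_FRACTION * len(ann.genes))
        assert len(ann.categories) == expected


class TestSimSvReadpairs:
    def test_no_events_no_discordant_pairs(self):
        cfg = sim.SimConfig(seed=7, scaffold_lengths={"s1": 300_000})
        pairs, depth, _ = sim.sim_sv_readpairs(cfg)
        df = pairs["fieldA"]["s1"]
        assert (df["left_strand"] == "+").all() and (df["right_strand"] == "-").all()
        assert abs(depth["fieldA"]["s1"].mean() - cfg.depth) < 0.2

    def test_tandem_dup_doubles_depth(self):
        plan = [sim.SvPlan("tandem_dup", "s1", 100_000, 50_000, {"fieldA": 1.0})]
        cfg = sim.SimConfig(seed=8, scaffold_lengths={"s1": 300_000}, sv_plan=plan)
        _, depth, _ = sim.sim_sv_readpairs(cfg)
        inside = depth["fieldA"]["s1"][100_000:149_999]
        se = np.sqrt(60.0 / len(inside))
        assert abs(inside.mean() - 60.0) < 3 * se

    def test_inversion_leaves_depth_flat_with_same_strand_pairs(self):
        plan = [sim.SvPlan("inversion", "s1", 100_000, 50_000, {"fieldA": 1.0})]
        cfg = sim.SimConfig(seed=9, scaffold_lengths={"s1": 300_000}, sv_plan=plan)
        pairs, depth, _ = sim.sim_sv_readpairs(cfg)
        inside = depth["fieldA"]["s1"][100_000:149_999]
        se = np.sqrt(30.0 / len(inside))
        assert abs(inside.mean() - 30.0) < 3 * se
        df = pairs["fieldA"]["s1"]
        ss = df[df["left_strand"] == df["right_strand"]]
        assert len(ss) > 10
        # same-strand clusters tie the two boundaries together
        assert np.median(np.abs(ss["left_pos"] - 100_000)) < 500
        assert np.median(np.abs(ss["right_pos"] - 149_999)) < 500

    def test_pairs_within_scaffold(self):
        plan = [sim.SvPlan("inverted_dup", "s1", 20_000, 10_000, {"fieldA": 0.8})]
        cfg = sim.SimConfig(seed=10, scaffold_lengths={"s1": 100_000}, sv_plan=plan)
        pairs, _, _ = sim.sim_sv_readpairs(cfg)
        for pool in pairs:
            df = pairs[pool]["s1"]
            assert (df["left_pos"] >= 1).all()
            assert (df["right_pos"] + df["read_len"] - 1 <= 100_000).all()

    def test_event_past_scaffold_end_rejected(self):
        plan = [sim.SvPlan("inversion", "s1", 90_000, 50_000, {"fieldA": 1.0})]
        with pytest.raises(ConfigError):
            sim.SimConfig(seed=0, scaffold_lengths={"s1": 100_000}, sv_plan=plan)


class TestSimBioassay:
    def test_mortality_half_at_ld50(self):
        plans = [sim.BioassayPlan("x", 10.0, 2.0, (10.0,), n_replicates=200,
                                  n_per_replicate=10)]
        tbl = sim.sim_bioassay(plans, seed=11)
        trt = tbl[tbl["dose"] > 0]
        p = trt["n_dead"].sum() / trt["n_exposed"].sum()
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / trt["n_exposed"].sum())

    def test_steep_slope_is_step_function(self):
        plans = [sim.BioassayPlan("x", 10.0, 500.0, (5.0, 20.0), n_replicates=5)]
        tbl = sim.sim_bioassay(plans, seed=12)
        below = tbl[tbl["dose"] == 5.0]["n_dead"].sum()
        above = tbl[tbl["dose"] == 20.0]
        assert below == 0 and (above["n_dead"] == above["n_exposed"]).all()

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ConfigError):
            sim.sim_bioassay([sim.BioassayPlan("x", 10.0, 2.0, (0.0, 5.0))])

    def test_ld95_closed_form_relation(self):
        # log10 LD95 = log10 LD50 + z(0.95)/slope
        slope, ld95 = 2.0, 21.0
        ld50 = ld95 / 10 ** (stats.norm.ppf(0.95) / slope)
        p = stats.norm.cdf(slope * (np.log10(ld95) - np.log10(ld50)))
        assert abs(p - 0.95) < 1e-12
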