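import numpy as np
import pandas as pd
import pytest

from poolscan import simulate as sim
from poolscan import sv


def pair_frame(rows):
    df = pd.DataFrame(rows, columns=["left_pos", "right_pos", "left_strand",
                                     "right_strand"])
    df["read_len"] = 100
    df["scaffold"] = "s1"
    df["insert"] = df["right_pos"] + 100 - df["left_pos"]
    return df


@pytest.fixture
def normal_stats():
    rng = np.random.default_rng(0)
    n = 5000
    left = rng.integers(1, 100_000, n)
    ins = rng.normal(300, 50, n).astype(int)
    df = pair_frame([(l, l + i - 100, "+", "-") for l, i in zip(left, ins)])
    return sv.insert_stats(df, "s1")


class TestInsertStats:
    def test_cutoff_is_four_sd(self, normal_stats):
        # Normal(300, 50) inserts: cutoff ~ 200 (slightly less after the
        # top-1% trim), q99 ~ 300 + 2.326 * 50
        assert 160 < normal_stats.cutoff < 210
        assert abs(normal_stats.q99 - 416) < 10

    def test_constant_inserts_skipped(self):
        df = pair_frame([(i * 10, i * 10 + 200, "+", "-") for i in range(100)])
        assert sv.insert_stats(df, "s1") is None

    def test_too_few_pairs_skipped(self):
        df = pair_frame([(100, 400, "+", "-")] * 10)
        assert sv.insert_stats(df, "s1") is None


class TestClassify:
    def test_classes(self, normal_stats):
        df = pair_frame([
            (100, 300, "+", "-"),   # proper
            (100, 300, "-", "+"),   # everted: tandem-duplication signature
            (100, 300, "+", "+"),   # same-strand: inversion signature
            (100, 300, "-", "-"),   # same-strand
            (100, 5000, "+", "-"),  # distant: insert above q99
        ])
        cls = sv.classify_pairs(df, normal_stats)
        assert cls.tolist() == ["proper", "everted", "same_strand",
                                "same_strand", "distant"]


class TestCluster:
    def test_tight_group_single_event(self, normal_stats):
        rows = [(1000 + i * 10, 9000 + i * 10, "-", "+") for i in range(5)]
        ev = sv.cluster_events(pair_frame(rows), "everted", normal_stats)
        assert len(ev) == 1 and ev[0].support == 5

    def test_distant_groups_split(self, normal_stats):
        rows = ([(1000 + i, 9000 + i, "-", "+") for i in range(4)]
                + [(11_000 + i, 19_000 + i, "-", "+") for i in range(4)])
        ev = sv.cluster_events(pair_frame(rows), "everted", normal_stats)
        assert len(ev) == 2

    def test_min_support(self, normal_stats):
        rows = [(1000, 9000, "-", "+"), (1010, 9010, "-", "+")]
        assert sv.cluster_events(pair_frame(rows), "everted", normal_stats,
                                 min_support=3) == []

    def test_left_close_right_far_not_joined(self, normal_stats):
        rows = ([(1000 + i, 9000 + i, "-", "+") for i in range(3)]
                + [(1000 + i, 30_000 + i, "-", "+") for i in range(3)])
        ev = sv.cluster_events(pair_frame(rows), "everted", normal_stats)
        assert len(ev) == 2


class TestMatch:
    def mk(self, start, end, orientation="everted"):
        return sv.CandidateEvent("s1", orientation, start, end, 5)

    def test_identical_matched(self):
        m = sv.match_events([self.mk(100, 9000)], [self.mk(100, 9000)], 200, 200)
        assert m[0][1] is not None

    def test_boundary_inclusive(self):
        m = sv.match_events([self.mk(100, 9000)], [self.mk(500, 9000)], 200, 200)
        assert m[0][1] is not None  # start difference exactly the cutoff sum

    def test_beyond_boundary_unmatched(self):
        m = sv.match_events([self.mk(100, 9000)], [self.mk(501, 9000)], 200, 200)
        assert m[0][1] is None

    def test_class_mismatch_unmatched(self):
        m = sv.match_events([self.mk(100, 9000)],
                            [self.mk(100, 9000, "same_strand")], 200, 200)
        assert m[0][1] is None

    def test_reference_event_used_once(self):
        m = sv.match_events([self.mk(100, 9000), self.mk(150, 9050)],
                            [self.mk(100, 9000)], 200, 200)
        assert sum(r is not None for _, r in m) == 1


class TestMaskedDepth:
    def test_uniform(self):
        t = sv.DepthTrack(np.full(1000, 30))
        assert t.masked_mean(1, 1000) == pytest.approx(30)

    def test_masked_bases_excluded_not_zeroed(self):
        depth = np.concatenate([np.full(500, 30), np.zeros(500)])
        t = sv.DepthTrack(depth, [(501, 1000)])
        assert t.masked_mean(1, 1000) == pytest.approx(30)

    def test_over_ninety_percent_masked_missing(self):
        t = sv.DepthTrack(np.full(1000, 30), [(1, 950)])
        assert np.isnan(t.masked_mean(1, 1000))


class TestNullRatioTable:
    def test_identical_tracks_unit_ratio(self):
        depth = {"s1": np.full(2_000_000, 30)}
        tf = {"s1": sv.DepthTrack(depth["s1"])}
        tab = sv.null_ratio_table(tf, tf, {"s1": 2_000_000}, n=400, seed=0)
        assert np.allclose(tab.q25[~np.isnan(tab.q25)], 1)
        assert np.allclose(tab.q75[~np.isnan(tab.q75)], 1)

    def test_doubled_focal(self):
        tf = {"s1": sv.DepthTrack(np.full(2_000_000, 60))}
        tr = {"s1": sv.DepthTrack(np.full(2_000_000, 30))}
        tab = sv.null_ratio_table(tf, tr, {"s1": 2_000_000}, n=400, seed=0)
        assert np.allclose(tab.q75[~np.isnan(tab.q75)], 2)

    def test_poisson_tracks_bracket_one(self):
        # classes whose windows are small relative to the scaffold give
        # near-independent samples whose IQR brackets 1; the largest classes
        # reuse almost the whole track and only reflect its global ratio
        rng = np.random.default_rng(1)
        tf = {"s1": sv.DepthTrack(rng.poisson(30, 2_000_000))}
        tr = {"s1": sv.DepthTrack(rng.poisson(30, 2_000_000))}
        tab = sv.null_ratio_table(tf, tr, {"s1": 2_000_000}, n=800, seed=2)
        small = tab.edges[1:] <= 2_000_000 / 8
        ok = small & ~np.isnan(tab.q25)
        assert ok.sum() >= 4
        assert np.all(tab.q25[ok] <= 1) and np.all(tab.q75[ok] >= 1)


class TestTypeAndFilter:
    def mk_tracks(self, ratio=1.8, n=3_000_000):
        tf = {"s1": sv.DepthTrack(np.full(n, int(30 * ratio)))}
        tr = {"s1": sv.DepthTrack(np.full(n, 30))}
        return tf, tr

    def null(self):
        return sv.NullRatioTable(sv.size_class_edges(),
                                 np.full(8, 0.95), np.full(8, 1.2), np.full(8, 50), 0)

    def test_everted_high_ratio_tandem(self):
        tf, tr = self.mk_tracks(1.8)
        ev = sv.CandidateEvent("s1", "everted", 10_000, 15_000, 5)
        out = sv.type_and_filter([ev], self.null(), tf, tr)
        assert out and out[0].sv_class == "tandem_dup"

    def test_same_strand_unit_ratio_inversion(self):
        tf, tr = self.mk_tracks(1.0)
        ev = sv.CandidateEvent("s1", "same_strand", 10_000, 15_000, 5)
        out = sv.type_and_filter([ev], self.null(), tf, tr)
        assert out and out[0].sv_class == "inversion"

    def test_everted_unit_ratio_discarded(self):
        tf, tr = self.mk_tracks(1.0)
        ev = sv.CandidateEvent("s1", "everted", 10_000, 15_000, 5)
        assert sv.type_and_filter([ev], self.null(), tf, tr) == []

    def test_span_filter(self):
        tf, tr = self.mk_tracks(1.8)
        ev = sv.CandidateEvent("s1", "everted", 10_000, 13_498, 5)  # span 3499
        assert sv.type_and_filter([ev], self.null(), tf, tr) == []


class TestTeExtremityFilter:
    def mk(self):
        return sv.CandidateEvent("s1", "everted", 10_000, 20_000, 5,
                                 sv_class="tandem_dup")

    def test_overlap_exactly_100_retained(self):
        mask = {"s1": [(10_000, 10_099)]}  # 100 bp of the left 150 bp window
        assert sv.te_extremity_filter([self.mk()], mask)

    def test_overlap_101_dropped(self):
        mask = {"s1": [(10_000, 10_100)]}
        assert sv.te_extremity_filter([self.mk()], mask) == []

    def test_no_te_retained(self):
        assert sv.te_extremity_filter([self.mk()], {"s1": [(50_000, 60_000)]})


class TestFrequencyAndFst:
    def test_zero_support_zero_frequency(self):
        assert sv.sv_frequency(0, 30.0, 300, 50, 100, "inversion") == 0.0

    def test_capped_at_one(self):
        assert sv.sv_frequency(1000, 30.0, 300, 50, 100, "tandem_dup") == 1.0

    def test_consistent_for_inversion_geometry(self):
        # expected support per junction at f: f * depth/(2*rl) * E[(F-2rl)+];
        # two junctions for an inversion
        f, depth, rl = 0.6, 30.0, 100
        overhang = 100.44  # E[(F-200)+] for Normal(300,50)
        support = 2 * f * depth / (2 * rl) * overhang
        est = sv.sv_frequency(support, depth, 300, 50, rl, "inversion")
        assert est == pytest.approx(f, abs=0.02)

    def test_duplication_flank_amplification_inverted(self):
        f, depth, rl = 0.6, 30.0, 100
        overhang = 100.44
        support = f * depth / (2 * rl) * overhang
        flank = depth * (1 + f)  # inward flanks share the amplification
        est = sv.sv_frequency(support, flank, 300, 50, rl, "tandem_dup")
        assert est == pytest.approx(f, abs=0.02)

    def test_fst_values(self):
        assert sv.sv_fst(1.0, 0.0) == pytest.approx(1.0)
        assert sv.sv_fst(0.4, 0.1) == pytest.approx(0.09 / 0.42)
        assert sv.sv_fst(0.0, 0.0) == 0.0

    def test_select_requires_focal_higher(self):
        df = pd.DataFrame({
            "sv_class": ["inversion"] * 3,
            "f_focal": [0.2, 0.9, 0.5], "f_ref": [0.5, 0.1, 0.2],
            "scaffold": "s1", "start": [1, 2, 3], "end": [10, 20, 30]})
        out = sv.sv_fst_and_select(df, q=0.5)
        assert set(out.index) == {1, 2}
        assert out.loc[1, "selected"]  # highest FST of the class


class TestGenesOverlapping:
    def test_margin(self):
        from poolscan.io import GeneModel, GenomeAnnotation
        g1 = GeneModel("near", "s1", "+", 20_500, 21_000)  # 500 bp downstream
        g2 = GeneModel("far", "s1", "+", 21_001, 22_000)   # 1001 bp away
        g3 = GeneModel("inside", "s1", "+", 12_000, 13_000)
        ann = GenomeAnnotation({"s1": 100_000}, genes=[g1, g2, g3],
                               categories={"near": "P450"})
        ev = pd.DataFrame({"scaffold": ["s1"], "start": [10_000], "end": [20_000],
                           "sv_class": ["tandem_dup"]})
        out = sv.genes_overlapping(ev, ann, margin=1000)
        assert set(out["gene_id"]) == {"near", "inside"}
        assert out.loc[out["gene_id"] == "near", "category"].iloc[0] == "P450"


class TestEndToEnd:
    def test_planted_events_recovered(self):
        plan = [
            sim.SvPlan("tandem_dup", "s1", 100_000, 20_000, {"fieldA": 0.8, "labA": 0.0}),
            sim.SvPlan("inverted_dup", "s1", 300_000, 15_000, {"fieldA": 0.8, "labA": 0.0}),
        ]
        cfg = sim.SimConfig(seed=21, scaffold_lengths={"s1": 600_000}, sv_plan=plan,
                            n_loci=10)
        pairs, depth, _ = sim.sim_sv_readpairs(cfg)
        ev = sv.detect_svs(pairs["fieldA"], pairs["labA"], depth["fieldA"],
                           depth["labA"], {"s1": 600_000}, seed=3,
                           n_null_windows=800)
        ev = ev.sort_values("start").reset_index(drop=True)
        assert list(ev["sv_class"]) == ["tandem_dup", "inverted_dup"]
        assert abs(ev.loc[0, "start"] - 100_000) < 100
        assert abs(ev.loc[0, "end"] - 119_999) < 100
        assert (ev["f_ref"] == 0).all()
        assert (ev["f_focal"] > 0.5).all()

    def test_identical_pools_nothing_selected(self):
        plan = [sim.SvPlan("tandem_dup", "s1", 100_000, 20_000,
                           {"fieldA": 0.8, "labA": 0.8})]
        cfg = sim.SimConfig(seed=22, scaffold_lengths={"s1": 400_000}, sv_plan=plan,
                            n_loci=10)
        pairs, depth, _ = sim.sim_sv_readpairs(cfg)
        ev = sv.detect_svs(pairs["fieldA"], pairs["fieldA"], depth["fieldA"],
                           depth["fieldA"], {"s1": 400_000}, seed=3,
                           n_null_windows=800)
        # identical pair sets: frequencies tie, so nothing passes selection
        assert not ev["selected"].any()
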