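"""End-to-end benchmark scenarios exercising every stage of the scan on
synthetic data at the study's design scale.  Each function simulates its
inputs, runs the relevant pipeline stages, and returns measured quantities;
the test suite and the acceptance script both consume these."""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import bioassay as ba
from . import contrast, enrichment, outliers, simulate as sim, snp_stats, sv
from .io import PoolSnpTable, PoolSpec


def worked_example_resistance_ratio() -> dict:
    """Resistance ratio between LD95 values of 69.2 and 21.0 ng per insect."""
    raw, rounded = ba.resistance_ratio(69.2, 21.0)
    return {"ratio_raw": raw, "ratio_rounded": rounded}


def fst_estimator_checks(seed: int = 0) -> dict:
    """Estimator identities and null behaviour of the pool FST."""
    rng = np.random.default_rng(seed)
    pools = [PoolSpec("a", "resistant", 30), PoolSpec("b", "susceptible", 30)]

    # dual-route: per-locus estimator vs direct evaluation of the formulas
    cov = rng.integers(2, 60, size=(1000, 2))
    alt = rng.integers(0, cov + 1)
    t = _table(pools, cov - alt, alt)
    r = snp_stats.pool_fst(t, "a", "b")
    max_diff = 0.0
    for l in range(1000):
        pa, pb = alt[l, 0] / cov[l, 0], alt[l, 1] / cov[l, 1]
        ha = 2 * pa * (1 - pa) * (60 / 59) * (cov[l, 0] / (cov[l, 0] - 1))
        hb = 2 * pb * (1 - pb) * (60 / 59) * (cov[l, 1] / (cov[l, 1] - 1))
        q1, q2 = 1 - (ha + hb) / 2, pa * pb + (1 - pa) * (1 - pb)
        if q2 < 1:
            max_diff = max(max_diff, abs(r.per_locus[l] - (q1 - q2) / (1 - q2)))

    fixed = _table(pools, [[0, 30]], [[30, 0]])
    fixed_fst = float(snp_stats.pool_fst(fixed, "a", "b").per_locus[0])

    # identical-pool null at depth 30x, haploid size 60
    L = 10_000
    pi = rng.uniform(0.05, 0.95, L)
    covn = np.maximum(rng.poisson(30, size=(L, 2)), 2)
    k = rng.binomial(60, pi[:, None], size=(L, 2))
    altn = rng.binomial(covn, k / 60)
    null = snp_stats.pool_fst(_table(pools, covn - altn, altn), "a", "b")
    return {"formula_max_abs_diff": max_diff, "fixed_difference_fst": fixed_fst,
            "null_mean_abs_fst": abs(float(np.nanmean(null.per_locus)))}


def fst_island_calibration(seed: int = 0, n_loci: int = 50_000,
                           true_fst: float = 0.05) -> dict:
    """Global pairwise FST on an island model with known differentiation."""
    t = sim.sim_island_snps(n_loci, fst=true_fst, seed=seed)
    names = [p.name for p in t.pools]
    ests = [snp_stats.pool_fst(t, a, b).global_fst
            for i, a in enumerate(names) for b in names[i + 1:]]
    return {"true_fst": true_fst, "mean_global_fst": float(np.mean(ests)),
            "max_abs_error": float(np.max(np.abs(np.array(ests) - true_fst)))}


def _contrast_scan(table, pools, focal, matched):
    freqs = table.alt_freq
    keep = snp_stats.maf_filter(freqs.mean(axis=1))
    sub = table.subset(keep)
    a, m = contrast.standardize(freqs[keep])
    omega = contrast.estimate_omega(a)
    c = np.array([1.0 if p.status == "resistant" else -1.0 for p in pools])
    res = contrast.c2_statistic(a, omega, c)
    res.lfdr = contrast.local_fdr(res.p_value)
    res.db = contrast.approx_bayes_factor(res.y)
    fst = snp_stats.pool_fst(sub, focal, matched)
    flags = outliers.combine(
        outliers.fst_top_quantile(fst.per_locus[m]),
        res.lfdr, res.db,
        outliers.derived_up_filter(freqs[keep][m], table.pool_index(focal),
                                   table.pool_index(matched)))
    return keep, m, res, flags


def c2_null_calibration(seed: int = 0, n_loci: int = 50_000) -> dict:
    """Type-I calibration of the contrast statistic under the null."""
    cfg = sim.SimConfig(seed=seed, n_loci=n_loci,
                        scaffold_lengths={"scaf1": 30_000_000})
    table, _ = sim.sim_pool_snps(cfg)
    freqs = table.alt_freq
    keep = snp_stats.maf_filter(freqs.mean(axis=1))
    a, _ = contrast.standardize(freqs[keep])
    omega = contrast.estimate_omega(a)
    res = contrast.c2_statistic(a, omega, np.array([1.0, 1, -1, -1]))
    ks = stats.kstest(res.c2, stats.chi2(1).cdf)
    return {"frac_p_below_05": float((res.p_value < 0.05).mean()),
            "ks_p_value": float(ks.pvalue), "n_loci": int(len(res.c2))}


def outlier_recovery(seed: int = 0, n_loci: int = 100_000,
                     n_selected: int = 100, delta: float = 0.35) -> dict:
    """Precision/recall of the combined outlier filter on a synthetic
    superlocus, plus an exact brute-force check of the window counts."""
    blk = sim.SelectedBlock("scaf2", 2_000_000, 8_000_000,
                            n_selected=n_selected, delta=delta)
    cfg = sim.SimConfig(seed=seed, n_loci=n_loci,
                        scaffold_lengths={f"scaf{i}": 10_000_000 for i in (1, 2, 3)},
                        selected=blk)
    table, truth = sim.sim_pool_snps(cfg)
    keep, m, res, flags = _contrast_scan(table, cfg.pools, "fieldA", "labA")
    sel = truth["selected"].to_numpy()[keep][m]
    call = flags["is_outlier"].to_numpy()
    tp = int((call & sel).sum())
    sub = table.subset(keep).subset(m)
    out_pos = {s: sub.position[(sub.scaffold == s) & call]
               for s in cfg.scaffold_lengths}
    rec, q99 = snp_stats.sliding_outlier_counts(out_pos, cfg.scaffold_lengths)
    rng = np.random.default_rng(seed + 1)
    brute_ok = all(
        row["count"] == ((out_pos[row["scaffold"]] >= row["start"])
                         & (out_pos[row["scaffold"]] <= row["end"])).sum()
        for row in rec[rng.choice(len(rec), 500, replace=False)])
    return {"n_called": int(call.sum()), "true_positives": tp,
            "precision": tp / max(int(call.sum()), 1),
            "recall": tp / n_selected,
            "window_counts_match_brute_force": bool(brute_ok),
            "window_q99": q99}


def _sv_plan(rng, classes, scaffold_lengths, freq):
    plan, i = [], 0
    per_scaf = len(classes) // len(scaffold_lengths)
    for scaf in scaffold_lengths:
        pos = 100_000
        for _ in range(per_scaf):
            span = int(rng.uniform(5_000, 50_000))
            plan.append(sim.SvPlan(classes[i], scaf, pos, span, dict(freq)))
            pos += span + 150_000
            i += 1
    return plan


def sv_recovery(seed: int = 0) -> dict:
    """Detection of 45 planted events (15 per class) at focal frequency 0.8."""
    rng = np.random.default_rng(seed)
    classes = ["tandem_dup"] * 15 + ["inverted_dup"] * 15 + ["inversion"] * 15
    rng.shuffle(classes)
    scafs = {f"scaf{i}": 3_000_000 for i in (1, 2, 3)}
    plan = _sv_plan(rng, classes, scafs, {"fieldA": 0.8, "labA": 0.0})
    cfg = sim.SimConfig(seed=seed, n_loci=10, scaffold_lengths=scafs, sv_plan=plan)
    pairs, depth, truth = sim.sim_sv_readpairs(cfg)
    events = sv.detect_svs(pairs["fieldA"], pairs["labA"], depth["fieldA"],
                           depth["labA"], scafs, seed=seed)
    detected_correct = 0
    bp_err = []
    for ev in plan:
        hits = events[(events["scaffold"] == ev.scaffold)
                      & (abs(events["start"] - ev.start) < 2000)
                      & (abs(events["end"] - ev.end) < 2000)]
        match = hits[hits["sv_class"] == ev.sv_class]
        if len(match):
            detected_correct += 1
            bp_err.append(max(abs(int(match["start"].iloc[0]) - ev.start),
                              abs(int(match["end"].iloc[0]) - ev.end)))
    dup_in_inversion = 0
    for _, e in events[events["sv_class"] == "tandem_dup"].iterrows():
        for ev in plan:
            if (ev.sv_class == "inversion" and ev.scaffold == e["scaffold"]
                    and e["start"] >= ev.start - 500 and e["end"] <= ev.end + 500):
                dup_in_inversion += 1
    # null-table sanity on equal-coverage tracks
    rng2 = np.random.default_rng(seed + 5)
    tf = {"s": sv.DepthTrack(rng2.poisson(30, 3_000_000))}
    tr = {"s": sv.DepthTrack(rng2.poisson(30, 3_000_000))}
    tab = sv.null_ratio_table(tf, tr, {"s": 3_000_000}, n=2000, seed=seed)
    small = tab.edges[1:] <= 3_000_000 / 8
    ok = small & ~np.isnan(tab.q25)
    null_brackets_one = bool(np.all(tab.q25[ok] <= 1) and np.all(tab.q75[ok] >= 1))
    return {"n_planted": len(plan), "n_detected_correct_class": detected_correct,
            "detection_rate": detected_correct / len(plan),
            "max_breakpoint_error_bp": int(max(bp_err)) if bp_err else -1,
            "insert_sd": cfg.insert_sd,
            "tandem_calls_inside_inversions": dup_in_inversion,
            "null_table_brackets_one": null_brackets_one}


def sv_frequency_consistency(seed: int = 0, n_per_freq: int = 9) -> dict:
    """Median |f_hat - f| for planted tandem duplications at several f."""
    rng = np.random.default_rng(seed)
    scafs = {"scaf1": 3_500_000, "scaf2": 3_500_000, "scaf3": 3_500_000}
    freqs_true = [0.2, 0.5, 0.8]
    plan, i = [], 0
    for scaf in scafs:
        pos = 100_000
        for _ in range(n_per_freq):
            span = int(rng.uniform(8_000, 30_000))
            f = freqs_true[i % 3]
            plan.append(sim.SvPlan("tandem_dup", scaf, pos, span,
                                   {"fieldA": f, "labA": 0.0}))
            pos += span + 80_000
            i += 1
    cfg = sim.SimConfig(seed=seed, n_loci=10, scaffold_lengths=scafs, sv_plan=plan)
    pairs, depth, _ = sim.sim_sv_readpairs(cfg)
    events = sv.detect_svs(pairs["fieldA"], pairs["labA"], depth["fieldA"],
                           depth["labA"], scafs, seed=seed)
    errors = []
    for ev in plan:
        hits = events[(events["scaffold"] == ev.scaffold)
                      & (abs(events["start"] - ev.start) < 2000)
                      & (events["sv_class"] == "tandem_dup")]
        if len(hits):
            errors.append(abs(float(hits["f_focal"].iloc[0]) - ev.freq["fieldA"]))
    return {"n_planted": len(plan), "n_measured": len(errors),
            "median_abs_freq_error": float(np.median(errors)) if errors else 1.0}


def pinpis_neutrality(seed: int = 0, n_genes: int = 500) -> dict:
    """Mean piN/piS under equal-rate CDS mutation, and site-count closure."""
    from .effects import nei_gojobori_sites, pi_n_pi_s
    from .io import GeneModel
    rng = np.random.default_rng(seed)
    pools = [PoolSpec("a", "resistant", 30), PoolSpec("b", "susceptible", 30)]
    ratios = []
    max_site_closure_err = 0.0
    for i in range(n_genes):
        L = 900
        seq = sim._random_cds(rng, L)
        g = GeneModel(f"g{i}", "s1", "+", 1001, 1000 + L,
                      cds_segments=[(1001, 1000 + L)], exons=[(1001, 1000 + L)],
                      cds_seq=seq)
        nn, ss = nei_gojobori_sites(seq)
        max_site_closure_err = max(max_site_closure_err, abs(nn + ss - L))
        pos = np.sort(rng.choice(L, 120, replace=False)) + 1001
        refs = np.array([seq[p - 1001] for p in pos], dtype=object)
        alts = np.array([rng.choice([b for b in "ACGT" if b != r]) for r in refs],
                        dtype=object)
        t = _table(pools, np.full((120, 2), 15), np.full((120, 2), 15),
                   positions=pos, scaffold="s1")
        t.ref, t.alt = refs, alts
        r = pi_n_pi_s(g, t, "a")
        if r.pi_s > 0:
            ratios.append(r.ratio)
    return {"mean_ratio": float(np.mean(ratios)), "n_genes": len(ratios),
            "max_site_count_error": max_site_closure_err}


def enrichment_checks(seed: int = 0, n_replicates: int = 100) -> dict:
    """Exact binomial tails vs brute force; scaffold chi-square under uniform
    SV placement."""
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(200):
        n = int(rng.integers(5, 1000))
        x = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.001, 0.999))
        r = enrichment.binomial_enrichment(x, n, p0)
        brute = float(stats.binom.pmf(np.arange(x, n + 1), n, p0).sum())
        max_diff = max(max_diff, abs(r.p_raw - brute))
    lens = {f"s{i}": 1_000_000 for i in range(12)}
    n_sig = 0
    for _ in range(n_replicates):
        scafs = rng.choice(12, 300)
        counts = {f"s{i}": int((scafs == i).sum()) for i in range(12)}
        res = enrichment.sv_scaffold_chi2(counts, lens)
        n_sig += any(r.p_corrected < 0.05 for r in res)
    return {"binomial_tail_max_abs_diff": max_diff,
            "frac_replicates_no_significant_scaffold": 1 - n_sig / n_replicates}


def probit_recovery(seed: int = 0, n_assays: int = 100) -> dict:
    """CI coverage of LD95 across simulated assays, and the closed form."""
    slope, ld95 = 2.0, 21.0
    ld50 = ld95 / 10 ** (stats.norm.ppf(0.95) / slope)
    doses = tuple(ld50 * np.geomspace(0.15, 8, 7))
    covered = 0
    fit = None
    for i in range(n_assays):
        tbl = sim.sim_bioassay([sim.BioassayPlan("x", ld50, slope, doses)],
                               seed=seed * 100_003 + i)
        fit = ba.fit_probit(tbl, "x")
        lo, hi = ba.ld(fit, 0.95).ci95
        covered += lo <= ld95 <= hi
    closed = abs(np.log10(ba.ld(fit, 0.95).ld)
                 - (stats.norm.ppf(0.95) - fit.intercept) / fit.slope)
    return {"ci95_coverage": covered, "n_assays": n_assays,
            "closed_form_abs_err": float(closed), "true_ld95": ld95}


def _table(pools, ref_counts, alt_counts, positions=None, scaffold="scaf1"):
    ref_counts = np.atleast_2d(np.asarray(ref_counts)).astype(np.int64)
    alt_counts = np.atleast_2d(np.asarray(alt_counts)).astype(np.int64)
    L = ref_counts.shape[0]
    positions = np.asarray(positions if positions is not None
                           else np.arange(1, L + 1) * 100)
    return PoolSnpTable(
        pools, np.array([scaffold] * L, dtype=object), positions,
        np.array(["A"] * L, dtype=object), np.array(["T"] * L, dtype=object),
        ref_counts, alt_counts)
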