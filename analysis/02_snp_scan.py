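#!/usr/bin/env python
"""SNP branch of the scan: coverage/MAF filtering, pool FST, PCA,
covariance-aware contrast statistics, and the combined outlier call.

Reads results/inputs/, writes per-locus statistics and window counts under
results/, and prints the headline numbers (retained loci, global FST,
outlier count, precision against the simulation truth).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from poolscan import contrast, outliers, snp_stats
from poolscan.io import read_sync
from poolscan.simulate import default_pools

ROOT = Path(__file__).resolve().parent.parent / "results"
IN = ROOT / "inputs"

pools = default_pools()
table = read_sync(IN / "snps.sync", pools)
truth = pd.read_csv(IN / "snp_truth.tsv", sep="\t")

freqs = table.alt_freq
keep = snp_stats.maf_filter(freqs.mean(axis=1), 0.2)
sub = table.subset(keep)
print(f"{len(table)} biallelic SNPs in coverage bounds; {keep.sum()} pass MAF >= 0.2")

fst = snp_stats.pool_fst(sub, "fieldA", "labA")
print(f"global FST fieldA vs labA: {fst.global_fst:.4f}")

coords, frac = snp_stats.pca_pools(freqs[keep], [p.name for p in pools])
print("PCA variance fractions:", np.round(frac[:3], 3))

a, m = contrast.standardize(freqs[keep])
omega = contrast.estimate_omega(a)
res = contrast.c2_statistic(a, omega, np.array([1.0, 1, -1, -1]))
res.lfdr = contrast.local_fdr(res.p_value)
res.db = contrast.approx_bayes_factor(res.y)
flags = outliers.combine(
    outliers.fst_top_quantile(fst.per_locus[m], 0.95),
    res.lfdr, res.db,
    outliers.derived_up_filter(freqs[keep][m], sub.pool_index("fieldA"),
                               sub.pool_index("labA")))

sub2 = sub.subset(m)
out = pd.DataFrame({"scaffold": sub2.scaffold, "position": sub2.position,
                    "fst": fst.per_locus[m], "c2": res.c2, "p": res.p_value,
                    "lfdr": res.lfdr, "db": res.db})
out = pd.concat([out, flags.reset_index(drop=True)], axis=1)
out.to_csv(ROOT / "outlier_snps.tsv", sep="\t", index=False)

called = out[out["is_outlier"]]
truth_idx = truth.set_index(["scaffold", "position"])["selected"]
hits = truth_idx.reindex(list(zip(called["scaffold"], called["position"]))).fillna(False)
print(f"{len(called)} outlier SNPs called; {int(hits.sum())} are truly selected "
      f"(precision {hits.mean() if len(called) else float('nan'):.2f})")

lengths = {s: int(sub2.position[sub2.scaffold == s].max()) for s in set(sub2.scaffold)}
pos = {s: called.loc[called["scaffold"] == s, "position"].to_numpy() for s in lengths}
windows, q99 = snp_stats.sliding_outlier_counts(pos, lengths)
pd.DataFrame(windows).to_csv(ROOT / "outlier_windows.tsv", sep="\t", index=False)
dense = windows[windows["count"] > max(q99, 0)]
print(f"window q99 = {q99:.1f}; {len(dense)} windows above it "
      f"(densest at {windows[np.argmax(windows['count'])]['scaffold']}:"
      f"{windows[np.argmax(windows['count'])]['start']})")
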