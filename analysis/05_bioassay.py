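#!/usr/bin/env python
"""Bioassay branch: probit fits per strain, LD95 with delta-method standard
errors, pairwise comparisons and resistance ratios; writes
results/bioassay_comparison.tsv."""

from pathlib import Path

import numpy as np

from poolscan import bioassay as ba
from poolscan.io import read_bioassay

ROOT = Path(__file__).resolve().parent.parent / "results"

tbl = read_bioassay(ROOT / "inputs" / "bioassay.tsv")
for strain in tbl.loc[tbl["dose"] > 0, "strain"].unique():
    fit = ba.fit_probit(tbl, strain)
    est = ba.ld(fit, 0.95)
    lo, hi = est.ci95
    print(f"{strain:>8}: slope {fit.slope:.2f}, LD95 {est.ld:7.2f} ng "
          f"[{lo:.2f}, {hi:.2f}]")

cmp_tbl = ba.strain_comparison_table(tbl)
cmp_tbl.to_csv(ROOT / "bioassay_comparison.tsv", sep="\t", index=False)
print("\npairwise LD95 comparisons:")
for _, r in cmp_tbl.iterrows():
    print(f"  {r['strain_a']:>8} vs {r['strain_b']:<8} "
          f"RR {r['resistance_ratio']:6.2f} (~{r['resistance_ratio_rounded']}x) "
          f"z {r['z']:6.2f} p {r['p_value']:.2e} {r['stars']}")
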