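#!/usr/bin/env python
"""Annotation branch: place outlier SNPs in genomic features, call coding
effects, compute per-gene piN/piS for the focal pool, test resistance-gene
category enrichment in the outlier-dense region, and overlap selected SVs
with genes."""

from pathlib import Path

import numpy as np
import pandas as pd

from poolscan import effects, enrichment, sv
from poolscan.io import read_bed_mask, read_gff3, read_sync
from poolscan.simulate import default_pools

ROOT = Path(__file__).resolve().parent.parent / "results"
IN = ROOT / "inputs"

ann = read_gff3(IN / "genes.gff3")
from poolscan.simulate import attach_cds_fasta
attach_cds_fasta(ann, IN / "cds.fasta")
ann.te_mask = read_bed_mask(IN / "te_mask.bed")
cats = pd.read_csv(IN / "gene_categories.tsv", sep="\t")
ann.categories = dict(zip(cats["gene_id"], cats["category"]))
table = read_sync(IN / "snps.sync", default_pools())
out = pd.read_csv(ROOT / "outlier_snps.tsv", sep="\t")

idx = effects.build_gene_index(ann)
calls = [effects.locate_snp(r["scaffold"], int(r["position"]), ann, index=idx)
         for _, r in out[out["is_outlier"]].iterrows()]
feat_counts = pd.Series([c.feature for c in calls]).value_counts()
print("outlier SNP feature placement:", feat_counts.to_dict())

# per-gene piN/piS in the focal pool
rows = []
for g in ann.genes:
    r = effects.pi_n_pi_s(g, table, "fieldA")
    if r is not None:
        rows.append({"gene_id": g.gene_id, "pi_n": r.pi_n, "pi_s": r.pi_s,
                     "ratio": r.ratio, "n_sites": r.n_sites, "s_sites": r.s_sites})
pinpis = pd.DataFrame(rows)
pinpis.to_csv(ROOT / "pinpis.tsv", sep="\t", index=False)
valid = pinpis["ratio"].dropna()
print(f"piN/piS over {len(valid)} genes with piS > 0: "
      f"mean {valid.mean():.2f}, 95% quantile {valid.quantile(0.95):.2f}")

# category enrichment inside the outlier-dense region vs the whole genome
dense = out[out["is_outlier"]]
if len(dense):
    scaf = dense["scaffold"].mode()[0]
    lo, hi = dense["position"].min() - 50_000, dense["position"].max() + 50_000
    region = [g for g in ann.genes if g.scaffold == scaf and g.start <= hi and g.end >= lo]
    n_region = len(region)
    x_region = sum(g.gene_id in ann.categories for g in region)
    x_genome = len(ann.categories)
    n_genome = len(ann.genes)
    res = enrichment.category_proportion_tests(
        {"resistance": (x_region, max(n_region, 1), x_genome, n_genome)})
    if res:
        r = res[0]
        print(f"region {scaf}:{lo}-{hi}: {x_region}/{n_region} resistance genes vs "
              f"{x_genome}/{n_genome} genome-wide (fold {r.fold:.2f}, p {r.p_raw:.3f})")

# genes overlapped by selected SVs (1 kb margin)
events = pd.read_csv(ROOT / "sv_events.tsv", sep="\t")
sel = events[events["selected"]]
ov = sv.genes_overlapping(sel, ann)
ov.to_csv(ROOT / "sv_gene_overlap.tsv", sep="\t", index=False)
n_res = int((ov["category"] != "").sum()) if len(ov) else 0
print(f"{len(ov)} gene overlaps with selected SVs ({n_res} resistance-category)")
if len(ov):
    t = enrichment.sv_gene_overlap_test(
        int((ov.drop_duplicates('gene_id')["category"] != "").sum()),
        int(ov["gene_id"].nunique()), len(ann.categories) / len(ann.genes))
    print(f"resistance-gene enrichment among SV-overlapped genes: p = {t.p_raw:.3f}")
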