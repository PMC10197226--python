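#!/usr/bin/env python
"""Generate the synthetic study cohort every later step consumes.

Four pools (two resistant field strains, two susceptible lab strains, ~30
diploids each, ~30x), a two-scaffold toy genome with ~7 kb genes and TE
intervals, a superlocus of selected SNPs, planted structural variants at
high frequency in the focal field pool, and probit bioassays.  Writes the
input bundle under results/inputs/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from poolscan import simulate as sim
from poolscan.cli import write_gff3
from poolscan.io import write_pairs_tsv, write_sync

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

OUT.mkdir(parents=True, exist_ok=True)
scaffolds = {"scaf1": 900_000, "scaf2": 700_000}
sv_plan = [
    sim.SvPlan("tandem_dup", "scaf1", 150_000, 20_000, {"fieldA": 0.8, "labA": 0.0}),
    sim.SvPlan("inverted_dup", "scaf1", 450_000, 15_000, {"fieldA": 0.8, "labA": 0.0}),
    sim.SvPlan("inversion", "scaf2", 250_000, 30_000, {"fieldA": 0.8, "labA": 0.0}),
]
cfg = sim.SimConfig(
    seed=SEED, n_loci=20_000, scaffold_lengths=scaffolds, sv_plan=sv_plan,
    selected=sim.SelectedBlock("scaf1", 250_000, 700_000, n_selected=60, delta=0.35),
    n_genes=120)

table, truth = sim.sim_pool_snps(cfg)
ann = sim.sim_genome(cfg)
sim.harmonize_snp_refs(table, ann, seed=SEED)
write_sync(table, OUT / "snps.sync")
truth.to_csv(OUT / "snp_truth.tsv", sep="\t", index=False)

write_gff3(ann, OUT / "genes.gff3")
sim.write_cds_fasta(ann, OUT / "cds.fasta")
with open(OUT / "te_mask.bed", "w") as fh:
    for scaf, ivs in ann.te_mask.items():
        for s, e in ivs:
            fh.write(f"{scaf}\t{s - 1}\t{e}\n")
cats = pd.DataFrame(sorted(ann.categories.items()), columns=["gene_id", "category"])
cats.to_csv(OUT / "gene_categories.tsv", sep="\t", index=False)

pairs, depth, sv_truth = sim.sim_sv_readpairs(cfg)
for pool in ("fieldA", "labA"):
    write_pairs_tsv(pairs[pool], OUT / f"pairs_{pool}.tsv")
    frames = [pd.DataFrame({"scaffold": scaf,
                            "position": np.arange(1, len(arr) + 1), "depth": arr})
              for scaf, arr in depth[pool].items()]
    pd.concat(frames).to_csv(OUT / f"depth_{pool}.tsv", sep="\t", index=False)
sv_truth.to_csv(OUT / "sv_truth.tsv", sep="\t", index=False)

# strains parameterized by their LD95 (ng per insect); slope 2 per log10 dose
z95 = 1.6448536269514722
ld95s = {"fieldA": 21.0, "fieldB": 69.2, "labA": 1.3, "labB": 0.4}
plans = [
    sim.BioassayPlan(strain, ld95 / 10 ** (z95 / 2.0), 2.0,
                     tuple(ld95 * np.geomspace(0.02, 3.0, 7)))
    for strain, ld95 in ld95s.items()
]
sim.sim_bioassay(plans, seed=SEED).to_csv(OUT / "bioassay.tsv", sep="\t", index=False)
(OUT / "manifest.json").write_text(json.dumps(cfg.manifest(), indent=2))

print(f"wrote {len(table)} SNPs ({int(truth['selected'].sum())} selected), "
      f"{len(ann.genes)} genes, {len(sv_plan)} planted SVs, "
      f"{len(plans)} bioassay strains -> {OUT}")
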