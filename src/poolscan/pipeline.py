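"""End-to-end orchestration of the scan with configuration and provenance.

``run_all`` executes the SNP branch (io -> frequencies/FST -> contrast ->
outliers -> annotation effects -> enrichment), the SV branch (pairs/depth ->
SV detection -> gene overlap enrichment) and the bioassay branch on a
directory of input files, writing TSV outputs plus a JSON manifest with
seeds, the configuration hash, and per-stage record counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bioassay as ba
from . import contrast, enrichment, outliers, snp_stats, sv
from .io import (PoolSpec, read_bed_mask, read_bioassay, read_gff3,
                 read_marker_table, read_pairs_tsv, read_sync)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    pools: list[PoolSpec]
    focal_resistant: str
    matched_susceptible: str
    min_cov: int = 10
    max_cov: int = 50
    maf: float = 0.2
    fst_quantile: float = 0.95
    lfdr_max: float = 0.2
    bf_min_db: float = 5.0
    enable_bf: bool = True
    sv_upper_q: float = 0.75
    sv_lower_q: float = 0.25
    sv_fst_quantile: float = 0.90
    min_span: int = 3500
    flank: int = 150
    te_overlap: int = 100
    window: int = 100_000
    step: int = 10_000
    promoter_len: int = 1000
    min_support: int = 3
    seed: int = 0

    def validate(self) -> None:
        names = {p.name for p in self.pools}
        if self.focal_resistant not in names or self.matched_susceptible not in names:
            raise ValueError("focal/matched pool not among pool specs")
        for attr, lo, hi in [("maf", 0, 0.5), ("fst_quantile", 0, 1),
                             ("lfdr_max", 0, 1), ("sv_fst_quantile", 0, 1)]:
            v = getattr(self, attr)
            if not lo <= v <= hi:
                raise ValueError(f"{attr}={v} outside [{lo}, {hi}]")

    def config_hash(self) -> str:
        blob = json.dumps({k: (v if not isinstance(v, list) else
                               [(p.name, p.status, p.n_individuals) for p in v])
                           for k, v in self.__dict__.items()}, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        pools = [PoolSpec(p["name"], p["status"], p["n_individuals"])
                 for p in raw.pop("pools")]
        return cls(pools=pools, **raw)


def _stage(manifest, name, n_in, n_out):
    manifest["stages"].append({"stage": name, "records_in": int(n_in),
                               "records_out": int(n_out),
                               "records_dropped": int(n_in - n_out)})


def run_all(config: RunConfig, indir, outdir) -> dict:
    """Run every stage on the files in ``indir``; returns the manifest.

    Expected inputs: snps.sync, genes.gff3, te_mask.bed, markers.tsv,
    pairs_<pool>.tsv, depth_<pool>.tsv, bioassay.tsv.  Missing bioassay or
    SV inputs skip those branches; a missing sync or GFF3 aborts.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    manifest = {"config_hash": config.config_hash(), "seed": config.seed, "stages": []}

    # --- io ---------------------------------------------------------------
    sync = indir / "snps.sync"
    gff = indir / "genes.gff3"
    for f, stage in [(sync, "io:snps"), (gff, "io:annotation")]:
        if not f.exists():
            raise FileNotFoundError(f"stage {stage}: missing input {f}")
    table = read_sync(sync, config.pools, config.min_cov, config.max_cov)
    ann = read_gff3(gff, promoter_len=config.promoter_len)
    if (indir / "te_mask.bed").exists():
        ann.te_mask = read_bed_mask(indir / "te_mask.bed")
    if (indir / "markers.tsv").exists():
        ann.lg_map = read_marker_table(indir / "markers.tsv")
    scaffold_lengths = ann.scaffold_lengths or {
        s: int(table.position[table.scaffold == s].max()) + 1000
        for s in np.unique(table.scaffold)}

    # --- snp branch --------------------------------------------------------
    freqs = table.alt_freq
    keep = snp_stats.maf_filter(freqs.mean(axis=1), config.maf)
    _stage(manifest, "maf_filter", len(table), keep.sum())
    sub = table.subset(keep)
    freqs = freqs[keep]
    fst = snp_stats.pool_fst(sub, config.focal_resistant, config.matched_susceptible)
    a, amask = contrast.standardize(freqs)
    sub2 = sub.subset(amask)
    omega = contrast.estimate_omega(a)
    cvec = np.array([1.0 if p.status == "resistant" else -1.0 for p in config.pools])
    res = contrast.c2_statistic(a, omega, cvec)
    res.lfdr = contrast.local_fdr(res.p_value)
    res.db = contrast.approx_bayes_factor(res.y)
    fst_sub = fst.per_locus[amask]
    flags = outliers.combine(
        outliers.fst_top_quantile(fst_sub, config.fst_quantile),
        res.lfdr, res.db,
        outliers.derived_up_filter(freqs[amask],
                                   sub.pool_index(config.focal_resistant),
                                   sub.pool_index(config.matched_susceptible)),
        lfdr_max=config.lfdr_max, db_min=config.bf_min_db, enable_bf=config.enable_bf)
    _stage(manifest, "outlier_scan", len(flags), flags["is_outlier"].sum())
    out_tbl = pd.DataFrame({
        "scaffold": sub2.scaffold, "position": sub2.position,
        "fst": fst_sub, "c2": res.c2, "p": res.p_value, "lfdr": res.lfdr,
        "db": res.db})
    out_tbl = pd.concat([out_tbl, flags.reset_index(drop=True)], axis=1)
    out_tbl.to_csv(outdir / "outlier_snps.tsv", sep="\t", index=False)

    out_pos = {s: out_tbl.loc[(out_tbl["scaffold"] == s) & out_tbl["is_outlier"],
                              "position"].to_numpy()
               for s in scaffold_lengths}
    windows, q99 = snp_stats.sliding_outlier_counts(out_pos, scaffold_lengths,
                                                    config.window, config.step)
    pd.DataFrame(windows).to_csv(outdir / "outlier_windows.tsv", sep="\t", index=False)

    # LG enrichment of outliers (binomial, Bonferroni)
    lg_of = ann.lg_map
    if lg_of:
        tot_out = int(out_tbl["is_outlier"].sum())
        tot = len(out_tbl)
        res_enr = []
        lgs = sorted({lg for lg in lg_of.values()})
        for lg in lgs:
            scafs = {s for s, l in lg_of.items() if l == lg}
            on_lg = out_tbl["scaffold"].isin(scafs)
            n_lg = int(on_lg.sum())
            x = int((on_lg & out_tbl["is_outlier"]).sum())
            if n_lg and tot_out:
                p0 = max(min(tot_out / tot, 1 - 1e-12), 1e-12)
                res_enr.append(enrichment.binomial_enrichment(
                    x, n_lg, p0, n_tests=len(lgs), unit=lg))
        pd.DataFrame([vars(r) for r in res_enr]).to_csv(
            outdir / "lg_enrichment.tsv", sep="\t", index=False)

    # --- sv branch ---------------------------------------------------------
    pf = indir / f"pairs_{config.focal_resistant}.tsv"
    pr = indir / f"pairs_{config.matched_susceptible}.tsv"
    if pf.exists() and pr.exists():
        frames_f, _ = read_pairs_tsv(pf)
        frames_r, _ = read_pairs_tsv(pr)
        depth_f = _read_depth(indir / f"depth_{config.focal_resistant}.tsv",
                              scaffold_lengths)
        depth_r = _read_depth(indir / f"depth_{config.matched_susceptible}.tsv",
                              scaffold_lengths)
        events = sv.detect_svs(frames_f, frames_r, depth_f, depth_r,
                               scaffold_lengths, ann.te_mask,
                               min_support=config.min_support,
                               min_span=config.min_span, seed=config.seed,
                               fst_quantile=config.sv_fst_quantile,
                               flank=config.flank)
        events.to_csv(outdir / "sv_events.tsv", sep="\t", index=False)
        _stage(manifest, "sv_detect", sum(len(f) for f in frames_f.values()),
               len(events))
        if len(events):
            sel = events[events["selected"]]
            ov = sv.genes_overlapping(sel, ann)
            ov.to_csv(outdir / "sv_gene_overlap.tsv", sep="\t", index=False)
            counts = events.groupby("scaffold").size().to_dict()
            try:
                enr = enrichment.sv_scaffold_chi2(counts, scaffold_lengths)
                pd.DataFrame([vars(r) for r in enr]).to_csv(
                    outdir / "sv_scaffold_enrichment.tsv", sep="\t", index=False)
            except ValueError:
                pass

    # --- bioassay ----------------------------------------------------------
    bio = indir / "bioassay.tsv"
    if bio.exists():
        tbl = read_bioassay(bio)
        cmp_tbl = ba.strain_comparison_table(tbl)
        cmp_tbl.to_csv(outdir / "bioassay_comparison.tsv", sep="\t", index=False)

    manifest["window_q99"] = q99
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _read_depth(path: Path, scaffold_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Depth TSV (scaffold, position, depth) -> per-scaffold arrays."""
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    out = {}
    for scaf, slen in scaffold_lengths.items():
        arr = np.zeros(slen, dtype=np.int32)
        sub = df[df["scaffold"] == scaf]
        arr[sub["position"].to_numpy() - 1] = sub["depth"].to_numpy()
        out[scaf] = arr
    return out
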