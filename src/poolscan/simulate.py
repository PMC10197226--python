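"""Synthetic data with the statistical structure the analysis assumes.

Every generator is seed-deterministic (numpy ``default_rng``) and mirrors the
study design: four pools (two resistant, two susceptible) of ~30 diploid
bed bugs sequenced at ~30x, a multi-scaffold draft genome with ~7 kb genes
and TE intervals, paired-end libraries with planted structural variants, and
binomial probit mortality curves.

Model for pool SNPs: ancestral (derived-allele) frequency pi_l ~ Beta(0.7,
0.7) truncated to [0.05, 0.95]; per-pool standardized deviations are
multivariate normal with covariance Omega (shared demographic history);
pool frequencies are pi + sqrt(pi(1-pi)) * deviation, clipped to [0, 1].
Selected loci get a shift ``delta`` added to the derived-allele frequency in
resistant pools; their ancestral frequencies are drawn low (resistance
alleles are derived and ancestrally rare).  Read counts arise by binomial
sampling of 2N chromosomes followed by binomial read sampling at
Poisson-distributed coverage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import (BASES, ConfigError, GeneModel, GenomeAnnotation, PoolSpec,
                 PoolSnpTable, merge_intervals)

RESISTANCE_CATEGORIES = (
    "P450", "GST", "esterase", "ABC_transporter", "cuticular",
    "target_and_nervous_system", "UDPGT", "sulfotransferase",
    "redox_homeostasis", "other_detox",
)

#: genome-wide fraction of genes in a resistance category (431 of 13,208)
RESISTANCE_GENE_FRACTION = 431 / 13208


def default_pools() -> list[PoolSpec]:
    return [
        PoolSpec("fieldA", "resistant", 30),
        PoolSpec("fieldB", "resistant", 30),
        PoolSpec("labA", "susceptible", 28),
        PoolSpec("labB", "susceptible", 30),
    ]


def default_omega(pools: list[PoolSpec] | None = None) -> np.ndarray:
    """Block-structured covariance of standardized frequencies.

    Diagonal 0.02 (moderate drift since strain separation) with higher
    covariance between the same-origin field/lab pair (fieldA, labA) and a
    small shared background, mirroring common demographic history.
    """
    pools = pools or default_pools()
    J = len(pools)
    omega = np.full((J, J), 0.002)
    np.fill_diagonal(omega, 0.02)
    omega[0, 2] = omega[2, 0] = 0.012  # fieldA and labA share a recent origin
    return omega


@dataclass
class SelectedBlock:
    scaffold: str
    start: int
    end: int
    n_selected: int = 100
    delta: float = 0.35
    #: ancestral derived-allele frequency range at selected loci
    pi_range: tuple[float, float] = (0.05, 0.25)


@dataclass
class SvPlan:
    sv_class: str  # tandem_dup | inverted_dup | inversion
    scaffold: str
    start: int
    length: int
    freq: dict[str, float]  # pool name -> frequency

    @property
    def end(self) -> int:
        return self.start + self.length - 1


@dataclass
class SimConfig:
    seed: int = 0
    pools: list[PoolSpec] = field(default_factory=default_pools)
    n_loci: int = 20000
    scaffold_lengths: dict[str, int] = field(
        default_factory=lambda: {f"scaf{i}": 3_000_000 for i in range(1, 4)})
    omega_true: np.ndarray | None = None
    selected: SelectedBlock | None = None
    depth: float = 30.0
    min_cov: int = 10
    max_cov: int = 50
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    sv_plan: list[SvPlan] = field(default_factory=list)
    te_fraction: float = 0.05
    n_genes: int = 300
    gene_median_bp: float = 7000.0

    def __post_init__(self):
        if self.omega_true is None:
            self.omega_true = default_omega(self.pools)
        self.omega_true = np.asarray(self.omega_true, dtype=float)
        if not np.allclose(self.omega_true, self.omega_true.T):
            raise ConfigError("omega_true must be symmetric")
        if np.linalg.eigvalsh(self.omega_true).min() <= 0:
            raise ConfigError("omega_true must be positive-definite")
        for ev in self.sv_plan:
            if ev.end > self.scaffold_lengths[ev.scaffold]:
                raise ConfigError(f"SV at {ev.scaffold}:{ev.start} extends past scaffold end")
            if not all(0.0 <= f <= 1.0 for f in ev.freq.values()):
                raise ConfigError("SV frequencies must lie in [0, 1]")

    def manifest(self) -> dict:
        blob = json.dumps({
            "seed": self.seed, "n_loci": self.n_loci,
            "pools": [(p.name, p.status, p.n_individuals) for p in self.pools],
            "scaffolds": self.scaffold_lengths, "depth": self.depth,
            "omega": self.omega_true.tolist(),
        }, sort_keys=True)
        return {"seed": self.seed,
                "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16]}


# ---------------------------------------------------------------------------
# pool SNPs


def _truncated_beta(rng, a, b, lo, hi, size):
    lo_q, hi_q = stats.beta.cdf([lo, hi], a, b)
    u = rng.uniform(lo_q, hi_q, size=size)
    return stats.beta.ppf(u, a, b)


def sim_pool_snps(config: SimConfig) -> tuple[PoolSnpTable, pd.DataFrame]:
    """Simulate the SNP pool; returns (table, truth frame).

    Truth columns: scaffold, position, pi (ancestral derived frequency),
    selected (bool), true per-pool frequencies ``p_<pool>``.
    """
    rng = np.random.default_rng(config.seed)
    J = len(config.pools)
    L = config.n_loci

    scaf_names = list(config.scaffold_lengths)
    lens = np.array([config.scaffold_lengths[s] for s in scaf_names], dtype=float)
    n_per = rng.multinomial(L, lens / lens.sum())
    scaffold = np.repeat(np.array(scaf_names, dtype=object), n_per)
    position = np.concatenate([
        np.sort(rng.choice(np.int64(config.scaffold_lengths[s]), size=n, replace=False) + 1)
        for s, n in zip(scaf_names, n_per)])

    pi = _truncated_beta(rng, 0.7, 0.7, 0.05, 0.95, L)
    selected = np.zeros(L, dtype=bool)
    if config.selected is not None:
        blk = config.selected
        in_block = np.flatnonzero(
            (scaffold == blk.scaffold) & (position >= blk.start) & (position <= blk.end))
        if len(in_block) < blk.n_selected:
            raise ConfigError("selected block does not contain enough loci")
        chosen = rng.choice(in_block, size=blk.n_selected, replace=False)
        selected[chosen] = True
        pi[chosen] = rng.uniform(*blk.pi_range, size=blk.n_selected)

    dev = rng.multivariate_normal(np.zeros(J), config.omega_true, size=L,
                                  method="cholesky")
    p_true = np.clip(pi[:, None] + np.sqrt(pi * (1 - pi))[:, None] * dev, 0.0, 1.0)
    if config.selected is not None:
        res = np.array([p.status == "resistant" for p in config.pools])
        p_true[np.ix_(selected, res)] = np.clip(
            p_true[np.ix_(selected, res)] + config.selected.delta, 0.0, 1.0)

    n_hap = np.array([p.haploid_size for p in config.pools])
    pool_counts = rng.binomial(n_hap[None, :], p_true)
    pool_freq = pool_counts / n_hap[None, :]

    cov = rng.poisson(config.depth, size=(L, J))
    while (cov < config.min_cov).any():  # truncate below min_cov by redraw
        low = cov < config.min_cov
        cov[low] = rng.poisson(config.depth, size=int(low.sum()))
    alt = rng.binomial(cov, pool_freq)
    ref = cov - alt

    ref_base = rng.choice(np.array(BASES, dtype=object), size=L)
    alt_base = np.empty(L, dtype=object)
    for l in range(L):  # alt distinct from ref
        choices = [b for b in BASES if b != ref_base[l]]
        alt_base[l] = choices[rng.integers(3)]

    table = PoolSnpTable(config.pools, scaffold, position, ref_base, alt_base, ref, alt)
    truth = pd.DataFrame({"scaffold": scaffold, "position": position, "pi": pi,
                          "selected": selected})
    for j, p in enumerate(config.pools):
        truth[f"p_{p.name}"] = p_true[:, j]
    return table, truth


def sim_island_snps(n_loci: int, fst: float, pools: list[PoolSpec] | None = None,
                    depth: float = 30.0, seed: int = 0) -> PoolSnpTable:
    """Island-model pools with known true FST, for estimator calibration.

    Per locus, pool frequencies are independent Beta draws around a
    Uniform(0.1, 0.9) ancestral frequency with Var = fst * pi(1-pi); counts
    follow the same two-stage binomial sampling as ``sim_pool_snps``.
    """
    rng = np.random.default_rng(seed)
    pools = pools or default_pools()
    J = len(pools)
    pi = rng.uniform(0.1, 0.9, n_loci)
    ab = 1.0 / fst - 1.0
    ref_c, alt_c = [], []
    for j, pool in enumerate(pools):
        p = rng.beta(pi * ab, (1 - pi) * ab)
        k = rng.binomial(pool.haploid_size, p)
        cov = np.maximum(rng.poisson(depth, n_loci), 2)
        alt = rng.binomial(cov, k / pool.haploid_size)
        ref_c.append(cov - alt)
        alt_c.append(alt)
    L = n_loci
    return PoolSnpTable(
        pools, np.array(["scaf1"] * L, dtype=object), np.arange(1, L + 1),
        np.array(["A"] * L, dtype=object), np.array(["T"] * L, dtype=object),
        np.stack(ref_c, axis=1), np.stack(alt_c, axis=1))


# ---------------------------------------------------------------------------
# genome


_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(rng, length: int) -> str:
    """Random CDS of ``length`` (multiple of 3) without internal stop codons."""
    codons = []
    bases = np.array(list("ACGT"))
    for _ in range(length // 3):
        while True:
            c = "".join(rng.choice(bases, size=3))
            if c not in _STOPS:
                break
        codons.append(c)
    return "".join(codons)


def sim_genome(config: SimConfig) -> GenomeAnnotation:
    """Toy multi-scaffold genome: non-overlapping genes (log-normal lengths,
    median ~7 kb), each with a CDS of length divisible by 3 carried as
    sequence, ~3.3% of genes in resistance categories, TE intervals covering
    ``te_fraction`` of the genome."""
    rng = np.random.default_rng(config.seed + 1)
    genes: list[GeneModel] = []
    scaf_names = list(config.scaffold_lengths)
    lens = np.array([config.scaffold_lengths[s] for s in scaf_names], dtype=float)
    n_per = rng.multinomial(config.n_genes, lens / lens.sum())
    gid = 0
    for scaf, n in zip(scaf_names, n_per):
        slen = config.scaffold_lengths[scaf]
        lengths = np.exp(rng.normal(np.log(config.gene_median_bp), 0.45, size=n))
        lengths = np.maximum(600, lengths.astype(int))
        if lengths.sum() * 1.5 > slen:
            raise ConfigError(f"cannot place {n} genes on {scaf}")
        # place genes left to right with random gaps
        gaps = rng.dirichlet(np.ones(n + 1)) * (slen - lengths.sum())
        cur = 1
        for i in range(n):
            cur += int(gaps[i])
            start = max(1, cur)
            end = start + int(lengths[i]) - 1
            cur = end + 1
            strand = "+" if rng.random() < 0.5 else "-"
            glen = end - start + 1
            cds_len = max(300, int(glen * 0.3) // 3 * 3)
            cds_len = min(cds_len, glen // 3 * 3)
            # split the CDS into 1-3 exon segments inside the gene span
            n_seg = int(rng.integers(1, 4))
            seg_lens = np.maximum(3, (rng.dirichlet(np.ones(n_seg)) * cds_len).astype(int))
            seg_lens = (seg_lens // 3) * 3
            seg_lens[0] += cds_len - seg_lens.sum()
            intron_budget = glen - cds_len
            offsets = np.sort(rng.choice(max(intron_budget, 1), size=n_seg, replace=True))
            segs, pos = [], start
            for k in range(n_seg):
                pos = start + int(offsets[k]) + int(seg_lens[:k].sum())
                segs.append((pos, pos + int(seg_lens[k]) - 1))
            segs = [(s, e) for s, e in segs if e <= end]
            if not segs or sum(e - s + 1 for s, e in segs) % 3 != 0:
                segs = [(start, start + cds_len - 1)]
            order = sorted(segs) if strand == "+" else sorted(segs, key=lambda t: -t[0])
            total = sum(e - s + 1 for s, e in segs)
            gm = GeneModel(
                gene_id=f"gene{gid:05d}", scaffold=scaf, strand=strand,
                start=start, end=end, cds_segments=order, exons=sorted(segs),
                cds_seq=_random_cds(rng, total),
            )
            pstart, pend = ((start - 1000, start - 1) if strand == "+"
                            else (end + 1, end + 1000))
            pstart = max(1, pstart)
            pend = min(pend, slen)
            if pstart <= pend:
                gm.promoter = (pstart, pend)
            genes.append(gm)
            gid += 1
    n_cat = int(round(RESISTANCE_GENE_FRACTION * len(genes)))
    cat_genes = rng.choice(len(genes), size=n_cat, replace=False)
    categories = {genes[i].gene_id: RESISTANCE_CATEGORIES[int(rng.integers(len(RESISTANCE_CATEGORIES)))]
                  for i in cat_genes}
    te_mask: dict[str, list[tuple[int, int]]] = {}
    if config.te_fraction > 0:
        for scaf in scaf_names:
            slen = config.scaffold_lengths[scaf]
            target = config.te_fraction * slen
            ivs, covered = [], 0
            while covered < target:
                te_len = int(rng.integers(200, 5000))
                s = int(rng.integers(1, max(2, slen - te_len)))
                ivs.append((s, s + te_len - 1))
                covered += te_len
            te_mask[scaf] = merge_intervals(ivs)
    lg_map = {scaf: f"LG{1 + i % 14}" for i, scaf in enumerate(scaf_names)}
    return GenomeAnnotation(scaffold_lengths=dict(config.scaffold_lengths),
                            genes=genes, te_mask=te_mask, categories=categories,
                            lg_map=lg_map)


_COMP = str.maketrans("ACGT", "TGCA")


def harmonize_snp_refs(table: PoolSnpTable, annotation: GenomeAnnotation,
                       seed: int = 0) -> None:
    """Make ref/alt bases of CDS-overlapping SNPs agree with the gene CDS
    sequences (in place), so coding-effect calls are coherent on synthetic
    bundles where SNP bases and gene sequences are drawn independently."""
    rng = np.random.default_rng(seed)
    by_scaf: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        if g.cds_seq:
            by_scaf.setdefault(g.scaffold, []).append(g)
    for l in range(len(table)):
        for g in by_scaf.get(table.scaffold[l], []):
            idx = g.genome_to_cds_index(int(table.position[l]))
            if idx is None:
                continue
            base = g.cds_seq[idx]
            if g.strand == "-":
                base = base.translate(_COMP)
            table.ref[l] = base
            if table.alt[l] == base:
                table.alt[l] = rng.choice([b for b in BASES if b != base])
            break


def write_cds_fasta(annotation: GenomeAnnotation, path) -> None:
    """Spliced CDS sequences of a synthetic genome, one record per gene."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            if g.cds_seq:
                fh.write(f">{g.gene_id}\n{g.cds_seq}\n")


def attach_cds_fasta(annotation: GenomeAnnotation, path) -> None:
    """Load CDS sequences back onto gene models (inverse of write_cds_fasta)."""
    seqs: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = ""
            elif name:
                seqs[name] += line
    for g in annotation.genes:
        if g.gene_id in seqs:
            g.cds_seq = seqs[g.gene_id]


# ---------------------------------------------------------------------------
# read pairs and depth tracks with planted SVs


def _expected_overhang(insert_mean: float, insert_sd: float, read_len: int) -> float:
    """E[(F - 2*read_len)+] for F ~ Normal(insert_mean, insert_sd)."""
    z = (insert_mean - 2 * read_len) / insert_sd
    return (insert_mean - 2 * read_len) * stats.norm.cdf(z) + insert_sd * stats.norm.pdf(z)


def _junction_pairs(rng, n: int, a: int, b: int, kind: str, config: SimConfig):
    """Reference coordinates of n pairs spanning a breakpoint junction.

    ``kind`` encodes the mapping geometry (see module docs):
      tandem   : left read '-' near a, right read '+' near b (everted)
      inv_pp   : both '+', left just left of a, right just left of b
      inv_mm   : both '-', left just right of a, right just right of b
    """
    F = rng.normal(config.insert_mean, config.insert_sd, size=n)
    rl = config.read_len
    F = np.maximum(F, 2 * rl + 2)
    u = rng.uniform(rl, F - rl)  # junction offset within the fragment
    if kind == "tandem":
        left = a + (F - u - rl)
        right = b - u + 1
        ls, rs = "-", "+"
    elif kind == "inv_pp":
        left = a - u
        right = b - (F - u) + 1
        ls, rs = "+", "+"
    elif kind == "inv_mm":
        left = a + u - rl + 1
        right = b + (F - u) - rl + 1
        ls, rs = "-", "-"
    else:  # pragma: no cover
        raise ValueError(kind)
    return (np.asarray(left, dtype=np.int64), np.asarray(right, dtype=np.int64), ls, rs)


def sim_sv_readpairs(config: SimConfig) -> tuple[
        dict[str, dict[str, pd.DataFrame]], dict[str, dict[str, np.ndarray]],
        pd.DataFrame]:
    """Paired-end mapping records and per-base depth per pool with planted SVs.

    Returns (pairs[pool][scaffold] frame, depth[pool][scaffold] array,
    truth frame).  Background pairs are proper FR with Normal insert at rate
    depth/(2*read_len) per bp.  Breakpoint-spanning discordant pairs appear
    at a rate proportional to the event frequency in the pool: everted pairs
    across the copy junction for tandem duplications; same-strand pairs for
    inversions (both boundaries) and inverted duplications.  Depth inside
    duplications is multiplied by (1 + f); inversions leave depth unchanged.
    """
    rng = np.random.default_rng(config.seed + 2)
    rl = config.read_len
    lam = config.depth / (2 * rl)  # fragments per bp
    overhang = _expected_overhang(config.insert_mean, config.insert_sd, rl)
    pairs: dict[str, dict[str, pd.DataFrame]] = {}
    depth: dict[str, dict[str, np.ndarray]] = {}
    for pool in config.pools:
        pairs[pool.name] = {}
        depth[pool.name] = {}
        for scaf, slen in config.scaffold_lengths.items():
            n_bg = rng.poisson(lam * slen)
            left = rng.integers(1, slen - int(config.insert_mean + 5 * config.insert_sd),
                                size=n_bg)
            F = rng.normal(config.insert_mean, config.insert_sd, size=n_bg)
            F = np.maximum(F, 2 * rl).astype(np.int64)
            right = left + F - rl
            frames = [pd.DataFrame({
                "left_pos": left, "right_pos": right,
                "left_strand": "+", "right_strand": "-"})]
            dep_factor = np.ones(slen + 1)
            for ev in config.sv_plan:
                if ev.scaffold != scaf:
                    continue
                f = ev.freq.get(pool.name, 0.0)
                if f > 0:
                    n_j = rng.poisson(f * lam * overhang)
                    if ev.sv_class == "tandem_dup":
                        kinds = [("tandem", ev.start, ev.end, n_j)]
                    elif ev.sv_class == "inversion":
                        kinds = [("inv_pp", ev.start, ev.end, n_j),
                                 ("inv_mm", ev.start, ev.end,
                                  rng.poisson(f * lam * overhang))]
                    else:  # inverted_dup: one spanning same-strand cluster
                        kinds = [("inv_mm", ev.start, ev.end, n_j)]
                    for kind, a, b, n in kinds:
                        if n == 0:
                            continue
                        lpos, rpos, ls, rs = _junction_pairs(rng, n, a, b, kind, config)
                        frames.append(pd.DataFrame({
                            "left_pos": lpos, "right_pos": rpos,
                            "left_strand": ls, "right_strand": rs}))
                    if ev.sv_class in ("tandem_dup", "inverted_dup"):
                        dep_factor[ev.start:ev.end + 1] = 1.0 + f
            df = pd.concat(frames, ignore_index=True)
            df["scaffold"] = scaf
            df["read_len"] = rl
            df["insert"] = df["right_pos"] + rl - df["left_pos"]
            df = df[(df["left_pos"] >= 1) & (df["right_pos"] + rl - 1 <= slen)]
            pairs[pool.name][scaf] = df.reset_index(drop=True)
            depth[pool.name][scaf] = rng.poisson(
                config.depth * dep_factor[1:]).astype(np.int32)
    truth = pd.DataFrame([{
        "sv_class": ev.sv_class, "scaffold": ev.scaffold, "start": ev.start,
        "end": ev.end, **{f"f_{k}": v for k, v in ev.freq.items()}}
        for ev in config.sv_plan])
    return pairs, depth, truth


# ---------------------------------------------------------------------------
# bioassay


@dataclass
class BioassayPlan:
    strain: str
    ld50: float  # ng per insect
    slope: float  # probit slope per log10 dose
    doses: tuple[float, ...]
    n_replicates: int = 3
    n_per_replicate: int = 10
    control_mortality: float = 0.0


def sim_bioassay(plans: list[BioassayPlan], seed: int = 0) -> pd.DataFrame:
    """Binomial probit mortality table, three replicates of ten insects per
    dose plus controls by default."""
    rng = np.random.default_rng(seed)
    rows = []
    for plan in plans:
        if any(d <= 0 for d in plan.doses):
            raise ConfigError("doses must be positive (controls are implicit)")
        for rep in range(plan.n_replicates):
            p0 = plan.control_mortality
            rows.append({"strain": plan.strain, "dose": 0.0, "replicate": rep,
                         "n_exposed": plan.n_per_replicate,
                         "n_dead": int(rng.binomial(plan.n_per_replicate, p0))})
            for dose in plan.doses:
                p = stats.norm.cdf(plan.slope * (np.log10(dose) - np.log10(plan.ld50)))
                p = p0 + (1 - p0) * p
                rows.append({"strain": plan.strain, "dose": dose, "replicate": rep,
                             "n_exposed": plan.n_per_replicate,
                             "n_dead": int(rng.binomial(plan.n_per_replicate, p))})
    return pd.DataFrame(rows)
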