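"""Frequency-level SNP statistics for pooled sequencing.

The pairwise FST estimator works on identity probabilities.  For pool i
with read counts c_i / coverage C_i and haploid pool size n_i, the unbiased
within-pool heterozygosity is

    h_i = 2 p_i (1 - p_i) * n_i/(n_i - 1) * C_i/(C_i - 1)

(the double correction undoes both binomial read sampling and the binomial
sampling of chromosomes into the pool).  With Q1 = 1 - (h_a + h_b)/2 the
within-pool identity and Q2 = p_a p_b + (1-p_a)(1-p_b) the between-pool
identity, the per-locus estimator is (Q1 - Q2)/(1 - Q2) and the global
(multilocus) estimator is the ratio of sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import PoolSnpTable

log = logging.getLogger(__name__)


def maf_filter(mean_freq: np.ndarray, threshold: float = 0.2) -> np.ndarray:
    """Boolean mask of loci passing the minor-allele-frequency trim.

    MAF is computed on the across-pool mean frequency p as 0.5 - |p - 0.5|;
    loci with MAF >= threshold are kept (inclusive).
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("threshold must lie in [0, 0.5]")
    maf = 0.5 - np.abs(np.asarray(mean_freq) - 0.5)
    return maf >= threshold - 1e-12  # inclusive despite float rounding


def pool_heterozygosity(ref: np.ndarray, alt: np.ndarray, n_haploid: int) -> np.ndarray:
    """Unbiased per-site heterozygosity from pool read counts."""
    cov = ref + alt
    p = np.where(cov > 0, alt / np.maximum(cov, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (2.0 * p * (1.0 - p)
                * (n_haploid / (n_haploid - 1.0))
                * (cov / np.maximum(cov - 1.0, 1e-300)))


@dataclass
class FstResult:
    per_locus: np.ndarray  # NaN where excluded (both pools fixed same allele)
    global_fst: float
    n_excluded: int


def pool_fst(table: PoolSnpTable, pool_a: str, pool_b: str) -> FstResult:
    """Pairwise pool FST; identity-probability form with pool-size and
    read-depth corrections.  Loci where both pools are fixed for the same
    allele (Q2 = 1) are excluded from the per-locus output and both sums."""
    ja, jb = table.pool_index(pool_a), table.pool_index(pool_b)
    na = table.pools[ja].haploid_size
    nb = table.pools[jb].haploid_size
    ra, aa = table.ref_counts[:, ja], table.alt_counts[:, ja]
    rb, ab = table.ref_counts[:, jb], table.alt_counts[:, jb]
    pa = aa / (ra + aa)
    pb = ab / (rb + ab)
    ha = pool_heterozygosity(ra, aa, na)
    hb = pool_heterozygosity(rb, ab, nb)
    q1 = 1.0 - (ha + hb) / 2.0
    q2 = pa * pb + (1.0 - pa) * (1.0 - pb)
    num, den = q1 - q2, 1.0 - q2
    excluded = den <= 0
    per_locus = np.full(len(table), np.nan)
    ok = ~excluded
    per_locus[ok] = num[ok] / den[ok]
    if excluded.any():
        log.info("pool_fst: %d loci fixed in both pools excluded", int(excluded.sum()))
    global_fst = float(num[ok].sum() / den[ok].sum())
    return FstResult(per_locus, global_fst, int(excluded.sum()))


def nucleotide_diversity(table: PoolSnpTable, pool: str, window: int,
                         step: int | None = None) -> "np.recarray":
    """Per-window nucleotide diversity pi for one pool.

    pi(window) = sum of per-site heterozygosities / window size (monomorphic
    sites contribute 0, so only table sites matter and SNP-free windows give
    pi = 0).  Returns a recarray (scaffold, start, end, pi, n_snps); windows
    are laid per scaffold over [1, max position].
    """
    step = step or window
    j = table.pool_index(pool)
    h = pool_heterozygosity(table.ref_counts[:, j], table.alt_counts[:, j],
                            table.pools[j].haploid_size)
    rows = []
    for scaf in np.unique(table.scaffold):
        m = table.scaffold == scaf
        pos = table.position[m]
        hs = h[m]
        top = int(pos.max()) if len(pos) else window
        for start in range(1, max(top - window + 2, 2), step):
            end = start + window - 1
            inw = (pos >= start) & (pos <= end)
            n = int(inw.sum())
            rows.append((scaf, start, end, float(hs[inw].sum() / window), n))
    return np.rec.fromrecords(rows, names=["scaffold", "start", "end", "pi", "n_snps"])


def pca_pools(freqs: np.ndarray, pool_names: list[str]):
    """PCA of pools on centered per-locus frequencies.

    ``freqs`` is (L, J).  Returns (coordinates (J, k), variance fractions).
    """
    J = freqs.shape[1]
    if J < 2:
        raise ValueError("PCA needs at least 2 pools")
    X = freqs.T - freqs.mean(axis=1)  # (J, L), centered per locus
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / max(var.sum(), 1e-300)
    coords = u * s
    return coords, frac


def sliding_outlier_counts(outlier_positions: dict[str, np.ndarray],
                           scaffold_lengths: dict[str, int],
                           window: int = 100_000, step: int = 10_000):
    """Count outlier SNPs in sliding windows (100 kb / 10 kb by default).

    Returns (recarray of scaffold/start/end/count, 99% quantile of counts).
    """
    rows = []
    for scaf, slen in scaffold_lengths.items():
        pos = np.sort(np.asarray(outlier_positions.get(scaf, []), dtype=np.int64))
        for start in range(1, max(slen - window + 2, 2), step):
            end = start + window - 1
            cnt = int(np.searchsorted(pos, end, "right") - np.searchsorted(pos, start, "left"))
            rows.append((scaf, start, end, cnt))
    rec = np.rec.fromrecords(rows, names=["scaffold", "start", "end", "count"])
    q99 = float(np.quantile(rec["count"], 0.99))
    return rec, q99
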