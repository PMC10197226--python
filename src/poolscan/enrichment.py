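"""Enrichment tests: outliers per linkage group / scaffold (exact binomial,
Bonferroni), resistance categories in regions (two-sample proportion
chi-square with continuity correction, Benjamini-Hochberg), SV excess per
scaffold (two-cell chi-square, 1 d.f., Bonferroni, scaffolds with fewer
than 5 expected events removed), SV-gene overlap (exact binomial)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    unit: str
    observed: float
    expected: float
    fold: float
    p_raw: float
    p_corrected: float
    method: str


def binomial_enrichment(x: int, n: int, p0: float, n_tests: int = 1,
                        unit: str = "") -> EnrichmentResult:
    """One-sided exact binomial upper tail P(X >= x | n, p0), Bonferroni."""
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    if not 0 <= x <= n:
        raise ValueError("need 0 <= x <= n")
    p = float(stats.binom.sf(x - 1, n, p0)) if x > 0 else 1.0
    expected = n * p0
    fold = (x / n) / p0 if n > 0 else np.nan
    return EnrichmentResult(unit, x, expected, fold, p,
                            min(1.0, p * n_tests), "binomial_bonferroni")


def proportion_chi2(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Two-sample proportion test: 2x2 chi-square with Yates continuity
    correction (the R stats default), two-sided."""
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    total = table.sum()
    exp = row @ col / total
    if (exp == 0).any():
        return 0.0, 1.0
    adj = np.maximum(np.abs(table - exp) - 0.5, 0.0)
    chi2 = float((adj**2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def category_proportion_tests(counts: dict[str, tuple[int, int, int, int]]
                              ) -> list[EnrichmentResult]:
    """Per-category proportion tests with BH (FDR) correction.

    ``counts`` maps category -> (x_region, n_region, x_genome, n_genome).
    Categories with n_region = 0 are skipped (missing).
    """
    units, raws, folds, obs, expd = [], [], [], [], []
    for cat, (x1, n1, x2, n2) in counts.items():
        if n1 == 0:
            continue
        _, p = proportion_chi2(x1, n1, x2, n2)
        units.append(cat)
        raws.append(p)
        p_genome = x2 / n2 if n2 else np.nan
        folds.append((x1 / n1) / p_genome if p_genome else np.nan)
        obs.append(x1)
        expd.append(n1 * p_genome)
    if not units:
        return []
    _, p_adj, _, _ = multipletests(raws, method="fdr_bh")
    return [EnrichmentResult(u, o, e, f, pr, float(pa), "proportion_fdr")
            for u, o, e, f, pr, pa in zip(units, obs, expd, folds, raws, p_adj)]


def sv_scaffold_chi2(event_counts: dict[str, int], scaffold_lengths: dict[str, int],
                     min_expected: float = 5.0,
                     continuity: bool = True) -> list[EnrichmentResult]:
    """Per-scaffold excess of SV events against a uniform-by-length null.

    expected_s = total * len_s / sum(len); scaffolds with expected <
    ``min_expected`` are removed before testing; the statistic is the
    two-cell chi-square (in / out of the scaffold), 1 d.f., Bonferroni over
    the tested scaffolds.  By default the Yates continuity correction is
    applied (as in R's proportion tests); without it the plain chi-square is
    anticonservative at moderate expected counts and its familywise error
    exceeds the nominal level.
    """
    total = sum(event_counts.values())
    if total == 0:
        raise ValueError("no events")
    tot_len = sum(scaffold_lengths.values())
    cc = 0.5 if continuity else 0.0
    tested = []
    for scaf, slen in scaffold_lengths.items():
        exp = total * slen / tot_len
        if exp < min_expected:
            continue
        obs = event_counts.get(scaf, 0)
        d = max(abs(obs - exp) - cc, 0.0)
        chi2 = d**2 / exp + d**2 / (total - exp)
        p = float(stats.chi2.sf(chi2, df=1))
        tested.append((scaf, obs, exp, p))
    n_tests = len(tested)
    return [EnrichmentResult(scaf, obs, exp, obs / exp if exp else np.nan, p,
                             min(1.0, p * n_tests), "chi2_bonferroni")
            for scaf, obs, exp, p in tested]


def sv_gene_overlap_test(n_resistance_overlapped: int, n_overlapped_total: int,
                         p0: float) -> EnrichmentResult:
    """Exact binomial enrichment of resistance genes among SV-overlapped
    genes, against the genome-wide resistance-gene proportion p0."""
    return binomial_enrichment(n_resistance_overlapped, n_overlapped_total, p0,
                               unit="sv_gene_overlap")
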