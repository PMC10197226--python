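"""Combine the scan criteria into the final outlier-SNP call set.

A SNP is an outlier when all enabled flags hold:
  * per-locus FST (focal field vs matched lab strain) in the top 5% of the
    genome-wide distribution (ties at the threshold included),
  * local false discovery rate of the contrast statistic strictly below 0.2,
  * Bayes factor strictly above 5 deciban (severable: it derives from the
    analytic surrogate model),
  * the derived (non-reference) allele strictly more frequent in the focal
    resistant pool than in the matched susceptible pool.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def fst_top_quantile(per_locus_fst: np.ndarray, q: float = 0.95) -> np.ndarray:
    """Flag loci with FST at or above the empirical q-quantile (ties included)."""
    fst = np.asarray(per_locus_fst, dtype=float)
    ok = ~np.isnan(fst)
    if not ok.any():
        raise ValueError("all FST values missing")
    thr = np.quantile(fst[ok], q)
    if np.nanmin(fst) == np.nanmax(fst):
        log.warning("fst_top_quantile: constant FST, all loci flagged")
    return ok & (fst >= thr)


def derived_up_filter(freqs: np.ndarray, focal_idx: int, reference_idx: int) -> np.ndarray:
    """Derived (alt) allele strictly more frequent in the focal pool."""
    return freqs[:, focal_idx] > freqs[:, reference_idx]


def combine(top5_fst: np.ndarray, lfdr: np.ndarray, db: np.ndarray,
            derived_up: np.ndarray, lfdr_max: float = 0.2, db_min: float = 5.0,
            enable_bf: bool = True) -> pd.DataFrame:
    """Conjunction of the scan filters (strict inequalities at thresholds)."""
    n = len(top5_fst)
    for arr in (lfdr, db, derived_up):
        if len(arr) != n:
            raise ValueError("filter inputs cover different locus sets")
    flags = pd.DataFrame({
        "top5_fst": np.asarray(top5_fst, dtype=bool),
        "lfdr_pass": np.asarray(lfdr) < lfdr_max,
        "bf_pass": np.asarray(db) > db_min,
        "derived_up": np.asarray(derived_up, dtype=bool),
    })
    conj = flags["top5_fst"] & flags["lfdr_pass"] & flags["derived_up"]
    if enable_bf:
        conj &= flags["bf_pass"]
    flags["is_outlier"] = conj
    log.info("outlier filter counts: %s", flags.sum().to_dict())
    return flags
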