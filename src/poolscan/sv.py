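"""Structural-variant detection from discordant read pairs and depth ratios.

Pipeline (adapted from the poolCNVcomp approach for pooled resequencing):

1. per-scaffold insert statistics over proper pairs; the clustering distance
   ``insertSizeDiffCutoff`` is four times the insert standard deviation;
2. discordant-pair classification: everted pairs (left read '-', right read
   '+') are the tandem-duplication junction signature; same-strand pairs the
   inversion / inverted-duplication signature; FR pairs with insert above
   the top-1% quantile are "distant" (not used further);
3. single-linkage clustering of each class into candidate events; event
   breakpoints come from an insert-aware per-pair estimator (a junction-
   adjacent read on the '+' strand sits on average half an insert upstream
   of its breakpoint, a '-' read half an insert minus a read length
   downstream);
4. cross-pool matching with ``distancecutoff`` = the sum of the two pools'
   insertSizeDiffCutoff values;
5. TE-masked mean depth ratio focal/reference per event, compared with an
   empirical null built from randomly placed windows (500 bp - 2.5 Mb,
   n = 10,000 by default) in log-spaced size classes: ratios above the
   class 75% quantile type a duplication, ratios between the 25% and 75%
   quantiles type a same-strand cluster as an inversion;
6. size filter (>= 3.5 kb), TE-extremity filter (breakpoint-side 150 bp
   windows overlapping TEs by more than 100 bp), per-pool frequency
   estimation from discordant support over flank coverage, and FST-based
   selection of differentiated events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)

SIZE_RANGE = (500, 2_500_000)
N_SIZE_CLASSES = 8


@dataclass
class InsertStats:
    scaffold: str
    mean: float
    sd: float
    q99: float
    n_proper: int

    @property
    def cutoff(self) -> float:
        """insertSizeDiffCutoff: 4 x insert standard deviation."""
        return 4.0 * self.sd


def insert_stats(pairs: pd.DataFrame, scaffold: str, min_pairs: int = 50) -> InsertStats | None:
    """Insert mean/sd/q99 over proper (FR, non-extreme) pairs of a scaffold.

    Returns None (scaffold skipped) with fewer than ``min_pairs`` FR pairs
    or a degenerate (zero) standard deviation.
    """
    fr = pairs[(pairs["left_strand"] == "+") & (pairs["right_strand"] == "-")]
    if len(fr) < min_pairs:
        log.warning("scaffold %s: only %d FR pairs, skipped", scaffold, len(fr))
        return None
    q99 = float(np.quantile(fr["insert"], 0.99))
    proper = fr[fr["insert"] <= q99]
    sd = float(proper["insert"].std(ddof=1))
    if not sd > 0:
        log.warning("scaffold %s: degenerate insert distribution, skipped", scaffold)
        return None
    return InsertStats(scaffold, float(proper["insert"].mean()), sd, q99, len(proper))


def classify_pairs(pairs: pd.DataFrame, stats: InsertStats) -> pd.Series:
    """proper | everted | same_strand | distant, vectorized."""
    ls, rs = pairs["left_strand"], pairs["right_strand"]
    out = pd.Series("proper", index=pairs.index)
    out[(ls == "-") & (rs == "+")] = "everted"
    out[ls == rs] = "same_strand"
    fr = (ls == "+") & (rs == "-")
    out[fr & (pairs["insert"] > stats.q99)] = "distant"
    return out


@dataclass
class CandidateEvent:
    scaffold: str
    orientation: str  # everted | same_strand
    start: int
    end: int
    support: int
    pair_index: np.ndarray = field(repr=False, default=None)
    sv_class: str | None = None
    depth_ratio: float | None = None
    ref_support: int = 0
    freq: dict = field(default_factory=dict)
    fst: float | None = None

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def _breakpoints(sub: pd.DataFrame, stats: InsertStats) -> tuple[int, int]:
    """Insert-aware per-pair breakpoint estimates, aggregated by median."""
    mu, rl = stats.mean, sub["read_len"].to_numpy()
    lp = sub["left_pos"].to_numpy(dtype=float)
    rp = sub["right_pos"].to_numpy(dtype=float)
    jl = np.where(sub["left_strand"] == "+", lp + mu / 2.0, lp - (mu / 2.0 - rl))
    jr = np.where(sub["right_strand"] == "+", rp + mu / 2.0 - 1, rp - (mu / 2.0 - rl) - 1)
    return int(round(np.median(jl))), int(round(np.median(jr)))


def cluster_events(pairs: pd.DataFrame, orientation: str, stats: InsertStats,
                   min_support: int = 3) -> list[CandidateEvent]:
    """Single-linkage clustering of one discordant class.

    Two pairs join when both their left and their right coordinates differ
    by at most ``insertSizeDiffCutoff``.  Clusters below ``min_support``
    are discarded.
    """
    if pairs.empty:
        return []
    cutoff = stats.cutoff
    df = pairs.sort_values("left_pos").reset_index(drop=True)
    n = len(df)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    left = df["left_pos"].to_numpy()
    right = df["right_pos"].to_numpy()
    for i in range(n):
        j = i + 1
        while j < n and left[j] - left[i] <= cutoff:
            if abs(right[j] - right[i]) <= cutoff:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
            j += 1
    labels = np.array([find(i) for i in range(n)])
    events = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < min_support:
            continue
        sub = df.iloc[idx]
        start, end = _breakpoints(sub, stats)
        if end < start:
            start, end = end, start
        events.append(CandidateEvent(
            scaffold=stats.scaffold, orientation=orientation, start=start,
            end=end, support=len(idx), pair_index=idx))
    events.sort(key=lambda e: e.start)
    return events


def match_events(events_a: list[CandidateEvent], events_b: list[CandidateEvent],
                 cutoff_a: float, cutoff_b: float
                 ) -> list[tuple[CandidateEvent, CandidateEvent | None]]:
    """Greedy nearest-start matching of focal (a) against reference (b).

    Same orientation class and both |start_a - start_b| and |end_a - end_b|
    within cutoff_a + cutoff_b (inclusive); each reference event matched at
    most once; unmatched focal events are kept with reference support 0.
    """
    tol = cutoff_a + cutoff_b
    used = set()
    out = []
    for ev in sorted(events_a, key=lambda e: e.start):
        best, best_d = None, None
        for k, rb in enumerate(events_b):
            if k in used or rb.orientation != ev.orientation:
                continue
            if abs(ev.start - rb.start) <= tol and abs(ev.end - rb.end) <= tol:
                d = abs(ev.start - rb.start)
                if best is None or d < best_d:
                    best, best_d = k, d
        if best is not None:
            used.add(best)
            out.append((ev, events_b[best]))
        else:
            out.append((ev, None))
    return out


# ---------------------------------------------------------------------------
# depth


class DepthTrack:
    """Per-base depth of one scaffold with a TE mask, prefix-summed so that
    masked window means are O(1)."""

    def __init__(self, depth: np.ndarray, mask_intervals: list[tuple[int, int]] | None = None):
        self.depth = np.asarray(depth)
        n = len(self.depth)
        masked = np.zeros(n, dtype=bool)
        for s, e in (mask_intervals or []):
            masked[max(0, s - 1):min(n, e)] = True
        self._cum_depth = np.concatenate([[0], np.cumsum(np.where(masked, 0, self.depth))])
        self._cum_unmasked = np.concatenate([[0], np.cumsum(~masked)])

    def __len__(self):
        return len(self.depth)

    def masked_mean(self, start: int, end: int, max_masked_frac: float = 0.9) -> float:
        """Mean depth over unmasked bases of [start, end] (1-based inclusive);
        NaN when more than ``max_masked_frac`` of the interval is masked."""
        start = max(1, start)
        end = min(len(self.depth), end)
        if end < start:
            return np.nan
        span = end - start + 1
        n_um = self._cum_unmasked[end] - self._cum_unmasked[start - 1]
        if n_um <= (1.0 - max_masked_frac) * span - 1e-12 or n_um == 0:
            return np.nan
        tot = self._cum_depth[end] - self._cum_depth[start - 1]
        return tot / n_um


def masked_depth(track: DepthTrack, start: int, end: int) -> float:
    return track.masked_mean(start, end)


def size_class_edges() -> np.ndarray:
    return np.geomspace(SIZE_RANGE[0], SIZE_RANGE[1], N_SIZE_CLASSES + 1)


def size_class_of(span: int) -> int:
    edges = size_class_edges()
    if span > SIZE_RANGE[1]:
        log.warning("event span %d above largest size class, using largest", span)
        return N_SIZE_CLASSES - 1
    return int(np.clip(np.searchsorted(edges, span, "right") - 1, 0, N_SIZE_CLASSES - 1))


@dataclass
class NullRatioTable:
    edges: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_windows: np.ndarray
    seed: int


def null_ratio_table(tracks_focal: dict[str, DepthTrack],
                     tracks_ref: dict[str, DepthTrack],
                     scaffold_lengths: dict[str, int],
                     n: int = 10_000, seed: int = 0) -> NullRatioTable:
    """Empirical null of the focal/reference depth ratio.

    ``n`` windows total, split equally over the log-spaced size classes;
    window sizes log-uniform within class, positions uniform within
    scaffolds long enough to hold the window.  Windows with missing or zero
    reference depth are resampled (up to 10 tries).
    """
    rng = np.random.default_rng(seed)
    edges = size_class_edges()
    per_class = n // N_SIZE_CLASSES
    q25 = np.full(N_SIZE_CLASSES, np.nan)
    q75 = np.full(N_SIZE_CLASSES, np.nan)
    counts = np.zeros(N_SIZE_CLASSES, dtype=int)
    scafs = list(scaffold_lengths)
    lens = np.array([scaffold_lengths[s] for s in scafs], dtype=float)
    for k in range(N_SIZE_CLASSES):
        ratios = []
        for _ in range(per_class):
            for _try in range(10):
                size = int(np.exp(rng.uniform(np.log(edges[k]), np.log(edges[k + 1]))))
                ok = lens >= size
                if not ok.any():
                    break
                w = lens * ok
                scaf = scafs[int(rng.choice(len(scafs), p=w / w.sum()))]
                start = int(rng.integers(1, scaffold_lengths[scaf] - size + 2))
                df = tracks_focal[scaf].masked_mean(start, start + size - 1)
                dr = tracks_ref[scaf].masked_mean(start, start + size - 1)
                if np.isnan(df) or np.isnan(dr) or dr == 0:
                    continue
                ratios.append(df / dr)
                break
        if ratios:
            q25[k] = np.quantile(ratios, 0.25)
            q75[k] = np.quantile(ratios, 0.75)
            counts[k] = len(ratios)
    return NullRatioTable(edges, q25, q75, counts, seed)


# ---------------------------------------------------------------------------
# typing, filters, frequencies


def type_and_filter(candidates: list[CandidateEvent], null_table: NullRatioTable,
                    tracks_focal: dict[str, DepthTrack],
                    tracks_ref: dict[str, DepthTrack],
                    min_span: int = 3500) -> list[CandidateEvent]:
    """Assign SV classes from orientation and depth-ratio quantile rules.

    everted + ratio > q75(size class)          -> tandem_dup
    same_strand + ratio > q75                  -> inverted_dup
    same_strand + q25 <= ratio <= q75          -> inversion
    anything else discarded; events with span < ``min_span`` discarded.
    """
    out = []
    for ev in candidates:
        if ev.span < min_span:
            continue
        ratio = tracks_focal[ev.scaffold].masked_mean(ev.start, ev.end)
        dref = tracks_ref[ev.scaffold].masked_mean(ev.start, ev.end)
        if np.isnan(ratio) or np.isnan(dref) or dref == 0:
            log.info("event %s:%d-%d dropped: masked depth unavailable",
                     ev.scaffold, ev.start, ev.end)
            continue
        ratio /= dref
        k = size_class_of(ev.span)
        lo, hi = null_table.q25[k], null_table.q75[k]
        ev.depth_ratio = float(ratio)
        if ev.orientation == "everted":
            if ratio > hi:
                ev.sv_class = "tandem_dup"
        else:
            if ratio > hi:
                ev.sv_class = "inverted_dup"
            elif lo <= ratio <= hi:
                ev.sv_class = "inversion"
        if ev.sv_class is not None:
            out.append(ev)
    return out


def _overlap_len(start: int, end: int, mask: list[tuple[int, int]]) -> int:
    return sum(max(0, min(end, e) - max(start, s) + 1) for s, e in mask)


def te_extremity_filter(events: list[CandidateEvent],
                        te_mask: dict[str, list[tuple[int, int]]],
                        flank: int = 150, max_overlap: int = 100) -> list[CandidateEvent]:
    """Drop events whose breakpoint-side 150 bp inward windows overlap TEs by
    more than ``max_overlap`` bp (strictly)."""
    out = []
    for ev in events:
        mask = te_mask.get(ev.scaffold, [])
        left = _overlap_len(ev.start, ev.start + flank - 1, mask)
        right = _overlap_len(ev.end - flank + 1, ev.end, mask)
        if left > max_overlap or right > max_overlap:
            continue
        out.append(ev)
    return out


def _junctions_for(sv_class: str, orientation: str) -> int:
    if sv_class == "inversion":
        return 2
    return 1


def sv_frequency(support: int, flank_cov: float, insert_mean: float,
                 insert_sd: float, read_len: float, sv_class: str) -> float:
    """Event frequency from discordant support over flank coverage.

    The raw ratio (2 x support x read_len / (flank coverage x expected
    junction overhang)) estimates f for copy-neutral events; for
    duplications the inward flanks are themselves amplified by (1 + f), so
    the raw ratio estimates f/(1+f) and is inverted.  Capped at 1.
    """
    if not flank_cov > 0 or np.isnan(flank_cov):
        return np.nan
    z = (insert_mean - 2 * read_len) / insert_sd
    overhang = ((insert_mean - 2 * read_len) * sps.norm.cdf(z)
                + insert_sd * sps.norm.pdf(z))
    if overhang <= 0:
        return np.nan
    n_j = _junctions_for(sv_class, "")
    # support counts pairs; 2x converts to reads, matching read-depth coverage
    raw = support * 2.0 * read_len / (flank_cov * overhang * n_j)
    if sv_class in ("tandem_dup", "inverted_dup"):
        if raw >= 1.0:
            return 1.0
        return min(1.0, raw / (1.0 - raw))
    return min(1.0, raw)


def sv_fst(f1: float, f2: float) -> float:
    """Two-pool FST on event frequencies; 0 when both are 0."""
    denom = f1 * (1.0 - f2) + f2 * (1.0 - f1)
    if denom <= 0:
        return 0.0
    return (f1 - f2) ** 2 / denom


def sv_fst_and_select(events: pd.DataFrame, q: float = 0.90) -> pd.DataFrame:
    """Keep events more frequent in the focal pool, flag the per-class top
    (1-q) FST fraction as selected.  Expects columns sv_class, f_focal,
    f_ref; adds fst, fst_threshold, selected."""
    df = events[events["f_focal"] > events["f_ref"]].copy()
    df["fst"] = [sv_fst(a, b) for a, b in zip(df["f_focal"], df["f_ref"])]
    df["fst_threshold"] = np.nan
    df["selected"] = False
    for cls, sub in df.groupby("sv_class"):
        thr = float(np.quantile(sub["fst"], q))
        df.loc[sub.index, "fst_threshold"] = thr
        df.loc[sub.index, "selected"] = sub["fst"] >= thr
    return df


def genes_overlapping(events: pd.DataFrame, annotation, margin: int = 1000) -> pd.DataFrame:
    """Event-gene pairs where the gene span intersects the event extended by
    ``margin`` bp on both sides; resistance-category genes flagged."""
    rows = []
    genes_by_scaf: dict[str, list] = {}
    for g in annotation.genes:
        genes_by_scaf.setdefault(g.scaffold, []).append(g)
    for _, ev in events.iterrows():
        lo, hi = ev["start"] - margin, ev["end"] + margin
        for g in genes_by_scaf.get(ev["scaffold"], []):
            if g.start <= hi and g.end >= lo:
                rows.append({
                    "scaffold": ev["scaffold"], "start": ev["start"], "end": ev["end"],
                    "sv_class": ev["sv_class"], "gene_id": g.gene_id,
                    "category": annotation.categories.get(g.gene_id, ""),
                })
    return pd.DataFrame(rows, columns=["scaffold", "start", "end", "sv_class",
                                       "gene_id", "category"])


# ---------------------------------------------------------------------------
# end-to-end driver


def detect_svs(pairs_focal: dict[str, pd.DataFrame],
               pairs_ref: dict[str, pd.DataFrame],
               depth_focal: dict[str, np.ndarray],
               depth_ref: dict[str, np.ndarray],
               scaffold_lengths: dict[str, int],
               te_mask: dict[str, list[tuple[int, int]]] | None = None,
               min_support: int = 3, min_span: int = 3500,
               n_null_windows: int = 10_000, seed: int = 0,
               fst_quantile: float = 0.90, flank: int = 150) -> pd.DataFrame:
    """Run the full SV pipeline for a focal/reference pool pair.

    Returns a frame of typed, filtered events with per-pool frequencies and
    FST selection flags.
    """
    te_mask = te_mask or {}
    tracks_f = {s: DepthTrack(depth_focal[s], te_mask.get(s)) for s in scaffold_lengths}
    tracks_r = {s: DepthTrack(depth_ref[s], te_mask.get(s)) for s in scaffold_lengths}
    null = null_ratio_table(tracks_f, tracks_r, scaffold_lengths,
                            n=n_null_windows, seed=seed)
    rows = []
    for scaf in scaffold_lengths:
        pf = pairs_focal.get(scaf)
        pr = pairs_ref.get(scaf)
        if pf is None or pr is None:
            continue
        st_f = insert_stats(pf, scaf)
        st_r = insert_stats(pr, scaf)
        if st_f is None or st_r is None:
            continue
        cls_f = classify_pairs(pf, st_f)
        cls_r = classify_pairs(pr, st_r)
        cand_f, cand_r = [], []
        for orientation in ("everted", "same_strand"):
            cand_f += cluster_events(pf[cls_f == orientation], orientation, st_f,
                                     min_support)
            cand_r += cluster_events(pr[cls_r == orientation], orientation, st_r,
                                     min_support)
        matched = match_events(cand_f, cand_r, st_f.cutoff, st_r.cutoff)
        typed = type_and_filter([ev for ev, _ in matched], null, tracks_f, tracks_r,
                                min_span)
        typed = te_extremity_filter(typed, te_mask)
        ref_by_id = {id(ev): rb for ev, rb in matched}
        for ev in typed:
            rb = ref_by_id.get(id(ev))
            ev.ref_support = rb.support if rb is not None else 0
            fl_f = np.nanmean([tracks_f[scaf].masked_mean(ev.start, ev.start + flank - 1),
                               tracks_f[scaf].masked_mean(ev.end - flank + 1, ev.end)])
            fl_r = np.nanmean([tracks_r[scaf].masked_mean(ev.start, ev.start + flank - 1),
                               tracks_r[scaf].masked_mean(ev.end - flank + 1, ev.end)])
            if np.isnan(fl_f):
                log.info("event %s:%d-%d dropped: flanks masked", scaf, ev.start, ev.end)
                continue
            f_f = sv_frequency(ev.support, fl_f, st_f.mean, st_f.sd,
                               float(pf["read_len"].iloc[0]), ev.sv_class)
            f_r = (sv_frequency(ev.ref_support, fl_r, st_r.mean, st_r.sd,
                                float(pr["read_len"].iloc[0]), ev.sv_class)
                   if not np.isnan(fl_r) else 0.0)
            if np.isnan(f_r):
                f_r = 0.0
            rows.append({
                "scaffold": scaf, "start": ev.start, "end": ev.end,
                "span": ev.span, "sv_class": ev.sv_class,
                "orientation": ev.orientation, "support": ev.support,
                "ref_support": ev.ref_support, "depth_ratio": ev.depth_ratio,
                "f_focal": f_f, "f_ref": f_r,
            })
    events = pd.DataFrame(rows, columns=[
        "scaffold", "start", "end", "span", "sv_class", "orientation",
        "support", "ref_support", "depth_ratio", "f_focal", "f_ref"])
    if not len(events):
        for col, val in [("fst", np.nan), ("fst_threshold", np.nan),
                         ("selected", False)]:
            events[col] = val
    if len(events):
        assert (events["span"] >= min_span).all()
        assert (events["support"] >= min_support).all()
        sel = sv_fst_and_select(events, q=fst_quantile)
        events = events.merge(
            sel[["scaffold", "start", "end", "fst", "fst_threshold", "selected"]],
            on=["scaffold", "start", "end"], how="left")
        events["selected"] = events["selected"].fillna(False).astype(bool)
    return events
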