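"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: everything in memory is 1-based, inclusive on both
ends (the native convention of sync and GFF3).  BED input (0-based,
half-open) is converted at the boundary.  Intervals are ``(start, end)``
tuples with ``start <= end``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BASES = ("A", "T", "C", "G")
_SYNC_ORDER = "ATCGN*"  # column order of a sync count string A:T:C:G:N:del


class SyncParseError(ValueError):
    """Malformed sync line; message names the offending line number."""


class ConfigError(ValueError):
    """Inconsistent configuration (e.g. pool count mismatch)."""


@dataclass(frozen=True)
class PoolSpec:
    """One sequenced pool of diploid individuals.

    ``n_individuals`` is the diploid count; the haploid sample size used by
    the FST estimator is ``2 * n_individuals``.
    """

    name: str
    status: str  # "resistant" | "susceptible"
    n_individuals: int

    def __post_init__(self):
        if self.status not in ("resistant", "susceptible"):
            raise ConfigError(f"unknown status {self.status!r}")
        if self.n_individuals < 1:
            raise ConfigError("n_individuals must be >= 1")

    @property
    def haploid_size(self) -> int:
        return 2 * self.n_individuals


def check_pool_specs(pools: list[PoolSpec]) -> None:
    names = [p.name for p in pools]
    if len(set(names)) != len(names):
        raise ConfigError(f"duplicate pool names in {names}")


@dataclass
class PoolSnpTable:
    """Biallelic SNPs with per-pool ref/alt read counts.

    ``scaffold``, ``position`` (1-based), ``ref``, ``alt`` are per-locus
    arrays of length L; ``ref_counts`` and ``alt_counts`` are (L, J) integer
    matrices over the J pools of ``pools``.
    """

    pools: list[PoolSpec]
    scaffold: np.ndarray
    position: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ref_counts: np.ndarray
    alt_counts: np.ndarray

    def __post_init__(self):
        check_pool_specs(self.pools)
        L = len(self.position)
        for arr in (self.scaffold, self.ref, self.alt):
            assert len(arr) == L
        assert self.ref_counts.shape == (L, len(self.pools))
        assert self.alt_counts.shape == self.ref_counts.shape

    def __len__(self) -> int:
        return len(self.position)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def coverage(self) -> np.ndarray:
        return self.ref_counts + self.alt_counts

    @property
    def alt_freq(self) -> np.ndarray:
        """(L, J) alternative-allele frequency p_hat = alt / (ref + alt)."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.alt_counts / np.maximum(cov, 1), np.nan)

    def pool_index(self, name: str) -> int:
        for j, p in enumerate(self.pools):
            if p.name == name:
                return j
        raise KeyError(name)

    def subset(self, idx) -> "PoolSnpTable":
        return PoolSnpTable(
            self.pools,
            self.scaffold[idx],
            self.position[idx],
            self.ref[idx],
            self.alt[idx],
            self.ref_counts[idx],
            self.alt_counts[idx],
        )


@dataclass
class GeneModel:
    """One gene: representative (longest) mRNA with ordered CDS segments.

    ``cds_segments`` are (start, end) on the genome, ordered 5'->3' along the
    coding strand.  ``cds_seq`` is the spliced coding sequence (coding-strand
    orientation) when available (synthetic genomes carry it).
    """

    gene_id: str
    scaffold: str
    strand: str
    start: int
    end: int
    cds_segments: list[tuple[int, int]] = field(default_factory=list)
    exons: list[tuple[int, int]] = field(default_factory=list)
    promoter: tuple[int, int] | None = None
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    cds_seq: str | None = None

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def codable(self) -> bool:
        return bool(self.cds_segments) and self.cds_length % 3 == 0

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gene span minus exons (exons fall back to CDS segments)."""
        exons = sorted(self.exons or self.cds_segments)
        out, cur = [], self.start
        for s, e in exons:
            if s > cur:
                out.append((cur, s - 1))
            cur = max(cur, e + 1)
        if cur <= self.end:
            out.append((cur, self.end))
        return out

    def genome_to_cds_index(self, pos: int) -> int | None:
        """0-based index of a genomic position within the spliced CDS."""
        off = 0
        segs = self.cds_segments
        for s, e in segs:
            if s <= pos <= e:
                if self.strand == "+":
                    return off + (pos - s)
                return off + (e - pos)
            off += e - s + 1
        return None


@dataclass
class GenomeAnnotation:
    scaffold_lengths: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    te_mask: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    lg_map: dict[str, str] = field(default_factory=dict)

    def genes_on(self, scaffold: str) -> list[GeneModel]:
        return [g for g in self.genes if g.scaffold == scaffold]


@dataclass
class ReadPairRecord:
    """One aligned pair; ``insert`` is the outer distance."""

    scaffold: str
    left_pos: int
    right_pos: int
    left_strand: str
    right_strand: str
    read_len: int

    @property
    def insert(self) -> int:
        return self.right_pos + self.read_len - self.left_pos


# ---------------------------------------------------------------------------
# sync


def _parse_count_string(s: str, lineno: int) -> np.ndarray:
    parts = s.split(":")
    if len(parts) != 6:
        raise SyncParseError(f"line {lineno}: bad count string {s!r}")
    try:
        return np.array([int(x) for x in parts], dtype=np.int64)
    except ValueError as exc:
        raise SyncParseError(f"line {lineno}: bad count string {s!r}") from exc


def read_sync(path, pool_specs: list[PoolSpec], min_cov: int = 10,
              max_cov: int = 50) -> PoolSnpTable:
    """Read a PoPoolation2-style sync file into a biallelic SNP table.

    Keeps only biallelic loci (the two most frequent alleles summed over
    pools, one of which must be the reference base) whose per-pool coverage
    lies within ``[min_cov, max_cov]`` inclusive.  Drop reasons are logged.
    """
    check_pool_specs(pool_specs)
    J = len(pool_specs)
    scaffolds, positions, refs, alts = [], [], [], []
    ref_counts, alt_counts = [], []
    dropped = {"coverage": 0, "not_biallelic": 0, "ref_not_major2": 0}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + J:
                raise ConfigError(
                    f"line {lineno}: expected {J} pool columns, got {len(fields) - 3}")
            scaf, pos, ref = fields[0], int(fields[1]), fields[2].upper()
            counts = np.stack([_parse_count_string(f, lineno) for f in fields[3:]])
            acgt = counts[:, :4]  # per pool, order A T C G
            cov = counts[:, :5].sum(axis=1)  # N counts toward coverage, del does not
            if (cov < min_cov).any() or (cov > max_cov).any():
                dropped["coverage"] += 1
                continue
            totals = acgt.sum(axis=0)
            present = np.flatnonzero(totals > 0)
            if len(present) > 2:
                # keep only truly biallelic loci: a third allele must be absent
                dropped["not_biallelic"] += 1
                continue
            order = np.argsort(totals)[::-1]
            top2 = [b for b in order[:2] if totals[b] > 0]
            base_names = [_SYNC_ORDER[b] for b in top2]
            if ref not in BASES or ref not in base_names:
                dropped["ref_not_major2"] += 1
                continue
            if len(base_names) == 1:
                continue  # monomorphic: not a SNP
            alt = base_names[0] if base_names[1] == ref else base_names[1]
            ri, ai = _SYNC_ORDER.index(ref), _SYNC_ORDER.index(alt)
            scaffolds.append(scaf)
            positions.append(pos)
            refs.append(ref)
            alts.append(alt)
            ref_counts.append(acgt[:, ri])
            alt_counts.append(acgt[:, ai])
    if dropped["coverage"] or dropped["not_biallelic"] or dropped["ref_not_major2"]:
        log.info("read_sync dropped loci: %s", dropped)
    L = len(positions)
    return PoolSnpTable(
        pool_specs,
        np.array(scaffolds, dtype=object),
        np.array(positions, dtype=np.int64),
        np.array(refs, dtype=object),
        np.array(alts, dtype=object),
        np.stack(ref_counts) if L else np.zeros((0, J), dtype=np.int64),
        np.stack(alt_counts) if L else np.zeros((0, J), dtype=np.int64),
    )


def write_sync(table: PoolSnpTable, path) -> None:
    """Write a biallelic table back to sync (only ref/alt columns non-zero)."""
    with open(path, "w") as fh:
        for l in range(len(table)):
            cols = [str(table.scaffold[l]), str(table.position[l]), str(table.ref[l])]
            ri = _SYNC_ORDER.index(table.ref[l])
            ai = _SYNC_ORDER.index(table.alt[l])
            for j in range(table.n_pools):
                c = [0] * 6
                c[ri] = int(table.ref_counts[l, j])
                c[ai] = int(table.alt_counts[l, j])
                cols.append(":".join(map(str, c)))
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(path, promoter_len: int = 1000,
              scaffold_lengths: dict[str, int] | None = None) -> GenomeAnnotation:
    """Parse gene models from GFF3 (via gffutils), one longest mRNA per gene.

    A promoter of ``promoter_len`` bp immediately upstream of the gene start
    (strand-aware) is synthesized when the annotation carries none; it is
    clipped at scaffold bounds when lengths are known.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    scaffold_lengths = dict(scaffold_lengths or {})
    for d in db.directives:
        if d.startswith("sequence-region"):
            _, scaf, start, end = d.split()
            scaffold_lengths.setdefault(scaf, int(end))
    genes = []
    for g in db.features_of_type("gene"):
        mrnas = list(db.children(g, featuretype="mRNA"))
        if mrnas:
            rep = max(mrnas, key=lambda m: m.end - m.start)
            cds = sorted((c.start, c.end) for c in db.children(rep, featuretype="CDS"))
            exons = sorted((e.start, e.end) for e in db.children(rep, featuretype="exon"))
        else:
            cds = sorted((c.start, c.end) for c in db.children(g, featuretype="CDS"))
            exons = sorted((e.start, e.end) for e in db.children(g, featuretype="exon"))
        if g.strand == "-":
            cds = sorted(cds, key=lambda t: -t[0])  # 5'->3' on the coding strand
        gm = GeneModel(
            gene_id=g.id, scaffold=g.seqid, strand=g.strand,
            start=g.start, end=g.end, cds_segments=cds, exons=exons,
        )
        slen = scaffold_lengths.get(g.seqid)
        if g.strand == "+":
            pstart, pend = g.start - promoter_len, g.start - 1
        else:
            pstart, pend = g.end + 1, g.end + promoter_len
        pstart = max(1, pstart)
        if slen is not None:
            pend = min(pend, slen)
        if pstart <= pend:
            gm.promoter = (pstart, pend)
        if gm.cds_segments and not gm.codable:
            log.warning("gene %s: CDS length %d not divisible by 3; flagged non-codable",
                        gm.gene_id, gm.cds_length)
        genes.append(gm)
    return GenomeAnnotation(scaffold_lengths=scaffold_lengths, genes=genes)


# ---------------------------------------------------------------------------
# BED mask


def merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or adjacent 1-based inclusive intervals."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1] + 1:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def read_bed_mask(path) -> dict[str, list[tuple[int, int]]]:
    """Read a BED file into per-scaffold sorted merged 1-based intervals."""
    raw: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            scaf, start0, end0 = f[0], int(f[1]), int(f[2])
            if start0 >= end0:
                log.warning("bed line %d: start >= end, skipped", lineno)
                continue
            raw.setdefault(scaf, []).append((start0 + 1, end0))
    return {scaf: merge_intervals(ivs) for scaf, ivs in raw.items()}


# ---------------------------------------------------------------------------
# read pairs


def read_pairs_tsv(path) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Read pair records from TSV into per-scaffold frames.

    Columns: scaffold, left_pos, right_pos, left_strand, right_strand,
    read_len.  Rows with right_pos < left_pos are swapped (with strands).
    Returns (frames keyed by scaffold, drop counters).
    """
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str})
    need = ["scaffold", "left_pos", "right_pos", "left_strand", "right_strand", "read_len"]
    missing = set(need) - set(df.columns)
    if missing:
        raise ConfigError(f"pairs TSV missing columns {sorted(missing)}")
    swap = df["right_pos"] < df["left_pos"]
    if swap.any():
        lp = df.loc[swap, "left_pos"].copy()
        df.loc[swap, "left_pos"] = df.loc[swap, "right_pos"]
        df.loc[swap, "right_pos"] = lp
        ls = df.loc[swap, "left_strand"].copy()
        df.loc[swap, "left_strand"] = df.loc[swap, "right_strand"]
        df.loc[swap, "right_strand"] = ls
    df["insert"] = df["right_pos"] + df["read_len"] - df["left_pos"]
    frames = {scaf: sub.reset_index(drop=True) for scaf, sub in df.groupby("scaffold")}
    return frames, {"read": len(df), "retained": len(df), "dropped_interscaffold": 0}


def read_pairs_sam(path) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Assemble pairs from a name-sorted SAM; inter-scaffold mates dropped."""
    import pysam

    rows = []
    dropped = 0
    read = 0
    with pysam.AlignmentFile(str(path), "r") as sam:
        pending: dict[str, object] = {}
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            mate = pending.pop(aln.query_name, None)
            if mate is None:
                pending[aln.query_name] = aln
                continue
            read += 1
            if mate.reference_name != aln.reference_name:
                dropped += 1
                continue
            a, b = sorted((mate, aln), key=lambda r: r.reference_start)
            rows.append((
                aln.reference_name, a.reference_start + 1, b.reference_start + 1,
                "-" if a.is_reverse else "+", "-" if b.is_reverse else "+",
                a.query_length or a.infer_query_length() or 0,
            ))
        dropped += len(pending)  # unmated
    df = pd.DataFrame(rows, columns=["scaffold", "left_pos", "right_pos",
                                     "left_strand", "right_strand", "read_len"])
    df["insert"] = df["right_pos"] + df["read_len"] - df["left_pos"]
    frames = {scaf: sub.reset_index(drop=True) for scaf, sub in df.groupby("scaffold")}
    counters = {"read": read + dropped, "retained": len(df),
                "dropped_interscaffold": dropped}
    assert counters["read"] >= counters["retained"]
    return frames, counters


def write_pairs_tsv(frames: dict[str, pd.DataFrame], path) -> None:
    cols = ["scaffold", "left_pos", "right_pos", "left_strand", "right_strand", "read_len"]
    pd.concat([f[cols] for f in frames.values()], ignore_index=True).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# marker table and bioassay


def read_marker_table(path) -> dict[str, str]:
    """Scaffold -> linkage-group map from a marker table.

    TSV columns: marker_id, scaffold, position, lg, unique (1/0).  A scaffold
    is assigned when it carries >= 1 uniquely mapped marker and all its
    unique markers agree; conflicting scaffolds are left unplaced.
    """
    df = pd.read_csv(path, sep="\t", dtype={"scaffold": str, "lg": str})
    if df["marker_id"].duplicated().any():
        dups = df.loc[df["marker_id"].duplicated(), "marker_id"].tolist()
        raise ConfigError(f"duplicate marker ids: {dups}")
    if "unique" not in df.columns:
        df["unique"] = 1
    lg_map: dict[str, str] = {}
    for scaf, sub in df[df["unique"] == 1].groupby("scaffold"):
        lgs = set(sub["lg"])
        if len(lgs) == 1:
            lg_map[scaf] = lgs.pop()
        else:
            log.warning("scaffold %s: conflicting LGs %s, left unplaced", scaf, sorted(lgs))
    return lg_map


def read_bioassay(path) -> pd.DataFrame:
    """Strain x dose mortality table; control rows have dose = 0."""
    df = pd.read_csv(path, sep="\t", dtype={"strain": str})
    need = {"strain", "dose", "n_exposed", "n_dead"}
    if not need <= set(df.columns):
        raise ConfigError(f"bioassay TSV missing columns {sorted(need - set(df.columns))}")
    if ((df["n_dead"] < 0) | (df["n_dead"] > df["n_exposed"])).any():
        raise ConfigError("n_dead outside [0, n_exposed]")
    if (df["dose"] < 0).any():
        raise ConfigError("negative dose")
    return df
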