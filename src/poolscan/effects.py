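"""SNP placement in genomic features, coding-effect calls, per-gene piN/piS.

Site counting for piN/piS follows Nei & Gojobori's equal-rate scheme: each
CDS position contributes, over its three possible single-base changes, a
fraction of a nonsynonymous and of a synonymous site (the two fractions sum
to one, so per-gene site counts sum to the CDS length exactly).  Changes
creating a stop codon count as nonsynonymous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import GeneModel, GenomeAnnotation
from .snp_stats import pool_heterozygosity

log = logging.getLogger(__name__)

CODON_TABLE = {}
_BASES = "TCAG"
_AAS = ("FFLLSSSSYY**CC*W" "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR" "VVVVAAAADDEEGGGG")
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AAS[16 * _i + 4 * _j + _k]

_COMP = str.maketrans("ACGT", "TGCA")

FEATURE_PRIORITY = ["exon_cds", "5UTR", "3UTR", "promoter", "intron", "intergenic"]


@dataclass
class EffectCall:
    scaffold: str
    position: int
    gene_id: str | None
    feature: str
    effect: str = "none"  # synonymous | nonsynonymous | nonsense | none
    ref_aa: str | None = None
    alt_aa: str | None = None
    secondary: tuple = ()


def _feature_of(gene: GeneModel, pos: int) -> str | None:
    if gene.promoter and gene.promoter[0] <= pos <= gene.promoter[1]:
        in_prom = True
    else:
        in_prom = False
    if gene.start <= pos <= gene.end:
        for s, e in gene.cds_segments:
            if s <= pos <= e:
                return "exon_cds"
        for s, e in gene.utr5:
            if s <= pos <= e:
                return "5UTR"
        for s, e in gene.utr3:
            if s <= pos <= e:
                return "3UTR"
        for s, e in gene.exons:
            if s <= pos <= e:
                return "5UTR" if _is_five_prime(gene, pos) else "3UTR"
        return "intron"
    if in_prom:
        return "promoter"
    return None


def _is_five_prime(gene: GeneModel, pos: int) -> bool:
    """Non-CDS exonic position before the first CDS base along the strand."""
    if not gene.cds_segments:
        return True
    cds_min = min(s for s, _ in gene.cds_segments)
    cds_max = max(e for _, e in gene.cds_segments)
    return pos < cds_min if gene.strand == "+" else pos > cds_max


def locate_snp(scaffold: str, position: int, annotation: GenomeAnnotation,
               index=None) -> EffectCall:
    """Primary feature label (priority exon_cds > 5UTR > 3UTR > promoter >
    intron > intergenic) plus all secondary gene overlaps."""
    slen = annotation.scaffold_lengths.get(scaffold)
    if slen is not None and not 1 <= position <= slen:
        raise ValueError(f"{scaffold}:{position} outside scaffold bounds")
    hits = []
    genes = index.get(scaffold, []) if index is not None else annotation.genes_on(scaffold)
    for gene in genes:
        lo = min(gene.start, gene.promoter[0] if gene.promoter else gene.start)
        hi = max(gene.end, gene.promoter[1] if gene.promoter else gene.end)
        if lo <= position <= hi:
            feat = _feature_of(gene, position)
            if feat is not None:
                hits.append((gene.gene_id, feat))
    if not hits:
        return EffectCall(scaffold, position, None, "intergenic")
    hits.sort(key=lambda h: FEATURE_PRIORITY.index(h[1]))
    gene_id, feature = hits[0]
    return EffectCall(scaffold, position, gene_id, feature, secondary=tuple(hits[1:]))


def build_gene_index(annotation: GenomeAnnotation) -> dict[str, list[GeneModel]]:
    idx: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        idx.setdefault(g.scaffold, []).append(g)
    return idx


def coding_effect(gene: GeneModel, position: int, ref: str, alt: str) -> EffectCall:
    """Substitute the alternative base into its codon and translate.

    Bases are reverse-complemented on minus-strand genes.  A mismatch between
    the table's reference base and the CDS sequence flags the call and leaves
    the effect as none.
    """
    call = EffectCall(gene.scaffold, position, gene.gene_id, "exon_cds")
    if not gene.codable or gene.cds_seq is None:
        return call
    idx = gene.genome_to_cds_index(position)
    if idx is None:
        return call
    ref_c, alt_c = ref.upper(), alt.upper()
    if gene.strand == "-":
        ref_c = ref_c.translate(_COMP)
        alt_c = alt_c.translate(_COMP)
    if gene.cds_seq[idx] != ref_c:
        log.warning("gene %s pos %d: ref %s does not match CDS sequence %s",
                    gene.gene_id, position, ref_c, gene.cds_seq[idx])
        return call
    codon_i = idx // 3
    codon = gene.cds_seq[3 * codon_i: 3 * codon_i + 3]
    mutant = codon[: idx % 3] + alt_c + codon[idx % 3 + 1:]
    ref_aa = CODON_TABLE[codon]
    alt_aa = CODON_TABLE[mutant]
    call.ref_aa, call.alt_aa = ref_aa, alt_aa
    if alt_aa == ref_aa:
        call.effect = "synonymous"
    elif alt_aa == "*":
        call.effect = "nonsense"
    else:
        call.effect = "nonsynonymous"
    return call


def nei_gojobori_sites(cds_seq: str) -> tuple[float, float]:
    """Fractional (nonsynonymous, synonymous) site counts of a CDS.

    Each position contributes n/3 nonsynonymous and s/3 synonymous sites
    where n + s = 3 are its possible single-base changes; totals sum to the
    CDS length.
    """
    n_sites = 0.0
    for i in range(0, len(cds_seq) - 2, 3):
        codon = cds_seq[i:i + 3]
        aa = CODON_TABLE[codon]
        for k in range(3):
            for b in "ACGT":
                if b == codon[k]:
                    continue
                mutant = codon[:k] + b + codon[k + 1:]
                if CODON_TABLE[mutant] != aa:
                    n_sites += 1.0 / 3.0
    return n_sites, len(cds_seq) - n_sites


@dataclass
class PiNPiS:
    gene_id: str
    pi_n: float
    pi_s: float
    n_sites: float
    s_sites: float
    n_snps_n: int
    n_snps_s: int

    @property
    def ratio(self) -> float:
        return self.pi_n / self.pi_s if self.pi_s > 0 else np.nan


def pi_n_pi_s(gene: GeneModel, table, pool: str) -> PiNPiS | None:
    """Per-gene piN and piS for one pool.

    piN = sum of per-site heterozygosities over nonsynonymous CDS SNPs
    divided by the gene's nonsynonymous site count; piS analogous.  Nonsense
    changes count as nonsynonymous.  Returns None for non-codable genes.
    """
    if not gene.codable or gene.cds_seq is None:
        return None
    nn, ss = nei_gojobori_sites(gene.cds_seq)
    j = table.pool_index(pool)
    m = table.scaffold == gene.scaffold
    h = pool_heterozygosity(table.ref_counts[:, j], table.alt_counts[:, j],
                            table.pools[j].haploid_size)
    sum_n = sum_s = 0.0
    cnt_n = cnt_s = 0
    for l in np.flatnonzero(m):
        pos = int(table.position[l])
        if gene.genome_to_cds_index(pos) is None:
            continue
        call = coding_effect(gene, pos, str(table.ref[l]), str(table.alt[l]))
        if call.effect in ("nonsynonymous", "nonsense"):
            sum_n += h[l]
            cnt_n += 1
        elif call.effect == "synonymous":
            sum_s += h[l]
            cnt_s += 1
    pi_n = sum_n / nn if nn > 0 else 0.0
    pi_s = sum_s / ss if ss > 0 else 0.0
    return PiNPiS(gene.gene_id, pi_n, pi_s, nn, ss, cnt_n, cnt_s)
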