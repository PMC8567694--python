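"""Genomic-context and cCRE annotation of pMEIs.

Each pMEI receives exactly one context label with fixed precedence —
exonic (>= 5 bp exon overlap) > promoter (>= 50 bp overlap with the
strand-aware TSS window, 2 kb upstream to 1 kb downstream) > intronic
(overlapping a gene body) > intergenic — plus any number of cCRE class
labels for ENCODE candidate cis-regulatory elements whose 50 bp-slopped
span it touches.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .intervals import GenomicInterval, GeneModel, edge_distance, overlap_length

CONTEXTS = ("exonic", "promoter", "intronic", "intergenic")
DEFAULT_MIN_EXON_OVERLAP = 5
DEFAULT_MIN_PROMOTER_OVERLAP = 50
PROMOTER_UPSTREAM = 2_000
PROMOTER_DOWNSTREAM = 1_000
DEFAULT_CCRE_SLOP = 50


@dataclass
class PmeiAnnotation:
    instance_id: str
    context: str
    ccre_labels: set[str] = field(default_factory=set)
    nearest_gene: str | None = None
    nearest_gene_distance: int | None = None


def promoter_window(gene: GeneModel,
                    upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> GenomicInterval:
    """Strand-aware promoter window around the TSS (half-open coordinates).

    On '+' the window runs ``[tss - upstream, tss + downstream)``; on '-' the
    transcribed direction points to lower coordinates, so the window is
    mirrored around the TSS base.
    """
    if gene.strand == "+":
        start, end = gene.tss - upstream, gene.tss + downstream
    else:
        start, end = gene.tss + 1 - downstream, gene.tss + 1 + upstream
    return GenomicInterval(gene.body.chrom, max(0, start), end, gene.strand)


def classify_context(
    pmei: GenomicInterval,
    genes: Sequence[GeneModel],
    min_exon_overlap: int = DEFAULT_MIN_EXON_OVERLAP,
    min_promoter_overlap: int = DEFAULT_MIN_PROMOTER_OVERLAP,
) -> str:
    """One of exonic / promoter / intronic / intergenic (fixed precedence)."""
    chrom_genes = [g for g in genes if g.body.chrom == pmei.chrom]
    for gene in chrom_genes:
        if any(overlap_length(pmei, exon) >= min_exon_overlap for exon in gene.exons):
            return "exonic"
    for gene in chrom_genes:
        if overlap_length(pmei, promoter_window(gene)) >= min_promoter_overlap:
            return "promoter"
    for gene in chrom_genes:
        if overlap_length(pmei, gene.body) >= 1:
            return "intronic"
    return "intergenic"


def nearest_gene(
    pmei: GenomicInterval, genes: Sequence[GeneModel]
) -> tuple[str | None, int | None]:
    """(gene_id, edge distance) of the nearest-TSS gene on the chromosome.

    Nearest-TSS wins; ties break lexicographically by gene_id.  Returns
    (None, None) on a gene-free chromosome.
    """
    best: tuple[int, str] | None = None
    best_gene: GeneModel | None = None
    for gene in genes:
        if gene.body.chrom != pmei.chrom:
            continue
        tss_dist = min(abs(gene.tss - pmei.start), abs(gene.tss - (pmei.end - 1)))
        if pmei.start <= gene.tss < pmei.end:
            tss_dist = 0
        key = (tss_dist, gene.gene_id)
        if best is None or key < best:
            best, best_gene = key, gene
    if best_gene is None:
        return None, None
    return best_gene.gene_id, edge_distance(pmei, best_gene.body)


def assign_ccre(
    pmei: GenomicInterval,
    ccres: Sequence[tuple[GenomicInterval, str]],
    slop: int = DEFAULT_CCRE_SLOP,
) -> set[str]:
    """cCRE class labels whose slopped element overlaps the pMEI by >= 1 bp.

    Slop compensates for the low read mappability of young TE sequences,
    which truncates cCRE calls at their edges.
    """
    labels: set[str] = set()
    for iv, label in ccres:
        if iv.chrom != pmei.chrom:
            continue
        slopped_start = max(0, iv.start - slop)
        slopped_end = iv.end + slop
        if min(slopped_end, pmei.end) - max(slopped_start, pmei.start) >= 1:
            labels.add(label)
    return labels


def annotate_pmeis(
    pmeis: Sequence[tuple[str, GenomicInterval]],
    genes: Sequence[GeneModel],
    ccres: Sequence[tuple[GenomicInterval, str]] = (),
    ccre_slop: int = DEFAULT_CCRE_SLOP,
) -> list[PmeiAnnotation]:
    """Annotate (instance_id, interval) pairs with context, cCREs, nearest gene."""
    out = []
    for instance_id, iv in pmeis:
        gene_id, dist = nearest_gene(iv, genes)
        out.append(
            PmeiAnnotation(
                instance_id=instance_id,
                context=classify_context(iv, genes),
                ccre_labels=assign_ccre(iv, ccres, ccre_slop),
                nearest_gene=gene_id,
                nearest_gene_distance=dist,
            )
        )
    return out
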