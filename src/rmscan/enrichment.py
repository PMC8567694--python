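"""Subfamily-set and gene-proximity enrichment tests.

Used to ask whether the RMS list is over-represented among disease-causing
or somatically mobilised subfamilies, and whether genes flanking pMEIs show
an excess of allele-specific expression (ASE).  All tests are one-sided
Fisher exact tests for enrichment.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval, GeneModel, edge_distance
from .screen import fisher_subfamily

DEFAULT_MAX_GENE_DISTANCE = 50_000


@dataclass
class EnrichmentResult:
    """A 2x2 enrichment table with its one-sided Fisher p-value."""

    table: tuple[tuple[int, int], tuple[int, int]]
    universe_size: int
    overlap: int
    p_value: float
    description: str = ""

    def __post_init__(self) -> None:
        total = sum(self.table[0]) + sum(self.table[1])
        if total != self.universe_size:
            raise ValueError(
                f"table sums to {total}, not universe_size {self.universe_size}"
            )


def remap_subfamilies(
    names: Sequence[str],
    remap: Mapping[str, str],
    universe: Iterable[str] | None = None,
) -> list[str]:
    """Translate obsolete subfamily names onto the annotation's naming.

    External catalogues occasionally use subfamily names with no instances
    in the working RepeatMasker annotation (e.g. consensus sequences that
    align perfectly to regions annotated as an older subfamily); a remap
    table collapses those names.  Unmapped names pass through; the returned
    multiset preserves duplicates.
    """
    if universe is not None:
        universe = set(universe)
        bad = sorted(set(remap.values()) - universe)
        if bad:
            raise ValueError(f"remap targets absent from subfamily universe: {bad}")
    return [remap.get(name, name) for name in names]


def subfamily_set_enrichment(
    universe: Iterable[str],
    hit_set: Iterable[str],
    target_set: Iterable[str],
    description: str = "",
) -> EnrichmentResult:
    """One-sided Fisher test for hit/target co-occurrence within a universe.

    The 2x2 table is ``[[|hit & target|, |target - hit|],
    [|hit - target|, |universe - (hit | target)|]]``.
    """
    universe = set(universe)
    hits = set(hit_set)
    targets = set(target_set)
    stray = sorted((hits | targets) - universe)
    if stray:
        raise ValueError(f"members outside the universe: {stray[:10]}")
    a = len(hits & targets)
    b = len(targets - hits)
    c = len(hits - targets)
    d = len(universe) - a - b - c
    p = fisher_subfamily(a, b, a + c, b + d)
    return EnrichmentResult(
        table=((a, b), (c, d)),
        universe_size=len(universe),
        overlap=a,
        p_value=p,
        description=description,
    )


def flanking_genes(
    pmeis: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_GENE_DISTANCE,
) -> set[str]:
    """Gene ids whose nearest pMEI lies strictly closer than ``max_distance``.

    Distance is edge-to-edge between the gene body and the pMEI span, 0 when
    they overlap.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in pmeis:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: set[str] = set()
    for gene in genes:
        for iv in by_chrom.get(gene.body.chrom, []):
            d = edge_distance(gene.body, iv)
            if d is not None and d < max_distance:
                out.add(gene.gene_id)
                break
    return out


def gene_proximity_enrichment(
    pmeis: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    ase_genes: Iterable[str],
    expressed_genes: Iterable[str],
    max_distance: int = DEFAULT_MAX_GENE_DISTANCE,
) -> EnrichmentResult:
    """Is ASE over-represented among expressed genes flanking a pMEI?

    The universe is the expressed gene set; "flanking" means nearest-pMEI
    distance strictly below ``max_distance`` bp.
    """
    expressed = set(expressed_genes)
    ase = set(ase_genes)
    if not ase <= expressed:
        raise ValueError("ase_genes must be a subset of expressed_genes")
    flanking = flanking_genes(
        pmeis, [g for g in genes if g.gene_id in expressed], max_distance
    )
    return subfamily_set_enrichment(
        expressed, flanking, ase,
        description=f"ASE among genes < {max_distance} bp from a pMEI",
    )
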