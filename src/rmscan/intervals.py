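"""Core genomic-interval data model and overlap arithmetic.

All coordinates in this package are 0-based, half-open ``[start, end)`` on a
named sequence.  RepeatMasker ``.out`` (1-based inclusive) and VCF (1-based,
POS anchored before the event) are converted on read; BED passes through
unchanged.  Strand is carried but ignored by every overlap computation.
"""
from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A span ``[start, end)`` on a chromosome; strictly positive length."""

    chrom: str
    start: int
    end: int
    strand: str = field(default=".", compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def length(self) -> int:
        return self.end - self.start

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TEInstance:
    """One RepeatMasker annotation row: a TE copy in the reference genome.

    ``divergence`` is the percent substitutions from the subfamily consensus;
    ``human_specific`` is None until the cross-genome filter has run.
    """

    interval: GenomicInterval
    subfamily: str
    family: str
    divergence: float
    instance_id: str
    human_specific: bool | None = None

    def __post_init__(self) -> None:
        if self.divergence < 0:
            raise ValueError(f"negative divergence for {self.instance_id}")


@dataclass
class IndelRecord:
    """A polymorphic indel relative to the reference genome.

    Only ``svtype == "DEL"`` records enter the statistical test; ``retained``
    records whether the record survived redundancy pruning (None = not yet
    pruned).
    """

    interval: GenomicInterval
    svtype: str
    source: str
    indel_id: str
    retained: bool | None = None

    def __post_init__(self) -> None:
        if self.svtype not in ("DEL", "INS"):
            raise ValueError(f"unknown svtype {self.svtype!r}")


@dataclass
class GeneModel:
    """A gene body with its TSS and exon structure.

    ``tss`` is the 0-based position of the first transcribed base: the gene
    body start on '+' strand, ``end - 1`` on '-' strand.
    """

    gene_id: str
    body: GenomicInterval
    tss: int
    strand: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        expected = self.body.start if self.strand == "+" else self.body.end - 1
        if self.tss != expected:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.strand} strand body {self.body.start}-{self.body.end}"
            )


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of shared base pairs; 0 for different chromosomes."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def mutual_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Overlap length divided by the LONGER of the two intervals.

    Dividing by the longer interval makes "mutual overlap >= f" equivalent to
    reciprocal overlap >= f of both intervals, the strictest common reading.
    """
    return overlap_length(a, b) / max(a.length(), b.length())


def edge_distance(a: GenomicInterval, b: GenomicInterval) -> int | None:
    """Edge-to-edge distance in bp; 0 when overlapping, None across chroms."""
    if a.chrom != b.chrom:
        return None
    return max(0, max(a.start, b.start) - min(a.end, b.end))
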