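"""Human-specificity classification of TE instances.

A reference-genome TE instance is called human-specific when at most 20% of
its span maps to each of a panel of non-human primate genomes, and it is not
completely contained within an annotated tandem repeat (a signature of
segmental duplication rather than insertion).
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, TEInstance

DEFAULT_MAX_MAPPED_FRACTION = 0.20


def classify_human_specific(
    tes: Sequence[TEInstance],
    mappings: Mapping[str, Mapping[str, float]],
    max_fraction: float = DEFAULT_MAX_MAPPED_FRACTION,
    strict: bool = True,
) -> list[TEInstance]:
    """Set ``human_specific`` on every instance and return the flagged list.

    ``mappings`` maps instance_id -> {genome: mapped_fraction}.  Sparse input
    is allowed: a missing genome (or a missing instance altogether) means the
    instance did not map there, i.e. fraction 0.  The boundary is inclusive:
    a maximum mapped fraction of exactly ``max_fraction`` still counts as
    human-specific ("no more than" 20%).

    Raises ``KeyError`` listing offenders if the table references unknown
    instance ids; pass ``strict=False`` when ``tes`` is deliberately a
    subset of the annotated universe (e.g. after the tandem-repeat filter).
    """
    if strict:
        known = {te.instance_id for te in tes}
        unknown = sorted(set(mappings) - known)
        if unknown:
            raise KeyError(
                f"mapping rows reference unknown instance ids: {unknown[:10]}"
            )
    for te in tes:
        fractions = mappings.get(te.instance_id, {})
        worst = max(fractions.values(), default=0.0)
        te.human_specific = worst <= max_fraction
    return [te for te in tes if te.human_specific]


def filter_tandem_contained(
    tes: Iterable[TEInstance],
    tandem_repeats: Iterable[GenomicInterval],
) -> list[TEInstance]:
    """Drop instances completely contained within a tandem repeat.

    Partial overlap is kept; only full containment (both boundaries inside a
    single tandem-repeat interval) removes an instance.
    """
    by_chrom: dict[str, IntervalTree] = {}
    for tr in tandem_repeats:
        by_chrom.setdefault(tr.chrom, IntervalTree()).addi(tr.start, tr.end)

    kept = []
    for te in tes:
        tree = by_chrom.get(te.interval.chrom)
        contained = tree is not None and any(
            hit.begin <= te.interval.start and te.interval.end <= hit.end
            for hit in tree.overlap(te.interval.start, te.interval.end)
        )
        if not contained:
            kept.append(te)
    return kept
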