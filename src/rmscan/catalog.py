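"""Non-redundant deletion catalogue: size filter, overlap graph, pruning.

Public deletion call sets frequently contain near-identical records of the
same event, both within and across cohorts.  To stop one TE from matching
several copies of the same deletion, the catalogue is pruned on an overlap
graph: nodes are deletions, edges join pairs with >= 50% mutual overlap, and
the highest-degree node is removed repeatedly until no edges remain.

Removed records are kept in memory with ``retained=False`` because the
expanded pMEI scan later rescues TE matches to discarded duplicates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .intervals import IndelRecord, mutual_overlap

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 50
DEFAULT_EDGE_THRESHOLD = 0.5


def filter_deletions(
    indels: Sequence[IndelRecord], min_size: int = DEFAULT_MIN_SIZE
) -> list[IndelRecord]:
    """Keep deletions of length >= ``min_size`` bp (boundary inclusive).

    Short indels are unlikely to correspond to mobile-element insertions, so
    records under 50 bp are discarded by default.  Any INS records that
    slipped through the reader are dropped here as a safety net.
    """
    return [
        r for r in indels
        if r.svtype == "DEL" and r.interval.length() >= min_size
    ]


@dataclass
class IndelOverlapGraph:
    """Undirected overlap graph over indel records.

    ``adjacency`` maps indel_id -> set of neighbouring indel_ids; the record
    list is kept so the pruning tie-break can use genomic coordinates.
    """

    records: dict[str, IndelRecord]
    adjacency: dict[str, set[str]] = field(default_factory=dict)

    def degree(self, indel_id: str) -> int:
        return len(self.adjacency[indel_id])

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.adjacency.values()) // 2


def build_overlap_graph(
    indels: Sequence[IndelRecord],
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> IndelOverlapGraph:
    """Edges join pairs of indels with mutual overlap >= ``edge_threshold``.

    An interval index keeps the pair enumeration near-linear in the number of
    genuinely overlapping pairs.  Duplicate indel_ids across pooled sources
    are disambiguated with a numeric suffix.
    """
    records: dict[str, IndelRecord] = {}
    for r in indels:
        key = r.indel_id
        n = 2
        while key in records:
            key = f"{r.indel_id}.{n}"
            n += 1
        if key != r.indel_id:
            r.indel_id = key
        records[key] = r

    graph = IndelOverlapGraph(records, {k: set() for k in records})
    trees: dict[str, IntervalTree] = {}
    for key, r in records.items():
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, key
        )
    for key, r in records.items():
        for hit in trees[r.interval.chrom].overlap(r.interval.start, r.interval.end):
            other = hit.data
            if other == key:
                continue
            if mutual_overlap(r.interval, records[other].interval) >= edge_threshold:
                graph.adjacency[key].add(other)
                graph.adjacency[other].add(key)
    return graph


def _prune_order_key(graph: IndelOverlapGraph, indel_id: str):
    iv = graph.records[indel_id].interval
    return (iv.chrom, iv.start, iv.end, indel_id)


def prune_by_degree(graph: IndelOverlapGraph) -> set[str]:
    """Iteratively remove the max-degree node until every degree is 0.

    Ties among equal-degree nodes are broken by (chrom, start, end, indel_id)
    so the retained set is independent of input order.  Returns the retained
    id set and writes ``retained`` onto every record.
    """
    adjacency = {k: set(v) for k, v in graph.adjacency.items()}
    removed: set[str] = set()
    active = {k for k, v in adjacency.items() if v}
    while active:
        max_degree = max(len(adjacency[k]) for k in active)
        worst = min(
            (k for k in active if len(adjacency[k]) == max_degree),
            key=lambda k: _prune_order_key(graph, k),
        )
        removed.add(worst)
        for neigh in adjacency[worst]:
            adjacency[neigh].discard(worst)
            if not adjacency[neigh]:
                active.discard(neigh)
        adjacency[worst] = set()
        active.discard(worst)

    retained = set(graph.records) - removed
    for key, rec in graph.records.items():
        rec.retained = key in retained
    # contract: no retained pair may remain mutually overlapping
    for key in retained:
        offenders = graph.adjacency[key] & retained
        assert not offenders, f"pruning left overlapping pair {key} / {offenders}"
    return retained


def build_catalog(
    indels: Sequence[IndelRecord],
    min_size: int = DEFAULT_MIN_SIZE,
    edge_threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> tuple[list[IndelRecord], list[IndelRecord]]:
    """Full funnel: size filter, overlap graph, degree pruning.

    Returns (retained, discarded) record lists; logs the funnel counts.
    """
    n_input = len(indels)
    dels = [r for r in indels if r.svtype == "DEL"]
    sized = filter_deletions(dels, min_size=min_size)
    graph = build_overlap_graph(sized, edge_threshold=edge_threshold)
    retained_ids = prune_by_degree(graph)
    retained = [r for r in sized if r.indel_id in retained_ids]
    discarded = [r for r in sized if r.indel_id not in retained_ids]
    logger.info(
        "indel funnel: %d input -> %d DEL -> %d >=%d bp -> %d retained (%d discarded)",
        n_input, len(dels), len(sized), min_size, len(retained), len(discarded),
    )
    return retained, discarded
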