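"""Post-processing of per-tile regulatory scores into predicted DNase
hypersensitive sites (DHS), and per-subfamily hypersensitivity summaries.

A sequence model (e.g. a gapped k-mer SVM trained per cell line) scores the
genome in 151 bp tiles stepped by 75 bp.  Tiles scoring >= 1 are merged into
candidate regions capped at 601 bp (a run of 7 tiles), each region keeping
its best member score and trimmed back to 151 bp; the score threshold is
then set so the predicted-DHS count equals the measured-DHS count for that
cell line.  Model training is out of scope — scores arrive as input.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, TEInstance, overlap_length

DEFAULT_TILE_WIDTH = 151
DEFAULT_TILE_OVERLAP = 76
DEFAULT_SCORE_MIN = 1.0
DEFAULT_MAX_SPAN = 601
DEFAULT_MIN_DHS_OVERLAP = 50


@dataclass(frozen=True)
class TileScore:
    """Model output for one fixed-width genomic tile in one cell line."""

    interval: GenomicInterval
    score: float
    cell_line: str = ""


@dataclass(frozen=True)
class ScoredRegion:
    interval: GenomicInterval
    score: float


def tile_genome(
    chrom_lengths: Mapping[str, int],
    width: int = DEFAULT_TILE_WIDTH,
    overlap: int = DEFAULT_TILE_OVERLAP,
) -> list[GenomicInterval]:
    """Fixed-width tiles stepped by ``width - overlap``; partial tail dropped."""
    if not width > overlap >= 0:
        raise ValueError("require width > overlap >= 0")
    step = width - overlap
    tiles = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        for start in range(0, length - width + 1, step):
            tiles.append(GenomicInterval(chrom, start, start + width))
    return tiles


def merge_and_trim(
    scored_tiles: Sequence[TileScore],
    score_min: float = DEFAULT_SCORE_MIN,
    max_span: int = DEFAULT_MAX_SPAN,
    out_width: int = DEFAULT_TILE_WIDTH,
) -> list[ScoredRegion]:
    """Merge overlapping passing tiles into span-capped candidate regions.

    Tiles with score >= ``score_min`` are merged greedily left to right; a
    new region begins whenever the next passing tile does not overlap the
    current region or would push its span beyond ``max_span``.  Each region
    takes its best member score and is trimmed symmetrically to
    ``out_width`` (the extra base pair trimmed from the right when the
    excess is odd).
    """
    passing = sorted(
        (t for t in scored_tiles if t.score >= score_min),
        key=lambda t: (t.interval.chrom, t.interval.start),
    )
    regions: list[ScoredRegion] = []
    cur: list[TileScore] = []

    def _flush() -> None:
        if not cur:
            return
        start = cur[0].interval.start
        end = max(t.interval.end for t in cur)
        excess = (end - start) - out_width
        if excess > 0:
            start += excess // 2
            end = start + out_width
        regions.append(
            ScoredRegion(GenomicInterval(cur[0].interval.chrom, start, end),
                         max(t.score for t in cur))
        )

    for tile in passing:
        if cur:
            same_chrom = tile.interval.chrom == cur[0].interval.chrom
            touches = same_chrom and tile.interval.start < max(
                t.interval.end for t in cur
            )
            span_ok = same_chrom and (
                max(tile.interval.end, *(t.interval.end for t in cur))
                - cur[0].interval.start <= max_span
            )
            if not (touches and span_ok):
                _flush()
                cur = []
        cur.append(tile)
    _flush()
    return regions


def threshold_to_count(
    regions: Sequence[ScoredRegion], n_measured: int
) -> list[ScoredRegion]:
    """Keep the ``n_measured`` best-scoring regions (score desc, then
    chrom/start for ties at the cut); all regions if fewer candidates exist.

    Calibrating the predicted-DHS count to the measured count makes the
    predicted and measured hypersensitive fractions directly comparable.
    """
    if n_measured < 0:
        raise ValueError("n_measured must be non-negative")
    ranked = sorted(
        regions, key=lambda r: (-r.score, r.interval.chrom, r.interval.start)
    )
    return ranked[:n_measured]


def hypersensitive_fraction(
    subfamily_instances: Sequence[TEInstance],
    dhs_set: Iterable[GenomicInterval],
    min_overlap: int = DEFAULT_MIN_DHS_OVERLAP,
) -> float:
    """Fraction of a subfamily's genomic instances overlapping a DHS >= 50 bp.

    Uses the entire genomic instance set of the subfamily, polymorphic or
    not.  Empty subfamily -> NaN (undefined).
    """
    if not subfamily_instances:
        return float("nan")
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for dhs in dhs_set:
        by_chrom.setdefault(dhs.chrom, []).append(dhs)
    n_hit = 0
    for te in subfamily_instances:
        for dhs in by_chrom.get(te.interval.chrom, []):
            if overlap_length(te.interval, dhs) >= min_overlap:
                n_hit += 1
                break
    return n_hit / len(subfamily_instances)


def specificity_matrix(fractions: pd.DataFrame) -> pd.DataFrame:
    """Augment a subfamily x cell-line fraction matrix with summaries.

    Adds ``largest_fraction`` (row max) and per-cell fold-enrichment columns
    (``fold:<cell>`` = fraction / row mean); rows with mean 0 get missing
    folds.  Fold rows average to 1 when no value is missing.
    """
    if ((fractions < 0) | (fractions > 1)).any().any():
        raise ValueError("hypersensitive fractions must lie in [0, 1]")
    out = fractions.copy()
    row_mean = fractions.mean(axis=1)
    out["largest_fraction"] = fractions.max(axis=1)
    for cell in fractions.columns:
        with np.errstate(divide="ignore", invalid="ignore"):
            out[f"fold:{cell}"] = np.where(
                row_mean > 0, fractions[cell] / row_mean, np.nan
            )
    return out


def ancient_subfamily_reference(
    tes: Sequence[TEInstance],
    min_divergence: float = 20.0,
    min_instances: int = 1000,
) -> list[str]:
    """Subfamilies old and abundant enough to serve as a mappability-robust
    reference set (>= ``min_divergence``% average divergence and
    >= ``min_instances`` genomic copies)."""
    div: dict[str, list[float]] = {}
    for te in tes:
        div.setdefault(te.subfamily, []).append(te.divergence)
    return sorted(
        name for name, values in div.items()
        if len(values) >= min_instances and float(np.mean(values)) >= min_divergence
    )
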