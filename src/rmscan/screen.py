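"""The recently-mobile-subfamily (RMS) screen.

For every retained polymorphic deletion, a local null is built by tiling
flanking "pseudo-indels" of the same size into both flanks (250 per side by
default, adjacent tiles sharing half their length).  A human-specific TE
instance matches an indel when the two spans show >= 90% mutual overlap.
Per subfamily, a one-sided Fisher's exact test compares the fraction of true
deletions matched (T_TE / N_true) with the fraction of pseudo-indels matched
(P_TE / N_pseudo); Benjamini-Hochberg correction across all subfamilies with
at least one human-specific instance yields FDR Q-values, and subfamilies at
Q <= 0.001 are designated recently mobile.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IndelRecord, TEInstance, mutual_overlap

DEFAULT_N_PSEUDO_PER_INDEL = 500
DEFAULT_MATCH_THRESHOLD = 0.9
DEFAULT_Q_THRESHOLD = 0.001


@dataclass(frozen=True)
class PseudoIndel:
    """One simulated flanking indel; same length as its parent deletion."""

    interval: GenomicInterval
    parent_id: str
    side: str  # "left" or "right"
    rank: int  # 1 = innermost tile on that side


def generate_pseudo_indels(
    indel: IndelRecord | GenomicInterval,
    chrom_length: int,
    n_total: int = DEFAULT_N_PSEUDO_PER_INDEL,
) -> list[PseudoIndel]:
    """Tile ``n_total/2`` pseudo-indels outward into each flank.

    Tiles have the parent's length L and step ``L - floor(L/2)``, so adjacent
    same-side tiles share ``floor(L/2)`` bp (50% overlap; floored for odd L).
    The innermost right tile starts at ``indel.end``; the innermost left tile
    ends at ``indel.start``.  Tiles extending past ``[0, chrom_length)`` are
    dropped — callers must account for the shortfall in N_pseudo.
    """
    if n_total % 2:
        raise ValueError("n_total must be even (tiles are split equally per side)")
    iv = indel.interval if isinstance(indel, IndelRecord) else indel
    parent_id = indel.indel_id if isinstance(indel, IndelRecord) else "anon"
    L = iv.length()
    step = L - L // 2
    n_side = n_total // 2
    out: list[PseudoIndel] = []
    for k in range(n_side):  # left flank, innermost first
        end = iv.start - k * step
        if end - L < 0:
            break
        out.append(PseudoIndel(GenomicInterval(iv.chrom, end - L, end),
                               parent_id, "left", k + 1))
    for k in range(n_side):  # right flank
        start = iv.end + k * step
        if start + L > chrom_length:
            break
        out.append(PseudoIndel(GenomicInterval(iv.chrom, start, start + L),
                               parent_id, "right", k + 1))
    return out


def pseudo_indel_arrays(
    indels: Sequence[IndelRecord],
    chrom_lengths: Mapping[str, int],
    n_total: int = DEFAULT_N_PSEUDO_PER_INDEL,
) -> dict[str, np.ndarray]:
    """Vectorised pseudo-indel tiling for the genome-wide screen.

    Returns per-chromosome ``(n, 2)`` arrays of [start, end) rows, equivalent
    to concatenating :func:`generate_pseudo_indels` over ``indels``.
    """
    if n_total % 2:
        raise ValueError("n_total must be even")
    n_side = n_total // 2
    chunks: dict[str, list[np.ndarray]] = {}
    for rec in indels:
        iv = rec.interval
        L = iv.length()
        step = L - L // 2
        clen = chrom_lengths[iv.chrom]
        n_left = min(n_side, (iv.start - L) // step + 1) if iv.start - L >= 0 else 0
        n_right = min(n_side, (clen - L - iv.end) // step + 1) if iv.end + L <= clen else 0
        starts_l = iv.start - L - step * np.arange(n_left, dtype=np.int64)
        starts_r = iv.end + step * np.arange(n_right, dtype=np.int64)
        starts = np.concatenate([starts_l, starts_r])
        chunks.setdefault(iv.chrom, []).append(
            np.stack([starts, starts + L], axis=1)
        )
    return {
        chrom: np.concatenate(parts, axis=0)
        for chrom, parts in chunks.items()
    }


def match_te(te: TEInstance, indel_interval: GenomicInterval,
             threshold: float = DEFAULT_MATCH_THRESHOLD) -> bool:
    """A TE matches an indel when their mutual overlap is >= ``threshold``."""
    return mutual_overlap(te.interval, indel_interval) >= threshold


class IntervalMatchIndex:
    """Start-sorted per-chromosome index for reciprocal-overlap queries.

    A query interval of length M can only reach mutual overlap >= f with
    targets whose start lies within ``(1-f)/f * M`` of its own, so a binary
    search plus a vectorised exact check on the narrow candidate window
    replaces a full scan.
    """

    def __init__(self, spans_by_chrom: Mapping[str, np.ndarray]):
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        self.total = 0
        for chrom, spans in spans_by_chrom.items():
            spans = np.asarray(spans, dtype=np.int64)
            order = np.argsort(spans[:, 0], kind="stable")
            self._starts[chrom] = spans[order, 0]
            self._ends[chrom] = spans[order, 1]
            self._order[chrom] = order
            self.total += len(spans)

    @classmethod
    def from_records(cls, records: Sequence[IndelRecord]) -> "IntervalMatchIndex":
        by_chrom: dict[str, list[list[int]]] = {}
        for r in records:
            by_chrom.setdefault(r.interval.chrom, []).append(
                [r.interval.start, r.interval.end]
            )
        return cls({c: np.array(v, dtype=np.int64) for c, v in by_chrom.items()})

    def matching_positions(
        self, query: GenomicInterval, threshold: float = DEFAULT_MATCH_THRESHOLD
    ) -> np.ndarray:
        """Sorted-order positions of targets with mutual overlap >= threshold."""
        starts = self._starts.get(query.chrom)
        if starts is None or len(starts) == 0:
            return np.empty(0, dtype=np.int64)
        ends = self._ends[query.chrom]
        M = query.length()
        half = int(math.ceil((1.0 - threshold) / threshold * M)) + 1
        lo = np.searchsorted(starts, query.start - half, side="left")
        hi = np.searchsorted(starts, query.start + half, side="right")
        if lo == hi:
            return np.empty(0, dtype=np.int64)
        cs, ce = starts[lo:hi], ends[lo:hi]
        overlap = np.minimum(ce, query.end) - np.maximum(cs, query.start)
        longer = np.maximum(ce - cs, M)
        hits = overlap >= threshold * longer
        return np.arange(lo, hi, dtype=np.int64)[hits]

    def original_indices(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Map sorted-order positions back to input ordering for a chromosome."""
        return self._order[chrom][positions]


def count_matches(
    subfamily_tes: Sequence[TEInstance],
    true_index: IntervalMatchIndex,
    pseudo_index: IntervalMatchIndex,
    threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> tuple[int, int]:
    """(T_TE, P_TE): true indels / pseudo-indels matched by >= 1 given TE.

    Each indel or pseudo-indel is counted at most once even if several TE
    instances of the subfamily match it.
    """
    true_hits: set[tuple[str, int]] = set()
    pseudo_hits: set[tuple[str, int]] = set()
    for te in subfamily_tes:
        q = te.interval
        for pos in true_index.matching_positions(q, threshold):
            true_hits.add((q.chrom, int(pos)))
        for pos in pseudo_index.matching_positions(q, threshold):
            pseudo_hits.add((q.chrom, int(pos)))
    return len(true_hits), len(pseudo_hits)


def fisher_subfamily(t_te: int, p_te: int, n_true: int, n_pseudo: int) -> float:
    """One-sided (enrichment) Fisher exact p for the 2x2 table
    ``[[T_TE, N_true - T_TE], [P_TE, N_pseudo - P_TE]]``.

    The one-sided tail tests whether true deletions carry an excess of TE
    matches relative to the pseudo-indel null; equals the hypergeometric
    survival probability P(X >= T_TE).
    """
    if min(t_te, p_te, n_true - t_te, n_pseudo - p_te) < 0:
        raise ValueError(
            f"inconsistent contingency counts: T={t_te} P={p_te} "
            f"N_true={n_true} N_pseudo={n_pseudo}"
        )
    if t_te == 0:
        return 1.0  # one-sided tail P(X >= 0) covers the whole support
    return float(hypergeom.sf(t_te - 1, n_true + n_pseudo, t_te + p_te, n_true))


def log10_fisher_subfamily(t_te: int, p_te: int, n_true: int, n_pseudo: int) -> float:
    """log10 of the one-sided p, usable when the p-value itself underflows."""
    if t_te == 0:
        return 0.0
    return float(
        hypergeom.logsf(t_te - 1, n_true + n_pseudo, t_te + p_te, n_true)
    ) / math.log(10)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR Q-values (monotone in p-rank)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class SubfamilyTestResult:
    """Per-subfamily contingency counts and test outcome (one Table row)."""

    subfamily: str
    n_human_specific: int
    avg_divergence: float
    t_te: int
    p_te: int
    n_true: int
    n_pseudo: int
    p_value: float
    log10_p: float
    q_value: float = float("nan")
    is_rms: bool = False

    @property
    def expected_matches(self) -> float:
        return self.p_te * self.n_true / self.n_pseudo if self.n_pseudo else float("nan")

    @property
    def fold_enrichment(self) -> float:
        exp = self.expected_matches
        if exp and exp > 0:
            return self.t_te / exp
        return float("inf") if self.t_te > 0 else float("nan")


def run_screen(
    hs_tes: Sequence[TEInstance],
    retained_indels: Sequence[IndelRecord],
    chrom_lengths: Mapping[str, int],
    n_pseudo_per_indel: int = DEFAULT_N_PSEUDO_PER_INDEL,
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> list[SubfamilyTestResult]:
    """Run the full per-subfamily screen and call RMSs.

    ``hs_tes`` must already be restricted to human-specific instances; every
    subfamily present is tested (the tested universe m for BH).  N_pseudo is
    the number of pseudo-indels actually generated after boundary clipping,
    not the nominal ``500 x N_true``.
    """
    pseudo = pseudo_indel_arrays(retained_indels, chrom_lengths, n_pseudo_per_indel)
    true_index = IntervalMatchIndex.from_records(retained_indels)
    pseudo_index = IntervalMatchIndex(pseudo)
    n_true = len(retained_indels)
    n_pseudo = pseudo_index.total

    by_subfamily: dict[str, list[TEInstance]] = {}
    for te in hs_tes:
        by_subfamily.setdefault(te.subfamily, []).append(te)

    results: list[SubfamilyTestResult] = []
    for subfamily in sorted(by_subfamily):
        tes = by_subfamily[subfamily]
        t_te, p_te = count_matches(tes, true_index, pseudo_index, match_threshold)
        results.append(
            SubfamilyTestResult(
                subfamily=subfamily,
                n_human_specific=len(tes),
                avg_divergence=float(np.mean([te.divergence for te in tes])),
                t_te=t_te,
                p_te=p_te,
                n_true=n_true,
                n_pseudo=n_pseudo,
                p_value=fisher_subfamily(t_te, p_te, n_true, n_pseudo),
                log10_p=log10_fisher_subfamily(t_te, p_te, n_true, n_pseudo),
            )
        )
    return call_rms(results, q_threshold)


def call_rms(
    results: list[SubfamilyTestResult],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> list[SubfamilyTestResult]:
    """BH-adjust across the tested universe and flag RMSs at Q <= threshold.

    Returns the results sorted by (Q, p, subfamily) ascending.
    """
    if not results:
        return results
    qs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
        r.is_rms = q <= q_threshold
    results.sort(key=lambda r: (r.q_value, r.p_value, r.subfamily))
    return results


def results_table(results: Sequence[SubfamilyTestResult]) -> pd.DataFrame:
    """Results as a DataFrame shaped like the screen's summary table."""
    return pd.DataFrame(
        {
            "subfamily": [r.subfamily for r in results],
            "avg_divergence_pct": [r.avg_divergence for r in results],
            "n_human_specific": [r.n_human_specific for r in results],
            "T_TE": [r.t_te for r in results],
            "P_TE": [r.p_te for r in results],
            "expected_matches": [r.expected_matches for r in results],
            "fold_enrichment": [r.fold_enrichment for r in results],
            "p_value": [r.p_value for r in results],
            "log10_p": [r.log10_p for r in results],
            "q_value": [r.q_value for r in results],
            "is_rms": [r.is_rms for r in results],
        }
    )


def expanded_pmei_scan(
    rms_subfamilies: Iterable[str],
    hs_tes: Sequence[TEInstance],
    retained_indels: Sequence[IndelRecord],
    discarded_indels: Sequence[IndelRecord],
    match_threshold: float = DEFAULT_MATCH_THRESHOLD,
) -> list[TEInstance]:
    """Final pMEI list: RMS human-specific TEs matching ANY catalogued indel.

    Redundancy pruning discards near-duplicate deletions, which can hide a
    genuine pMEI whose only matching record was discarded; the expanded scan
    therefore matches against retained and discarded deletions alike.  Each
    TE instance appears once regardless of how many indels it matches.
    """
    rms_set = set(rms_subfamilies)
    pool = list(retained_indels) + list(discarded_indels)
    if not pool:
        return []
    index = IntervalMatchIndex.from_records(pool)
    out: list[TEInstance] = []
    seen: set[str] = set()
    for te in hs_tes:
        if te.subfamily not in rms_set or te.instance_id in seen:
            continue
        if len(index.matching_positions(te.interval, match_threshold)):
            out.append(te)
            seen.add(te.instance_id)
    out.sort(key=lambda te: (te.interval.chrom, te.interval.start,
                             te.interval.end, te.instance_id))
    return out
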