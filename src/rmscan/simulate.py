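"""Synthetic genomes with planted pMEI / pMED / background deletion truth.

The generator emulates the observable signatures the screen exploits, on a
desk-scale genome:

* TE instances of many subfamilies, placed uniformly without overlap;
* a human-specific subset per subfamily (low cross-genome mapped fractions);
* mobile subfamilies whose human-specific instances are paired with
  boundary-matched deletions (planted pMEIs, >= 90% mutual overlap by
  construction);
* ancestral instances occasionally deleted together with flanking sequence
  (planted pMEDs, mutual overlap with the TE pushed below the match
  threshold by the flank spill);
* background deletions >= 50 bp placed independently of TEs.

No sequence is generated: the screen operates purely on intervals and
labels, so emitting annotation tables, mapping tables and deletion calls
exercises the entire pipeline including its I/O path.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as rio
from .catalog import build_catalog
from .human_specific import classify_human_specific
from .intervals import GenomicInterval, IndelRecord, TEInstance, mutual_overlap
from .screen import (
    DEFAULT_N_PSEUDO_PER_INDEL,
    DEFAULT_Q_THRESHOLD,
    SubfamilyTestResult,
    run_screen,
)

PRIMATE_GENOMES = ("panTro5", "gorGor3", "ponAbe2", "nomLeu3", "rheMac8")


@dataclass(frozen=True)
class SubfamilySpec:
    """Generative parameters for one TE subfamily."""

    name: str
    n_instances: int = 100
    length_mean: float = 300.0
    length_sd: float = 30.0
    length_min: int = 150
    divergence: float = 10.0
    mobile: bool = False
    n_planted_pmeis: int = 0
    boundary_jitter_max: int = 5
    hs_fraction: float = 0.2


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrSim1": 10_000_000}
    )
    subfamilies: tuple[SubfamilySpec, ...] = ()
    pmed_rate: float = 0.02
    flank_spill: tuple[int, int] = (50, 200)
    n_background_indels: int = 5000
    background_log_mean: float = 5.3   # log-bp; median ~200 bp
    background_log_sd: float = 0.8
    background_min_size: int = 50
    n_pseudo_per_indel: int = DEFAULT_N_PSEUDO_PER_INDEL

    def validate(self) -> None:
        for sub in self.subfamilies:
            n_hs = int(round(sub.hs_fraction * sub.n_instances))
            if sub.n_planted_pmeis > n_hs:
                raise ValueError(
                    f"{sub.name}: {sub.n_planted_pmeis} planted pMEIs exceed "
                    f"the human-specific pool ({n_hs})"
                )
            # planted deletions must keep >= 90% mutual overlap even when the
            # jitter shrinks the deletion on both sides
            if 2 * sub.boundary_jitter_max > 0.1 * sub.length_min:
                raise ValueError(
                    f"{sub.name}: boundary_jitter_max {sub.boundary_jitter_max} "
                    f"too large for length_min {sub.length_min}; planted pMEIs "
                    "could fall below the 90% mutual-overlap match threshold"
                )
        if not 0 <= self.pmed_rate <= 1:
            raise ValueError("pmed_rate must lie in [0, 1]")
        if self.background_min_size < 1:
            raise ValueError("background_min_size must be positive")


def default_config(
    seed: int = 0,
    n_mobile: int = 3,
    n_null: int = 37,
    n_planted_pmeis: int = 15,
    n_background_indels: int = 5000,
) -> SimulationConfig:
    """The reference study conditions: one 10 Mb chromosome, 40 subfamilies
    of 100 instances each, 3 mobile subfamilies with 15 planted pMEIs, and
    5,000 background deletions."""
    subs = [
        SubfamilySpec(
            name=f"SimY{m + 1}", divergence=1.0 + 0.5 * m, mobile=True,
            n_planted_pmeis=n_planted_pmeis,
        )
        for m in range(n_mobile)
    ] + [
        SubfamilySpec(name=f"SimS{k + 1}", divergence=5.0 + 0.7 * k)
        for k in range(n_null)
    ]
    return SimulationConfig(
        seed=seed,
        subfamilies=tuple(subs),
        n_background_indels=n_background_indels,
    )


@dataclass
class SimulationTruth:
    indel_labels: dict[str, str]          # indel_id -> pMEI | pMED | background
    te_human_specific: dict[str, bool]    # instance_id -> flag
    subfamily_mobile: dict[str, bool]     # subfamily -> flag
    planted_pairs: dict[str, str]         # pMEI indel_id -> TE instance_id


@dataclass
class SimulationResult:
    config: SimulationConfig
    tes: list[TEInstance]
    mappings: dict[str, dict[str, float]]
    indels: list[IndelRecord]
    truth: SimulationTruth

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return self.config.chrom_lengths


def _place_nonoverlapping(
    rng: np.random.Generator,
    lengths: np.ndarray,
    chrom_lengths: dict[str, int],
) -> list[tuple[str, int, int]]:
    """Place intervals of the given lengths uniformly without overlap.

    Instances are assigned to chromosomes proportionally to length; within a
    chromosome, placing n blocks uniformly at random without overlap is done
    by drawing n sorted uniform gap positions in the free space and laying
    the blocks down cumulatively.
    """
    chroms = sorted(chrom_lengths)
    weights = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    assignment = rng.choice(len(chroms), size=len(lengths), p=weights / weights.sum())
    placements: list[tuple[str, int, int] | None] = [None] * len(lengths)
    for ci, chrom in enumerate(chroms):
        idx = np.flatnonzero(assignment == ci)
        if len(idx) == 0:
            continue
        lens = lengths[idx]
        free = chrom_lengths[chrom] - int(lens.sum())
        if free < 0:
            raise ValueError(
                f"cannot place {len(idx)} instances totalling {lens.sum()} bp "
                f"on {chrom} ({chrom_lengths[chrom]} bp)"
            )
        gaps = np.sort(rng.uniform(0, free, size=len(idx)))
        starts = (gaps + np.concatenate([[0], np.cumsum(lens[:-1])])).astype(np.int64)
        for j, i in enumerate(idx):
            placements[i] = (chrom, int(starts[j]), int(starts[j] + lens[j]))
    return placements  # type: ignore[return-value]


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate one synthetic dataset; byte-identical for a fixed seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- TE instances ---------------------------------------------------
    lengths = []
    owners: list[SubfamilySpec] = []
    for sub in config.subfamilies:
        lens = rng.normal(sub.length_mean, sub.length_sd, size=sub.n_instances)
        lens = np.maximum(np.round(lens), sub.length_min).astype(np.int64)
        lengths.append(lens)
        owners.extend([sub] * sub.n_instances)
    all_lengths = np.concatenate(lengths) if lengths else np.empty(0, dtype=np.int64)
    placements = _place_nonoverlapping(rng, all_lengths, config.chrom_lengths)

    tes: list[TEInstance] = []
    per_sub_counter: dict[str, int] = {}
    for (chrom, start, end), sub in zip(placements, owners):
        k = per_sub_counter.get(sub.name, 0) + 1
        per_sub_counter[sub.name] = k
        strand = "+" if rng.random() < 0.5 else "-"
        tes.append(
            TEInstance(
                GenomicInterval(chrom, start, end, strand),
                subfamily=sub.name,
                family="SimFam",
                divergence=float(max(0.0, rng.normal(sub.divergence, 0.3))),
                instance_id=f"{sub.name}.{k}",
            )
        )

    # --- human-specificity and cross-genome mapped fractions ------------
    spec_by_name = {s.name: s for s in config.subfamilies}
    by_sub: dict[str, list[TEInstance]] = {}
    for te in tes:
        by_sub.setdefault(te.subfamily, []).append(te)

    hs_flags: dict[str, bool] = {}
    planted_tes: dict[str, list[TEInstance]] = {}
    for name, members in sorted(by_sub.items()):
        sub = spec_by_name[name]
        n_hs = int(round(sub.hs_fraction * len(members)))
        hs_idx = rng.choice(len(members), size=n_hs, replace=False)
        hs_set = {members[i].instance_id for i in hs_idx}
        for te in members:
            hs_flags[te.instance_id] = te.instance_id in hs_set
        if sub.mobile and sub.n_planted_pmeis:
            chosen = rng.choice(sorted(hs_set), size=sub.n_planted_pmeis,
                                replace=False)
            id_map = {te.instance_id: te for te in members}
            planted_tes[name] = [id_map[i] for i in chosen]

    planted_ids = {te.instance_id for group in planted_tes.values() for te in group}
    mappings: dict[str, dict[str, float]] = {}
    for te in tes:
        if te.instance_id in planted_ids:
            fracs = np.zeros(len(PRIMATE_GENOMES))
        elif hs_flags[te.instance_id]:
            fracs = rng.uniform(0.0, 0.15, size=len(PRIMATE_GENOMES))
        else:
            fracs = rng.uniform(0.85, 1.0, size=len(PRIMATE_GENOMES))
        mappings[te.instance_id] = {
            genome: float(round(f, 4)) for genome, f in zip(PRIMATE_GENOMES, fracs)
        }

    # --- deletions -------------------------------------------------------
    indels: list[IndelRecord] = []
    labels: dict[str, str] = {}
    pairs: dict[str, str] = {}
    counter = 0

    def _add(iv: GenomicInterval, label: str, paired_te: str | None = None) -> None:
        nonlocal counter
        counter += 1
        indel_id = f"sim_del_{counter}"
        indels.append(IndelRecord(iv, "DEL", "simulated", indel_id))
        labels[indel_id] = label
        if paired_te is not None:
            pairs[indel_id] = paired_te

    for name in sorted(planted_tes):
        jmax = spec_by_name[name].boundary_jitter_max
        for te in planted_tes[name]:
            iv = te.interval
            j1 = int(rng.integers(-jmax, jmax + 1))
            j2 = int(rng.integers(-jmax, jmax + 1))
            start = max(0, iv.start + j1)
            end = min(config.chrom_lengths[iv.chrom], iv.end + j2)
            deletion = GenomicInterval(iv.chrom, start, end)
            assert mutual_overlap(deletion, iv) >= 0.9, "planted pMEI drifted"
            _add(deletion, "pMEI", te.instance_id)

    ancestral = [te for te in tes if not hs_flags[te.instance_id]]
    if config.pmed_rate > 0 and ancestral:
        n_pmed = int(round(config.pmed_rate * len(ancestral)))
        for i in rng.choice(len(ancestral), size=n_pmed, replace=False):
            te = ancestral[i]
            s1 = int(rng.integers(config.flank_spill[0], config.flank_spill[1] + 1))
            s2 = int(rng.integers(config.flank_spill[0], config.flank_spill[1] + 1))
            start = max(0, te.interval.start - s1)
            end = min(config.chrom_lengths[te.interval.chrom], te.interval.end + s2)
            _add(GenomicInterval(te.interval.chrom, start, end), "pMED",
                 te.instance_id)

    chroms = sorted(config.chrom_lengths)
    weights = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    for _ in range(config.n_background_indels):
        size = 0
        while size < config.background_min_size:
            size = int(round(np.exp(
                rng.normal(config.background_log_mean, config.background_log_sd)
            )))
        chrom = chroms[rng.choice(len(chroms), p=weights / weights.sum())]
        start = int(rng.integers(0, config.chrom_lengths[chrom] - size))
        _add(GenomicInterval(chrom, start, start + size), "background")

    truth = SimulationTruth(
        indel_labels=labels,
        te_human_specific=hs_flags,
        subfamily_mobile={s.name: s.mobile for s in config.subfamilies},
        planted_pairs=pairs,
    )
    return SimulationResult(config, tes, mappings, indels, truth)


def write_outputs(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Emit the simulated dataset in the formats the pipeline reads."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "tes": out_dir / "te_annotation.tsv",
        "mappings": out_dir / "mapped_fractions.tsv",
        "deletions": out_dir / "deletions.bed",
        "truth": out_dir / "truth.tsv",
        "chroms": out_dir / "chrom_lengths.tsv",
    }
    rio.write_tsv(
        [
            (te.interval.chrom, te.interval.start, te.interval.end,
             te.interval.strand, te.subfamily, te.family,
             f"{te.divergence:.2f}", te.instance_id)
            for te in result.tes
        ],
        paths["tes"],
        header=["chrom", "start", "end", "strand", "subfamily", "family",
                "divergence", "instance_id"],
    )
    rio.write_tsv(
        [
            (instance_id, genome, frac)
            for instance_id, row in result.mappings.items()
            for genome, frac in row.items()
        ],
        paths["mappings"],
        header=["instance_id", "genome", "mapped_fraction"],
    )
    rio.write_bed(
        [r.interval for r in result.indels], paths["deletions"],
        names=[r.indel_id for r in result.indels],
    )
    rio.write_tsv(
        [
            (indel_id, label, result.truth.planted_pairs.get(indel_id, ""))
            for indel_id, label in result.truth.indel_labels.items()
        ],
        paths["truth"],
        header=["indel_id", "label", "paired_te"],
    )
    rio.write_tsv(
        sorted(result.chrom_lengths.items()), paths["chroms"],
        header=["chrom", "length"],
    )
    return paths


@dataclass
class SeedReport:
    seed: int
    results: list[SubfamilyTestResult]
    called: set[str]
    planted: set[str]

    @property
    def true_positives(self) -> set[str]:
        return self.called & self.planted

    @property
    def false_positives(self) -> set[str]:
        return self.called - self.planted

    @property
    def false_negatives(self) -> set[str]:
        return self.planted - self.called


def run_pipeline_on_simulation(
    result: SimulationResult,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> list[SubfamilyTestResult]:
    """Simulated data through the real pipeline: human-specificity filter,
    catalogue pruning, then the per-subfamily screen."""
    hs = classify_human_specific(result.tes, result.mappings)
    retained, _ = build_catalog(result.indels)
    return run_screen(
        hs, retained, result.chrom_lengths,
        n_pseudo_per_indel=result.config.n_pseudo_per_indel,
        q_threshold=q_threshold,
    )


def recovery_harness(
    config: SimulationConfig,
    seeds: Sequence[int],
    q_threshold: float = DEFAULT_Q_THRESHOLD,
) -> list[SeedReport]:
    """Run simulate -> pipeline over a seed list and score against truth."""
    from dataclasses import replace

    reports = []
    planted = {s.name for s in config.subfamilies if s.mobile and s.n_planted_pmeis}
    for seed in seeds:
        sim = simulate(replace(config, seed=int(seed)))
        results = run_pipeline_on_simulation(sim, q_threshold)
        called = {r.subfamily for r in results if r.is_rms}
        reports.append(SeedReport(int(seed), results, called, set(planted)))
    return reports


def confusion_table(reports: Sequence[SeedReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seed": [r.seed for r in reports],
            "n_tested": [len(r.results) for r in reports],
            "n_called": [len(r.called) for r in reports],
            "true_positives": [len(r.true_positives) for r in reports],
            "false_positives": [len(r.false_positives) for r in reports],
            "false_negatives": [len(r.false_negatives) for r in reports],
        }
    )
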