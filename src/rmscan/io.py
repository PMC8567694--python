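"""Readers and writers for the interval formats the pipeline consumes.

Supported inputs: RepeatMasker ``.out`` (or an equivalent TSV with a declared
header), BED3+ deletion calls, uncompressed VCF deletion calls (via pysam),
cross-genome mapping TSVs, gene-model TSVs and cCRE BED files.  All writers
emit BED or TSV.
"""
from __future__ import annotations

import csv
import warnings
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import pysam

from .intervals import GenomicInterval, GeneModel, IndelRecord, TEInstance

_RM_TSV_REQUIRED = {"chrom", "start", "end", "subfamily"}


class FormatError(ValueError):
    """Raised for malformed or unrecognised input files."""


def _parse_rm_out_row(fields: list[str], lineno: int, path: str) -> TEInstance:
    try:
        chrom = fields[4]
        begin = int(fields[5])  # 1-based inclusive
        end = int(fields[6])
        strand = "-" if fields[8] in ("C", "-") else "+"
        subfamily = fields[9]
        family = fields[10].split("/")[0]
        divergence = float(fields[1])
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}:{lineno}: malformed RepeatMasker row: {exc}") from exc
    return TEInstance(
        interval=GenomicInterval(chrom, begin - 1, end, strand),
        subfamily=subfamily,
        family=family,
        divergence=divergence,
        instance_id=f"{chrom}:{begin - 1}-{end}:{subfamily}",
    )


def read_repeatmasker(path: str | Path) -> list[TEInstance]:
    """Read TE annotations from RepeatMasker ``.out`` or a headered TSV.

    ``.out`` coordinates (1-based inclusive) are converted to 0-based
    half-open.  The TSV dialect must declare at least the columns
    ``chrom start end subfamily`` (plus optional ``strand family divergence
    instance_id``) and already be 0-based half-open.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.strip():
            # possibly the blank-padded .out header; peek further below
            pass
        header_fields = first.rstrip("\n").split("\t")
        if _RM_TSV_REQUIRED.issubset(header_fields):
            return _read_repeatmasker_tsv(fh, header_fields, str(path))
        if first.lstrip().startswith(("SW", "score", "bit")):
            return _read_repeatmasker_out(fh, str(path))
        if not first.strip():
            rest = fh.read().strip()
            if not rest:
                return []
        raise FormatError(f"{path}: unrecognised TE annotation dialect")


def _read_repeatmasker_out(fh, path: str) -> list[TEInstance]:
    tes: list[TEInstance] = []
    seen_ids: Counter[str] = Counter()
    for lineno, line in enumerate(fh, start=2):
        if lineno <= 3 or not line.strip():  # 3 header lines then annotations
            continue
        if line.lstrip().startswith("*"):
            continue
        te = _parse_rm_out_row(line.split(), lineno, path)
        seen_ids[te.instance_id] += 1
        if seen_ids[te.instance_id] > 1:
            te.instance_id += f".{seen_ids[te.instance_id]}"
        tes.append(te)
    return tes


def _read_repeatmasker_tsv(fh, header: list[str], path: str) -> list[TEInstance]:
    idx = {name: i for i, name in enumerate(header)}
    tes: list[TEInstance] = []
    seen_ids: Counter[str] = Counter()
    for lineno, line in enumerate(fh, start=2):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        try:
            chrom = f[idx["chrom"]]
            start, end = int(f[idx["start"]]), int(f[idx["end"]])
            subfamily = f[idx["subfamily"]]
            strand = f[idx["strand"]] if "strand" in idx else "."
            family = f[idx["family"]] if "family" in idx else subfamily
            divergence = float(f[idx["divergence"]]) if "divergence" in idx else 0.0
            instance_id = (
                f[idx["instance_id"]]
                if "instance_id" in idx
                else f"{chrom}:{start}-{end}:{subfamily}"
            )
        except (IndexError, ValueError, KeyError) as exc:
            raise FormatError(f"{path}:{lineno}: malformed TE row: {exc}") from exc
        seen_ids[instance_id] += 1
        if seen_ids[instance_id] > 1:
            instance_id += f".{seen_ids[instance_id]}"
        tes.append(
            TEInstance(GenomicInterval(chrom, start, end, strand), subfamily,
                       family, divergence, instance_id)
        )
    return tes


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".bed", ".bed3", ".bed6"):
        return "bed"
    if suffix == ".vcf" or path.name.lower().endswith(".vcf.gz"):
        return "vcf"
    raise FormatError(f"{path}: cannot infer format from extension; pass formats=")


def read_deletions(
    paths: Sequence[str | Path],
    formats: Sequence[str] | None = None,
    sources: Sequence[str] | None = None,
) -> list[IndelRecord]:
    """Read deletion calls from BED and/or VCF files.

    Only deletions relative to the reference are emitted: VCF insertion
    records are discarded, and unresolvable VCF records are skipped (a
    warning reports the per-file skip count).  Duplicates across files are
    kept; deduplication is the catalogue module's job.
    """
    paths = [Path(p) for p in paths]
    if formats is None:
        formats = [_sniff_format(p) for p in paths]
    if sources is None:
        sources = [p.stem for p in paths]
    records: list[IndelRecord] = []
    for path, fmt, source in zip(paths, formats, sources):
        if fmt == "bed":
            records.extend(_read_bed_deletions(path, source))
        elif fmt == "vcf":
            records.extend(_read_vcf_deletions(path, source))
        else:
            raise FormatError(f"{path}: unknown format {fmt!r}")
    return records


def _read_bed_deletions(path: Path, source: str) -> list[IndelRecord]:
    out: list[IndelRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            try:
                iv = GenomicInterval(f[0], int(f[1]), int(f[2]))
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            out.append(IndelRecord(iv, "DEL", source, f"{source}:{lineno}"))
    return out


def _read_vcf_deletions(path: Path, source: str) -> list[IndelRecord]:
    out: list[IndelRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vf:
        for i, rec in enumerate(vf):
            span = _vcf_deletion_span(rec)
            if span is None:
                continue
            if span == "skip":
                skipped += 1
                continue
            start, end = span
            out.append(
                IndelRecord(
                    GenomicInterval(rec.chrom, start, end), "DEL", source,
                    rec.id or f"{source}:{i + 1}",
                )
            )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} VCF records with unresolvable length")
    return out


def _vcf_deletion_span(rec) -> tuple[int, int] | str | None:
    """Deleted span for a VCF record, "skip" if unresolvable, None if not a DEL."""
    alt = rec.alts[0] if rec.alts else None
    if alt is None:
        return "skip"
    if alt.startswith("<"):
        if alt not in ("<DEL>", "<DEL:ME>") and not alt.startswith("<DEL"):
            return None
        end = rec.stop  # END, 0-based exclusive
        if end <= rec.start + 1:
            svlen = rec.info.get("SVLEN")
            if svlen is None:
                return "skip"
            svlen = abs(svlen[0] if isinstance(svlen, tuple) else svlen)
            end = rec.start + 1 + svlen
        return rec.start + 1, end
    if any(c not in "ACGTNacgtn" for c in alt) or rec.ref is None:
        return "skip"
    diff = len(rec.ref) - len(alt)
    if diff <= 0:
        return None  # insertion or balanced substitution
    return rec.start + 1, rec.start + 1 + diff


def read_mapped_fractions(path: str | Path) -> dict[str, dict[str, float]]:
    """Read a cross-genome mapping TSV: instance_id, genome, mapped_fraction."""
    table: dict[str, dict[str, float]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"instance_id", "genome", "mapped_fraction"}
        if not required.issubset(reader.fieldnames or []):
            raise FormatError(f"{path}: mapping TSV must declare columns {sorted(required)}")
        for row in reader:
            frac = float(row["mapped_fraction"])
            if not 0.0 <= frac <= 1.0:
                raise FormatError(
                    f"{path}: mapped_fraction {frac} for {row['instance_id']} "
                    "outside [0, 1]"
                )
            table.setdefault(row["instance_id"], {})[row["genome"]] = frac
    return table


def read_bed_intervals(path: str | Path, label_column: int | None = None):
    """Read a BED file as plain intervals; optionally return a parallel label list."""
    intervals: list[GenomicInterval] = []
    labels: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            try:
                intervals.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
                if label_column is not None:
                    labels.append(f[label_column])
            except (IndexError, ValueError) as exc:
                raise FormatError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
    if label_column is not None:
        return intervals, labels
    return intervals


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from a TSV: gene_id, chrom, start, end, strand,
    exon_starts, exon_ends (comma-separated, 0-based half-open)."""
    genes: list[GeneModel] = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            body = GenomicInterval(row["chrom"], int(row["start"]), int(row["end"]),
                                   row["strand"])
            starts = [int(x) for x in row["exon_starts"].split(",") if x]
            ends = [int(x) for x in row["exon_ends"].split(",") if x]
            exons = [GenomicInterval(row["chrom"], s, e, row["strand"])
                     for s, e in zip(starts, ends)]
            tss = body.start if row["strand"] == "+" else body.end - 1
            genes.append(GeneModel(row["gene_id"], body, tss, row["strand"], exons))
    return genes


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    extra: Sequence[Sequence] | None = None,
) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if names is not None:
                cols.append(names[i])
            if extra is not None:
                cols.extend(str(x) for x in extra[i])
            fh.write("\t".join(cols) + "\n")


def write_tsv(rows: Iterable[Sequence], path: str | Path, header: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        writer.writerows(rows)
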