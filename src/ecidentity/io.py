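"""Readers and writers for the standard formats the pipeline touches.

BED3/BED6 intervals, BED/GTF gene models, GMT gene sets, dense/triplet
expression matrices, DEG tables, and BED6 peak output. Everything is
converted to the package's internal 0-based half-open convention on read.

Bulk interval files (millions of fragments) are handled as a plain pandas
DataFrame with columns (chrom, start, end, strand) — the "interval frame" —
so the coverage pipeline never materialises per-read objects.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import (
    DifferentialExpressionTable,
    ExpressionMatrix,
    GeneModel,
    GeneSetCollection,
    GenomicInterval,
    Peak,
)

logger = logging.getLogger(__name__)

INTERVAL_COLUMNS = ["chrom", "start", "end", "strand"]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t")


# ---------------------------------------------------------------------------
# gene models


def read_gene_models(path: PathLike, format: str = "bed") -> list[GeneModel]:
    """Read gene models from BED6/BED12 (0-based) or GTF (1-based, converted).

    For GTF, the span of a gene is the union of all ``gene``/``exon`` records
    sharing a ``gene_id``; transcript-to-gene collapsing beyond that union is
    deliberately not attempted. Duplicate gene_ids with conflicting
    coordinates (different chromosome or strand) are an error.
    """
    if format == "bed":
        return _read_gene_models_bed(path)
    if format == "gtf":
        return _read_gene_models_gtf(path)
    raise ValueError(f"unknown gene-model format {format!r}")


def _read_gene_models_bed(path: PathLike) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 6:
                raise ParseError(f"{path}:{lineno}: BED gene models need >=6 columns")
            try:
                chrom, start, end, name, _score, strand = (
                    f[0], int(f[1]), int(f[2]), f[3], f[4], f[5],
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                gene = GeneModel(name, chrom, start, end, strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if name in genes:
                prev = genes[name]
                if (prev.chrom, prev.start, prev.end, prev.strand) != (
                    chrom, start, end, strand,
                ):
                    raise ParseError(
                        f"{path}:{lineno}: duplicate gene_id {name!r} with "
                        "conflicting coordinates"
                    )
            genes[name] = gene
    return list(genes.values())


def _gtf_attribute(attrs: str, key: str) -> Optional[str]:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + " ") or part.startswith(key + "="):
            value = part[len(key):].strip(" =")
            return value.strip('"')
    return None


def _read_gene_models_gtf(path: PathLike) -> list[GeneModel]:
    spans: dict[str, list] = {}  # gene_id -> [chrom, start0, end, strand]
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = _fields(line)
            if len(f) < 9:
                raise ParseError(f"{path}:{lineno}: GTF needs 9 columns")
            chrom, _src, feature, start1, end1, _score, strand = f[0], f[1], f[2], f[3], f[4], f[5], f[6]
            if feature not in ("gene", "exon"):
                continue
            try:
                start0, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            if start0 < 0 or start0 >= end:
                raise ParseError(f"{path}:{lineno}: bad GTF span {start1}-{end1}")
            gene_id = _gtf_attribute(f[8], "gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: record lacks gene_id attribute")
            rec = spans.get(gene_id)
            if rec is None:
                spans[gene_id] = [chrom, start0, end, strand]
            else:
                if rec[0] != chrom or rec[3] != strand:
                    raise ParseError(
                        f"{path}:{lineno}: gene_id {gene_id!r} spans conflicting "
                        "chromosome/strand"
                    )
                rec[1] = min(rec[1], start0)
                rec[2] = max(rec[2], end)
    return [
        GeneModel(gid, chrom, start, end, strand)
        for gid, (chrom, start, end, strand) in spans.items()
    ]


# ---------------------------------------------------------------------------
# intervals / fragments


def read_intervals_bed(path: PathLike) -> list[GenomicInterval]:
    """Read BED3/BED6 as a list of GenomicInterval (strand from column 6)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else None
            try:
                out.append(GenomicInterval(f[0], start, end, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_interval_frame(path: PathLike) -> pd.DataFrame:
    """Bulk BED reader returning an interval frame (chrom/start/end/strand)."""
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2, 3, 4, 5],
            names=["chrom", "start", "end", "name", "score", "strand"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
    except ValueError:
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        df["strand"] = None
    if df.empty:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    if (df["start"] >= df["end"]).any():
        bad = int(np.argmax((df["start"] >= df["end"]).to_numpy())) + 1
        raise ParseError(f"{path}: empty/inverted interval at data row {bad}")
    if "strand" in df and df["strand"].isin(["+", "-"]).all():
        strand = df["strand"]
    else:
        strand = df.get("strand")
        if strand is not None:
            strand = strand.where(strand.isin(["+", "-"]), None)
    out = df[["chrom", "start", "end"]].copy()
    out["strand"] = strand
    return out


def intervals_to_frame(intervals: Sequence[GenomicInterval]) -> pd.DataFrame:
    if len(intervals) == 0:
        return pd.DataFrame(columns=INTERVAL_COLUMNS)
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start": np.array([iv.start for iv in intervals], dtype=np.int64),
            "end": np.array([iv.end for iv in intervals], dtype=np.int64),
            "strand": [iv.strand for iv in intervals],
        }
    )


def as_interval_frame(
    intervals: Union[pd.DataFrame, Sequence[GenomicInterval]]
) -> pd.DataFrame:
    if isinstance(intervals, pd.DataFrame):
        missing = [c for c in ("chrom", "start", "end") if c not in intervals.columns]
        if missing:
            raise ValueError(f"interval frame missing columns {missing}")
        if "strand" not in intervals.columns:
            intervals = intervals.assign(strand=None)
        return intervals
    return intervals_to_frame(list(intervals))


def write_interval_frame(df: pd.DataFrame, path: PathLike) -> None:
    """Write an interval frame as BED6 (name '.', score 0)."""
    strand = (
        df["strand"].astype(object).where(df["strand"].notna(), ".")
        if "strand" in df else "."
    )
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].astype(str),
            "start": df["start"],
            "end": df["end"],
            "name": ".",
            "score": 0,
            "strand": strand,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# peaks


def write_peaks_bed(peaks: Sequence[Peak], path: PathLike) -> None:
    """Write peaks as BED6; score column carries Peak.score to 6 sig digits."""
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, 1):
            strand = p.interval.strand or "."
            fh.write(
                f"{p.interval.chrom}\t{p.interval.start}\t{p.interval.end}"
                f"\tpeak_{i}\t{p.score:.6g}\t{strand}\n"
            )


def read_peaks_bed(path: PathLike) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >=3 columns")
            try:
                start, end = int(f[1]), int(f[2])
                score = float(f[4]) if len(f) >= 5 else 0.0
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            strand = f[5] if len(f) >= 6 and f[5] in ("+", "-") else None
            try:
                peaks.append(Peak(GenomicInterval(f[0], start, end, strand), score))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gmt(path: PathLike) -> GeneSetCollection:
    """Read a GMT file: name, description, then >=1 gene id per line.

    Duplicate ids within one line are deduplicated with a logged warning;
    duplicate set names across lines are an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = _fields(line)
            if len(f) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description, >=1 gene"
                )
            name, genes = f[0], [g for g in f[2:] if g]
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} has no genes")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.warning(
                    "%s:%d: set %r contained %d duplicate gene ids (deduplicated)",
                    path, lineno, name, len(genes) - len(deduped),
                )
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = deduped
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: PathLike,
              description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description] + list(genes)) + "\n")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: PathLike, format: str = "tsv_dense",
                           cell_labels=None) -> ExpressionMatrix:
    """Read a genes x cells matrix.

    ``tsv_dense``: header row of cell ids, one row per gene (first column id).
    ``triplet``: rows of (gene, cell, value); missing entries are 0 and a
    duplicated (gene, cell) pair is an error.
    """
    if format == "tsv_dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return ExpressionMatrix(df.astype(float), cell_labels)
    if format == "triplet":
        tri = pd.read_csv(
            path, sep="\t", header=None, names=["gene", "cell", "value"],
            dtype={"gene": str, "cell": str, "value": float},
        )
        if tri.duplicated(["gene", "cell"]).any():
            raise ParseError(f"{path}: duplicate (gene, cell) triplet entries")
        if (tri["value"] < 0).any():
            raise ValueError(f"{path}: negative expression value")
        df = tri.pivot(index="gene", columns="cell", values="value").fillna(0.0)
        return ExpressionMatrix(df, cell_labels)
    raise ValueError(f"unknown expression format {format!r}")


def write_expression_matrix(matrix: ExpressionMatrix, path: PathLike) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id",
                         float_format="%.6g")


def read_cell_labels(path: PathLike) -> dict[str, str]:
    """Two-column TSV (cell_id, group), no header."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell_id", "group"],
                     dtype=str)
    if df["cell_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate cell ids in label file")
    return dict(zip(df["cell_id"], df["group"]))


def write_cell_labels(labels: dict[str, str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for cell in labels:
            fh.write(f"{cell}\t{labels[cell]}\n")


# ---------------------------------------------------------------------------
# DEG tables and gene lists


def read_deg_table(path: PathLike) -> DifferentialExpressionTable:
    df = pd.read_csv(path, sep="\t")
    return DifferentialExpressionTable(df)


def read_gene_list(path: PathLike) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(g + "\n")
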