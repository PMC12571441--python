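"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based half-open (BED convention). GTF input is
converted on read and back on write; nothing downstream ever sees 1-based
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand is not None and self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """0-based position of the 5' end (requires strand)."""
        if self.strand is None:
            raise ValueError("strand required to locate 5' end")
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class GeneModel:
    """A gene locus: the unit of identity ranking and regulatory potential.

    The TSS is the strand-dependent 5' end of the gene span: ``start`` on the
    plus strand, ``end - 1`` on the minus strand.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("empty gene_id")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"bad gene span {self.gene_id} {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Peak:
    """An enriched interval with a score.

    ``score`` is -log10 of the Poisson upper-tail P at the summit bin for
    called peaks, or whatever score column an imported BED carried.
    """

    interval: GenomicInterval
    score: float
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError(f"negative peak score {self.score}")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError("summit outside peak interval")


class GeneSetCollection:
    """Named gene sets (GMT semantics): unique names, no duplicate ids per set."""

    def __init__(self, sets: Mapping[str, Sequence[str]]):
        self._sets: dict[str, list[str]] = {}
        for name, genes in sets.items():
            genes = list(genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate gene ids in set {name!r}")
            if name in self._sets:
                raise ValueError(f"duplicate set name {name!r}")
            self._sets[name] = genes

    def __getitem__(self, name: str) -> list[str]:
        return list(self._sets[name])

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def items(self):
        return self._sets.items()


class DifferentialExpressionTable:
    """Rows of (gene_id, log2_fold_change, fdr, mean_expression), gene_id unique."""

    COLUMNS = ("gene_id", "log2_fold_change", "fdr", "mean_expression")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"DEG table missing columns: {missing}")
        df = df.loc[:, list(self.COLUMNS)].copy()
        if df["gene_id"].duplicated().any():
            dupes = df.loc[df["gene_id"].duplicated(), "gene_id"].unique()[:5]
            raise ValueError(f"duplicate gene_id in DEG table: {list(dupes)}")
        fdr = df["fdr"].to_numpy(float)
        if np.any((fdr < 0) | (fdr > 1) | ~np.isfinite(fdr)):
            raise ValueError("fdr values must lie in [0, 1]")
        if np.any(df["mean_expression"].to_numpy(float) < 0):
            raise ValueError("mean_expression must be >= 0")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)


class ExpressionMatrix:
    """Genes x cells matrix of non-negative normalized expression values.

    ``cell_labels`` optionally maps a subset of cell ids to group labels.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        cell_labels: Optional[Mapping[str, str]] = None,
    ):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if values.columns.duplicated().any():
            raise ValueError("duplicate cell ids in expression matrix")
        arr = values.to_numpy(float)
        if np.any(arr < 0) or not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite and >= 0")
        self.values = values
        self.cell_labels = dict(cell_labels) if cell_labels else {}
        unknown = set(self.cell_labels) - set(values.columns)
        if unknown:
            raise ValueError(
                f"labeled cells absent from matrix: {sorted(unknown)[:5]}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


def check_shared_chromosomes(a: Sequence[str], b: Sequence[str],
                             what_a: str = "first input",
                             what_b: str = "second input") -> None:
    """Hard error when two inputs share no chromosome names.

    Chromosome names are taken verbatim (no 'chr' normalization); a silent
    zero-overlap result is worse than an error.
    """
    sa, sb = set(a), set(b)
    if sa and sb and not (sa & sb):
        raise ValueError(
            f"no shared chromosome names between {what_a} {sorted(sa)[:5]} "
            f"and {what_b} {sorted(sb)[:5]}"
        )
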