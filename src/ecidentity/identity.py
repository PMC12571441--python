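"""Ranking candidate cell-identity genes by chromatin-mark breadth.

Cell-identity genes are empirically marked by unusually broad domains of
active-chromatin marks (H3K4me3, H3K27ac). For each gene, the breadth of a
mark is the total base pairs of called-peak territory within the gene body
plus a flank (default +/-10 kb). Genes are ranked per mark (widest first,
mid-ranks on ties) and the per-mark ranks are summed into a single ordering;
for a fixed number of marks the sum and the mean of ranks give the same
order, and both are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import (
    DifferentialExpressionTable,
    GeneModel,
    GenomicInterval,
    Peak,
    check_shared_chromosomes,
)

DEFAULT_FLANK = 10_000


@dataclass
class BreadthTable:
    """Per-gene mark breadth (bp of unioned peak overlap within the window)."""

    mark_name: str
    breadths: dict[str, int]
    flank: int = DEFAULT_FLANK


@dataclass
class IdentityRanking:
    """The aggregated ordering; ``table`` rows are sorted by final_position."""

    table: pd.DataFrame  # gene_id, breadth_<mark>..., rank_<mark>..., rank_sum,
    #                      rank_mean, final_position
    marks: list[str] = field(default_factory=list)

    def top(self, k: int) -> list[str]:
        return list(self.table["gene_id"].iloc[:k])


def gene_window(gene: GeneModel, flank: int,
                chrom_length: Optional[int] = None) -> GenomicInterval:
    """The gene body extended by ``flank`` bp on both sides, clipped to the
    chromosome."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = max(0, gene.start - flank)
    end = gene.end + flank
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(gene.chrom, start, end)


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    """Union of sorted-by-start intervals; returns merged (starts, ends)."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    cur_s, cur_e = None, None
    for s, e in zip(starts, ends):
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged_s.append(cur_s)
            merged_e.append(cur_e)
            cur_s, cur_e = s, e
    if cur_s is not None:
        merged_s.append(cur_s)
        merged_e.append(cur_e)
    return np.asarray(merged_s, dtype=np.int64), np.asarray(merged_e, dtype=np.int64)


def breadth_per_gene(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    flank: int = DEFAULT_FLANK,
    mark_name: str = "mark",
    chrom_lengths: Optional[Mapping[str, int]] = None,
    mode: str = "union",
) -> BreadthTable:
    """Total bp of peak territory within each gene's window.

    Overlapping peaks are unioned before measuring, so fragmented calls are
    not double-counted (mode='union', the default). mode='max_single'
    instead reports the largest single peak-window overlap, for users who
    want the widest-domain reading of breadth.
    """
    if mode not in ("union", "max_single"):
        raise ValueError(f"unknown breadth mode {mode!r}")
    peak_chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if peaks:
        check_shared_chromosomes(
            [p.interval.chrom for p in peaks], [g.chrom for g in genes],
            "peaks", "gene models",
        )
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        s = np.array([p.interval.start for p in plist], dtype=np.int64)
        e = np.array([p.interval.end for p in plist], dtype=np.int64)
        if mode == "union":
            s, e = _merge_intervals(s, e)
        else:
            order = np.argsort(s, kind="stable")
            s, e = s[order], e[order]
        peak_chroms[chrom] = (s, e)

    breadths: dict[str, int] = {}
    for gene in genes:
        clen = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        win = gene_window(gene, flank, clen)
        entry = peak_chroms.get(gene.chrom)
        if entry is None:
            breadths[gene.gene_id] = 0
            continue
        s, e = entry
        overlap = np.minimum(e, win.end) - np.maximum(s, win.start)
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            breadths[gene.gene_id] = 0
        elif mode == "union":
            breadths[gene.gene_id] = int(overlap.sum())
        else:
            breadths[gene.gene_id] = int(overlap.max())
    return BreadthTable(mark_name=mark_name, breadths=breadths, flank=flank)


def rank_by_breadth(table: BreadthTable) -> dict[str, float]:
    """Rank genes by breadth, widest = rank 1, mid-ranks on ties."""
    if not table.breadths:
        raise ValueError("empty breadth table")
    genes = list(table.breadths)
    values = np.array([table.breadths[g] for g in genes], dtype=float)
    ranks = sps.rankdata(-values, method="average")
    return dict(zip(genes, ranks.astype(float)))


def aggregate_ranks(
    tables: Sequence[BreadthTable],
    whitelist: Optional[Sequence[str]] = None,
) -> IdentityRanking:
    """Sum per-mark ranks into one ordering (ascending rank_sum).

    The gene universe is the union over tables; a gene absent from a mark's
    table gets breadth 0 there before ranking. Ties on rank_sum are broken
    by greater total breadth, then lexicographic gene_id. ``whitelist``
    restricts the universe before ranking (e.g. to transcription factors).
    """
    if not tables:
        raise ValueError("need at least one breadth table")
    universe: list[str] = []
    seen = set()
    for t in tables:
        for g in t.breadths:
            if g not in seen:
                universe.append(g)
                seen.add(g)
    if whitelist is not None:
        allowed = set(whitelist)
        universe = [g for g in universe if g in allowed]
        if not universe:
            raise ValueError("whitelist excludes every gene in the tables")
    universe = sorted(universe)

    data: dict[str, list] = {"gene_id": universe}
    rank_cols = []
    marks = []
    for t in tables:
        filled = BreadthTable(
            mark_name=t.mark_name,
            breadths={g: t.breadths.get(g, 0) for g in universe},
            flank=t.flank,
        )
        ranks = rank_by_breadth(filled)
        data[f"breadth_{t.mark_name}"] = [filled.breadths[g] for g in universe]
        data[f"rank_{t.mark_name}"] = [ranks[g] for g in universe]
        rank_cols.append(f"rank_{t.mark_name}")
        marks.append(t.mark_name)
    df = pd.DataFrame(data)
    df["rank_sum"] = df[rank_cols].sum(axis=1)
    df["rank_mean"] = df["rank_sum"] / len(tables)
    total_breadth = df[[f"breadth_{m}" for m in marks]].sum(axis=1)
    df["_neg_total_breadth"] = -total_breadth
    df = df.sort_values(
        ["rank_sum", "_neg_total_breadth", "gene_id"], kind="stable"
    ).drop(columns="_neg_total_breadth")
    df["final_position"] = np.arange(1, len(df) + 1)
    return IdentityRanking(table=df.reset_index(drop=True), marks=marks)


def filter_deg_table(
    table: DifferentialExpressionTable,
    fdr_max: float = 0.05,
    abs_l2fc_min: float = 1.0,
    min_expression: float = 1.0,
) -> tuple[list[str], list[str]]:
    """Split a DEG table into (up, down) gene lists.

    up: fdr < fdr_max and log2FC > abs_l2fc_min and expression > min_expression;
    down symmetric with log2FC < -abs_l2fc_min. The defaults are the usual
    FDR < 0.05, |log2FC| > 1, FPKM > 1 gates.
    """
    df = table.df
    expressed = (df["fdr"] < fdr_max) & (df["mean_expression"] > min_expression)
    up = df.loc[expressed & (df["log2_fold_change"] > abs_l2fc_min), "gene_id"]
    down = df.loc[expressed & (df["log2_fold_change"] < -abs_l2fc_min), "gene_id"]
    return list(up), list(down)
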