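"""Peak-to-gene regulatory-potential scoring and gene-set comparisons.

A transcription-factor binding peak contributes to a gene proportionally to
an exponentially decaying function of its distance to the TSS:
weight = 2^(-d / half_distance), i.e. the weight halves every
``half_distance`` bp, and peaks beyond ``max_distance`` are ignored. A
gene's regulatory potential is the sum of weights over all peaks in the
window. The decay constant and window are transparent stand-ins for the
family of published regulatory-potential scores; the downstream comparison
(cumulative-fraction curves of a gene set vs matched random genes, Wilcoxon
rank-sum P) only needs a monotone distance-decay score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import GeneModel, Peak, check_shared_chromosomes
from .stats import GroupComparison, wilcoxon_rank_sum

logger = logging.getLogger(__name__)


@dataclass
class RegPotParams:
    half_distance: int = 10_000   # bp at which a peak's weight halves
    max_distance: int = 100_000   # peaks farther from the TSS are ignored
    anchor: str = "peak_center"   # or "peak_summit"

    def __post_init__(self) -> None:
        if not (0 < self.half_distance <= self.max_distance):
            raise ValueError("need 0 < half_distance <= max_distance")
        if self.anchor not in ("peak_center", "peak_summit"):
            raise ValueError(f"unknown anchor {self.anchor!r}")


@dataclass
class RegPotTable:
    scores: dict[str, float]
    params: RegPotParams = field(default_factory=RegPotParams)


def _peak_anchor(peak: Peak, anchor: str) -> int:
    if anchor == "peak_summit":
        if peak.summit is None:
            raise ValueError("anchor=peak_summit but peak has no summit")
        return peak.summit
    return (peak.interval.start + peak.interval.end) // 2


def regulatory_potential(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    params: RegPotParams | None = None,
) -> RegPotTable:
    """score(g) = sum over peaks with d = |anchor - tss| <= max_distance of
    2^(-d / half_distance). Genes with no peak in the window score 0."""
    params = params or RegPotParams()
    if peaks and genes:
        check_shared_chromosomes(
            [p.interval.chrom for p in peaks], [g.chrom for g in genes],
            "peaks", "gene models",
        )
    anchors: dict[str, np.ndarray] = {}
    for p in peaks:
        anchors.setdefault(p.interval.chrom, []).append(
            _peak_anchor(p, params.anchor)
        )
    anchors = {c: np.sort(np.asarray(a, dtype=np.int64)) for c, a in anchors.items()}

    scores: dict[str, float] = {}
    for gene in genes:
        arr = anchors.get(gene.chrom)
        if arr is None or arr.size == 0:
            scores[gene.gene_id] = 0.0
            continue
        lo = np.searchsorted(arr, gene.tss - params.max_distance, side="left")
        hi = np.searchsorted(arr, gene.tss + params.max_distance, side="right")
        d = np.abs(arr[lo:hi] - gene.tss)
        d = d[d <= params.max_distance]
        scores[gene.gene_id] = float(
            np.sum(np.exp2(-d / params.half_distance))
        )
    return RegPotTable(scores=scores, params=params)


def sample_random_gene_set(universe: Sequence[str], n: int, seed: int) -> list[str]:
    """Uniform sample of n gene ids without replacement; deterministic per seed."""
    universe = list(universe)
    if n > len(universe):
        raise ValueError(f"cannot sample {n} genes from a universe of {len(universe)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(universe), size=n, replace=False)
    return [universe[i] for i in idx]


def cumulative_fraction_curve(
    table: RegPotTable, gene_set: Sequence[str]
) -> list[tuple[float, float]]:
    """Empirical CDF of the set's scores: (distinct score, fraction <= score).

    Set members absent from the table are dropped with a logged count; the
    curve is non-decreasing and ends at 1.
    """
    present = [g for g in gene_set if g in table.scores]
    dropped = len(gene_set) - len(present)
    if dropped:
        logger.warning("cumulative_fraction_curve: dropped %d absent genes", dropped)
    if not present:
        raise ValueError("no gene-set member present in the score table")
    values = np.sort(np.array([table.scores[g] for g in present], dtype=float))
    uniq, counts = np.unique(values, return_counts=True)
    frac = np.cumsum(counts) / values.size
    return list(zip(uniq.tolist(), frac.tolist()))


def compare_regpot(
    table: RegPotTable,
    set_a: Sequence[str],
    set_b: Sequence[str],
    mode: str = "auto",
) -> GroupComparison:
    """Wilcoxon rank-sum comparison of two gene sets' regulatory potentials."""
    a = [table.scores[g] for g in set_a if g in table.scores]
    b = [table.scores[g] for g in set_b if g in table.scores]
    if not a or not b:
        raise ValueError("each gene set needs >=1 member in the score table")
    dropped = (len(set_a) - len(a)) + (len(set_b) - len(b))
    if dropped:
        logger.warning("compare_regpot: dropped %d absent genes", dropped)
    return wilcoxon_rank_sum(a, b, mode=mode)
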