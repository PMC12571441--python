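"""Rank-based per-cell gene-signature scoring and state classification.

The score follows the UCell family of Mann-Whitney-U statistics: within each
cell, all genes are ranked by descending expression (mid-ranks on ties),
ranks beyond ``rank_cap`` (1500 by default) are truncated to rank_cap + 1,
and for a set of n genes with capped rank sum R,

    U = R - n(n+1)/2,      score = 1 - U / (n * rank_cap).

A set occupying the cell's top n ranks scores exactly 1; a set entirely at
the cap scores the floor (n-1) / (2 * rank_cap). Because only ranks enter,
the score is invariant to any monotone per-cell transform of expression
(log-normalized vs raw-normalized values give identical scores).

Endothelial vs mesenchymal state labels (EC-like / EndoMT / mesenchymal-like)
are assigned from z-scaled signature scores: with three marker sets the label
is the argmax; with only endothelial and mesenchymal sets, cells whose two
z-scores are within a margin of each other are labelled the transitional
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import ExpressionMatrix, GeneSetCollection
from .stats import GroupComparison, student_t_two_sided, wilcoxon_rank_sum

ENDOMT_LABEL = "EndoMT"


@dataclass
class SignatureScoreParams:
    rank_cap: int = 1500
    missing_gene_policy: str = "cap_rank"  # or "drop"

    def __post_init__(self) -> None:
        if self.rank_cap < 2:
            raise ValueError("rank_cap must be >= 2")
        if self.missing_gene_policy not in ("cap_rank", "drop"):
            raise ValueError(f"unknown policy {self.missing_gene_policy!r}")


@dataclass
class CellScores:
    """cells x sets score frame; ``scores.loc[cell, set]`` in [floor, 1]."""

    scores: pd.DataFrame
    params: SignatureScoreParams = field(default_factory=SignatureScoreParams)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.scores.index)


@dataclass
class SubgroupAssignment:
    labels: dict[str, str]
    zscores: pd.DataFrame  # cells x sets, the z-scaled scores used


def score_cells(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    params: SignatureScoreParams | None = None,
) -> CellScores:
    """Per-cell U-statistic signature score for every set in the collection.

    Under the default ``cap_rank`` policy, set genes absent from the matrix
    take the capped rank rank_cap + 1 (so scores stay comparable across
    matrices); under ``drop`` they are excluded from the set. A set with no
    gene in the matrix, or an effective size >= rank_cap, is an error.
    """
    params = params or SignatureScoreParams()
    cap = params.rank_cap
    X = matrix.values.to_numpy(float)
    # ranks of descending expression per cell, mid-ranks on ties
    ranks = sps.rankdata(-X, axis=0, method="average")
    capped = np.where(ranks > cap, cap + 1.0, ranks)
    gene_index = {g: i for i, g in enumerate(matrix.values.index)}

    out: dict[str, np.ndarray] = {}
    for name, genes in sets.items():
        idx = [gene_index[g] for g in genes if g in gene_index]
        n_missing = len(genes) - len(idx)
        if not idx:
            raise ValueError(f"gene set {name!r} has no gene in the matrix")
        n = len(idx) if params.missing_gene_policy == "drop" else len(genes)
        if n >= cap:
            raise ValueError(
                f"set {name!r}: effective size {n} >= rank_cap {cap}"
            )
        r_sum = capped[idx, :].sum(axis=0)
        if params.missing_gene_policy == "cap_rank":
            r_sum = r_sum + n_missing * (cap + 1.0)
        u = r_sum - n * (n + 1) / 2.0
        out[name] = 1.0 - u / (n * cap)
    df = pd.DataFrame(out, index=matrix.values.columns)
    return CellScores(scores=df, params=params)


def zscale_scores(scores: CellScores) -> CellScores:
    """z-scale each set's scores across cells (sample sd, ddof=1)."""
    df = scores.scores
    if len(df) < 2:
        raise ValueError("z-scaling needs >=2 cells")
    sd = df.std(ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(
            f"zero variance across cells for set(s) {list(flat.index)}"
        )
    z = (df - df.mean()) / sd
    return CellScores(scores=z, params=scores.params)


def compare_score_groups(
    scores: CellScores,
    labels: Mapping[str, str],
    set_name: str,
    test: str = "t_test",
) -> GroupComparison:
    """Two-group comparison of one signature's per-cell scores.

    ``labels`` must place the scored cells into exactly two groups (cells
    without a label are ignored); groups are ordered by sorted group name.
    """
    if set_name not in scores.scores.columns:
        raise ValueError(f"unknown set {set_name!r}")
    series = scores.scores[set_name]
    groups: dict[str, list[float]] = {}
    for cell, grp in labels.items():
        if cell in series.index:
            groups.setdefault(grp, []).append(float(series[cell]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {sorted(groups)}")
    (ga, xs), (gb, ys) = sorted(groups.items())
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("need >=2 cells per group")
    if test == "t_test":
        res = student_t_two_sided(xs, ys)
    elif test == "wilcoxon":
        res = wilcoxon_rank_sum(xs, ys)
    else:
        raise ValueError(f"unknown test {test!r}")
    res.summary["groups"] = [ga, gb]
    return res


def assign_subgroups(
    matrix: ExpressionMatrix,
    marker_sets: GeneSetCollection,
    params: SignatureScoreParams | None = None,
    margin: float = 0.25,
    transitional_label: str = ENDOMT_LABEL,
) -> SubgroupAssignment:
    """Label each cell by its dominant marker signature.

    With three marker sets, the label is the set name with the maximal
    z-scaled score (ties broken by the order the sets were supplied in).
    With two sets (endothelial-like and mesenchymal-like markers, no
    explicit transitional set), cells whose two z-scores lie within
    ``margin`` of each other get ``transitional_label`` — a documented
    heuristic for partial-transition states.
    """
    n_sets = len(marker_sets)
    if n_sets not in (2, 3):
        raise ValueError("subgroup assignment needs 2 or 3 marker sets")
    raw = score_cells(matrix, marker_sets, params)
    z = zscale_scores(raw).scores
    names = list(z.columns)
    labels: dict[str, str] = {}
    if n_sets == 3:
        arr = z.to_numpy()
        winners = np.argmax(arr, axis=1)  # argmax takes the first on ties
        for cell, w in zip(z.index, winners):
            labels[str(cell)] = names[w]
    else:
        a, b = names
        for cell in z.index:
            za, zb = float(z.at[cell, a]), float(z.at[cell, b])
            if abs(za - zb) <= margin:
                labels[str(cell)] = transitional_label
            else:
                labels[str(cell)] = a if za > zb else b
    return SubgroupAssignment(labels=labels, zscores=z)
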