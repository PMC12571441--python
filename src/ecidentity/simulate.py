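"""Synthetic data with planted ground truth for every pipeline stage.

Three generators emulate the data regimes the pipeline is built for:

* ``simulate_mark_reads`` — Poisson background sequencing fragments over a
  chromosome, with broad enriched domains planted over the bodies of
  designated identity genes and narrow peaks over a disjoint subset of
  other genes, plus a matched background-only input control.
* ``simulate_regpot_scenario`` — a binding-peak set whose distance-to-TSS
  distribution differs between a target gene set (peaks within 20 kb of the
  TSS) and background genes (peaks beyond 50 kb, or none).
* ``simulate_expression`` — a negative-binomial genes x cells matrix with
  three cell subgroups (EC-like, EndoMT, mesenchymal-like), planted marker
  gene sets shifted by a stated effect size (EndoMT intermediate at half
  shift), a focal gene whose mean decreases stepwise across subgroups, and
  dropout zeros.

Every generator is a pure function of (config, seed): the random state is
derived from the config seed plus a stable per-stream offset, never from
global RNG state.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, GeneModel, GeneSetCollection, GenomicInterval, Peak

SUBGROUPS = ("EC-like", "EndoMT", "mesenchymal-like")


@dataclass
class SimulationConfig:
    seed: int = 0
    # genome / gene models
    n_genes: int = 1000
    n_chroms: int = 1
    chrom_length: int = 32_000_000
    gene_length_range: tuple[int, int] = (1000, 5000)
    min_gene_spacing: int = 25_000
    # chromatin marks
    n_identity_genes: int = 20
    broad_domain_span: tuple[int, int] = (5_000, 20_000)
    narrow_peak_span: tuple[int, int] = (500, 2_000)
    narrow_gene_fraction: float = 0.3
    enrichment_fold: float = 15.0
    background_rate: float = 2.0  # fragments per bin
    bin_size: int = 10
    fragment_length: int = 200
    read_length: int = 36
    # regulatory-potential scenario
    n_target_genes: int = 200
    target_tss_max_distance: int = 20_000
    background_min_distance: int = 50_000
    background_peak_fraction: float = 0.3
    # expression matrix
    n_cells: int = 600
    subgroup_proportions: tuple[float, float, float] = (0.4, 0.3, 0.3)
    signature_effect_size: float = 1.0
    signature_set_size: int = 50
    nb_dispersion: float = 0.3
    dropout_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.n_genes < 0 or self.n_cells <= 0 or self.chrom_length <= 0:
            raise ValueError("counts and lengths must be positive")
        if abs(sum(self.subgroup_proportions) - 1.0) > 1e-9:
            raise ValueError("subgroup_proportions must sum to 1")
        if any(p < 0 for p in self.subgroup_proportions):
            raise ValueError("subgroup_proportions must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1")


@dataclass
class GroundTruth:
    """Planted truth shared across generators; filled in stage by stage."""

    identity_genes: list[str] = field(default_factory=list)
    domains: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    narrow_genes: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)
    target_genes: list[str] = field(default_factory=list)
    cell_subgroups: dict[str, str] = field(default_factory=dict)
    condition_labels: dict[str, str] = field(default_factory=dict)
    marker_set_names: list[str] = field(default_factory=list)
    focal_gene: Optional[str] = None
    focal_subgroup_means: dict[str, float] = field(default_factory=dict)
    effect_size: float = 0.0

    def to_jsonable(self) -> dict:
        return {
            "identity_genes": self.identity_genes,
            "domains": {m: {g: list(v) for g, v in d.items()}
                        for m, d in self.domains.items()},
            "narrow_genes": {m: {g: list(v) for g, v in d.items()}
                             for m, d in self.narrow_genes.items()},
            "target_genes": self.target_genes,
            "cell_subgroups": self.cell_subgroups,
            "condition_labels": self.condition_labels,
            "marker_set_names": self.marker_set_names,
            "focal_gene": self.focal_gene,
            "focal_subgroup_means": self.focal_subgroup_means,
            "effect_size": self.effect_size,
        }


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Deterministic per-stream generator: seed + stable name hash."""
    return np.random.default_rng([config.seed, zlib.crc32(stream.encode())])


def chrom_names(config: SimulationConfig) -> list[str]:
    return [f"chr{i + 1}" for i in range(config.n_chroms)]


def chrom_lengths(config: SimulationConfig) -> dict[str, int]:
    return {c: config.chrom_length for c in chrom_names(config)}


# ---------------------------------------------------------------------------
# gene models


def simulate_gene_models(config: SimulationConfig) -> tuple[list[GeneModel], GroundTruth]:
    """Non-overlapping genes with >= ``min_gene_spacing`` bp between bodies.

    Genes are placed one per slot of chrom_length / n_per_chrom bp with a
    random jitter, so flanked windows (+/-10 kb) of neighbouring genes are
    pairwise disjoint by construction. Errors when the genes cannot fit.
    Also designates the planted identity genes.
    """
    rng = _rng(config, "genes")
    truth = GroundTruth()
    genes: list[GeneModel] = []
    if config.n_genes == 0:
        return genes, truth
    names = chrom_names(config)
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    lo_len, hi_len = config.gene_length_range
    gid = 0
    for chrom, n_here in zip(names, per_chrom):
        if n_here == 0:
            continue
        slot = config.chrom_length // n_here
        if slot < hi_len + config.min_gene_spacing:
            raise ValueError(
                f"cannot fit {n_here} genes of <= {hi_len} bp with "
                f"{config.min_gene_spacing} bp spacing into {config.chrom_length} bp"
            )
        lengths = rng.integers(lo_len, hi_len + 1, size=n_here)
        jitter_room = slot - lengths - config.min_gene_spacing
        offsets = rng.integers(0, jitter_room + 1)
        strands = rng.integers(0, 2, size=n_here)
        for j in range(n_here):
            gid += 1
            start = int(j * slot + offsets[j])
            genes.append(
                GeneModel(
                    gene_id=f"gene{gid:05d}",
                    chrom=chrom,
                    start=start,
                    end=start + int(lengths[j]),
                    strand="+" if strands[j] == 0 else "-",
                )
            )
    n_id = min(config.n_identity_genes, len(genes))
    idx = rng.choice(len(genes), size=n_id, replace=False)
    truth.identity_genes = sorted(genes[i].gene_id for i in idx)
    return genes, truth


# ---------------------------------------------------------------------------
# chromatin-mark reads


def _fragments_to_reads(starts: np.ndarray, frag_len: int, read_len: int,
                        rng: np.random.Generator, chrom: str,
                        chrom_len: int) -> pd.DataFrame:
    """Emit stranded reads whose 5'->3' extension by frag_len reproduces the
    fragment [s, s + frag_len)."""
    minus = rng.integers(0, 2, size=starts.size).astype(np.int8)
    read_start = np.where(minus == 1, starts + frag_len - read_len, starts)
    read_end = read_start + read_len
    return pd.DataFrame(
        {
            "chrom": pd.Categorical.from_codes(
                np.zeros(starts.size, dtype=np.int8), categories=[chrom]
            ),
            "start": read_start.astype(np.int64),
            "end": np.minimum(read_end, chrom_len).astype(np.int64),
            "strand": pd.Categorical.from_codes(minus, categories=["+", "-"]),
        }
    )


def simulate_mark_reads(
    genes: list[GeneModel],
    truth: GroundTruth,
    config: SimulationConfig,
    mark: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment and matched input-control reads for one chromatin mark.

    Background fragment starts are Poisson(background_rate per bin) uniform
    over each chromosome. Identity genes carry a broad planted domain
    (span from ``broad_domain_span``, always covering the gene body plus a
    random share of the flanks) at ``enrichment_fold`` x background; a
    random disjoint subset of the other genes carries a narrow TSS-centred
    peak at the same fold. The control sees background only. Returned as
    interval frames of stranded reads.
    """
    rng = _rng(config, f"mark:{mark}")
    frag, read_len = config.fragment_length, config.read_length
    lengths = chrom_lengths(config)
    frames: list[pd.DataFrame] = []
    truth.domains.setdefault(mark, {})
    truth.narrow_genes.setdefault(mark, {})

    identity = set(truth.identity_genes)
    others = [g for g in genes if g.gene_id not in identity]
    n_narrow = int(round(config.narrow_gene_fraction * len(others)))
    narrow_idx = (
        rng.choice(len(others), size=n_narrow, replace=False)
        if n_narrow else np.array([], dtype=int)
    )
    narrow_set = {others[i].gene_id for i in narrow_idx}

    per_bin = config.background_rate
    for chrom, L in lengths.items():
        n_bins = -(-L // config.bin_size)
        n_bg = int(rng.poisson(per_bin * n_bins))
        starts = rng.integers(0, L - frag, size=n_bg)
        frames.append(_fragments_to_reads(starts, frag, read_len, rng, chrom, L))

    extra_rate = (config.enrichment_fold - 1.0) * per_bin / config.bin_size

    def plant(domain_start: int, domain_end: int, chrom: str) -> None:
        span = domain_end - domain_start
        if span <= frag:
            domain_end = domain_start + frag + 1
            span = domain_end - domain_start
        n_extra = int(rng.poisson(extra_rate * span))
        if n_extra == 0:
            return
        s = rng.integers(domain_start, domain_end - frag, size=n_extra)
        frames.append(
            _fragments_to_reads(s, frag, read_len, rng, chrom, lengths[chrom])
        )

    lo_b, hi_b = config.broad_domain_span
    lo_n, hi_n = config.narrow_peak_span
    for gene in genes:
        L = lengths[gene.chrom]
        if gene.gene_id in identity:
            span = int(rng.integers(lo_b, hi_b + 1))
            span = max(span, gene.length + 2 * frag)
            left = int(rng.integers(0, span - gene.length + 1))
            dom_start = max(0, gene.start - left)
            dom_end = min(L, dom_start + span)
            truth.domains[mark][gene.gene_id] = (dom_start, dom_end)
            if config.enrichment_fold > 1:
                plant(dom_start, dom_end, gene.chrom)
        elif gene.gene_id in narrow_set:
            span = int(rng.integers(lo_n, hi_n + 1))
            pk_start = max(0, gene.tss - span // 2)
            pk_end = min(L, pk_start + span)
            truth.narrow_genes[mark][gene.gene_id] = (pk_start, pk_end)
            if config.enrichment_fold > 1:
                plant(pk_start, pk_end, gene.chrom)

    treatment = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "strand"]
    )

    ctrl_frames = []
    for chrom, L in lengths.items():
        n_bins = -(-L // config.bin_size)
        n_bg = int(rng.poisson(per_bin * n_bins))
        starts = rng.integers(0, L - frag, size=n_bg)
        ctrl_frames.append(_fragments_to_reads(starts, frag, read_len, rng, chrom, L))
    control = pd.concat(ctrl_frames, ignore_index=True)
    return treatment, control


# ---------------------------------------------------------------------------
# regulatory-potential scenario


def simulate_regpot_scenario(
    genes: list[GeneModel],
    config: SimulationConfig,
    null: bool = False,
) -> tuple[list[Peak], list[str], list[str], GroundTruth]:
    """Peaks planted near target-gene TSSs; background peaks far or absent.

    Every target gene receives 1-3 peaks with |distance to TSS| uniform on
    [0, target_tss_max_distance]; a fraction of background genes receives a
    single peak beyond ``background_min_distance``. With ``null=True`` the
    same number of peaks is placed uniformly at random (the near-TSS rule
    disabled), so target and random sets are exchangeable.
    """
    rng = _rng(config, "regpot")
    n_target = config.n_target_genes
    if n_target == 0:
        raise ValueError("empty target set requested")
    if 2 * n_target > len(genes):
        raise ValueError(
            f"need >= {2 * n_target} genes for a target set of {n_target}"
        )
    lengths = chrom_lengths(config)
    target_idx = rng.choice(len(genes), size=n_target, replace=False)
    target_ids = sorted(genes[i].gene_id for i in target_idx)
    target_set = set(target_ids)

    centers: list[tuple[str, int]] = []
    for gene in genes:
        L = lengths[gene.chrom]
        if gene.gene_id in target_set:
            for _ in range(int(rng.integers(1, 4))):
                d = int(rng.integers(0, config.target_tss_max_distance + 1))
                sign = -1 if rng.integers(0, 2) else 1
                centers.append((gene.chrom, min(max(gene.tss + sign * d, 0), L - 1)))
        elif rng.random() < config.background_peak_fraction:
            d = int(rng.integers(config.background_min_distance,
                                 2 * config.background_min_distance + 1))
            sign = -1 if rng.integers(0, 2) else 1
            centers.append((gene.chrom, min(max(gene.tss + sign * d, 0), L - 1)))

    if null:
        chroms = chrom_names(config)
        centers = [
            (chroms[int(rng.integers(0, len(chroms)))],
             int(rng.integers(0, config.chrom_length)))
            for _ in centers
        ]

    peaks: list[Peak] = []
    for chrom, center in centers:
        width = int(rng.integers(200, 1001))
        start = max(0, center - width // 2)
        end = min(lengths[chrom], start + width)
        peaks.append(Peak(GenomicInterval(chrom, start, end), score=1.0))

    truth = GroundTruth(target_genes=target_ids)
    universe = [g.gene_id for g in genes]
    return peaks, target_ids, universe, truth


# ---------------------------------------------------------------------------
# expression matrix


def simulate_expression(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, GeneSetCollection, GroundTruth]:
    """Three-subgroup negative-binomial expression matrix with planted
    signatures.

    Per-gene baseline means are log-normal; counts are negative binomial
    (dispersion ``nb_dispersion``) around the cell's subgroup mean. Marker
    genes are shifted on the log scale by ``signature_effect_size`` standard
    deviations of that gene's expression noise: EC markers up in EC-like
    cells, mesenchymal markers up in mesenchymal-like cells (EndoMT cells
    get half of each shift), and EndoMT markers up only in EndoMT cells.
    One focal gene decreases strictly EC-like -> EndoMT -> mesenchymal-like.
    Dropout zeros are injected at ``dropout_rate``; values are per-cell
    depth-normalized.
    """
    rng = _rng(config, "expression")
    n_genes, n_cells = config.n_genes, config.n_cells
    need = 3 * config.signature_set_size + 1
    if n_genes < need:
        raise ValueError(f"need >= {need} genes for the planted signatures")
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    cell_ids = [f"cell{i + 1:05d}" for i in range(n_cells)]

    counts_per_group = np.floor(
        np.asarray(config.subgroup_proportions) * n_cells
    ).astype(int)
    counts_per_group[0] += n_cells - counts_per_group.sum()
    subgroup_of = np.repeat(np.arange(3), counts_per_group)

    mu = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    # per-gene log-scale noise SD via the NB coefficient of variation
    sigma_log = np.sqrt(np.log1p(1.0 / mu + config.nb_dispersion))

    perm = rng.permutation(n_genes)
    m = config.signature_set_size
    set_idx = {
        SUBGROUPS[0]: perm[:m],
        SUBGROUPS[2]: perm[m:2 * m],
        SUBGROUPS[1]: perm[2 * m:3 * m],
    }
    focal_idx = int(perm[3 * m])
    e = config.signature_effect_size

    # log-fold weight per gene per subgroup
    w = np.zeros((n_genes, 3))
    w[set_idx[SUBGROUPS[0]], 0] = 1.0   # EC markers up in EC-like
    w[set_idx[SUBGROUPS[0]], 1] = 0.5
    w[set_idx[SUBGROUPS[2]], 2] = 1.0   # mesenchymal markers up in mes-like
    w[set_idx[SUBGROUPS[2]], 1] = 0.5
    w[set_idx[SUBGROUPS[1]], 1] = 1.0   # EndoMT markers up in EndoMT only
    w[focal_idx, :] = [1.0, 0.0, -1.0]  # stepwise decreasing focal gene

    log_shift = e * sigma_log[:, None] * w  # genes x 3
    group_means = mu[:, None] * np.exp(log_shift)

    means = group_means[:, subgroup_of]  # genes x cells
    r = 1.0 / config.nb_dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p).astype(float)
    if config.dropout_rate > 0:
        keep = rng.random(size=counts.shape) >= config.dropout_rate
        counts *= keep

    totals = counts.sum(axis=0)
    target_total = float(np.median(totals[totals > 0])) if np.any(totals > 0) else 1.0
    scale = np.where(totals > 0, target_total / np.maximum(totals, 1e-12), 0.0)
    values = counts * scale

    df = pd.DataFrame(values, index=gene_ids, columns=cell_ids)
    labels = {c: SUBGROUPS[s] for c, s in zip(cell_ids, subgroup_of)}
    matrix = ExpressionMatrix(df, cell_labels=labels)

    sets = GeneSetCollection(
        {name: [gene_ids[i] for i in np.sort(idx)] for name, idx in set_idx.items()}
    )
    truth = GroundTruth(
        cell_subgroups=labels,
        condition_labels={
            c: ("control" if labels[c] == SUBGROUPS[0] else "tgfb") for c in cell_ids
        },
        marker_set_names=list(SUBGROUPS),
        focal_gene=gene_ids[focal_idx],
        focal_subgroup_means={
            SUBGROUPS[s]: float(group_means[focal_idx, s]) for s in range(3)
        },
        effect_size=e,
    )
    return matrix, sets, truth
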