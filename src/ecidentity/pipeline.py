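"""Orchestration of the three analyses, plus the simulation bundle.

Each runner is a plain function over in-memory objects; the CLI wraps them
with file I/O and writes a run manifest (resolved parameters, input
checksums, seed, warning counts) next to the outputs. Two runs with equal
manifests produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io as eio
from .coverage import (
    CoverageTrack,
    PeakCallParams,
    build_coverage,
    call_peaks,
    extend_reads,
    normalize_depth,
    subtract_control,
)
from .identity import BreadthTable, IdentityRanking, aggregate_ranks, breadth_per_gene
from .models import ExpressionMatrix, GeneModel, GeneSetCollection, Peak
from .regpot import (
    RegPotParams,
    RegPotTable,
    compare_regpot,
    cumulative_fraction_curve,
    regulatory_potential,
    sample_random_gene_set,
)
from .signatures import (
    SignatureScoreParams,
    assign_subgroups,
    compare_score_groups,
    score_cells,
    zscale_scores,
)
from .simulate import (
    SimulationConfig,
    chrom_lengths,
    simulate_expression,
    simulate_gene_models,
    simulate_mark_reads,
    simulate_regpot_scenario,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# manifests


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, command: str, params: Mapping,
                   inputs: Mapping[str, str], seed: Optional[int] = None,
                   warnings: Optional[Mapping[str, int]] = None) -> Path:
    manifest = {
        "command": command,
        "parameters": params,
        # basenames, not absolute paths, so identical runs in different
        # directories produce identical manifests (and hence outputs)
        "inputs": {
            name: {"file": Path(p).name, "sha256": file_checksum(p)}
            for name, p in inputs.items()
        },
        "seed": seed,
        "warnings": dict(warnings or {}),
    }
    path = Path(out_dir) / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


# ---------------------------------------------------------------------------
# peak calling from reads


def peaks_from_reads(
    treatment_reads,
    control_reads,
    chrom_lens: Mapping[str, int],
    params: PeakCallParams,
) -> tuple[list[Peak], CoverageTrack]:
    """Extend reads, build binned coverage, subtract the depth-matched
    control, call peaks.

    The control is scaled to the treatment's fragment count before
    subtraction, and peaks are called on native-depth counts: the Poisson
    background test is calibrated only when bin values are on the scale of
    real fragment counts (scaling a track up by s inflates the variance s-
    fold relative to Poisson). ``params.normalization_target`` applies when
    tracks are exported for cross-sample comparison, not here.
    """
    treatment = extend_reads(treatment_reads, params.extension, chrom_lens)
    track = build_coverage(treatment, chrom_lens, params.bin_size)
    if control_reads is not None:
        control = extend_reads(control_reads, params.extension, chrom_lens)
        ctrack = build_coverage(control, chrom_lens, params.bin_size)
        ctrack = normalize_depth(ctrack, track.total_mass)
        track = subtract_control(track, ctrack)
    return call_peaks(track, params), track


# ---------------------------------------------------------------------------
# analysis runners (in-memory)


def identity_ranking_from_peaks(
    peaks_by_mark: Mapping[str, Sequence[Peak]],
    genes: Sequence[GeneModel],
    flank: int = 10_000,
    chrom_lens: Optional[Mapping[str, int]] = None,
    whitelist: Optional[Sequence[str]] = None,
    breadth_mode: str = "union",
) -> IdentityRanking:
    tables = [
        breadth_per_gene(list(peaks), genes, flank=flank, mark_name=mark,
                         chrom_lengths=chrom_lens, mode=breadth_mode)
        for mark, peaks in peaks_by_mark.items()
    ]
    return aggregate_ranks(tables, whitelist=whitelist)


def identity_ranking_from_reads(
    reads_by_mark: Mapping[str, tuple],
    genes: Sequence[GeneModel],
    chrom_lens: Mapping[str, int],
    peak_params: Optional[PeakCallParams] = None,
    flank: int = 10_000,
    whitelist: Optional[Sequence[str]] = None,
) -> tuple[IdentityRanking, dict[str, list[Peak]]]:
    """Call peaks per mark from (treatment, control) read pairs, then rank."""
    peak_params = peak_params or PeakCallParams()
    peaks_by_mark: dict[str, list[Peak]] = {}
    for mark, (treat, ctrl) in reads_by_mark.items():
        peaks, _ = peaks_from_reads(treat, ctrl, chrom_lens, peak_params)
        peaks_by_mark[mark] = peaks
    ranking = identity_ranking_from_peaks(
        peaks_by_mark, genes, flank=flank, chrom_lens=chrom_lens,
        whitelist=whitelist,
    )
    return ranking, peaks_by_mark


def regpot_analysis(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    gene_sets: Mapping[str, Sequence[str]],
    params: Optional[RegPotParams] = None,
    random_seed: int = 0,
    random_size: Optional[int] = None,
) -> dict:
    """Score all genes, build cumulative-fraction curves for each set plus a
    seeded random set, and compare each set against the random set.

    The random set is matched in size to the first analysed set unless
    ``random_size`` is given.
    """
    table = regulatory_potential(list(peaks), list(genes), params)
    universe = [g.gene_id for g in genes]
    sizes = [len(v) for v in gene_sets.values()]
    if not sizes or min(sizes) == 0:
        raise ValueError("need at least one non-empty gene set")
    n_random = random_size or sizes[0]
    random_set = sample_random_gene_set(universe, n_random, random_seed)
    curves = {"random": cumulative_fraction_curve(table, random_set)}
    comparisons = {}
    for name, members in gene_sets.items():
        curves[name] = cumulative_fraction_curve(table, list(members))
        comparisons[name] = compare_regpot(table, list(members), random_set)
    return {
        "table": table,
        "curves": curves,
        "comparisons": comparisons,
        "random_set": random_set,
    }


def signature_analysis(
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    labels: Mapping[str, str],
    params: Optional[SignatureScoreParams] = None,
    test: str = "t_test",
    zscale: bool = False,
    marker_sets: Optional[GeneSetCollection] = None,
) -> dict:
    """Per-cell signature scores, two-group tests per set, and (optionally)
    subgroup assignment from marker sets."""
    missing = [c for c in labels if c not in set(matrix.cell_ids)]
    if missing:
        raise ValueError(
            f"labeled cells absent from the matrix, e.g. {missing[:5]}"
        )
    scores = score_cells(matrix, sets, params)
    reported = zscale_scores(scores) if zscale else scores
    n_groups = len(set(labels.values()))
    if n_groups == 2:
        tests = {
            name: compare_score_groups(reported, labels, name, test=test)
            for name in sets.names
        }
    else:
        logger.warning(
            "skipping group tests: %d label groups present, need exactly 2",
            n_groups,
        )
        tests = {}
    out = {"scores": reported, "tests": tests}
    if marker_sets is not None:
        out["assignment"] = assign_subgroups(matrix, marker_sets, params)
    return out


# ---------------------------------------------------------------------------
# file-level runners used by the CLI


def run_simulate(config: SimulationConfig, out_dir,
                 marks: Sequence[str] = ("H3K4me3", "H3K27ac")) -> dict:
    """Write the full synthetic bundle: gene models, per-mark reads and
    controls, regulatory-potential peaks + gene lists, expression matrix,
    labels, signature GMT, and ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes, truth = simulate_gene_models(config)
    paths: dict[str, Path] = {}

    genes_bed = out / "genes.bed"
    with open(genes_bed, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["genes"] = genes_bed

    for mark in marks:
        treat, ctrl = simulate_mark_reads(genes, truth, config, mark)
        tp, cp = out / f"{mark}_treat.bed", out / f"{mark}_control.bed"
        eio.write_interval_frame(treat, tp)
        eio.write_interval_frame(ctrl, cp)
        paths[f"{mark}_treat"], paths[f"{mark}_control"] = tp, cp

    if 2 * config.n_target_genes <= len(genes):
        peaks, targets, universe, rp_truth = simulate_regpot_scenario(genes, config)
        truth.target_genes = rp_truth.target_genes
        pk_path = out / "tf_peaks.bed"
        eio.write_peaks_bed(peaks, pk_path)
        eio.write_gene_list(targets, out / "target_genes.txt")
        paths["tf_peaks"] = pk_path
        paths["target_genes"] = out / "target_genes.txt"

    matrix, sig_sets, expr_truth = simulate_expression(config)
    truth.cell_subgroups = expr_truth.cell_subgroups
    truth.condition_labels = expr_truth.condition_labels
    truth.marker_set_names = expr_truth.marker_set_names
    truth.focal_gene = expr_truth.focal_gene
    truth.focal_subgroup_means = expr_truth.focal_subgroup_means
    truth.effect_size = expr_truth.effect_size
    eio.write_expression_matrix(matrix, out / "expression.tsv")
    eio.write_cell_labels(matrix.cell_labels, out / "cell_labels.tsv")
    eio.write_cell_labels(truth.condition_labels, out / "condition_labels.tsv")
    eio.write_gmt(sig_sets, out / "signatures.gmt")
    paths["expression"] = out / "expression.tsv"
    paths["cell_labels"] = out / "cell_labels.tsv"
    paths["condition_labels"] = out / "condition_labels.tsv"
    paths["signatures"] = out / "signatures.gmt"

    with open(out / "ground_truth.json", "w") as fh:
        json.dump(truth.to_jsonable(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    write_manifest(out, "simulate", asdict(config), paths, seed=config.seed)
    return {"genes": genes, "truth": truth, "paths": paths}


def write_ranking_tsv(ranking: IdentityRanking, path) -> None:
    ranking.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_comparison_json(comparisons: Mapping, path) -> None:
    payload = {
        name: {
            "statistic": c.statistic,
            "p_value": c.p_value,
            "method": c.method,
            "n_x": c.n_x,
            "n_y": c.n_y,
            "direction": c.direction,
            "summary": c.summary,
        }
        for name, c in comparisons.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_curves_tsv(curves: Mapping[str, list], path) -> None:
    rows = []
    for name, pts in curves.items():
        for score, frac in pts:
            rows.append((name, score, frac))
    pd.DataFrame(rows, columns=["set", "score", "fraction"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
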