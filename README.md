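# ecidentity

Tools for finding candidate **cell-identity genes** from chromatin
landscapes and for quantifying **endothelial-to-mesenchymal transition
(EndoMT)** state in single-cell expression data.

Cell-identity genes — the genes that define and maintain a cell type — are
empirically marked by unusually *broad* domains of the active-chromatin
marks H3K4me3 and H3K27ac, in contrast to the narrow peaks found at most
other expressed genes. This package implements the discovery pipeline built
on that observation, together with the downstream analyses used to
characterise a candidate regulator:

1. **Poisson-background peak calling** (`ecidentity.coverage`) — reads are
   extended to fragment length (200 bp) from their 5′ end, binned at 10 bp,
   depth-matched input control subtracted, and a bin is called enriched when
   its count `k` is improbable under the genome-wide background rate λ:
   `P(X ≥ k) < 10⁻³⁰` for `X ~ Poisson(λ)`. Runs of significant bins become
   peaks.
2. **Identity ranking** (`ecidentity.identity`) — per gene, the *breadth*
   of a mark is the unioned base pairs of peak territory within the gene
   body ± 10 kb. Genes are ranked per mark (widest = rank 1, mid-ranks on
   ties) and ordered by the sum of the per-mark ranks.
3. **Regulatory potential** (`ecidentity.regpot`) — a transcription-factor
   peak at distance `d` from a gene's TSS contributes weight
   `2^(−d / 10 kb)` (zero beyond 100 kb); a gene's score is the sum over
   peaks. Gene sets (e.g. knockdown up-/down-regulated genes) are compared
   against size-matched random gene sets with a two-sided Wilcoxon rank-sum
   test and visualised as cumulative-fraction curves.
4. **Single-cell signature scores** (`ecidentity.signatures`) — a
   rank-based (UCell-style) per-cell score: with set size `n`, rank cap
   `c = 1500`, and capped rank sum `R`,
   `U = R − n(n+1)/2` and `score = 1 − U / (n·c)`, bounded in
   `[(n−1)/2c, 1]` and invariant to any monotone per-cell transform of
   expression. Cells are classified into EC-like / EndoMT /
   mesenchymal-like states from z-scaled marker-set scores.
5. **Synthetic data** (`ecidentity.simulate`) — seeded generators with
   planted ground truth for every input the pipeline consumes (fragment
   BEDs with planted broad domains, TSS-biased peak sets, three-subgroup
   negative-binomial expression matrices), so the entire pipeline is
   testable without sequencing data.

Statistical conventions: two-sided Wilcoxon rank-sum (exact by enumeration
for small tie-free samples, otherwise tie-corrected normal approximation
with continuity correction) and the two-tailed unpaired Student's *t*-test
(pooled variance; Welch variant available).

## Worked example

Simulate a small dataset with 5 planted identity genes among 200, then rank
genes by mark breadth:

```sh
$ cat cfg.yaml
simulation:
  n_genes: 200
  chrom_length: 7000000
  n_cells: 90
  n_identity_genes: 5
  signature_set_size: 20
  n_target_genes: 40

$ ecidentity simulate --config cfg.yaml --seed 11 --out demo
$ printf 'chr1\t7000000\n' > chrom.sizes
$ ecidentity rank-identity --genes demo/genes.bed \
    --mark H3K4me3=demo/H3K4me3_treat.bed,demo/H3K4me3_control.bed \
    --mark H3K27ac=demo/H3K27ac_treat.bed,demo/H3K27ac_control.bed \
    --chrom-sizes chrom.sizes --out rank
$ head -6 rank/identity_ranking.tsv
gene_id	breadth_H3K4me3	rank_H3K4me3	breadth_H3K27ac	rank_H3K27ac	rank_sum	rank_mean	final_position
gene00193	17170	1	9490	3	4	2	1
gene00168	15658	2	10540	2	4	2	2
gene00011	10580	4	12500	1	5	2.5	3
gene00084	14030	3	4990	5	8	4	4
gene00149	5230	5	8440	4	9	4.5	5
```

The five top-ranked genes are exactly the five planted identity genes
(`demo/ground_truth.json`): each carries a broad domain on both marks, so
its per-mark breadths (column 2 and 4, in bp within gene body ± 10 kb) and
hence its rank sum dominate the 195 background genes.

Regulatory potential of a planted target set vs 40 random genes:

```sh
$ ecidentity regpot --peaks demo/tf_peaks.bed --genes demo/genes.bed \
    --gene-set target=demo/target_genes.txt --seed 3 --out rp
```

`rp/comparisons.json` reports the target set stochastically larger
(median score 1.39 vs 0.34) with Wilcoxon `p = 9.7e-09`.

Per-cell signature scores between the two simulated conditions:

```sh
$ ecidentity signature --matrix demo/expression.tsv \
    --gmt demo/signatures.gmt --labels demo/condition_labels.tsv \
    --assign --out sig
```

`sig/tests.json` shows the EC-like signature higher in control cells
(*t*-test `p = 4.4e-15`) and the mesenchymal signature higher in treated
cells (`p = 1.9e-09`); `sig/assignments.tsv` holds the per-cell
EC-like / EndoMT / mesenchymal-like calls.

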