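# Methods

This note documents the models, parameter choices and numerical decisions
behind `ecidentity`, and what the synthetic-data tests do and do not show
about real data.

## Coverage tracks and Poisson peak calling

**Model.** Sequencing reads (ChIP-seq or CUT&RUN fragments with a matched
input control) are reduced to a binned density: each stranded read is
replaced by the interval of length `extension` starting at its 5′ end and
running 3′-ward (default 200 bp, the expected fragment length), and each
bin of width `bin_size` (default 10 bp) counts the fragments overlapping it
by at least one base. No smoothing is applied. Background is modelled as a
single genome-wide Poisson rate λ, estimated as the mean bin value over all
bins; a bin with (rounded) count `k` is enriched when
`P(X ≥ k | X ~ Poisson(λ)) < p_cutoff` (default 10⁻³⁰). Maximal runs of
enriched bins (optionally bridging `merge_gap` non-enriched bins, default
0) become peaks; the peak score is −log₁₀ of the smallest bin P inside the
peak and the summit is the centre of the bin attaining it (leftmost on
ties).

**Global vs local background.** A single global λ is used rather than
locally estimated backgrounds. This is a deliberate simplification of
dense-peak callers: it is exactly reproducible, and for the very stringent
cutoff used here (10⁻³⁰) local fluctuations of the background are far below
the significance boundary. Data with strong large-scale coverage biases
(copy-number variation, accessibility waves) would need a local background
and are outside this model.

**Control subtraction and depth normalization.** `normalize_depth` scales a
track to a target library size (default 25 × 10⁶ fragments) and
`subtract_control` takes the bin-wise `max(0, treatment − control)`. The
Poisson significance test, however, is calibrated only when bin values are
on the scale of actually observed counts: multiplying a track by a factor
`s` turns a Poisson(λ) variate into one with variance `s·λ` *after* the
model rescales, i.e. the scaled track is over-dispersed by `s` and the
10⁻³⁰ cutoff produces false positives for `s ≫ 1`. The pipeline therefore
scales the **control to the treatment's native depth** before subtraction
and calls peaks on native-scale counts; the 25 × 10⁶ target is applied when
exporting tracks for cross-sample display. Counts are rounded to the
nearest integer before the Poisson test (normalized subtraction produces
non-integers; rounding is the least surprising mapping onto the integer
support).

**Numerics.** The upper tail `P(X ≥ k)` is computed through the regularized
incomplete gamma function (`gammainc(k, λ)`), which holds ~13 significant
digits down to P ≈ 10⁻³⁰⁰ (verified against direct series summation). Peak
scores in deeper tails use a log-space series expansion of the tail around
the leading probability-mass term, so scores stay finite where the linear-
space tail underflows.

## Identity ranking by mark breadth

For each gene the *breadth* of a mark is the total base pairs of the union
of called-peak intervals intersected with the window gene body ± `flank`
(default 10 kb, clipped at chromosome boundaries). Union-before-measure
makes the statistic robust to peak fragmentation by the caller; an
alternative `max_single` mode reports the single largest peak overlap
instead. Genes are ranked per mark with the widest breadth at rank 1 and
mid-ranks on ties (so the rank sum over genes is always n(n+1)/2), and the
final ordering is ascending in the sum of per-mark ranks. For a fixed
number of marks the sum and the mean of ranks order identically; both are
reported. Ties on the rank sum break by greater total breadth, then
lexicographic gene id, making the output a deterministic permutation.
Genes absent from one mark's table enter with breadth 0 rather than being
dropped, so the ranked universe is stable; a user-supplied whitelist (e.g.
transcription factors only) restricts the universe before ranking.

All coordinates are 0-based half-open throughout; GTF input is converted on
read, and the span of a GTF gene is the union of its gene/exon records
sharing a `gene_id`. Chromosome names are never normalized — inputs whose
chromosome namespaces are disjoint raise an error listing both sides,
because a silent zero-overlap analysis is worse than a failure.

## Regulatory potential

A binding peak at distance `d = |anchor − TSS|` contributes
`2^(−d / half_distance)` to a gene's score (default half-distance 10 kb),
and peaks beyond `max_distance` (default 100 kb) contribute nothing; the
gene score is the sum over peaks. The anchor is the peak centre by default
(summits exist only for called peaks). This transparent exponential-decay
score stands in for the family of published regulatory-potential scores;
the downstream comparison — empirical CDFs of a gene set's scores against a
size-matched random set, with a two-sided Wilcoxon rank-sum P — only
requires that the score decay monotonically with TSS distance. The decay
constant and window are configurable; conclusions should be checked for
robustness to them. One TSS per gene model is assumed (multi-TSS genes are
out of scope).

Differential-expression tables are consumed, not estimated: the default
gates are FDR < 0.05, |log₂FC| > 1 and mean expression > 1, with strict
inequalities, producing disjoint up/down lists.

## Two-sample tests

The Wilcoxon rank-sum test enumerates the full rank-sum null distribution
(a dynamic program over subset rank sums) when `n + m ≤ 16` and the pooled
sample is tie-free, reporting `p = min(1, 2·min(P(W ≤ w), P(W ≥ w)))`;
otherwise it uses the normal approximation with tie-corrected variance and
a 0.5 continuity correction. When every pooled value is identical the test
reports p = 1 (no evidence of a shift) rather than failing. The Student's
*t*-test uses the classical pooled-variance form with `df = n + m − 2`; a
Welch variant (Satterthwaite df) is available behind a flag. Sample
standard deviations (ddof = 1) are used everywhere a z-score or t statistic
needs one.

## Signature scoring and state assignment

Within each cell all genes are ranked by descending expression with
mid-ranks on ties; ranks above `rank_cap` (default 1500, the published
default of the rank-based scoring method this follows) are truncated to
`rank_cap + 1`. For a set of `n` genes with capped rank sum `R`, the score
is `1 − (R − n(n+1)/2) / (n·rank_cap)`: exactly 1 when the set occupies the
cell's top `n` ranks, and `(n−1)/(2·rank_cap)` at the capped floor. Set
genes absent from the matrix take the capped rank by default (`cap_rank`
policy) so scores remain comparable across matrices; a `drop` policy
excludes them instead. Because only within-cell ranks enter, the score is
unaffected by whether the matrix holds raw-normalized or log-normalized
values.

State assignment z-scales each marker set's scores across cells
(sample SD) and labels each cell with the arg-max set when three marker
sets (endothelial, transitional, mesenchymal) are given, ties breaking by
the order the sets were supplied. With only endothelial and mesenchymal
sets, cells whose two z-scores lie within a margin ε (default 0.25) are
labelled the transitional state — an explicitly heuristic rule for partial
transitions, useful when no transitional marker set exists.

## Synthetic data generator

The generator emulates three data regimes with planted ground truth.

*Gene models*: non-overlapping genes (1–5 kb) placed one per genome slot
with ≥ 25 kb spacing, so ± 10 kb windows are pairwise disjoint by
construction. With the default 1000 genes this spacing requires ≥ 30 Mb;
the default chromosome length is 32 Mb.

*Mark reads*: background fragment starts are Poisson(2 per 10 bp bin)
uniform over the chromosome; designated identity genes carry a broad
planted domain (5–20 kb, covering the gene body plus a random share of the
flanks) at 15-fold background intensity, and 30% of the remaining genes
carry a narrow TSS-centred peak (0.5–2 kb) at the same fold; the matched
control is background only. Fragments are emitted as 36 bp stranded reads
whose 200 bp 5′-extension reproduces the fragment exactly.

*Regulatory-potential scenario*: each of 200 target genes receives 1–3
peaks within 20 kb of its TSS; 30% of background genes receive one peak
50–100 kb away. A `null` switch redistributes the same number of peaks
uniformly, making target and random sets exchangeable (used for
calibration).

*Expression*: per-gene baseline means are log-normal (median ≈ e); counts
are negative binomial with dispersion 0.3; marker genes shift on the log
scale by `effect_size` × the gene's own noise SD
(`σ = √log(1 + 1/μ + φ)`, the log-normal-matched NB coefficient of
variation) — endothelial markers up in EC-like cells, mesenchymal markers
up in mesenchymal-like cells, EndoMT cells receiving half of each shift,
and a third transitional marker set up only in EndoMT cells. One focal
gene decreases strictly across EC-like → EndoMT → mesenchymal-like (the
whole pattern scales with the effect size, so a zero effect is an exact
null). Dropout zeros are injected at rate 0.1 and values are per-cell
depth-normalized. Default: 600 cells at proportions 0.4 / 0.3 / 0.3.

Every generator is a pure function of its configuration seed (per-stream
generators derived from the seed plus a stable stream name), so outputs are
byte-identical across runs and platforms.

**What passing tests show — and don't.** The simulations demonstrate that
the implementations recover what they plant under their own model
assumptions: Poisson backgrounds with sharp-edged uniform enrichment,
disjoint gene windows, independent cells with NB noise. Real chromatin
data have positional biases, overlapping genes, replicate structure and
batch effects that the generator deliberately omits (as do doublets and
read-sequence-level artifacts), so passing tests validate the algorithms,
not the biology of any particular dataset.

## Problem sizes and runtime

The test suite and the acceptance script run at reduced but structurally
faithful problem sizes chosen as part of the package design: 1 Mb genomes
(30 genes) for peak-caller boundary checks, the full 32 Mb / 1000-gene
configuration (10 seeds) for identity-ranking recovery, 200-vs-200 gene
sets for regulatory-potential comparisons, and 600-cell matrices for
signature scoring; null calibrations use 200–500 seeds. The complete suite
finishes in a few minutes on one CPU.

## Known limitations

- Global (not local) Poisson background; no replicate handling, no FDR-
  based peak-width refinement, no paired-end fragment reconstruction.
- The regulatory-potential decay constant/window are package defaults, not
  a reproduction of any external tool's internals.
- The subgroup-assignment rule is a stand-in for package-based
  subclustering workflows; the ε-margin variant is heuristic.
- One TSS per gene; gene spans are record unions, which can overstate the
  body of genes with distant alternative isoforms.
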