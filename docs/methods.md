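# Methods

`orgstate` re-implements, as a tested library, the single-cell analysis
workflow used to characterize patient-derived pancreatic ductal
adenocarcinoma (PDAC) organoids: quality control and normalization, gene-set
and subtype scoring, shared-nearest-neighbor Louvain clustering and marker
detection, steady-state RNA velocity with Markov startpoint/endpoint tracing,
minimum-spanning-tree (MST) bifurcation pseudotime, imaging-based drug-screen
quantification, and RNA FISH signal-density quantification.  A synthetic
cohort generator provides ground truth for every stage, so the whole pipeline
is testable without any sequencing data.  The library functions together with
`scripts/acceptance.py` are the interface; there is no separate command-line
tool.

## Quality control and normalization (`io_qc`)

Cells are kept when they have at least 200 detected genes, at most 100,000
total counts and at most 15% mitochondrial counts (identified by the `MT-`
gene-name prefix); thresholds are inclusive at the boundary, so a cell at
exactly 100,000 counts or 15.0% mitochondrial fraction survives.  Genes must
be detected in at least 3 retained cells.  QC metrics are frozen at first
computation and cell filters are applied before the gene filter, which makes
`qc_filter` idempotent — applying it twice never removes anything more.  (The
alternative ordering, genes first on the unfiltered cell set, is not
idempotent: removing low-quality cells can drop a gene below the detection
threshold on a second pass.)

Normalization is `ln(1 + count / cell_total * 10,000)`; per cell the sum of
`expm1` over genes restores the scale factor exactly.  Highly variable genes
(2,000 by default) are ranked by the variance of trend-standardized counts: a
quadratic mean-variance trend in log10 space, counts standardized under the
trend and clipped at `sqrt(n_cells)`.  Scaling is per-gene z-scoring with the
population standard deviation, clipped at ±10.

## Scoring (`scores`)

A module score is the mean log-normalized expression of a signature minus the
mean of expression-matched controls: all genes are split into 24
equal-frequency bins of mean expression and each signature gene draws 100
control genes from its bin (with replacement when the bin is small).  Scores
are therefore invariant to adding a constant to all values.  Cell-cycle
phases use the S and G2/M marker lists shipped with the package: G2M when the
G2/M score exceeds the S score and zero, S when the S score is at least the
G2/M score and positive, G1 otherwise.  The PDAC subtype scores use the two
shipped 25-gene classical and basal-like signatures, combined per cell as

    S_moff = max(0, S_cla) - max(0, S_bas),

so positive values are classical-leaning.  An organoid is called subtype-
heterogeneous when, after within-sample clustering (resolution 0.5), at least
one cluster has median S_moff above +0.1 and another below −0.1, each holding
at least 1% of cells; these two thresholds are this package's
operationalization of a rule the source analyses applied visually.

## Clustering and integration (`cluster`)

PCA runs on the scaled HVG matrix with a fixed sign convention (the largest-
magnitude loading of each component is positive) and embeddings defined as
the explicit projection, so projecting the same data reproduces them exactly.
Clustering builds a kNN graph (k = 20) in 50-PC space, weights edges by the
Jaccard overlap of neighbor sets (pruned below 1/15), and optimizes the
Louvain modularity objective with a resolution parameter (0.7 for joint
analyses, 0.5 within samples) using `leidenalg`, seeded.  Markers come from
one-vs-rest Wilcoxon rank-sum tests with Benjamini–Hochberg adjustment
(Bonferroni available); per-sample signature genes additionally require
detection in ≥25% of the sample's cells and ≤90% of all others, keeping the
top 20 by effect.  Cross-sample integration is reference-projection based:
query cells are scaled with the reference gene statistics, projected onto the
reference PCA (first 50 PCs) and labeled by kNN majority vote with the vote
fraction as confidence; anchor-based integration is deliberately out of
scope.

## RNA velocity and endpoint tracing (`velocity`)

The steady-state model estimates a per-gene degradation ratio γ by regressing
unspliced on spliced through the origin over cells in the extreme 5%
quantiles of spliced expression; layers are depth-normalized per cell and
optionally kNN-pooled (k = 30) first.  The velocity `v = u − γs` is computed
on lightly pooled layers (k = 10) so narrow transition regions are not
smeared, and is recentered per gene by the median of `v/s` over
well-expressed cells: most such cells are near steady state, so the median
isolates residual γ-fit bias, which would otherwise become a coherent phantom
velocity shared by every cell expressing the gene.  The transition matrix
lives on a kNN graph (k = 50) in the 50-PC embedding of the spliced layer:
`T[i,j] ∝ exp(corr(v_i, x_j − x_i)/σ)` with σ = 0.2 in the pipeline, mixed
with a 30% uniform-diffusion component (sharp softmax kernels form two-cell
cycles under noise and probability stops propagating), and with neighbors
beyond 3× the median neighbor distance dropped (small isolated populations
otherwise exchange probability with remote cells).  Endpoint probabilities
propagate a uniform distribution 200 steps through the chain; startpoint
probabilities propagate through the chain built from the negated velocity
field.  The transpose-based reversal is also available (`markov_endpoints`)
but is vulnerable to in-degree artifacts, which is why the pipeline reverses
the field instead.

Known limitation: with plateau-dominated kinetics the per-cell velocity
direction is informative only near state transitions; under default noise
the backward chain tends to pool probability at the entry of the
differentiation branch rather than propagating it to the trunk source, so the
source state wins the start-minus-end ranking only in a minority of runs.
The corresponding acceptance test states the intended behavior and currently
fails; the endpoint (sink) side is usually correct.

## Bifurcation trajectory (`trajectory`)

Cells of the four clusters around the bifurcation are projected to
`u = −PC1 + (PC2 + PC3)`, `w = −PC1 − (PC2 + PC3)`; the MST runs on
Euclidean distances over a seeded subsample of at most 3,000 cells.  The
analysis flows in this package denoise coordinates by kNN averaging (k = 30,
first 10 PCs) before the MST — a documented choice; the raw `(u, w)` plane
is equally supported.  The root is either user-specified or the MST terminus
(leaf) whose 100-cell neighborhood maximizes a supplied per-cell root score;
the acceptance flow scores termini by proximity to the G2/M cluster centroid,
since the trajectory enters the bifurcation subset from the cycling
compartment.  Pseudotime is tree path length from the root; the bifurcation
node maximizes the smaller of its two largest child subtrees, whose members
become branch-A and branch-B.  Branch-dynamic genes are ranked by the
variance of expression smoothed along pseudotime (centered rolling mean over
10% of the branch) and clustered with complete linkage on correlation
distance.  The S_moff–PC1 association is summarized by ordinary least squares
over bin means, with equal-width bins taken along each variable and pooled.

Known limitation: per-branch Spearman correlation between pseudotime and the
generator's latent time reaches ≈0.75–0.95 depending on branch and seed at
the generator's default noise; ordering within short or weakly graded
segments is noise-limited (shown by comparing against the best linear
ordering of the denoised coordinates), so the acceptance test that demands
>0.9 on every branch currently fails for the weakest branch.

## Drug screen (`drugscreen`)

From binarized imaging areas: death fraction `cd = A_dead/A_total` at 72 h;
growth fold `g = A_total(72h)/A_total(0h)`; proliferation inhibition
`pi = clamp(1 − ln g / ln g(0), 0, 1)` (log-ratio normalization; a linear
option is configurable).  AUCd integrates `clamp(cd(c) − cd(0), 0, 1)` and
AUCpi integrates `pi(c)` by the trapezoid rule over log10 concentration,
normalized by the log-range so both lie in [0, 1] and are invariant to
rescaling all areas (pixel size) and comparable across drugs.  An LD50 is
fitted (4-parameter logistic of cd against log10 c) only when a one-way ANOVA
across concentration groups has p < 0.0005.  The subtype–response link is the
per-drug Pearson correlation between per-line median S_moff and AUCpi
(Spearman available).

## FISH quantification (`fishquant`)

Nuclei: Gaussian smoothing (σ = 2 px), Otsu binarization, Euclidean distance
transform, peak markers (min distance 10 px) and watershed; objects under
50 px are dropped.  Probe and gate channels are Otsu-binarized per image, so
densities are invariant to intensity rescaling; a nucleus is gated when at
least 10% of its pixels are gate-positive.  Density is the probe-positive
pixel fraction within the nucleus mask (no perinuclear dilation; a dilation
option exists).  Densities are normalized across samples by the reference
sample's mean density per probe, with the standard error of the mean
reported.

## Synthetic cohorts (`synth`)

The generator emulates the structure of the study cohort after integration:
12 organoid lines × 800 cells × 2,500 genes by default, nine shared cell
states on a cycling → differentiated hierarchy with a bifurcation at the
G1-like state (`Cycling-5`), where cells either re-enter the cycle
(`Cycling-1`) or differentiate (`Noncycling-1` → `Noncycling-2`); `IFN-1`
and `CXC-1` are small off-trajectory program states.  `Cycling-4` is the
designated trajectory source and `Noncycling-2` the sink.

Counts are negative binomial with θ = 10 — droplet UMI technical noise is
close to Poisson, and the overdispersion beyond it is modeled explicitly by
the biological terms — around a log-linear mean combining: per-state marker
blocks gated by compact-support smoothstep windows (exactly 0 outside and 1
on the interior plateau, walls 0.2 time units centered on state boundaries so
consecutive programs cross-fade); S-phase and G2/M gene lists active in the
S-like and G2/M-like states; a maturation wave of staggered symmetric bumps
covering the trunk and linking it through the bifurcation; branch-private
bump programs; classical/basal subtype programs weighted per cell (line base
mixture spread over [0.15, 0.85], plus a trend along latent time that folds
back toward basal on the re-entry branch, mirroring the coupling between
subtype and differentiation); 4 patient-private genes per line and a mild
patient wobble (sd 0.05 — patient effects are kept small because the cohort
emulates the post-integration structure, anchor integration being out of
scope); mitochondrial genes with per-cell expected fraction from Beta(2, 38);
library sizes log-normal (sd 0.35) around 6,000 counts per cell (typical 10x
depth).  A configurable fraction (4%) of QC-failing cells is injected with
truth flags (low gene count, high mitochondrial fraction, excessive reads),
each extreme enough to be caught by the printed thresholds.

Kinetics: spliced expectations equal the count means; unspliced expectations
are `u = s·(γ + r)/β` with the logarithmic rate of change `r` clipped to
±γ/2 (transcriptional modulation slower than turnover).  Deep inside a
plateau `r = 0`, so the unspliced/spliced ratio equals the true γ exactly;
induced genes have positive and repressed genes negative velocity.  Window
plateaus are deliberately wide relative to walls so that the extreme-quantile
cells used by the steady-state fit are genuinely steady.  Layer noise is
Poisson (exact expectations at noise level 0).

Drug plates follow a logistic dose–response whose amplitude and EC50 scale
with a per-line×drug sensitivity that increases linearly in the line's
classical weight, on a 1:3 dilution series with a c = 0 control; at zero
noise the recovered inhibition equals the generating curve exactly.  FISH
fields render disk nuclei (radius 13 px), a gate halo, and probe channels
lighting an exact per-nucleus pixel fraction recorded in the truth table.

What the generator does not emulate: ambient RNA, doublets, batch chemistry,
anchor-scale patient effects, discrete UMI saturation, or continuous
cell-cycle phase angle.  Passing tests therefore demonstrate correctness of
the algorithms under the stated model, not performance on raw unintegrated
tissue data.

## Problem sizes used by tests and the acceptance script

Degradation-rate recovery runs at 1 line × 1,000 cells × 520 genes
(noiseless); endpoint tracing at 5 seeds × 1,000 cells × 700 genes (default
noise); trajectory and clustering on the full default cohort (12 × 800);
drug-screen and FISH checks on the default plate (12 lines × 6 drugs × 3
replicates) and 10-nucleus fields.  These sizes keep the full suite and the
acceptance script each within a few minutes on one CPU.
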