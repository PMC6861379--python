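# Methods

## Data model and scope

The pipeline operates on per-study gene × sample count matrices with a
case/control design, an optional transcript→gene map, a gene × tissue
expression atlas, and GMT gene-set collections. Real inputs of this kind
come from public sequencing archives; the package ships a synthetic-data
generator instead, so every stage runs and is tested against known
ground truth at desk scale. All statistics are computed within study
first and combined at the effect-size level, which is what makes very
heterogeneous study sizes (3–234 samples per arm) usable without
cross-study batch correction.

## Normalization

Counts are normalized within each study by TMM with the published
defaults: reference column = the sample whose 75th-percentile count
fraction is closest to the mean of that quantity; per-sample factor =
2^(weighted trimmed mean of M-values against the reference), trimming
30 % of genes by M and 5 % by A, weighting by the inverse asymptotic
(binomial) variance, excluding genes with a zero in either sample;
factors are rescaled to geometric mean 1. Our implementation reproduces
edgeR's `calcNormFactors(method="TMM")` to 6 decimals on NB test
matrices, and an edgeR cross-check runs in the test suite. The analysis
scale is log2 CPM over TMM-effective library sizes with a prior count
(default 0.5): `log2((count + prior)/(lib·factor + 2·prior) · 1e6)`.

Exact invariance of the factors to rescaling one sample's column does
not hold (the precision weights and the A-trim depend on absolute
counts); edgeR drifts by the same ~2·10⁻³ on the fixtures we use, so the
property test asserts near-invariance at 5·10⁻³.

Transcript counts are aggregated to genes by plain summation (the
tximport default); unmapped transcripts abort with the offending ids
unless explicitly dropped. Whether to normalize within or across studies
is genuinely open; we normalize within study because the meta-analysis
combines study-level effects, and note this as an interpretation.

## Effect sizes and meta-analysis

Per gene and study: Hedges' g with its usual variance and a Welch-t
per-study p-value, computed on log2-CPM (configurable to un-logged CPM).
The SMD is computed on the log scale because the normal-theory variance
formula is defensible there; the small-sample correction J matters for
the 3-sample arms the design allows. Genes with zero pooled SD are
excluded with a reason code rather than given an arbitrary effect.

Across studies: Cochran's Q, I², and the switching rule — REM iff
(I² > 50 **and** p_Q < 0.01), strict inequalities, otherwise FEM. τ² is
DerSimonian–Laird; CIs use ±1.96·SE (normal), the standard
meta-analytic convention. DE calls require the 95 % CI to exclude zero
and BH-FDR < 0.05 across all tested genes of the run; subgroup runs
adjust within themselves. Genes in fewer than two studies are reported
untested. The AW-Fisher statistic is computed by scanning only the k
weight vectors that select the m smallest p-values (provably containing
the optimum); its minimum-tail statistic is anti-conservative as a
p-value, so `run_meta` calibrates it with group-label permutations
pooled across genes (default 50; 0 falls back to the raw minimum with a
logged warning). DE calling uses the SMD/CI/FDR rule; AW-Fisher is
reported alongside.

Known limitation, verified against both an ideal-conditions Monte Carlo
and R's `metafor` (`method="DL", test="z"`): DL with a normal CI covers
~92 % (not 95 %) at k = 10 and τ²/v ≈ 2. The acceptance suite asserts the
nominal 95 % ± 2 % band and therefore flags this inherent under-coverage
honestly; fixing it would require a Knapp–Hartung-type adjustment, which
is out of scope here.

## Tissue specificity

Atlas rows are converted to densities; score_t = 1 − √JSD(density, e_t)
with base-2 entropy, so scores live in [0, 1] and reach 1 exactly for
one-tissue genes. All-zero rows have no density and are excluded rather
than scored 0. Gene clustering uses Manhattan distance with complete
linkage by default (configurable); output is the merge table plus leaf
order, not an image.

## Co-expression network

Unsigned adjacency |Pearson r|^β. The soft power is the smallest
candidate whose signed scale-free fit R² (10 equal-width connectivity
bins, log–log regression of bin frequency on bin mean, sign of the
negative slope) reaches 0.8, falling back with a warning to the best
fit. TOM follows the standard formula and matches a triple-loop oracle
to 1e-12. Modules come from average-linkage clustering of 1 − TOM with a
**static gap cut**: the cut height is the midpoint of the largest gap
between consecutive merge heights in the dendrogram's top quarter
(falling back to 0.99·max height when no gap dominates), then branches
below `min_module_size` become label 0 and modules with eigengene
dissimilarity 1 − cor < 0.25 are merged. The gap rule replaces a plain
0.99·max cut because at the β the scale-free rule picks, TOM
dissimilarities compress toward 1 (within-module merges ≈ 0.995,
between-module ≈ 0.9999) and a fixed fraction of the maximum lands below
the within-module joins, shattering real modules. This remains a
simplification of the full dynamic tree-cut algorithm.

Module eigengenes are unit-variance first principal components of the
standardized module submatrix, sign-aligned to correlate positively with
their genes on average. Module relevance uses (i) eigengene–trait
correlation with a t-distribution p (df = n − 2) and (ii) the
correlation between |kME| and gene significance GS = |cor(gene, trait)|
within the module. Binary traits are encoded case = 1 / control = 0 and
brain = 1 / blood = 0; these encodings are package defaults, not
reconstructions of any particular study. Outlier samples are removed
before network construction by cutting the Euclidean/average-linkage
sample tree at a configurable height and dropping clusters smaller than
5.

## Enrichment

ORA: upper-tail hypergeometric p for the overlap of a module's genes
with each set, BH across tested sets, enriched iff adjusted p < 0.05.
The background universe is the set of genes entering the network (the
conservative self-contained choice); set-size filters default to
10–500 genes (relaxed to ≥5 in the synthetic demos, whose sets are
small). A permutation-calibrated weighted-KS running-sum statistic is
provided for ranked inputs, but module gene lists are unranked, so ORA
is the operative path.

## Synthetic data: what it emulates and what it does not

`generate_multistudy_counts` draws NB counts (gamma–Poisson, variance
μ + φμ², φ = 0.1 by default) with log-uniform library sizes
(0.5–2 M), log-normal relative abundances, and ~20 studies whose arm
sizes are drawn log-uniformly over the 3–58 case / 3–234 control
envelope of the emulated compendium. Planted effects are specified in
**standardized** units: a requested SMD δ is converted per gene to a
log2 fold change via the delta-method SD of log counts,
lfc = δ·√(1/μ + φ)/ln 2, so the true SMD on the analysis scale equals δ
and recovery tests have an analytic target (J·δ after the Hedges
correction). Between-study heterogeneity adds a N(0, τ²) perturbation to
the standardized effect per gene and study; the default τ² = 0.02
reproduces the ~3 % joint heterogeneity flag rate characteristic of this
kind of compendium. DE genes default to balanced up/down regulation
(`frac_up = 0.5`): with one-directional DE the library-size share of the
regulated genes shifts the CPM of every gene, and the per-gene M-value
noise at φ = 0.1 (SD ≈ 0.67) swamps the ~0.28 planted shift, so TMM —
ours and edgeR's alike — cannot remove the resulting ~0.06 SMD
compositional bias; balanced regulation is the standard simulator
default and keeps the analytic truth exact.

The atlas generator plants one-tissue-dominant genes at ≥10× every
other tissue; the co-expression generator uses latent module eigengenes
(gene = ρ·E_m + √(1−ρ²)·noise) with one module's eigengene tied to a
balanced binary trait; gene-set generation plants one set per module
drawing a chosen fraction of members from it.

Not emulated: read-level artifacts, gene length effects, batch effects
beyond the per-study random effect, correlated counts within the count
simulator (module structure lives in the dedicated generator), and
library-composition pathologies beyond the DE-direction imbalance
described above. Passing tests therefore demonstrate the statistics are
implemented correctly under the stated model, not that the model covers
everything real compendia do.

## Problem sizes and numerical choices

The standard exercises use 2 000 genes (10 000 for null calibration),
5–20 studies, and 200-gene/60-sample network benchmarks; these sizes
give Monte-Carlo error well inside every asserted band while the whole
suite plus the acceptance script completes in a few minutes on one CPU.
Determinism is by a single integer seed feeding `numpy`'s PCG64
generator per stage. p = 0 inputs to the Fisher combination are clipped
to the smallest positive float with a log message; Q with all-identical
effects is exactly 0 with I² = 0; REM collapses exactly to FEM when
Q ≤ df; ties in module renumbering break on the smaller original label.
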