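# lncmeta

Multi-study RNA-seq meta-analysis of disease-associated long noncoding
RNAs (lncRNAs). Individual case/control RNA-seq studies of a disease are
typically small and tissue-heterogeneous, so single-study differential
expression calls for lncRNAs replicate poorly. `lncmeta` implements the
standard remedy as a tested, reusable pipeline: per-gene effect sizes are
pooled across studies with a heterogeneity-aware meta-analysis, the
resulting disease-associated lncRNAs are scored for tissue specificity,
grouped into co-expression modules, and the modules tested for gene-set
enrichment. A first-class synthetic-data generator emulates the
multi-study design (including very unequal arm sizes) with known ground
truth, so every stage is testable without any downloads.

## The statistics at the core

Per study *i*, each gene's effect is the standardized mean difference
(Hedges' *g*) between cases and controls on log2-CPM after TMM
normalization:

- g = J·(x̄₁ − x̄₂)/s_pooled, J = 1 − 3/(4(n₁+n₂−2) − 1),
  v = (n₁+n₂)/(n₁n₂) + g²/(2(n₁+n₂))

Between-study heterogeneity is tested with Cochran's Q
(Q = Σ wᵢ(yᵢ − ȳ)², wᵢ = 1/vᵢ, χ² with k−1 df) and summarized as
I² = max(0, (Q−df)/Q)·100. A random-effects (DerSimonian–Laird) model is
used only when heterogeneity is significant (**I² > 50 and p_Q < 0.01**),
otherwise the fixed-effects inverse-variance model; a gene is called
differentially expressed when the pooled 95 % CI excludes zero **and**
its Benjamini–Hochberg FDR < 0.05. An adaptively weighted Fisher
combination (minimizing the χ² tail of −2Σwᵢ ln pᵢ over binary study
weights, calibrated by permutation) is reported alongside.

Tissue specificity of a gene's atlas expression density *p* is
1 − √JSD(p, e_t) with base-2 Jensen–Shannon divergence against the
extreme pattern e_t (expressed in one tissue only), giving scores in
[0, 1]. Co-expression modules come from an unsigned weighted network
a = |cor|^β (β picked for scale-free topology), topological-overlap
dissimilarity clustering and eigengene merging; module relevance uses
eigengene–trait correlation and the kME–GS correlation. Enrichment is the
upper-tail hypergeometric test, BH-adjusted.

## Worked example

```sh
python analysis/01_simulate_studies.py
python analysis/02_meta_analysis.py
```

prints (seed 0, the default study conditions: 20 studies, 398 cases,
1283 controls, 2000 genes, 10 % DE at SMD 0.6, τ² = 0.02):

```
[whole] heterogeneity flag rate 2.70%; 215 DE genes (106 up / 109 down); 200/200 planted DE recovered
[brain] heterogeneity flag rate 4.05%; 226 DE genes (113 up / 113 down); 198/200 planted DE recovered
[blood] heterogeneity flag rate 1.60%; 220 DE genes (111 up / 109 down); 197/200 planted DE recovered
93.95% of whole-sample DE genes also found in brain
92.56% of whole-sample DE genes also found in blood
```

i.e. only ~2.7 % of genes trip the joint heterogeneity rule (so >97 % are
pooled by the fixed-effects model), all 200 planted DE genes are
recovered in the whole-sample run at FDR < 0.05 (plus a tail of false
positives from unflagged mild heterogeneity), and the brain/blood
subgroup DE sets overlap the whole-sample set by >90 %. Steps
`03`–`05` score tissue specificity (planted dominant tissues recovered
100 %), detect co-expression modules on the latent-factor benchmark
(ARI 1.0 against truth; the trait-linked module ranks first) and confirm
the planted gene sets rank first in the module ORA. The same stages are
available as a CLI (`lncmeta simulate|normalize|meta|specificity|network|
enrich|overlap|run-all`); `lncmeta run-all` writes every TSV artifact
plus a manifest with SHA-256 hashes that reproduce exactly under a fixed
seed.

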