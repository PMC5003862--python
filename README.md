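# hubgenes

Imaging transcriptomics of brain network hubs: a tested, reusable
pipeline relating the nodal topology of functional MRI networks to
whole-genome regional gene expression.

Integrative features of brain networks — hubs mediating long-distance
connections between modules — are hypothesized to be metabolically
expensive, and their transcriptional signatures can be probed by
regressing network metrics on regional gene expression. `hubgenes`
implements that analysis end to end for researchers in network
neuroscience and systems biology:

* **Connectivity** — wavelet correlation matrices from regional BOLD
  time series (undecimated Daubechies-4 transform, dyadic frequency
  bands), and binary graphs anchored on the minimum spanning tree so
  they are connected at any connection density.
* **Topology** — consensus Louvain modules at resolution γ; per node
  the intra-modular degree k_intra, inter-modular degree k_inter,
  participation coefficient PC(i) = 1 − Σ_m (k_i(m)/k_i)², and mean
  connection distance d (mm); global Q, C, L, small-worldness σ and
  normalized rich club against degree-preserving nulls; class-wise
  ANOVA.
* **Transcriptome** — assembly of the gene × region matrix **T**:
  probe collapse, nearest-sample matching with hemispheric mirroring,
  donor averaging, per-gene Z-scoring, outlier-region exclusion.
* **PLS** — two-block partial least squares of **T** against the
  region × 3 response block **C** = [k_intra, k_inter, d]: components
  of expression with maximal covariance with nodal topology, % response
  variance per component, bootstrap standard errors and Z = w/SE gene
  rankings, and permutation tests of the fit — including a block
  permutation that respects spatial autocorrelation by shuffling
  spatially contiguous groups of regions.
* **Enrichment** — threshold-free minimum-hypergeometric (mHG) testing
  of ranked gene lists against GMT annotations with exact p-values and
  BH-FDR, plus permutation tests for a-priori candidate sets (e.g. a
  19-gene supragranular-enriched set).
* **Synthetic data** — a first-class generator that plants all of the
  above structure (spatially embedded bilateral modules, designated
  hubs, two expression components tied to k_intra − d and k_inter + d,
  spatially autocorrelated noise, enriched annotation terms) with
  recoverable ground truth, so every stage is verifiable offline.

## Worked example

`examples/` contains one narrative script per capability. The core
analysis (`examples/05_pls_gene_ranking.py`) generates a synthetic
study — 150 regions, 6 modules, 8 subjects, 2000 genes with two planted
expression components — and runs graph construction, consensus modules,
nodal metrics, PLS and inference:

```
cumulative % response variance: 46.8, 75.9, 93.4
PLS1 weight correlation with planted components: -0.36 / +0.82
PLS2 weight correlation with planted components: +0.76 / +0.22

component-metric correlations (Pearson r):
         k    PC  k_intra  k_inter     d   |x|     y     z
PLS1  0.57  0.79     0.18     0.79  0.87  0.29  0.16 -0.09
PLS2  0.81  0.27     0.88     0.28  0.14 -0.32 -0.23  0.09
PLS3 -0.01 -0.41     0.36    -0.48  0.41  0.53  0.16 -0.02

top 60 genes by bootstrap Z: 60 are planted signal genes
permutation test (naive): p = 0.002
permutation test (block): p = 0.002
```

Reading the output: the first three expression components capture 93%
of the standardized variance in nodal topology. One fitted component
aligns with the planted inter-modular-hub pattern (high PC, k_inter and
connection distance) and the other with the intra-modular pattern (high
k_intra); the cross-correlations between fitted and planted weight
vectors reflect the intrinsic collinearity of the two regional patterns
(they share connection distance with opposite signs — see
`docs/methods.md`). All 60 top-ranked genes by bootstrap Z are planted
signal genes, and both permutation schemes reject the null of no
expression–topology association.

The enrichment stage (`examples/06_enrichment.py`) then recovers
exactly the planted annotation terms at P_FDR < 0.001 and flags the
hub-derived 19-gene candidate set at the minimal attainable p = 0.001
while a uniform control set stays near the null.

A thin CLI wraps the same library for shell use:

```bash
hubgenes synth --out data/ --regions 200 --modules 8 --seed 1
hubgenes run --config config.json
```

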