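# Methods

`hubgenes` implements an imaging-transcriptomics analysis relating the
topology of functional brain networks to regional gene expression. This
note documents the models, the estimation and inference procedures, the
synthetic-data generator and its limits, and the numerical conventions.

## From time series to graphs

Functional connectivity is the Pearson correlation of wavelet detail
coefficients of regional BOLD time series. We use the undecimated
(shift-invariant) discrete wavelet transform with Daubechies-4 filters
(`pywt.swt`, `norm=True`); series are reflection-padded to the dyadic
length the transform requires and coefficients cropped back to the
original support. Scale *j* at sampling interval TR covers the band
[1/(2^(j+1)·TR), 1/(2^j·TR)] Hz; at TR = 2.42 s, scales 2–3 jointly
span 0.0258–0.1033 Hz — the slow oscillations resting-state analyses
target. (Published work sometimes quotes an upper edge of 0.111 Hz for
this TR and scale pair; that value is not reproducible from the dyadic
formula, and the package reports the dyadic band.) By default the
coefficients of the requested scales are concatenated before
correlating, yielding one matrix for the whole band; per-scale matrices
are available with `pool=False`. Undecimated-transform variants differ
only by per-scale coefficient scaling, which cancels in correlation.

Binary graphs are built per correlation matrix at a target connection
density: the minimum spanning tree of (1 − r) edge weights guarantees a
connected graph at any density, and remaining node pairs are added in
order of decreasing signed correlation until
max(n − 1, round(density · n(n−1)/2)) edges are present (rounding half
away from zero; correlation ties broken lexicographically by region
index, so construction is deterministic). Negative correlations are
never added before positive ones. Edge sets are nested across
densities by construction. Each edge carries the Euclidean distance
between its endpoints' centroids (mm).

## Modules and nodal metrics

Community structure is found by modularity maximization,
Q(γ) = (1/2m) Σ_ij [A_ij − γ k_i k_j / 2m] δ(c_i, c_j),
with the resolution parameter γ controlling partition coarseness. The
Louvain engine is `networkx.algorithms.community.louvain_communities`
(seeded, so node sweep order varies between runs as consensus
clustering requires). The consensus procedure is Lancichinetti–
Fortunato: run Louvain `n_runs` times (default 100), form the
co-classification matrix (fraction of runs placing two regions
together), threshold it at τ = 0.5, re-cluster the thresholded matrix,
and iterate (max 20 rounds) until all runs agree. A single-run call
reduces exactly to one Louvain run.

Against the resulting prototypical partition, each node is scored with:
total degree k; intra-modular degree k_intra (edges within its own
module); inter-modular degree k_inter = k − k_intra; participation
coefficient PC = 1 − Σ_m (k_i(m)/k_i)², which is 0 when all edges are
intra-modular and approaches 1 − 1/M for even spread over M modules;
and connection distance d, the mean Euclidean length of its edges (mm).
Isolated nodes get missing PC and d and are logged. In cohort analyses,
per-subject graphs are scored against the group partition and the nodal
tables averaged (mean by default, median available); the averaged
[k_intra, k_inter, d] block is the response matrix for PLS.

Global statistics are referenced to degree-preserving double-edge-swap
nulls (10·|E| swap attempts, rewires retried until connected, 100 nulls
by default): small-worldness σ = (C/C_rand)/(L/L_rand) with a
random-graph reference, and the normalized rich club
φ(k)/⟨φ_rand(k)⟩, reported for each degree k at which at least two
nodes qualify in the observed graph and every null. Class comparisons
use one-way ANOVA with explicit between/within sums of squares and
(n_classes − 1, n − n_classes) degrees of freedom.

## Expression matrix assembly

The microarray-to-parcellation chain is fixed: collapse probes to genes
(unmapped probes dropped and counted; probes of a gene averaged) →
match each region centroid, and its x-mirrored twin (homologous
hemisphere), to the nearest sample of each donor under Euclidean
distance (ties broken by lower sample id; optionally all samples within
a radius) → average over donors and hemispheres → Z-score each gene
across regions (sample sd; zero-variance genes dropped) → exclude
outlier regions and re-Z-score. A region is an outlier when its mean
correlation with all other regions' expression profiles falls below
median − 3·IQR of those means — a scale-free, robust rule with a single
threshold; flagging more than 20% of regions aborts with an error,
since that indicates an upstream coordinate mismatch rather than a few
bad samples. Every step logs its input/output dimensions.

## PLS and non-parametric inference

The core model is two-block PLS (PLS2): components of the regions ×
genes expression matrix with maximal covariance with the regions × 3
response block of standardized nodal metrics. Response columns are
standardized because degree counts and millimetres are incommensurate;
predictors are already Z-scored per gene. Estimation uses NIPALS with
predictor-block deflation, computed at its fixed point: the NIPALS
inner loop converges to the dominant singular pair of the deflated
cross-covariance X_dᵀY, so each component is obtained from that small
SVD directly — exact, deterministic, with no convergence tolerance.
Scores are orthogonal under predictor deflation, so the per-component
share of total standardized response sum of squares is additive;
cumulative shares are non-decreasing and reach 100% once the number of
components reaches the rank limit set by the number of regions.

Sign convention: each component is oriented so its largest-magnitude
gene weight is positive. (Orienting by the strongest component–metric
correlation is ill-posed here: a component aligned with
z(k_intra) − z(d) correlates with k_intra and d at exactly equal
magnitude and opposite sign, so that rule would be decided by noise.)
Flipping the sign of an underlying pattern flips the reported component
sign but no absolute correlation.

Inference is non-parametric throughout:

* **Bootstrap gene ranking.** Regions are resampled with replacement
  (degenerate draws redrawn, bounded retries); each refit's component
  is sign-aligned to the original by the inner product of weight
  vectors; the standard deviation over draws is the weight's standard
  error, and genes are ranked by Z = weight/SE (descending).
* **Permutation test of fit.** The statistic is the cumulative % of
  response variance explained by the leading components; the null
  permutes rows of the response block as whole vectors. p-values use
  the add-one estimator (1 + #{null ≥ observed})/(1 + n_perm) and never
  return zero.
* **Block permutation.** When regions are spatially dependent they are
  not individually exchangeable, and the naive null over-rejects. The
  block scheme permutes whole spatially contiguous blocks: blocks are
  concatenated in a uniformly shuffled order with within-block region
  order preserved — valid for any block-size multiset, and identical to
  the naive scheme when every block has size one. Block labels come
  from the data (e.g. the generator's spatial clusters) or from k-means
  on region centroids (n/10 blocks, fixed seed).
  `spatial_calibration_check` quantifies the phenomenon on null data
  with block-level random effects (within-block correlation ρ): at
  ρ = 0 both schemes reject at the nominal level; at ρ = 0.7 the naive
  scheme's rejection rate approaches 1 while the block scheme stays
  calibrated. The block-random-effects model mirrors dependence from
  homogeneous tissue within anatomical neighbourhoods; it is the regime
  in which whole blocks are exchangeable and the scheme is exact.
* **Candidate-set test.** The mean bootstrap Z of an a-priori gene set
  is compared with uniformly drawn same-size sets (genes missing from
  the ranking are dropped; null draws match the retained size).
  One-sided, add-one p. The null does not match co-expression or mean
  expression of the candidate genes — a deliberate simplification.

## Ranked-list enrichment

For each annotation term the minimum-hypergeometric (mHG) statistic is
the smallest hypergeometric upper tail over all rank cutoffs
(equivalently, over cutoffs ending at an annotated gene, where the
minima lie). The hypergeometric tail is computed in log space
(`gammaln` + stabilized summation). The term-level p-value accounts for
the minimization: when N·(K+1) ≤ 5·10⁵ (N ranked genes, K annotated) it
is computed exactly by big-integer path counting over the rank ×
annotation grid — the fraction of orderings whose hypergeometric walk
never reaches a tail ≤ the observed minimum; beyond that scale a
Bonferroni bound over the K candidate cutoffs is used. Both ends of the
ranking are tested (the reversed list covers negatively weighted
genes); BH-FDR is applied across terms within each direction. Terms
annotated with more than 2500 genes are flagged (a
visualization-oriented filter), and terms failing P_FDR < 0.001 are
flagged as non-significant; flagged rows are retained, never deleted.

## The synthetic-data generator

The generator plants every statistical structure the analysis assumes,
so the whole pipeline is verifiable without external data. Defaults are
the package's study conditions: 200 regions in 8 modules, 38 subjects,
256 timepoints at TR = 2.42 s, 5000 genes with two planted components
of 100 signal genes each at signal-to-noise 2.

* **Geometry.** Each module owns two mirrored Gaussian clusters of
  centroids (sd 12 mm), one per hemisphere of a 150 mm box, with module
  centres rejection-sampled for separation. Bilateral modules make
  intra-modular edges include long inter-hemispheric connections, so
  connection distance is not a mere proxy for inter-modular degree —
  with single compact clusters per module, r(k_inter, d) approaches
  0.8 and the two expression patterns below become almost anti-collinear.
  The 2M hemisphere clusters are emitted as block labels: a
  ground-truth spatially contiguous partition for the block permutation
  test. A synthetic cytoarchitectonic class cycles over seven labels
  with module.
* **Dynamics.** Per subject, each region's signal is a weighted sum of
  white-noise module factors (own module p_in = 0.8, others
  p_out = 0.1, designated hubs (p_in+p_out)/2 to every foreign module),
  a distance-decaying shared local field (kernel length 20 mm,
  amplitude 0.3), and unit-variance noise. A per-region gain, uniform
  on [0.5, 1.5], scales the factor couplings so degree varies within
  modules independently of position, giving a broad degree
  distribution.
* **Expression.** expression = effect · Σ_c w_c ⊗ p_c + noise, with
  regional patterns p₁ ∝ z(k_intra) − z(d) (intra-modular hubness with
  short wiring) and p₂ ∝ z(k_inter) + z(d) (inter-modular hubness with
  long wiring), computed from the synthetic network's own measured
  metrics. Planted weights are positive with ±20% jitter; component 1
  is ~30% stronger than component 2, which fixes the component order
  and breaks the exact rotational degeneracy of the cross-covariance
  SVD that equal strengths would leave. Noise is a Gaussian field mixed
  through a 5 mm distance kernel (rows renormalized, unit per-gene
  noise variance): long enough for clearly positive Moran's I, short
  relative to the 12 mm cluster scale so the planted components remain
  identifiable (see the identifiability note below). The annotation
  contains two terms per component drawn from that component's signal
  genes plus uniform background terms, and two 19-gene candidate sets
  (one from component-2 signal genes, one uniform control).

What the generator does **not** emulate: BOLD hemodynamics and
autocorrelated 1/f noise, head motion, multi-echo acquisition,
donor-level microarray batch effects, and cell-type composition.
Passing tests therefore demonstrate correctness and calibration of the
estimators under the planted model, not robustness to those real-data
nuisances.

### Identifiability of the planted components

Two structural facts bound how well the planted gene-weight vectors can
be recovered at the default scale, and both are worth knowing when
interpreting recovery numbers:

1. **Null-gene floor.** Any gene-wise linear readout of a 200-region
   matrix gives each of the 4800 non-signal genes a weight with
   variance ≥ 1/199 of the per-pattern projection. Even with perfect
   per-gene recovery the full-vector Pearson correlation with a
   100-gene planted weight vector is capped near
   √(100/(100 + 4800/199)) ≈ 0.90.
2. **Pattern collinearity.** p₁ and p₂ share z(d) with opposite signs,
   so their projections onto the standardized response block are
   substantially collinear (cosine ≈ −0.5 for any realistic metric
   correlation structure, including values reported for real cortical
   networks). The cross-covariance SVD therefore mixes the two
   gene-weight directions by roughly 25–45°, unless the planted
   strengths are made so asymmetric that the weaker component drowns
   instead.

Under the default conditions the matched recovery correlations measured
by the acceptance script land around 0.65–0.82 — close to the product
of those two ceilings. The bootstrap ranking is much less affected:
top-ranked genes are almost exclusively planted signal genes, because
ranking needs only support recovery, not proportional weight recovery.

## Pipeline and reproducibility

`run_pipeline` executes connectivity → consensus modules → nodal
metrics → expression assembly → PLS (+ bootstrap, permutation) →
enrichment from one configuration and one master seed; stage seeds are
the master seed plus fixed offsets, so stages consume independent but
reproducible streams. A stage failure is recorded in the results bundle
with its traceback and downstream stages are skipped explicitly —
nothing fails silently. An optional robustness sweep re-runs topology +
PLS across densities 0.10–0.30 and resolutions γ ∈ {1, 2} and reports
whether the sign pattern of the leading component–metric correlations
is stable; with well-separated components it is, while strong component
mixing (above) can flip signs between settings, which the sweep makes
visible rather than hiding. Default problem sizes throughout (200
regions, 5000 genes, 100-run consensus, 200–1000 bootstrap draws,
199–999 permutations) were chosen as the smallest sizes at which the
planted structure is comfortably detectable and calibration estimates
have useful precision.

## Known limitations

* Enrichment p-values switch from the exact path-counting computation
  to a Bonferroni bound for very large grids; the bound is conservative.
* Weighted-graph modularity, overlapping communities and directed
  graphs are out of scope, as are sparse/regularized PLS variants and
  cross-validated component selection.
* The candidate-set null ignores gene–gene correlation; matched-null
  variants are future work.
* Euclidean edge length understates true anatomical wiring length,
  exactly as in the real-data setting it mirrors.
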