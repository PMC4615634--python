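# Methods

## Curation and the perceptual matrix

Free-text descriptions are lowercased, whitespace-tokenized, filtered
against an editable stoplist of non-olfactory words (conjunctions,
adverbs, suffix-like words, auxiliary verbs, intensity words), passed
through a variant → canonical merge map ("alcoholic" → "alcohol",
"fruity" → "fruit"), and de-duplicated keeping first occurrence.  A
molecule whose tokens include a drop word ("odorless") is removed
entirely.  Curation is idempotent.  Multi-word descriptors are not
supported: tokens are single whitespace-separated words, matching how the
source databases phrase their descriptions.

An optional second pass merges morphological `-y`/`-like` variants, but
only when the stripped stem already occurs as a descriptor in the corpus
("woody" → "wood", while "spicy" survives if "spic" never occurs).  This
keeps the rule corpus-driven rather than dictionary-driven.

The dichotomous matrix *A* (m molecules × p descriptors) keeps only
molecules with ≥ 1 descriptor; columns are the vocabulary in
lexicographic order, which the databases themselves do not prescribe but
which makes every rebuild byte-identical.  Summary statistics: mean
descriptors per molecule AP_m = Σ A / m, mean molecules per descriptor
AM_p = Σ A / p, sparseness S_p = (1 − ΣA/(m·p))·100.  Conservation
m·AP_m = p·AM_p = ΣA holds by construction and is asserted in tests.

## Co-occurrence network

C = AᵀA over integers; the graph has one node per descriptor (isolated
nodes kept — node count must equal vocabulary size) and an edge of weight
C[i,j] per positive off-diagonal entry.  Metric conventions, chosen where
the field has competing ones:

- **Average weighted degree** 2·Σw/n; **weighted edge total** Σw.
- **Diameter / average path length**: unweighted hops on the largest
  connected component (co-occurrence graphs can be disconnected).
- **Density**: unweighted edges over C(n,2).
- **Clustering**: unweighted local coefficient averaged over *all* nodes,
  degree < 2 contributing zero.  This convention is what makes the G(n,m)
  null mean sit slightly *below* the density for sparse graphs (isolated
  and leaf nodes drag the average) and converge to it for dense ones.
- **Assortativity**: Pearson correlation of endpoint degrees over both
  orientations of every edge.  For regular graphs the correlation is
  undefined and is reported as a flagged null, never silently 0.
- **Degree for power-law fits and hub rankings**: weighted degree
  (strength).  Unweighted degree is capped at n−1, which is inconsistent
  with the magnitudes these networks exhibit at their cutoffs.

### Null model

`er_null` draws G(n,m) uniformly (m distinct pairs sampled without
replacement), scores each instance's average clustering as above, and
reports the ensemble mean and sd plus a two-sided normal z-test for an
empirical value.  The implementation is a dense-matrix batch (triangles
from (A·A)∘A row sums) rather than per-instance graph objects, keeping
1000-instance ensembles at n ≈ 500 to a few seconds; it is cross-checked
against a networkx-built ensemble in the tests.  A degenerate sd of 0
with a differing empirical value reports p = 0 with an explicit flag.

### Power-law fit

Discrete maximum likelihood with the Hurwitz-zeta normalisation: for each
candidate cutoff x_min (the unique observed values, capped at 200
candidates evenly subsampled, requiring ≥ 10 tail observations), α̂
maximises −n·log ζ(α, x_min) − α·Σ log x; the reported fit minimises the
KS distance between empirical and fitted tail CDFs.  The synthetic
sampler inverts the exact zeta-tail CCDF tabulated up to x = 10⁶ and
clips the remainder (tail mass ~10⁻⁸ at α = 2.5, x_min = 5) to the table
maximum; the induced bias is orders of magnitude below the ±0.05
recovery tolerance the tests demand.

### Communities

Weighted Louvain (networkx implementation) at resolution 1, node order
and tie-breaks randomised under a recorded seed, best of 10 restarts by
weighted modularity.  A caveat the tests document: for planted-partition
graphs the *modularity optimum* occasionally differs from the planted
partition by one or two boundary nodes — realisations exist where a
correct maximiser returns a strictly higher-Q partition that is not the
planted one, so exact-recovery rates plateau around ~90 % at
4 × 25 nodes, p_in = 0.3, p_out = 0.01 regardless of implementation.

## Semantic comparison

The bag-of-words network uses a forward-looking window: at each corpus
position holding a vocabulary word, every *distinct* vocabulary word
within the next window − 1 positions increments that pair's weight; no
self-pairs.  Window size per dataset is its AP_m rounded to the nearest
integer, clamped to 2–4.  The odour subnetwork is induced on the
vocabulary actually found in the corpus, weights preserved.

Eigen-similarity uses the weighted Laplacian L = D − W of both graphs
(neither is binarised: both carry meaningful counts).  Eigenvalues are
computed in full (graphs here stay ≤ ~500 nodes) and sorted descending;
values below 1e-9 in magnitude are treated as zero.  k_j is the smallest
count whose eigenvalue sum exceeds 90 % of graph j's spectral energy and
k = min(k₁, k₂) — the ambiguity in which graph "min" refers to is
resolved this way and makes sim symmetric in its arguments.  Scaling both
graphs' weights by c scales sim by c²; sim is not size-normalised, so it
is comparable only between graphs of similar scale, as in the matched
subnetwork design.

## Dual-space clustering

Feature preprocessing drops columns with any missing value or zero
variance and min-max scales the survivors to [0, 1].  Perceptual
similarity is the shared-descriptor count AAᵀ — the molecule-level
analogue of C = AᵀA.  Physico-chemical similarity is the self-tuning
kernel w_ij = exp(−d²_ij/(σᵢσⱼ)) with σᵢ the distance to the 7th nearest
neighbour (the common default); zero bandwidths from duplicate points are
floored at machine epsilon with a warning.

Cluster count selection: for each candidate k up to k_max (default 20),
the similarity matrix is embedded with the top k eigenvectors of the
symmetric-normalised affinity D^{−1/2}SD^{−1/2} (rows scaled to unit
length), partitioned by k-means, and scored with the Pelleg–Moore
spherical-Gaussian BIC; the best-scoring k wins and the full (k, BIC)
trace is reported.  Two numerical choices matter and were settled after
the obvious alternatives failed on planted-structure data:

- a *fixed* k_max-dimensional embedding (scored globally or by X-means
  split tests) lets the k_max − k_true noise eigenvectors dominate
  within-cluster variance, so the BIC either over-splits or refuses to
  split; embedding per candidate k makes the BIC peak sharply where the
  embedding collapses blocks to points;
- raw AAᵀ similarity contains tiny near-isolated molecule components
  whose normalised eigenvalues are exactly 1, outranking the main block
  structure, so 0.1·mean(S) is added to every pair before normalisation
  (the standard regularised-spectral-clustering remedy).  k = 1 is scored
  in the 2-eigenvector embedding because a connected kernel's
  1-dimensional NJW embedding is constant.

A similarity matrix that is exactly constant (all points identical) short
-circuits to k = 1.

The Hubert index is raw pair agreement: the fraction of unordered
molecule pairs co-clustered in both partitions or separated in both
(0 = least, 1 = highest overlap) — the verbal definition and anchors
match this Rand-form rather than the mean-centred Γ statistic.  Pair
counts come from the pair-confusion matrix; tests verify against explicit
pair enumeration.

## Prediction

Random forest (500 trees, √p features per split, recorded seed — the
procedure's robustness to forest hyperparameters is the point, not their
tuning) under stratified k-fold CV, k = 10 where class sizes allow.  CFS
merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff) with feature–class correlation
the point-biserial correlation against each one-vs-rest indicator
averaged over classes; greedy forward search stops at the first
non-improving addition.  Selection runs on the training split only — a
canary test plants a feature informative solely on a held-out fold and
asserts it is never selected for that fold nor inflates the AUC.  The
headline metric is macro one-vs-rest ROC AUC on pooled out-of-fold
probabilities (binary problems use the positive-class score directly);
reported feature counts are the consensus set selected in ≥ 50 % of
folds.

## Synthetic data: what it does and does not emulate

The generator reproduces the *statistical* structure the analyses assume:
descriptor popularity from a discrete power law (default exponent 2),
per-molecule descriptor counts Poisson-matched to a target sparseness
(resampling zeros), community-biased descriptor choice (default 7
communities, preference 0.9), class-conditioned Gaussian features whose
separation scales with a congruence parameter in [0, 1], and token
streams with planted adjacent vocabulary pairs.  Defaults mirror the
magnitudes real scraped databases show (~3000 molecules, ~500
descriptors, 99.3 % sparse, per-molecule counts spanning ~1–23).

It does not emulate: real chemistry (features are abstract reals, not
computed molecular properties), correlated descriptor semantics beyond
community structure, inter-database vocabulary overlap, or annotation
noise/disagreement between observers.  Passing tests therefore show the
pipeline recovers structure *of the kind assumed*, at realistic size and
sparseness — not that any particular real database has that structure.

Problem sizes in the shipped analyses and tests (1500 × 300 for the
narrative run, 400 × 120 for recovery checks, 1000-instance null
ensembles) were chosen as the smallest at which the estimated quantities
are stable against their own reported uncertainties.

## Known limitations

- Eigen-similarity is unnormalised; cross-scale comparisons need care.
- The BIC cluster-count selector assumes block-like similarity; elongated
  or hierarchical cluster geometry can split or merge blocks.
- CFS assumes roughly monotone feature–class relationships; purely
  interaction-coded classes defeat the point-biserial merit.
- The power-law fitter reports the KS-optimal tail; it does not test the
  power-law hypothesis against alternatives (lognormal, truncated).
- Exact community recovery is capped by modularity's own optimum
  occasionally differing from planted structure (see above).
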