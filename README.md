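# odorspace

Network analysis of odour perceptual space: from free-text odour
descriptions to co-occurrence networks, dual-space clustering and
structure–odour (QSOR) prediction.

## The problem

Odour databases (Flavornet, GoodScents, SuperScent, Sigma-Aldrich, the
Leon–Johnson archive) describe each molecule with a handful of free-text
words — "powerful green grass somewhat fruity gassy".  This package turns
such descriptions into quantitative structure and asks three questions:

1. **How is the perceptual vocabulary organised?**  Curated descriptions
   become a dichotomous molecules × descriptors matrix *A* (typically
   96–99.5 % sparse).  The descriptor co-occurrence matrix *C = AᵀA*
   defines a weighted network whose clustering coefficient is compared
   against Erdős–Rényi *G(n,m)* null ensembles (z-test), whose weighted
   degree distribution is fitted with a discrete power law
   *p(x) ∝ x⁻ᵅ* (MLE with Kolmogorov–Smirnov *x*<sub>min</sub>
   selection), and whose communities are found by weighted Louvain
   modularity maximisation.
2. **Is descriptor proximity just word semantics?**  A bag-of-words
   co-occurrence network built from a general text corpus (restricted to
   the olfactory vocabulary, window sizes 2–4) is compared with the
   matched odour subnetwork by Laplacian eigen-similarity:
   sim = Σᵢ≤k (λ₁ᵢ − λ₂ᵢ)², with *k* covering 90 % of spectral energy.
3. **Do perceptual and physico-chemical spaces agree?**  Molecules are
   clustered separately on shared-descriptor similarity (*AAᵀ*) and on a
   locally scaled Gaussian kernel over molecular descriptors, via spectral
   embedding with a BIC-selected cluster count (X-means-style).  Agreement
   is the Hubert pair-agreement index HI ∈ [0, 1].  Finally a random
   forest predicts a molecule's perceptual cluster from its descriptors,
   evaluated by 10-fold CV with greedy correlation-based feature selection
   (CFS) inside each training fold (macro one-vs-rest ROC AUC).

Real databases are scraped and carry no accessions, so the package ships a
synthetic-data module that reproduces their statistical structure (sparse
heavy-tailed incidence, planted descriptor communities, congruent or
incongruent feature geometry, token streams with controlled co-occurrence)
and makes the whole pipeline testable offline.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
data (1500 molecules, 300 descriptors, 7 planted communities):

```bash
python analysis/01_simulate.py
python analysis/02_describe_corpus.py
python analysis/03_network_analysis.py
python analysis/04_semantic_comparison.py
python analysis/05_dualspace_concordance.py
python analysis/06_predict_classes.py
```

Output of the network stage:

```
nodes: 300, weighted edge total: 7423
avg weighted degree: 49.49, diameter: 4, avg path length: 2.18
density: 0.081, clustering: 0.549
null clustering: 0.0807 ± 0.0016 (z = 294.4, p = 0)
power law: alpha = 2.75, x_min = 85, KS = 0.060
assortativity: -0.133
communities: 7 (Q = 0.651)
```

The empirical clustering (0.549) is hundreds of null standard deviations
above the random-graph mean (0.0807 — which, as theory predicts, sits at
the graph density), the weighted degrees follow a power law with α between
2 and 3, assortativity is negative (hub descriptors attach to specific
ones), and Louvain recovers the 7 planted descriptor communities.  The
dual-space stage then reports

```
perceptual clusters: 12, physico-chemical clusters: 7
Hubert index: 0.922
```

i.e. molecule pairs co-clustered by how they smell are overwhelmingly
co-clustered by what they are — and the prediction stage reaches macro
OvR ROC AUC 0.920 without and 0.919 with CFS, the latter using a handful
of consensus features out of 120.

The same stages are available as a CLI (`odorspace run-all --config
cfg.yaml --seed 42`) with per-stage subcommands and a manifest recording
config hash, seeds and artifact checksums.

## Layout

- `src/odorspace/` — library: `curation`, `network`, `powerfit`,
  `semantic`, `dualspace`, `predict`, `synth`, `pipeline`, `cli`.
- `analysis/` — numbered narrative drivers writing tables under `results/`.
- `tests/` — unit, property and whole-method tests.
- `docs/methods.md` — models, parameter choices, numerical details and
  known limitations.
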