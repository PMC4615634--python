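"""Dual-space molecule clustering and partition concordance.

Molecules are clustered twice: in perceptual space, where similarity is the
number of shared descriptors (A A^T), and in physico-chemical space, where
similarity is a locally scaled Gaussian kernel on Euclidean distances
(self-tuning bandwidths).  Both similarity matrices go through a
symmetric-normalised spectral embedding and an X-means-style cluster-number
search scored by the spherical-Gaussian BIC.  Agreement between the two
partitions is the Hubert pair-agreement index: the fraction of molecule
pairs either co-clustered in both spaces or separated in both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics.cluster import pair_confusion_matrix

__all__ = [
    "FeatureMatrix",
    "SimilarityMatrix",
    "ClusteringResult",
    "ClusterConcordance",
    "preprocess_features",
    "perceptual_similarity",
    "local_scaled_similarity",
    "spectral_xmeans",
    "hubert_index",
]


@dataclass(frozen=True)
class FeatureMatrix:
    """Molecules x numeric-features table, min-max scaled to [0, 1]."""

    molecule_ids: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray  # (m, f) float64 in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.molecule_ids), columns=list(self.feature_names)
        )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric non-negative molecule similarity matrix."""

    ids: tuple[str, ...]
    values: np.ndarray


def preprocess_features(raw: pd.DataFrame) -> FeatureMatrix:
    """Drop unusable descriptor columns and min-max scale the rest.

    Columns with any missing value or zero variance are removed; each
    survivor is scaled to [0, 1].
    """
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    keep = []
    for c in numeric.columns:
        col = numeric[c]
        if col.isna().any():
            continue
        if col.nunique() <= 1:
            continue
        keep.append(c)
    if not keep:
        raise ValueError("no feature columns survive preprocessing")
    sub = numeric[keep]
    lo = sub.min(axis=0)
    hi = sub.max(axis=0)
    scaled = (sub - lo) / (hi - lo)
    return FeatureMatrix(
        molecule_ids=tuple(map(str, raw.index)),
        feature_names=tuple(keep),
        values=scaled.to_numpy(dtype=np.float64),
    )


def perceptual_similarity(A) -> SimilarityMatrix:
    """Shared-descriptor counts between molecules: S = A A^T."""
    v = A.values.astype(np.int64)
    return SimilarityMatrix(ids=tuple(A.molecule_ids), values=(v @ v.T).astype(float))


def local_scaled_similarity(X: FeatureMatrix, k_neighbor: int = 7) -> SimilarityMatrix:
    """Self-tuning Gaussian kernel on Euclidean distances.

    w_ij = exp(-d_ij^2 / (sigma_i sigma_j)) with sigma_i the distance from
    point i to its k_neighbor-th nearest neighbour.  Duplicate points can
    force sigma = 0; those bandwidths are floored at machine epsilon scale
    with a warning.
    """
    n = X.values.shape[0]
    if not 1 <= k_neighbor < n:
        raise ValueError("k_neighbor must be in [1, n_molecules)")
    D = squareform(pdist(X.values, metric="euclidean"))
    # distance to the k-th nearest *other* point
    sigma = np.sort(D, axis=1)[:, k_neighbor]
    if np.any(sigma == 0):
        warnings.warn("duplicate points: flooring zero local bandwidths", stacklevel=2)
        floor = max(np.finfo(float).eps, 1e-12)
        sigma = np.maximum(sigma, floor)
    W = np.exp(-(D**2) / np.outer(sigma, sigma))
    np.fill_diagonal(W, 1.0)
    return SimilarityMatrix(ids=tuple(X.molecule_ids), values=W)


@dataclass(frozen=True)
class ClusteringResult:
    """Labels at the BIC-optimal cluster count plus the full BIC trace."""

    ids: tuple[str, ...]
    labels: np.ndarray  # ints in 1..k
    k: int
    bic_trace: tuple[tuple[int, float], ...]
    seed: int


def _spherical_bic(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    """BIC of a k-component identical spherical Gaussian mixture fitted by
    k-means (Pelleg–Moore X-means scoring)."""
    n, d = X.shape
    rss = 0.0
    counts = np.empty(k)
    for c in range(k):
        pts = X[labels == c]
        counts[c] = len(pts)
        if len(pts):
            rss += float(((pts - pts.mean(axis=0)) ** 2).sum())
    if n <= k:
        return -np.inf
    var = rss / (d * (n - k))
    var = max(var, 1e-12)
    ll = 0.0
    for c in range(k):
        nc = counts[c]
        if nc == 0:
            continue
        ll += (
            nc * np.log(max(nc, 1))
            - nc * np.log(n)
            - nc * d / 2.0 * np.log(2 * np.pi * var)
            - (nc - 1) * d / 2.0
        )
    n_params = k * (d + 1)  # k centroids + shared variance counted per split
    return ll - n_params / 2.0 * np.log(n)


def spectral_xmeans(
    S: SimilarityMatrix, k_max: int = 20, seed: int = 0, *, regularization: float = 0.1
) -> ClusteringResult:
    """Spectral embedding + BIC-scored cluster-number search.

    For each candidate k up to ``k_max`` the similarity matrix is embedded
    with the top k eigenvectors of the symmetric-normalised affinity
    (rows scaled to unit length), partitioned by k-means, and scored with
    the spherical-Gaussian BIC; the labels at the best-scoring k are
    returned along with the whole (k, BIC) trace.  When the candidate k
    matches the block structure of S the embedding collapses each block to
    a point, so the BIC peaks sharply at the true cluster count.

    Before normalisation ``regularization * mean(S)`` is added to every
    pair: shared-descriptor similarity matrices contain tiny near-isolated
    molecule components whose eigenvalues would otherwise outrank the main
    block structure (the usual regularized-spectral-clustering remedy).
    k = 1 is scored in the 2-eigenvector embedding, since its own
    one-dimensional embedding is degenerate for any connected kernel.
    Deterministic given (S, k_max, seed).
    """
    n = S.values.shape[0]
    if k_max < 2:
        raise ValueError("k_max must be at least 2")
    k_max = min(k_max, n - 1)
    # degenerate similarity (e.g. all points identical) -> single cluster
    if np.allclose(S.values, S.values[0, 0], atol=1e-12):
        return ClusteringResult(
            ids=tuple(S.ids),
            labels=np.ones(n, dtype=int),
            k=1,
            bic_trace=((1, 0.0),),
            seed=seed,
        )
    Sreg = S.values + regularization * S.values.mean()
    d = np.maximum(Sreg.sum(axis=1), 1e-12)
    Dinv = 1.0 / np.sqrt(d)
    M = Sreg * np.outer(Dinv, Dinv)
    _, vecs = np.linalg.eigh((M + M.T) / 2.0)
    vecs = vecs[:, ::-1]
    trace: list[tuple[int, float]] = []
    best_k, best_bic, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
    for k in range(1, k_max + 1):
        V = vecs[:, : max(k, 2)]
        norms = np.maximum(np.linalg.norm(V, axis=1, keepdims=True), 1e-12)
        X = V / norms
        if k == 1:
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=seed)
            labels = km.fit_predict(X)
        bic = float(_spherical_bic(X, labels, k))
        trace.append((k, bic))
        if bic > best_bic:
            best_k, best_bic, best_labels = k, bic, labels
    # relabel to 1..k in first-appearance order
    remap = {c: i + 1 for i, c in enumerate(dict.fromkeys(best_labels))}
    final = np.array([remap[c] for c in best_labels], dtype=int)
    return ClusteringResult(
        ids=tuple(S.ids),
        labels=final,
        k=best_k,
        bic_trace=tuple(trace),
        seed=seed,
    )


@dataclass(frozen=True)
class ClusterConcordance:
    """Pair-agreement between two molecule partitions."""

    hubert_index: float
    both_same: int
    both_different: int
    discordant: int


def hubert_index(labels1, labels2) -> ClusterConcordance:
    """Fraction of unordered molecule pairs on which two partitions agree.

    A pair agrees when the two molecules are co-clustered in both
    partitions or separated in both; 0 is least overlap, 1 highest.
    """
    a = np.asarray(labels1)
    b = np.asarray(labels2)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 molecules")
    # ordered-pair confusion matrix: [[both diff, diff->same], [same->diff, both same]]
    M = pair_confusion_matrix(a, b)
    both_diff = int(M[0, 0]) // 2
    both_same = int(M[1, 1]) // 2
    total = n * (n - 1) // 2
    discordant = total - both_same - both_diff
    return ClusterConcordance(
        hubert_index=(both_same + both_diff) / total,
        both_same=both_same,
        both_different=both_diff,
        discordant=discordant,
    )
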