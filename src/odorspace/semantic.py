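"""Semantic co-occurrence networks and Laplacian eigen-similarity.

To test whether descriptor proximity in odour networks merely reflects
everyday word usage, a bag-of-words network is built from a general text
corpus restricted to the olfactory vocabulary: within a forward-looking
window anchored at each vocabulary token, every distinct vocabulary word
increments the pair's edge weight.  Odour subnetworks induced on the
vocabulary actually found in the corpus are then compared with the
semantic networks via the summed squared difference of the top-k graph
Laplacian eigenvalues, k chosen to cover 90% of spectral energy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "TokenStream",
    "EigenSimilarityReport",
    "build_semantic_network",
    "matched_subnetwork",
    "eigen_similarity",
    "window_for_ap",
]


@dataclass(frozen=True)
class TokenStream:
    """An ordered, lowercase word sequence from a text corpus."""

    tokens: tuple[str, ...]
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError("empty token stream")

    @classmethod
    def from_text(cls, text: str, source_tag: str = "") -> "TokenStream":
        return cls(tokens=tuple(text.lower().split()), source_tag=source_tag)


def window_for_ap(ap_m: float) -> int:
    """Window size for a dataset: its mean descriptors-per-molecule rounded
    to the nearest integer and clamped to the range 2..4."""
    return int(min(4, max(2, round(ap_m))))


def build_semantic_network(
    stream: TokenStream, vocabulary: Iterable[str], window: int
) -> nx.Graph:
    """Windowed bag-of-words co-occurrence graph over a vocabulary.

    For each corpus position holding a vocabulary word, each *distinct*
    vocabulary word among the following ``window - 1`` positions increments
    that pair's weight by one; self-pairs are ignored.  All vocabulary words
    become nodes, so words never co-occurring stay as isolated nodes.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    vocab = set(vocabulary)
    G = nx.Graph()
    G.add_nodes_from(sorted(vocab))
    toks = stream.tokens
    n = len(toks)
    for i, anchor in enumerate(toks):
        if anchor not in vocab:
            continue
        seen: set[str] = set()
        for j in range(i + 1, min(i + window, n)):
            w = toks[j]
            if w in vocab and w != anchor and w not in seen:
                seen.add(w)
                if G.has_edge(anchor, w):
                    G[anchor][w]["weight"] += 1
                else:
                    G.add_edge(anchor, w, weight=1)
    return G


def matched_subnetwork(G_odour: nx.Graph, found_vocab: Iterable[str]) -> nx.Graph:
    """Induced subgraph of the odour network on the vocabulary found in the
    corpus, edge weights preserved."""
    found = set(found_vocab)
    if not found:
        raise ValueError("no overlap: found vocabulary is empty")
    missing = found - set(G_odour.nodes)
    if missing:
        raise ValueError(f"vocabulary not in odour network: {sorted(missing)[:5]}")
    return G_odour.subgraph(found).copy()


@dataclass(frozen=True)
class EigenSimilarityReport:
    """Eigen-similarity of two weighted graphs.

    ``lambda1``/``lambda2`` are the descending Laplacian spectra, ``k1``/
    ``k2`` the per-graph minimal counts covering 90% of spectral energy,
    ``k = min(k1, k2)`` the count compared, and ``sim`` the summed squared
    eigenvalue difference (0 means spectrally identical over the top k).
    """

    k1: int
    k2: int
    k: int
    lambda1: tuple[float, ...]
    lambda2: tuple[float, ...]
    sim: float


def _laplacian_spectrum(G: nx.Graph) -> np.ndarray:
    A = nx.to_numpy_array(G, weight="weight")
    if A.sum() == 0:
        raise ValueError("graph has zero total edge weight")
    L = np.diag(A.sum(axis=1)) - A
    vals = np.linalg.eigvalsh(L)
    vals = np.where(np.abs(vals) < 1e-9, 0.0, vals)
    return np.sort(vals)[::-1]


def _energy_k(lam: np.ndarray, energy: float = 0.9) -> int:
    total = lam.sum()
    cum = np.cumsum(lam) / total
    return int(np.argmax(cum > energy)) + 1


def eigen_similarity(G1: nx.Graph, G2: nx.Graph) -> EigenSimilarityReport:
    """Compare two graphs by their top-k Laplacian eigenvalues.

    sim = sum_{i<=k} (lambda1_i - lambda2_i)^2 with k = min(k1, k2), where
    k_j is the smallest count of descending eigenvalues whose sum exceeds
    90% of graph j's spectral energy.
    """
    lam1 = _laplacian_spectrum(G1)
    lam2 = _laplacian_spectrum(G2)
    k1 = _energy_k(lam1)
    k2 = _energy_k(lam2)
    k = min(k1, k2)
    a = lam1[:k]
    b = lam2[:k]
    if a.size < k:
        a = np.pad(a, (0, k - a.size))
    if b.size < k:
        b = np.pad(b, (0, k - b.size))
    sim = float(((a - b) ** 2).sum())
    return EigenSimilarityReport(
        k1=k1,
        k2=k2,
        k=k,
        lambda1=tuple(map(float, lam1)),
        lambda2=tuple(map(float, lam2)),
        sim=sim,
    )
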