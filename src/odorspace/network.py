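"""Descriptor co-occurrence networks: metrics, null models, hubs, communities.

The perceptual co-occurrence graph has one node per descriptor and an edge
between two descriptors weighted by the number of molecules jointly
described by both.  This module builds that graph from a co-occurrence
matrix and computes the standard characterisation suite: weighted average
degree, diameter and mean path length (largest component, unweighted hops),
graph density, local clustering averaged over all nodes, degree
assortativity, a power-law fit to the weighted degrees, Erdős–Rényi G(n,m)
null ensembles for the clustering coefficient with a z-test, hub rankings,
and Louvain modularity communities.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
from scipy.stats import norm

from .curation import CooccurrenceMatrix
from .powerfit import PowerLawFit, fit_power_law

__all__ = [
    "NetworkSummary",
    "RandomNullResult",
    "CommunityPartition",
    "build_graph",
    "summarize",
    "weighted_degrees",
    "er_null",
    "top_hubs",
    "detect_communities",
]


def build_graph(C: CooccurrenceMatrix) -> nx.Graph:
    """Build the weighted descriptor graph from co-occurrence counts.

    Every descriptor becomes a node (isolated nodes are kept); each positive
    off-diagonal count becomes an undirected edge with that integer weight.
    """
    G = nx.Graph()
    G.add_nodes_from(C.descriptors)
    counts = C.counts
    p = len(C.descriptors)
    iu, ju = np.triu_indices(p, k=1)
    mask = counts[iu, ju] > 0
    for i, j in zip(iu[mask], ju[mask]):
        G.add_edge(C.descriptors[i], C.descriptors[j], weight=int(counts[i, j]))
    return G


@dataclass(frozen=True)
class NetworkSummary:
    """The metric bundle characterising one co-occurrence network."""

    n_nodes: int
    weighted_edge_total: int
    avg_weighted_degree: float
    n_unweighted_edges: int
    diameter: int
    avg_path_length: float
    density: float
    clustering_avg: float
    assortativity: float | None
    assortativity_defined: bool
    powerlaw: PowerLawFit | None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def weighted_degrees(G: nx.Graph) -> dict:
    """Node strength: sum of incident edge weights."""
    return {n: int(d) for n, d in G.degree(weight="weight")}


def _assortativity(G: nx.Graph) -> tuple[float | None, bool]:
    """Pearson correlation of endpoint (unweighted) degrees over both edge
    orientations; undefined (flagged) for regular graphs."""
    deg = dict(G.degree())
    xs, ys = [], []
    for u, v in G.edges():
        xs.extend((deg[u], deg[v]))
        ys.extend((deg[v], deg[u]))
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return None, False
    r = float(np.corrcoef(x, y)[0, 1])
    return r, True


def summarize(G: nx.Graph, *, fit_degrees: bool = True) -> NetworkSummary:
    """Compute the full metric suite for a weighted co-occurrence graph.

    Diameter and average path length use unweighted hops on the largest
    connected component; clustering is the unweighted local coefficient
    averaged over *all* nodes with degree < 2 contributing zero.
    """
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("graph needs at least 2 nodes")
    if G.number_of_edges() == 0:
        raise ValueError("no edges")
    strengths = weighted_degrees(G)
    w_total = sum(d["weight"] for _, _, d in G.edges(data=True))
    lcc = G.subgraph(max(nx.connected_components(G), key=len))
    diameter = nx.diameter(lcc)
    avg_path = nx.average_shortest_path_length(lcc)
    clustering = nx.average_clustering(G, count_zeros=True)
    r, r_defined = _assortativity(G)
    fit = None
    if fit_degrees:
        vals = np.array([v for v in strengths.values() if v > 0])
        try:
            fit = fit_power_law(vals)
        except ValueError:
            fit = None
    return NetworkSummary(
        n_nodes=n,
        weighted_edge_total=int(w_total),
        avg_weighted_degree=2.0 * w_total / n,
        n_unweighted_edges=G.number_of_edges(),
        diameter=int(diameter),
        avg_path_length=float(avg_path),
        density=G.number_of_edges() / (n * (n - 1) / 2),
        clustering_avg=float(clustering),
        assortativity=r,
        assortativity_defined=r_defined,
        powerlaw=fit,
    )


@dataclass(frozen=True)
class RandomNullResult:
    """Clustering-coefficient null distribution from G(n,m) random graphs."""

    n: int
    m: int
    n_instances: int
    clustering_mean: float
    clustering_sd: float
    z_score: float | None = None
    p_value: float | None = None
    degenerate_sd: bool = False


def _gnm_clustering_batch(
    n: int, m: int, n_instances: int, rng: np.random.Generator
) -> np.ndarray:
    """Average local clustering (degree<2 counted as 0) of G(n,m) draws.

    Dense-matrix implementation: edges are sampled without replacement from
    the C(n,2) pairs, triangles per node come from (A @ A) * A row sums.
    """
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size
    out = np.empty(n_instances)
    for t in range(n_instances):
        pick = rng.choice(n_pairs, size=m, replace=False)
        A = np.zeros((n, n), dtype=np.float32)
        A[iu[pick], ju[pick]] = 1.0
        A += A.T
        tri = ((A @ A) * A).sum(axis=1) / 2.0  # triangles through each node
        k = A.sum(axis=1)
        denom = k * (k - 1) / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            local = np.where(denom > 0, tri / denom, 0.0)
        out[t] = local.mean()
    return out


def er_null(
    n: int,
    m: int,
    n_instances: int = 1000,
    seed: int | np.random.Generator = 0,
    *,
    clustering_emp: float | None = None,
) -> RandomNullResult:
    """Simulate the G(n,m) null distribution of the average clustering
    coefficient and, optionally, z-test an empirical value against it.

    The z-test is a two-sided normal approximation using the simulated mean
    and standard deviation.  If the null sd is zero (e.g. complete graphs)
    and the empirical value differs, the p-value is reported as 0 with
    ``degenerate_sd`` set.
    """
    max_m = n * (n - 1) // 2
    if not 0 <= m <= max_m:
        raise ValueError(f"m must be in [0, {max_m}]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    samples = _gnm_clustering_batch(n, m, n_instances, rng)
    mean = float(samples.mean())
    sd = float(samples.std(ddof=1)) if n_instances > 1 else 0.0
    z = p = None
    degenerate = False
    if clustering_emp is not None:
        if sd == 0:
            if clustering_emp == mean:
                z, p = 0.0, 1.0
            else:
                z, p, degenerate = float("inf"), 0.0, True
        else:
            z = (clustering_emp - mean) / sd
            p = float(2.0 * norm.sf(abs(z)))
    return RandomNullResult(
        n=n,
        m=m,
        n_instances=n_instances,
        clustering_mean=mean,
        clustering_sd=sd,
        z_score=z,
        p_value=p,
        degenerate_sd=degenerate,
    )


def top_hubs(G: nx.Graph, k: int) -> list[str]:
    """The k nodes of highest weighted degree, ties broken lexicographically."""
    if k > G.number_of_nodes():
        raise ValueError("k exceeds node count")
    strengths = weighted_degrees(G)
    ranked = sorted(strengths, key=lambda n: (-strengths[n], str(n)))
    return ranked[:k]


@dataclass(frozen=True)
class CommunityPartition:
    """A node -> community assignment with its weighted modularity."""

    assignment: dict
    modularity_q: float
    resolution: float
    n_communities: int


def detect_communities(
    G: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    *,
    restarts: int = 10,
) -> CommunityPartition:
    """Louvain modularity maximisation on edge weights.

    Node order and tie-breaking are randomised under the given seed; the
    best of ``restarts`` runs (by weighted modularity) is reported.
    """
    if G.number_of_edges() == 0:
        raise ValueError("no edges")
    best_q = -np.inf
    best: list[set] | None = None
    for r in range(restarts):
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=resolution, seed=seed + r
        )
        q = nx.community.modularity(G, comms, weight="weight", resolution=resolution)
        if q > best_q:
            best_q, best = q, comms
    assert best is not None
    assignment = {}
    for cid, members in enumerate(sorted(best, key=lambda s: sorted(map(str, s)))):
        for node in members:
            assignment[node] = cid
    return CommunityPartition(
        assignment=assignment,
        modularity_q=float(best_q),
        resolution=resolution,
        n_communities=len(best),
    )
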