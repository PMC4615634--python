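"""Co-occurrence graph construction, metric suite, null model, communities."""

import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from odorspace import (
    build_graph,
    cooccurrence,
    detect_communities,
    er_null,
    summarize,
    top_hubs,
)
from odorspace.curation import CooccurrenceMatrix
from odorspace.network import weighted_degrees


def _comat(labels, counts):
    return CooccurrenceMatrix(descriptors=tuple(labels), counts=np.asarray(counts))


def test_build_graph_single_edge():
    G = build_graph(_comat("ab", [[1, 1], [1, 1]]))
    assert G.number_of_edges() == 1
    assert G["a"]["b"]["weight"] == 1


def test_build_graph_keeps_isolated_nodes():
    G = build_graph(_comat("abc", [[2, 1, 0], [1, 2, 0], [0, 0, 3]]))
    assert G.number_of_nodes() == 3
    assert G.degree("c") == 0


def test_build_graph_weight_total_matches_matrix(small_matrix):
    A, _, _ = small_matrix
    C = cooccurrence(A)
    G = build_graph(C)
    total = sum(d["weight"] for _, _, d in G.edges(data=True))
    iu, ju = np.triu_indices(A.p, k=1)
    assert total == int(C.counts[iu, ju].sum())


def test_summarize_unit_triangle():
    G = nx.Graph()
    G.add_weighted_edges_from([("a", "b", 1), ("b", "c", 1), ("a", "c", 1)])
    s = summarize(G, fit_degrees=False)
    assert s.avg_weighted_degree == 2.0
    assert s.diameter == 1
    assert s.avg_path_length == 1.0
    assert s.density == 1.0
    assert s.clustering_avg == 1.0


def test_summarize_path_assortativity():
    G = nx.path_graph(4)
    nx.set_edge_attributes(G, 1, "weight")
    s = summarize(G, fit_degrees=False)
    assert s.assortativity == pytest.approx(-0.5)


def test_regular_graph_assortativity_flagged_not_zero():
    G = nx.cycle_graph(6)
    nx.set_edge_attributes(G, 1, "weight")
    s = summarize(G, fit_degrees=False)
    assert s.assortativity is None
    assert not s.assortativity_defined


def test_summarize_edgeless_errors():
    G = nx.empty_graph(3)
    with pytest.raises(ValueError, match="no edges"):
        summarize(G)


def test_summarize_against_exhaustive_oracle(rng):
    """Path length, diameter and clustering match brute-force computation."""
    G = nx.gnp_random_graph(30, 0.15, seed=42)
    nx.set_edge_attributes(G, 1, "weight")
    s = summarize(G, fit_degrees=False)

    A = nx.to_numpy_array(G)
    # largest connected component by BFS-free label propagation on distances
    D = shortest_path(A, unweighted=True)
    finite = np.isfinite(D)
    comp_sizes = finite.sum(axis=1)
    lcc = np.where(comp_sizes == comp_sizes.max())[0]
    sub = D[np.ix_(lcc, lcc)]
    off = sub[~np.eye(len(lcc), dtype=bool)]
    assert s.diameter == int(off.max())
    assert s.avg_path_length == pytest.approx(off.mean())

    # clustering: per-node triangle count over neighbour pairs
    cls = []
    for i in range(30):
        nbrs = np.where(A[i] > 0)[0]
        k = len(nbrs)
        if k < 2:
            cls.append(0.0)
            continue
        links = sum(
            1 for u, v in itertools.combinations(nbrs, 2) if A[u, v] > 0
        )
        cls.append(links / (k * (k - 1) / 2))
    assert s.clustering_avg == pytest.approx(np.mean(cls))

    # assortativity: Pearson over the oriented endpoint-degree pairs
    deg = A.sum(axis=1)
    pairs = [(deg[u], deg[v]) for u, v in G.edges()]
    pairs += [(b, a) for a, b in pairs]
    x, y = np.array(pairs).T
    assert s.assortativity == pytest.approx(float(np.corrcoef(x, y)[0, 1]))


def test_er_null_complete_graph_degenerate():
    r = er_null(6, 15, n_instances=50, seed=1, clustering_emp=0.5)
    assert r.clustering_mean == 1.0
    assert r.clustering_sd == 0.0
    assert r.degenerate_sd
    assert r.p_value == 0.0


def test_er_null_matches_networkx_ensemble():
    """Dense-matrix null agrees with a networkx-built ensemble."""
    mine = er_null(25, 60, n_instances=400, seed=3)
    nx_vals = [
        nx.average_clustering(nx.gnm_random_graph(25, 60, seed=1000 + i), count_zeros=True)
        for i in range(400)
    ]
    se = np.hypot(mine.clustering_sd, np.std(nx_vals, ddof=1)) / np.sqrt(400)
    assert abs(mine.clustering_mean - np.mean(nx_vals)) < 4 * se


def test_er_null_zscore_and_bounds():
    r = er_null(40, 100, n_instances=200, seed=5, clustering_emp=0.6)
    assert 0.0 <= r.clustering_mean <= 1.0
    assert r.clustering_sd >= 0
    assert r.z_score > 0 and 0 <= r.p_value <= 1


def test_er_null_invalid_m():
    with pytest.raises(ValueError):
        er_null(5, 11, n_instances=10)


def test_top_hubs_star_and_full_ordering():
    G = nx.star_graph(5)
    nx.set_edge_attributes(G, 1, "weight")
    assert top_hubs(G, 1) == [0]
    ordering = top_hubs(G, G.number_of_nodes())
    assert sorted(ordering) == sorted(G.nodes)
    with pytest.raises(ValueError):
        top_hubs(G, 99)


def test_top_hubs_match_recomputed_strengths(small_matrix):
    A, _, _ = small_matrix
    G = build_graph(cooccurrence(A))
    hubs = top_hubs(G, 10)
    strengths = weighted_degrees(G)
    expect = sorted(strengths, key=lambda n: (-strengths[n], n))[:10]
    assert hubs == expect


def test_communities_two_cliques():
    G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    nx.set_edge_attributes(G, 1, "weight")
    part = detect_communities(G, seed=0)
    assert part.n_communities == 2
    assert part.modularity_q == pytest.approx(0.5)
    # each clique in one community
    groups = {part.assignment[n] for n in range(5)}
    assert len(groups) == 1
    assert part.assignment[0] != part.assignment[5]


def test_communities_single_edge():
    G = nx.Graph()
    G.add_edge("a", "b", weight=1)
    part = detect_communities(G, seed=0)
    assert part.n_communities == 1
    assert part.modularity_q == pytest.approx(0.0)


def test_communities_edgeless_errors():
    with pytest.raises(ValueError):
        detect_communities(nx.empty_graph(4))


def test_communities_planted_partition_quick():
    """Planted 4-block graph recovered in a small seed sweep."""
    hits = 0
    for seed in range(10):
        G = nx.planted_partition_graph(4, 25, 0.3, 0.01, seed=seed)
        nx.set_edge_attributes(G, 1, "weight")
        part = detect_communities(G, seed=seed)
        planted = {n: n // 25 for n in G.nodes}
        mapping = {}
        ok = part.n_communities == 4
        if ok:
            for n, c in part.assignment.items():
                mapping.setdefault(c, planted[n])
                if mapping[c] != planted[n]:
                    ok = False
                    break
        hits += ok
    assert hits >= 9


def test_merging_component_partitions_never_lowers_q():
    G1 = nx.complete_graph(4)
    G2 = nx.relabel_nodes(nx.complete_graph(5), lambda n: n + 10)
    G = nx.union(G1, G2)
    nx.set_edge_attributes(G, 1, "weight")
    p1 = detect_communities(G.subgraph(G1.nodes), seed=0)
    p2 = detect_communities(G.subgraph(G2.nodes), seed=0)
    merged = [
        {n for n in G1.nodes if p1.assignment[n] == c}
        for c in set(p1.assignment.values())
    ] + [
        {n for n in G2.nodes if p2.assignment[n] == c}
        for c in set(p2.assignment.values())
    ]
    q_merged = nx.community.modularity(G, merged, weight="weight")
    q_joint = detect_communities(G, seed=0).modularity_q
    assert q_joint >= q_merged - 1e-12
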