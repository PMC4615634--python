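#!/usr/bin/env python
"""Compare the odour network with a semantic co-occurrence network.

Builds a windowed bag-of-words network from the simulated token corpus
restricted to the descriptor vocabulary, extracts the odour subnetwork on
the vocabulary actually found in the corpus, and compares the two graphs
by Laplacian eigen-similarity (top-k eigenvalues covering 90% of spectral
energy).  Large values mean the odour network's structure is not explained
by word usage alone.
"""

import json
from pathlib import Path

import networkx as nx

from odorspace import (
    TokenStream,
    build_graph,
    build_semantic_network,
    cooccurrence,
    eigen_similarity,
    matched_subnetwork,
    matrix_stats,
    read_perceptual_matrix,
    summarize,
    window_for_ap,
)

CORPUS = Path("results/synthetic/corpus.txt")
MATRIX = Path("results/corpus/perceptual_matrix.tsv")
OUT = Path("results/semantic")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    A = read_perceptual_matrix(MATRIX)

    window = window_for_ap(matrix_stats(A).ap_m)
    stream = TokenStream.from_text(CORPUS.read_text(), source_tag=str(CORPUS))
    G_sem = build_semantic_network(stream, A.descriptors, window)
    found = [n for n, d in G_sem.degree() if d > 0]
    G_odour = build_graph(cooccurrence(A))
    G_sub = matched_subnetwork(G_odour, found)

    rep = eigen_similarity(G_sub, G_sem.subgraph(found).copy())
    sem_summary = summarize(G_sem.subgraph(found).copy(), fit_degrees=False)
    sub_summary = summarize(G_sub, fit_degrees=False)

    report = {
        "window": window,
        "n_vocabulary_found": len(found),
        "semantic": {
            "weighted_edges": sem_summary.weighted_edge_total,
            "avg_degree": sem_summary.avg_weighted_degree,
            "density": sem_summary.density,
            "clustering": sem_summary.clustering_avg,
            "assortativity": sem_summary.assortativity,
        },
        "odour_subnetwork": {
            "weighted_edges": sub_summary.weighted_edge_total,
            "avg_degree": sub_summary.avg_weighted_degree,
            "density": sub_summary.density,
            "clustering": sub_summary.clustering_avg,
            "assortativity": sub_summary.assortativity,
        },
        "eigen_similarity": {"k1": rep.k1, "k2": rep.k2, "k": rep.k, "sim": rep.sim},
    }
    (OUT / "semantic_report.json").write_text(json.dumps(report, indent=2) + "\n")
    nx.write_graphml(G_sem, OUT / "semantic.graphml")

    print(f"window size: {window} (from mean descriptors/molecule)")
    print(f"vocabulary found in corpus: {len(found)} / {A.p}")
    print(
        f"semantic net: {sem_summary.weighted_edge_total} weighted edges, "
        f"clustering {sem_summary.clustering_avg:.3f}"
    )
    print(
        f"odour subnet: {sub_summary.weighted_edge_total} weighted edges, "
        f"clustering {sub_summary.clustering_avg:.3f}"
    )
    print(f"eigen similarity: {rep.sim:.3g} (k = {rep.k})")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
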