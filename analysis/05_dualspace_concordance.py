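#!/usr/bin/env python
"""Cluster molecules in perceptual and physico-chemical space and compare.

Perceptual similarity is the shared-descriptor count (A A^T); the feature
table is preprocessed (constant/missing columns dropped, min-max scaled)
and turned into a locally scaled Gaussian kernel.  Both similarity
matrices are clustered by spectral embedding + BIC-selected k, and the two
partitions are compared with the Hubert pair-agreement index.
"""

import json
from pathlib import Path

import pandas as pd

from odorspace import (
    hubert_index,
    local_scaled_similarity,
    perceptual_similarity,
    preprocess_features,
    read_perceptual_matrix,
    spectral_xmeans,
)

MATRIX = Path("results/corpus/perceptual_matrix.tsv")
FEATURES = Path("results/synthetic/features.csv")
OUT = Path("results/dualspace")
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    A = read_perceptual_matrix(MATRIX)
    raw = pd.read_csv(FEATURES, index_col="molecule_id").loc[list(A.molecule_ids)]
    X = preprocess_features(raw)
    print(f"features: {raw.shape[1]} raw -> {len(X.feature_names)} after preprocessing")

    res_perc = spectral_xmeans(perceptual_similarity(A), k_max=12, seed=SEED)
    res_chem = spectral_xmeans(
        local_scaled_similarity(X, k_neighbor=7), k_max=12, seed=SEED
    )
    conc = hubert_index(res_perc.labels, res_chem.labels)

    pd.DataFrame(
        {
            "molecule_id": A.molecule_ids,
            "perceptual_cluster": res_perc.labels,
            "physicochemical_cluster": res_chem.labels,
        }
    ).to_csv(OUT / "cluster_labels.tsv", sep="\t", index=False)
    pd.DataFrame(res_perc.bic_trace, columns=["k", "bic"]).to_csv(
        OUT / "bic_trace_perceptual.csv", index=False
    )
    pd.DataFrame(res_chem.bic_trace, columns=["k", "bic"]).to_csv(
        OUT / "bic_trace_physicochemical.csv", index=False
    )
    (OUT / "concordance.json").write_text(
        json.dumps(
            {
                "k_perceptual": res_perc.k,
                "k_physicochemical": res_chem.k,
                "hubert_index": conc.hubert_index,
                "both_same": conc.both_same,
                "both_different": conc.both_different,
                "discordant": conc.discordant,
            },
            indent=2,
        )
        + "\n"
    )

    print(f"perceptual clusters: {res_perc.k}, physico-chemical clusters: {res_chem.k}")
    print(f"Hubert index: {conc.hubert_index:.3f}")
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
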