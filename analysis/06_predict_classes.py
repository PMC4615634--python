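#!/usr/bin/env python
"""Predict perceptual clusters from physico-chemical features.

Uses the perceptual-space cluster labels from the dual-space stage as
classes and evaluates a random forest under 10-fold stratified
cross-validation, with and without greedy correlation-based feature
selection run inside each training fold.  Reports macro one-vs-rest ROC
AUC and the consensus feature set (selected in at least half the folds).
"""

import json
from pathlib import Path

import pandas as pd

from odorspace import (
    LabeledDataset,
    crossval_rf,
    preprocess_features,
    read_perceptual_matrix,
)

MATRIX = Path("results/corpus/perceptual_matrix.tsv")
FEATURES = Path("results/synthetic/features.csv")
LABELS = Path("results/dualspace/cluster_labels.tsv")
OUT = Path("results/predict")
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    A = read_perceptual_matrix(MATRIX)
    raw = pd.read_csv(FEATURES, index_col="molecule_id").loc[list(A.molecule_ids)]
    X = preprocess_features(raw)
    labels = pd.read_csv(LABELS, sep="\t").set_index("molecule_id")
    y = labels.loc[list(A.molecule_ids), "perceptual_cluster"].to_numpy()

    counts = pd.Series(y).value_counts()
    folds = int(min(10, counts.min()))
    data = LabeledDataset(X=X, y=y)
    rep_no = crossval_rf(data, folds=folds, with_selection=False, seed=SEED)
    rep_fs = crossval_rf(data, folds=folds, with_selection=True, seed=SEED)

    (OUT / "prediction_report.json").write_text(
        json.dumps(
            {
                "classes": int(counts.size),
                "folds": folds,
                "roc_without_selection": rep_no.roc_auc,
                "roc_with_selection": rep_fs.roc_auc,
                "n_features_consensus": rep_fs.n_features_consensus,
            },
            indent=2,
        )
        + "\n"
    )
    tally: dict[str, int] = {}
    for feats in rep_fs.selected_features_per_fold:
        for f in feats:
            tally[f] = tally.get(f, 0) + 1
    pd.DataFrame(
        sorted(tally.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["feature", "folds_selected"],
    ).to_csv(OUT / "consensus_features.tsv", sep="\t", index=False)

    print(f"classes: {counts.size}, folds: {folds}")
    print(f"ROC AUC without selection: {rep_no.roc_auc:.3f}")
    print(
        f"ROC AUC with selection: {rep_fs.roc_auc:.3f} "
        f"({rep_fs.n_features_consensus} consensus features "
        f"of {len(X.feature_names)})"
    )
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
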