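"""Perceptual-class prediction from physico-chemical descriptors.

A random forest predicts a molecule's perceptual cluster (assigned by the
dual-space clustering) from its physico-chemical features.  Evaluation is
10-fold stratified cross-validation with macro one-vs-rest ROC AUC on the
pooled out-of-fold probability scores.  Optionally a greedy
correlation-based feature selection (CFS) runs *inside* each training fold:
forward search maximising

    merit(S) = k * r_cf / sqrt(k + k (k - 1) * r_ff)

where r_cf is the mean absolute feature-class correlation of the k selected
features and r_ff the mean absolute inter-feature correlation among them.
Feature-class correlation is the point-biserial correlation against each
one-vs-rest class indicator, averaged over classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .dualspace import FeatureMatrix

__all__ = ["LabeledDataset", "PredictionReport", "cfs_select", "crossval_rf"]


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix plus a perceptual-cluster label per molecule."""

    X: FeatureMatrix
    y: np.ndarray

    def __post_init__(self) -> None:
        if len(self.y) != self.X.values.shape[0]:
            raise ValueError("labels and feature rows misaligned")


def _class_correlations(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Mean absolute point-biserial correlation of each feature against the
    one-vs-rest indicator of every class."""
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    Xc = X - X.mean(axis=0)
    Xs = X.std(axis=0)
    out = np.zeros(X.shape[1])
    for c in classes:
        ind = (y == c).astype(float)
        ind_c = ind - ind.mean()
        s = ind.std()
        if s == 0:
            raise ValueError("zero-variance class indicator")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc * ind_c[:, None]).mean(axis=0) / (Xs * s)
        out += np.abs(np.nan_to_num(r))
    return out / classes.size


def _merit(r_cf_sel: np.ndarray, r_ff_sum: float) -> float:
    k = r_cf_sel.size
    mean_cf = r_cf_sel.mean()
    mean_ff = r_ff_sum / (k * (k - 1)) * 2 if k > 1 else 0.0
    return k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)


def cfs_select(X: FeatureMatrix | np.ndarray, y, *, max_features: int | None = None) -> list[int]:
    """Greedy forward correlation-based feature selection.

    Returns the indices of the selected features in selection order.  The
    search stops as soon as no candidate addition improves the merit.
    """
    M = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = M.shape
    r_cf = _class_correlations(M, y)
    if p == 1:
        return [0]
    max_features = max_features or p

    Z = M - M.mean(axis=0)
    sd = M.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = Z / sd  # standardized columns; corr(i,j) = Z_i . Z_j / n

    selected: list[int] = [int(np.argmax(r_cf))]
    best_merit = _merit(r_cf[selected], 0.0)
    # pair_sums[j] = sum over selected s of |corr(j, s)|
    pair_sums = np.abs(Z.T @ Z[:, selected[0]]) / n
    while len(selected) < max_features:
        cand_mask = np.ones(p, dtype=bool)
        cand_mask[selected] = False
        if not cand_mask.any():
            break
        k = len(selected) + 1
        sel_cf_sum = r_cf[selected].sum()
        # existing intra-selected correlation sum (unordered pairs)
        intra = 0.0
        for a in range(len(selected)):
            for b in range(a + 1, len(selected)):
                intra += abs(float(Z[:, selected[a]] @ Z[:, selected[b]]) / n)
        cand = np.where(cand_mask)[0]
        mean_cf = (sel_cf_sum + r_cf[cand]) / k
        ff_pairs = intra + pair_sums[cand]
        mean_ff = np.where(k > 1, ff_pairs / (k * (k - 1) / 2), 0.0)
        merits = k * mean_cf / np.sqrt(k + k * (k - 1) * mean_ff)
        j = int(cand[np.argmax(merits)])
        if merits.max() <= best_merit + 1e-12:
            break
        best_merit = float(merits.max())
        selected.append(j)
        pair_sums = pair_sums + np.abs(Z.T @ Z[:, j]) / n
    return selected


def _macro_ovr_auc(y, proba, classes) -> float:
    if classes.size == 2:
        return float(roc_auc_score(y, proba[:, 1]))
    return float(
        roc_auc_score(y, proba, multi_class="ovr", average="macro", labels=classes)
    )


@dataclass(frozen=True)
class PredictionReport:
    """Cross-validated classification performance and selected features."""

    roc_auc: float
    per_fold_auc: tuple[float, ...]
    selected_features_per_fold: tuple[tuple[str, ...], ...]
    consensus_features: tuple[str, ...]
    n_features_consensus: int
    with_selection: bool
    folds: int
    seed: int


def crossval_rf(
    data: LabeledDataset,
    folds: int = 10,
    with_selection: bool = False,
    seed: int = 0,
    *,
    n_trees: int = 500,
) -> PredictionReport:
    """Stratified k-fold random-forest evaluation.

    When ``with_selection`` is on, CFS runs on each training split only and
    the forest sees just the selected columns.  The headline number is the
    macro one-vs-rest ROC AUC over the pooled out-of-fold probabilities;
    per-fold AUCs are also reported.  Deterministic given the seed.
    """
    X = data.X.values
    y = np.asarray(data.y)
    names = data.X.feature_names
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members < {folds} folds; "
            "reduce the fold count"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    n = len(y)
    proba = np.zeros((n, classes.size))
    fold_aucs: list[float] = []
    fold_feats: list[tuple[str, ...]] = []
    for f, (tr, te) in enumerate(skf.split(X, y)):
        cols = np.arange(X.shape[1])
        if with_selection:
            cols = np.asarray(cfs_select(X[tr], y[tr]))
        rf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            random_state=seed * 1000 + f,
            n_jobs=1,
        )
        rf.fit(X[np.ix_(tr, cols)], y[tr])
        pr = rf.predict_proba(X[np.ix_(te, cols)])
        # map forest class order onto global class order
        idx = np.searchsorted(classes, rf.classes_)
        proba[np.ix_(te, idx)] = pr
        fold_feats.append(tuple(names[c] for c in cols) if with_selection else ())
        fold_aucs.append(_macro_ovr_auc(y[te], proba[te], classes))
    overall = _macro_ovr_auc(y, proba, classes)
    if with_selection:
        tally: dict[str, int] = {}
        for feats in fold_feats:
            for fname in feats:
                tally[fname] = tally.get(fname, 0) + 1
        consensus = tuple(
            sorted(fname for fname, c in tally.items() if c >= folds / 2)
        )
    else:
        consensus = tuple(names)
    return PredictionReport(
        roc_auc=overall,
        per_fold_auc=tuple(fold_aucs),
        selected_features_per_fold=tuple(fold_feats),
        consensus_features=consensus,
        n_features_consensus=len(consensus),
        with_selection=with_selection,
        folds=folds,
        seed=seed,
    )
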