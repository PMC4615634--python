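"""Feature preprocessing, similarity kernels, spectral X-means, Hubert index."""

import itertools

import numpy as np
import pandas as pd
import pytest

from odorspace import (
    SimilarityMatrix,
    hubert_index,
    local_scaled_similarity,
    perceptual_similarity,
    preprocess_features,
    spectral_xmeans,
)


def test_preprocess_drops_constant_and_missing_scales_rest():
    df = pd.DataFrame(
        {
            "good": [2.0, 4.0, 6.0],
            "const": [1.0, 1.0, 1.0],
            "holey": [1.0, np.nan, 3.0],
        },
        index=["m1", "m2", "m3"],
    )
    X = preprocess_features(df)
    assert X.feature_names == ("good",)
    assert X.values[:, 0].tolist() == [0.0, 0.5, 1.0]


def test_preprocess_dragon_shaped_table(rng):
    """A 1666-column table with 177 constant/missing columns keeps 1489."""
    n = 40
    data = {f"f{i:04d}": rng.normal(size=n) for i in range(1489)}
    for i in range(100):
        data[f"c{i:03d}"] = np.full(n, 3.14)
    for i in range(77):
        col = rng.normal(size=n)
        col[rng.integers(0, n)] = np.nan
        data[f"na{i:03d}"] = col
    df = pd.DataFrame(data)
    assert df.shape[1] == 1666
    X = preprocess_features(df)
    assert len(X.feature_names) == 1489
    assert X.values.min() >= 0.0 and X.values.max() <= 1.0


def test_preprocess_nothing_survives_errors():
    df = pd.DataFrame({"a": [1.0, 1.0], "b": [np.nan, 2.0]})
    with pytest.raises(ValueError, match="no feature columns"):
        preprocess_features(df)


def test_perceptual_similarity_shared_counts(small_matrix):
    A, _, _ = small_matrix
    S = perceptual_similarity(A)
    assert np.array_equal(S.values, S.values.T)
    for i in range(0, A.m, 17):
        for j in range(0, A.m, 23):
            shared = int((A.values[i] & A.values[j]).sum())
            assert S.values[i, j] == shared
    # identical rows -> similarity equals the set size; disjoint -> 0
    i = 0
    assert S.values[i, i] == A.values[i].sum()


def test_local_scaled_collinear_hand_case():
    from odorspace.dualspace import FeatureMatrix

    F = FeatureMatrix(
        molecule_ids=("a", "b", "c"),
        feature_names=("x",),
        values=np.array([[0.0], [1.0], [3.0]]),
    )
    S = local_scaled_similarity(F, k_neighbor=1)
    assert S.values[0, 1] == pytest.approx(np.exp(-1.0))
    assert S.values[1, 2] == pytest.approx(np.exp(-2.0))
    assert S.values[0, 2] == pytest.approx(np.exp(-4.5))
    assert np.array_equal(S.values, S.values.T)
    assert np.diag(S.values).tolist() == [1.0, 1.0, 1.0]


def test_local_scaled_duplicates_warn_not_crash():
    from odorspace.dualspace import FeatureMatrix

    F = FeatureMatrix(
        molecule_ids=("a", "b", "c"),
        feature_names=("x",),
        values=np.array([[0.0], [0.0], [1.0]]),
    )
    with pytest.warns(UserWarning, match="duplicate"):
        S = local_scaled_similarity(F, k_neighbor=1)
    assert S.values[0, 1] == 1.0


def _blob_similarity(rng, centers, n_per, spread):
    pts = np.vstack(
        [rng.normal(c, spread, size=(n_per, len(c))) for c in centers]
    )
    from odorspace.dualspace import FeatureMatrix

    F = FeatureMatrix(
        molecule_ids=tuple(f"m{i}" for i in range(len(pts))),
        feature_names=tuple(f"f{j}" for j in range(pts.shape[1])),
        values=pts,
    )
    return local_scaled_similarity(F, k_neighbor=5)


def test_spectral_xmeans_three_blobs(rng):
    S = _blob_similarity(rng, [(0, 0), (10, 0), (0, 10)], 25, 0.5)
    res = spectral_xmeans(S, k_max=8, seed=0)
    assert res.k == 3
    planted = np.repeat([0, 1, 2], 25)
    assert hubert_index(res.labels, planted).hubert_index == 1.0
    assert [k for k, _ in res.bic_trace] == list(range(1, 9))


def test_spectral_xmeans_block_diagonal():
    n = 30
    S = np.full((n, n), 0.01)
    S[:15, :15] = 1.0
    S[15:, 15:] = 1.0
    res = spectral_xmeans(
        SimilarityMatrix(ids=tuple(map(str, range(n))), values=S), k_max=6, seed=1
    )
    assert res.k == 2
    assert len(set(res.labels[:15])) == 1 and len(set(res.labels[15:])) == 1


def test_spectral_xmeans_identical_points_single_cluster():
    n = 12
    S = np.ones((n, n))
    res = spectral_xmeans(
        SimilarityMatrix(ids=tuple(map(str, range(n))), values=S), k_max=5, seed=0
    )
    assert res.k == 1
    assert set(res.labels) == {1}


def test_spectral_xmeans_deterministic(rng):
    S = _blob_similarity(rng, [(0, 0), (8, 8)], 20, 0.6)
    a = spectral_xmeans(S, k_max=6, seed=4)
    b = spectral_xmeans(S, k_max=6, seed=4)
    assert a.k == b.k and np.array_equal(a.labels, b.labels)
    assert a.bic_trace == b.bic_trace


def test_spectral_xmeans_kmax_validation(rng):
    S = _blob_similarity(rng, [(0, 0)], 10, 0.5)
    with pytest.raises(ValueError):
        spectral_xmeans(S, k_max=1)


def test_hubert_worked_example_and_anchors():
    r = hubert_index([1, 1, 2, 2], [1, 2, 1, 2])
    assert r.hubert_index == pytest.approx(2 / 6)
    assert (r.both_same, r.both_different, r.discordant) == (0, 2, 4)
    assert hubert_index([1, 2, 3], [1, 2, 3]).hubert_index == 1.0
    assert hubert_index([1, 1], [1, 2]).hubert_index == 0.0
    with pytest.raises(ValueError):
        hubert_index([1, 2], [1, 2, 3])


def test_hubert_brute_force_and_symmetry(rng):
    a = rng.integers(1, 5, size=30)
    b = rng.integers(1, 4, size=30)
    r = hubert_index(a, b)
    agree = 0
    for i, j in itertools.combinations(range(30), 2):
        same_a = a[i] == a[j]
        same_b = b[i] == b[j]
        agree += same_a == same_b
    assert r.hubert_index == pytest.approx(agree / (30 * 29 / 2))
    assert r.both_same + r.both_different + r.discordant == 30 * 29 // 2
    # symmetry and label-permutation invariance
    assert hubert_index(b, a).hubert_index == r.hubert_index
    perm = {1: 9, 2: 7, 3: 5, 4: 3}
    assert (
        hubert_index([perm[v] for v in a], b).hubert_index == r.hubert_index
    )


def test_hubert_random_partitions_near_expectation(rng):
    """HI of independent uniform partitions concentrates near the
    combinatorial expectation p_same1*p_same2 + (1-p_same1)*(1-p_same2)."""
    n, k1, k2 = 400, 4, 5
    a = rng.integers(0, k1, size=n)
    b = rng.integers(0, k2, size=n)

    def p_same(labels):
        _, counts = np.unique(labels, return_counts=True)
        tot = n * (n - 1) / 2
        return sum(c * (c - 1) / 2 for c in counts) / tot

    expect = p_same(a) * p_same(b) + (1 - p_same(a)) * (1 - p_same(b))
    r = hubert_index(a, b)
    assert r.hubert_index == pytest.approx(expect, abs=0.05)
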