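"""Curation, perceptual matrix construction, summary stats, co-occurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from odorspace import (
    CurationConfig,
    MoleculeRecord,
    build_perceptual_matrix,
    cooccurrence,
    curate_description,
    curate_records,
    matrix_stats,
)
from odorspace.curation import infer_morphological_merges


@pytest.mark.parametrize(
    "raw, config, expected",
    [
        (
            "powerful green grass somewhat fruity gassy",
            CurationConfig(merge_map={}),
            ["green", "grass", "fruity", "gassy"],
        ),
        ("", CurationConfig(), []),
        ("odorless", CurationConfig(), []),
        ("sweet odorless fruit", CurationConfig(), []),
        (
            "fruity fruit",
            CurationConfig(merge_map={"fruity": "fruit"}),
            ["fruit"],
        ),
        ("Sweet SWEET sweet", CurationConfig(), ["sweet"]),
    ],
)
def test_curate_description(raw, config, expected):
    assert curate_description(raw, config) == expected


def test_curation_is_idempotent():
    cfg = CurationConfig()
    texts = [
        "powerful green grass somewhat fruity gassy",
        "sweet alcoholic note with fruity nuances",
        "has a strong sulfur and onion odour",
    ]
    for text in texts:
        once = curate_description(text, cfg)
        twice = curate_description(" ".join(once), cfg)
        assert twice == once


def test_merge_map_chains_rejected():
    with pytest.raises(ValueError, match="chain"):
        CurationConfig(merge_map={"a": "b", "b": "c"})


def test_stoplist_merge_key_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        CurationConfig(merge_map={"like": "alike"})


def test_morphological_merges_require_existing_stem():
    merges = infer_morphological_merges([["wood", "woody"], ["spicy"], ["rose-like", "rose"]])
    assert merges == {"woody": "wood", "rose-like": "rose"}


def _records(tokens_by_id):
    return [
        MoleculeRecord(molecule_id=k, raw_description=" ".join(v), tokens=tuple(v))
        for k, v in tokens_by_id.items()
    ]


def test_build_matrix_direct_construction():
    A = build_perceptual_matrix(_records({"m1": ["a", "b"], "m2": ["b"]}))
    assert A.descriptors == ("a", "b")
    assert A.molecule_ids == ("m1", "m2")
    assert A.values.tolist() == [[1, 1], [0, 1]]


def test_build_matrix_drops_empty_molecules():
    A = build_perceptual_matrix(_records({"m1": ["a"], "m2": []}))
    assert A.molecule_ids == ("m1",)
    assert A.values.shape == (1, 1)


def test_build_matrix_empty_corpus_errors():
    with pytest.raises(ValueError, match="empty corpus"):
        build_perceptual_matrix(_records({"m1": [], "m2": []}))


def test_build_matrix_row_sums_match_token_counts(rng):
    vocab = [f"d{i}" for i in range(30)]
    tokens_by_id = {
        f"m{i}": list(rng.choice(vocab, size=rng.integers(1, 8), replace=False))
        for i in range(50)
    }
    A = build_perceptual_matrix(_records(tokens_by_id))
    for mid, row in zip(A.molecule_ids, A.values):
        assert row.sum() == len(set(tokens_by_id[mid]))


def test_matrix_stats_dense_and_identity():
    dense = build_perceptual_matrix(
        _records({"m1": ["a", "b", "c"], "m2": ["a", "b", "c"]})
    )
    s = matrix_stats(dense)
    assert (s.ap_m, s.am_p, s.sparseness_pct) == (3.0, 2.0, 0.0)

    ident = build_perceptual_matrix(_records({"m1": ["a"], "m2": ["b"], "m3": ["c"]}))
    s = matrix_stats(ident)
    assert (s.ap_m, s.am_p) == (1.0, 1.0)
    assert round(s.sparseness_pct, 2) == 66.67


def test_matrix_stats_against_double_loop(small_matrix):
    A, _, _ = small_matrix
    s = matrix_stats(A)
    total = sum(
        int(A.values[i, j]) for i in range(A.m) for j in range(A.p)
    )
    assert s.ap_m == pytest.approx(total / A.m)
    assert s.am_p == pytest.approx(total / A.p)
    assert s.sparseness_pct == pytest.approx((1 - total / (A.m * A.p)) * 100)
    # conservation: m*AP_m = p*AM_p = total ones
    assert s.ap_m * A.m == pytest.approx(s.am_p * A.p) == pytest.approx(total)


def test_cooccurrence_single_molecule():
    A = build_perceptual_matrix(_records({"m1": ["a", "b"]}))
    C = cooccurrence(A)
    assert C.counts.tolist() == [[1, 1], [1, 1]]


def test_cooccurrence_disjoint_columns():
    A = build_perceptual_matrix(_records({"m1": ["a"], "m2": ["b"], "m3": ["a"]}))
    C = cooccurrence(A)
    off = C.counts - np.diag(np.diag(C.counts))
    assert not off.any()


def test_cooccurrence_pairwise_counting_oracle(small_matrix):
    A, _, _ = small_matrix
    C = cooccurrence(A)
    # brute-force: count molecules having both descriptors
    for i in range(0, A.p, 7):
        for j in range(0, A.p, 11):
            count = sum(
                1
                for r in range(A.m)
                if A.values[r, i] and A.values[r, j]
            )
            assert C.counts[i, j] == count
    # diagonal = column sums; C symmetric PSD
    assert np.array_equal(np.diag(C.counts), A.values.sum(axis=0))
    assert np.array_equal(C.counts, C.counts.T)
    assert np.linalg.eigvalsh(C.counts.astype(float)).min() > -1e-8
    # off-diagonal bounded by min of diagonal entries
    d = np.diag(C.counts)
    assert (C.counts <= np.minimum.outer(d, d) + np.diag(d)).all()


def test_deterministic_rebuild(small_matrix):
    A, _, _ = small_matrix
    records = _records(
        {mid: [d for d, v in zip(A.descriptors, row) if v] for mid, row in zip(A.molecule_ids, A.values)}
    )
    B = build_perceptual_matrix(records)
    assert B.descriptors == A.descriptors
    assert np.array_equal(B.values, A.values)


@settings(max_examples=50, deadline=None)
@given(st.text(alphabet=st.characters(whitelist_categories=("Ll", "Zs")), max_size=80))
def test_curation_never_returns_stopwords_or_duplicates(raw):
    cfg = CurationConfig()
    out = curate_description(raw, cfg)
    assert len(out) == len(set(out))
    assert not set(out) & cfg.stoplist


def test_curate_records_table_roundtrip():
    table = pd.DataFrame(
        {
            "molecule_id": ["1-2-3", "4-5-6", "7-8-9"],
            "description": [
                "powerful green grass somewhat fruity gassy",
                "odorless",
                "sweet alcoholic",
            ],
        }
    )
    recs = curate_records(table, CurationConfig())
    assert recs[0].tokens == ("green", "grass", "fruit", "gassy")
    assert recs[1].tokens == ()
    assert recs[2].tokens == ("sweet", "alcohol")


def test_curate_records_rejects_duplicate_ids():
    table = pd.DataFrame(
        {"molecule_id": ["x", "x"], "description": ["sweet", "sour"]}
    )
    with pytest.raises(ValueError, match="duplicate"):
        curate_records(table)
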