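"""Dataset builder: feature matrices, dedup, normalization, cross-join,
oversampling — including the hand-computed two-knowledgebase toy."""

import math

import numpy as np
import pytest
from scipy import sparse

from pathcolor.chem import CompoundRecord, PathwayRecord
from pathcolor.dataset import (FeatureMatrix, PairDataset,
                               aggregate_pathway_features,
                               build_compound_matrix, build_dataset,
                               cross_join, dedup, normalize,
                               oversample_positives, softmax_rows)

COLS = ["ca", "cb", "cc", "cd"]


def matrix_from_counts(entity_class, rows, metas):
    X = sparse.csr_matrix(np.asarray(rows, dtype=np.int64))
    return FeatureMatrix(entity_class, X,
                         [frozenset(m) for m in metas],
                         [(c,) for c in COLS])


@pytest.fixture
def toy():
    """Two KBs, five compounds, three pathways; c1 and c2 duplicate rows,
    columns cb and cd identical everywhere.

    counts:        ca  cb  cc  cd
      KB1 c1        1   0   0   0
      KB1 c2        1   0   0   0      (duplicate of c1)
      KB1 c3        2   1   0   1
      KB2 c4        0   1   1   1
      KB2 c5        1   0   2   0
    pathways: p1 = {c1, c2}; p2 = {c3} (KB1); p3 = {c4, c5} (KB2)
    """
    compounds = matrix_from_counts(
        "compound",
        [[1, 0, 0, 0], [1, 0, 0, 0], [2, 1, 0, 1], [0, 1, 1, 1],
         [1, 0, 2, 0]],
        [{("KB1", "c1")}, {("KB1", "c2")}, {("KB1", "c3")},
         {("KB2", "c4")}, {("KB2", "c5")}])
    pathway_records = [
        PathwayRecord("p1", "KB1", {"c1", "c2"}),
        PathwayRecord("p2", "KB1", {"c3"}),
        PathwayRecord("p3", "KB2", {"c4", "c5"}),
    ]
    annotations = [("KB1", "c1", "p1"), ("KB1", "c2", "p1"),
                   ("KB1", "c3", "p2"), ("KB2", "c4", "p3"),
                   ("KB2", "c5", "p3")]
    return compounds, pathway_records, annotations


class TestToyWorkedExample:

    def test_pathway_rows_are_member_sums(self, toy):
        compounds, pathways, _ = toy
        pmat = aggregate_pathway_features(pathways, compounds)
        assert pmat.X.toarray().tolist() == [
            [2, 0, 0, 0],      # p1 = c1 + c2
            [2, 1, 0, 1],      # p2 = c3
            [1, 1, 3, 1],      # p3 = c4 + c5
        ]

    def test_dedup_merges_duplicate_row_and_column(self, toy):
        compounds, _, _ = toy
        dc = dedup(compounds)
        assert dc.n_rows == 4
        assert dc.row_meta[0] == frozenset({("KB1", "c1"), ("KB1", "c2")})
        # columns cb and cd are identical -> merged, representative kept
        assert dc.n_cols == 3
        assert dc.col_meta == [("ca",), ("cb", "cd"), ("cc",)]
        assert dc.X.toarray().tolist() == [
            [1, 0, 0], [2, 1, 0], [0, 1, 1], [1, 0, 2]]

    def test_dedup_is_identity_on_unique_matrix(self, toy):
        compounds, _, _ = toy
        dc = dedup(compounds)
        again = dedup(dc)
        assert again.X.toarray().tolist() == dc.X.toarray().tolist()
        assert again.row_meta == dc.row_meta

    def test_normalized_values_hand_computed(self, toy):
        compounds, _, _ = toy
        nc = normalize(dedup(compounds))
        # softmax of deduped rows over 3 columns, computed by the formula
        raw = np.array([[1, 0, 0], [2, 1, 0], [0, 1, 1], [1, 0, 2]],
                       dtype=float)
        e = np.exp(raw - raw.max(axis=1, keepdims=True))
        S = e / e.sum(axis=1, keepdims=True)
        lo, hi = S.min(axis=0), S.max(axis=0)
        expected = (S - lo) / (hi - lo)
        assert np.allclose(nc.X, expected, atol=1e-15)
        # every non-constant column attains 0 and 1 exactly
        assert np.allclose(nc.X.min(axis=0), 0)
        assert np.allclose(nc.X.max(axis=0), 1)

    def test_pair_count_is_blockwise_product_sum(self, toy):
        compounds, pathways, annotations = toy
        comp = normalize(dedup(compounds))
        path = normalize(dedup(aggregate_pathway_features(pathways,
                                                          compounds)))
        pairs = cross_join(comp, path, annotations)
        # KB1: 2 compound rows x 2 pathway rows; KB2: 2 x 1
        assert pairs.n_pairs == 2 * 2 + 2 * 1 == 6

    def test_positive_set_exact(self, toy):
        compounds, pathways, annotations = toy
        comp = normalize(dedup(compounds))
        path = normalize(dedup(aggregate_pathway_features(pathways,
                                                          compounds)))
        pairs = cross_join(comp, path, annotations)
        # rows: 0={c1,c2} 1={c3} 2={c4} 3={c5}; pathways: 0=p1 1=p2 2=p3
        assert pairs.positives == frozenset(
            {(0, 0), (1, 1), (2, 2), (3, 2)})
        idx = pairs.valid_indices()
        assert pairs.labels(idx).sum() == 4

    def test_no_pair_without_shared_kb_witness(self, toy):
        compounds, pathways, annotations = toy
        comp = normalize(dedup(compounds))
        path = normalize(dedup(aggregate_pathway_features(pathways,
                                                          compounds)))
        pairs = cross_join(comp, path, annotations)
        for g in pairs.valid_indices():
            assert pairs.kb_witnesses(int(g)), f"pair {g} lacks a witness"


def test_softmax_of_zero_and_ln2_is_thirds():
    out = softmax_rows(np.array([[0.0, math.log(2.0)]]))
    assert out[0] == pytest.approx([1 / 3, 2 / 3], abs=1e-15)


def test_softmax_of_zero_row_is_uniform():
    out = softmax_rows(np.zeros((1, 5)))
    assert np.allclose(out, 0.2)


def test_double_normalization_rejected(toy):
    compounds, _, _ = toy
    nc = normalize(dedup(compounds))
    with pytest.raises(ValueError, match="already normalized"):
        normalize(nc)


def test_pathway_sums_use_raw_counts_not_normalized(toy):
    compounds, pathways, _ = toy
    with pytest.raises(ValueError, match="raw"):
        aggregate_pathway_features(pathways, normalize(dedup(compounds)))


def test_empty_compound_list_rejected():
    with pytest.raises(ValueError):
        build_compound_matrix([])


class TestOversampling:

    def test_ten_positives_ninety_five_negatives(self):
        idx = np.arange(105)
        labels = np.array([1] * 10 + [0] * 95)
        sampled = oversample_positives(idx, labels)
        pos_count = sum(1 for i in sampled if labels[i] == 1)
        assert pos_count == 100  # k = round(95/10) = 10
        assert sum(1 for i in sampled if labels[i] == 0) == 95

    def test_balanced_input_unchanged(self):
        idx = np.arange(10)
        labels = np.array([1] * 5 + [0] * 5)
        assert sorted(oversample_positives(idx, labels)) == sorted(idx)

    def test_three_positives_four_negatives_k_one(self):
        idx = np.arange(7)
        labels = np.array([1, 1, 1, 0, 0, 0, 0])
        assert len(oversample_positives(idx, labels)) == 7

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            oversample_positives(np.arange(3), np.array([0, 0, 0]))


def test_row_meta_conservation_through_dedup(molecule_batch, small_kb):
    raw = build_compound_matrix(small_kb.all_compounds())
    deduped = dedup(raw)
    assert sum(len(m) for m in deduped.row_meta) == raw.n_rows


def test_pipeline_is_deterministic(small_kb):
    a = build_dataset(small_kb.all_compounds(), small_kb.all_pathways())
    b = build_dataset(small_kb.all_compounds(), small_kb.all_pathways())
    assert a.fingerprint() == b.fingerprint()
    assert a.positives == b.positives
    assert np.array_equal(a.valid_indices(), b.valid_indices())


def test_blocks_are_kb_restricted(small_kb):
    pairs = build_dataset(small_kb.all_compounds(), small_kb.all_pathways())
    for blk in pairs.blocks:
        for i in blk.compound_rows:
            assert blk.kb in pairs.compounds.kbs_of_row(int(i))
        for j in blk.pathway_rows:
            assert blk.kb in pairs.pathways.kbs_of_row(int(j))
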