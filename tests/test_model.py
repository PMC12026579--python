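"""Pair MLP classifier: learning, determinism, thresholding, projection,
and the memory-bounded batching contract."""

import tracemalloc

import numpy as np
import pytest

from pathcolor.coloring import ColoringConfig
from pathcolor.dataset import (build_dataset, cross_join, normalize, dedup,
                               oversample_positives)
from pathcolor.evaluate import ConfusionCounts, mcc
from pathcolor.mlp import (MLPConfig, PairMLPClassifier, TrainedModel,
                           project_new_compound, train)
from pathcolor.standardize import StandardizationConfig
from pathcolor.synth import SyntheticConfig, generate

TINY_MLP = MLPConfig(hidden_sizes=(64,), batch_size=128, max_epochs=200,
                     early_stop_patience=200, learning_rate=3e-3, seed=0)


@pytest.fixture(scope="module")
def tiny_pairs():
    """2 KBs x 20 compounds x 4 pathways, noise-free: a linearly separable
    motif-detection task the MLP must be able to overfit exactly."""
    kb = generate(SyntheticConfig(n_kbs=2, compounds_per_kb=20,
                                  pathways_per_kb=4, membership_noise=0.0,
                                  crossref_fraction=0.0, seed=5))
    return build_dataset(kb.all_compounds(), kb.all_pathways(),
                         coloring=ColoringConfig(max_rounds=1))


def test_overfits_noise_free_motif_task_to_mcc_one(tiny_pairs):
    idx = tiny_pairs.valid_indices()
    y = tiny_pairs.labels(idx)
    model = train(tiny_pairs, oversample_positives(idx, y), TINY_MLP)
    y_pred = model.predict_pairs(tiny_pairs, idx)
    assert mcc(ConfusionCounts.from_predictions(y, y_pred)) == 1.0


def test_same_seed_reproduces_loss_curve(tiny_pairs):
    idx = tiny_pairs.valid_indices()
    y = tiny_pairs.labels(idx)
    sampled = oversample_positives(idx, y)
    cfg = MLPConfig(hidden_sizes=(32,), batch_size=128, max_epochs=3,
                    early_stop_patience=3, seed=42)
    m1 = train(tiny_pairs, sampled, cfg)
    m2 = train(tiny_pairs, sampled, cfg)
    assert m1.classifier.loss_curve_[0] == m2.classifier.loss_curve_[0]
    assert m1.classifier.loss_curve_ == m2.classifier.loss_curve_


def test_single_class_training_set_rejected(tiny_pairs):
    idx = tiny_pairs.valid_indices()
    y = tiny_pairs.labels(idx)
    negatives = idx[y == 0][:50]
    with pytest.raises(ValueError, match="single class"):
        train(tiny_pairs, negatives, TINY_MLP)


class TestThresholding:

    @pytest.fixture()
    def fitted(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 4)).astype(np.float32)
        y = (X[:, 0] > 0).astype(int)
        clf = PairMLPClassifier(hidden_sizes=(16,), max_epochs=30,
                                early_stop_patience=30, seed=1)
        return clf.fit(X, y), X

    def test_label_is_probability_at_least_threshold(self, fitted):
        clf, X = fitted
        p = clf.predict_proba(X)[:, 1]
        labels = clf.predict(X)
        assert np.array_equal(labels, (p >= 0.5).astype(np.int8))

    def test_probability_exactly_at_threshold_is_positive(self, fitted):
        clf, _ = fitted
        clf.threshold_ = 0.25
        X = np.zeros((1, 4), dtype=np.float32)
        p = clf.predict_proba(X)[0, 1]
        clf.threshold_ = float(p)
        assert clf.predict(X)[0] == 1

    def test_auto_threshold_requires_training_prior(self):
        cfg = MLPConfig(decision_threshold="auto")
        clf = PairMLPClassifier(decision_threshold="auto")
        clf.classes_ = np.array([0, 1])
        with pytest.raises(ValueError, match="auto"):
            _ = clf.effective_threshold

    def test_width_mismatch_rejected(self, fitted):
        clf, _ = fitted
        with pytest.raises(ValueError, match="width"):
            clf.predict(np.zeros((1, 7), dtype=np.float32))


def test_batch_size_invariance_of_predictions(tiny_pairs):
    idx = tiny_pairs.valid_indices()
    y = tiny_pairs.labels(idx)
    model = train(tiny_pairs, oversample_positives(idx, y), TINY_MLP)
    one = model.classifier.predict_pairs(tiny_pairs, idx, batch_size=1)
    big = model.classifier.predict_pairs(tiny_pairs, idx, batch_size=4096)
    assert np.array_equal(one, big)


def test_fingerprint_guard_on_foreign_dataset(tiny_pairs):
    idx = tiny_pairs.valid_indices()
    y = tiny_pairs.labels(idx)
    model = train(tiny_pairs, oversample_positives(idx, y), TINY_MLP)
    other = tiny_pairs.restrict_to_kb(tiny_pairs.blocks[0].kb)
    with pytest.raises(ValueError, match="fingerprint"):
        model.predict_pairs(other, other.valid_indices()[:5])
    # explicit override allowed for projected inputs
    model.predict_pairs(other, other.valid_indices()[:5],
                        override_fingerprint=True)


def test_training_memory_does_not_scale_with_pair_count():
    """Peak traced allocation during an epoch stays flat when the pair
    count grows ~8x at fixed batch size."""
    cfgs = [(30, 4), (90, 10)]  # ~small and ~8x pairs
    peaks = []
    for n_comp, n_path in cfgs:
        kb = generate(SyntheticConfig(n_kbs=2, compounds_per_kb=n_comp,
                                      pathways_per_kb=n_path,
                                      crossref_fraction=0.0, seed=9))
        pairs = build_dataset(kb.all_compounds(), kb.all_pathways(),
                              coloring=ColoringConfig(max_rounds=1))
        idx = pairs.valid_indices()
        y = pairs.labels(idx)
        cfg = MLPConfig(hidden_sizes=(16,), batch_size=64, max_epochs=1,
                        early_stop_patience=1, seed=0)
        tracemalloc.start()
        train(pairs, oversample_positives(idx, y), cfg)
        _, peak = tracemalloc.get_traced_memory()
        tracemalloc.stop()
        peaks.append(peak)
    assert peaks[1] < 3 * peaks[0], peaks


class TestProjection:

    @pytest.fixture(scope="class")
    def setup(self):
        kb = generate(SyntheticConfig(n_kbs=2, compounds_per_kb=20,
                                      pathways_per_kb=5, seed=6))
        coloring = ColoringConfig(max_rounds=1)
        pairs = build_dataset(kb.all_compounds(), kb.all_pathways(),
                              coloring=coloring)
        return kb, pairs, coloring

    def test_training_compound_projects_to_its_stored_row(self, setup):
        kb, pairs, coloring = setup
        comp = kb.all_compounds()[3]
        row_idx = pairs.compounds.row_index()[(comp.source_kb,
                                               comp.compound_id)]
        row, oov = project_new_compound(comp.graph, pairs.compounds,
                                        coloring,
                                        StandardizationConfig.none())
        assert oov == 0.0
        assert np.allclose(row, pairs.compounds.X[row_idx], atol=1e-12)

    def test_fully_unseen_molecule_reports_total_oov(self, setup, benzene):
        _, pairs, coloring = setup
        row, oov = project_new_compound(benzene, pairs.compounds, coloring,
                                        StandardizationConfig.none())
        # no synthetic molecule contains a bare benzene environment
        assert oov == 1.0
        assert row.shape == (pairs.compounds.n_cols,)
        assert np.all((0 <= row) & (row <= 1))

    def test_reordered_twin_projects_identically(self, setup):
        kb, pairs, coloring = setup
        from pathcolor.synth import perturb_representation
        comp = kb.all_compounds()[0]
        twin = perturb_representation(comp.graph, "atom_reorder")
        a, _ = project_new_compound(comp.graph, pairs.compounds, coloring,
                                    StandardizationConfig.none())
        b, _ = project_new_compound(twin, pairs.compounds, coloring,
                                    StandardizationConfig.none())
        assert np.array_equal(a, b)
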