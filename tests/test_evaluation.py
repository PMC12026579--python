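"""Metrics, stratified CV splits, per-KB tallies, cross-KB and
cross-reference analyses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathcolor.coloring import ColoringConfig
from pathcolor.dataset import build_dataset, oversample_positives
from pathcolor.evaluate import (ConfusionCounts, CVConfig, all_metrics,
                                companion_metrics, cross_kb_eval,
                                cross_reference_analysis, mcc, run_cv,
                                stratified_cv_splits)
from pathcolor.mlp import MLPConfig, train
from pathcolor.standardize import StandardizationConfig
from pathcolor.synth import SyntheticConfig, generate

FAST_MLP = MLPConfig(hidden_sizes=(32,), batch_size=256, max_epochs=25,
                     early_stop_patience=25, learning_rate=3e-3, seed=0)


class TestMCC:

    def test_perfect_prediction(self):
        assert mcc(ConfusionCounts(tp=5, tn=5, fp=0, fn=0)) == 1.0

    def test_chance_level(self):
        assert mcc(ConfusionCounts(1, 1, 1, 1)) == 0.0

    def test_worked_example_five_twelfths(self):
        assert mcc(ConfusionCounts(tp=2, tn=3, fp=1, fn=1)) == \
            pytest.approx(5 / 12)

    def test_zero_denominator_convention(self):
        assert mcc(ConfusionCounts(tp=0, tn=10, fp=0, fn=0)) == 0.0
        assert mcc(ConfusionCounts(tp=3, tn=0, fp=0, fn=0)) == 0.0


class TestCompanionMetrics:

    def test_all_perfect(self):
        m = companion_metrics(ConfusionCounts(5, 5, 0, 0))
        assert m == {"f1": 1.0, "precision": 1.0, "recall": 1.0,
                     "accuracy": 1.0}

    def test_degenerate_all_negative(self):
        m = companion_metrics(ConfusionCounts(0, 10, 0, 0))
        assert (m["precision"], m["recall"], m["f1"]) == (0.0, 0.0, 0.0)
        assert m["accuracy"] == 1.0

    def test_worked_example(self):
        m = companion_metrics(ConfusionCounts(2, 3, 1, 1))
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f1"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(5 / 7)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.tuples(*[st.integers(0, 500)] * 4))
def test_metrics_match_direct_formulas(quad):
    tp, tn, fp, fn = quad
    c = ConfusionCounts(tp, tn, fp, fn)
    num = tp * tn - fp * fn
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    expected = 0.0 if den == 0 else num / math.sqrt(den)
    assert mcc(c) == pytest.approx(expected, abs=1e-12)
    m = companion_metrics(c)
    assert m["precision"] == (tp / (tp + fp) if tp + fp else 0.0)
    assert m["recall"] == (tp / (tp + fn) if tp + fn else 0.0)


def test_mcc_agrees_with_sklearn_on_expanded_vectors():
    from sklearn.metrics import matthews_corrcoef
    rng = np.random.default_rng(0)
    for _ in range(50):
        tp, tn, fp, fn = rng.integers(0, 30, size=4)
        if tp + tn + fp + fn == 0:
            continue
        y_true = np.array([1] * (tp + fn) + [0] * (tn + fp))
        y_pred = np.array([1] * tp + [0] * fn + [0] * tn + [1] * fp)
        ours = mcc(ConfusionCounts(int(tp), int(tn), int(fp), int(fn)))
        assert ours == pytest.approx(matthews_corrcoef(y_true, y_pred),
                                     abs=1e-12)


class TestStratifiedSplits:

    def test_partition_and_size(self):
        y = np.array([1] * 100 + [0] * 900)
        splits = stratified_cv_splits(y, CVConfig(3, 10, 0))
        assert len(splits) == 3
        for tr, te in splits:
            assert len(te) == 100
            assert set(tr) | set(te) == set(range(1000))
            assert not set(tr) & set(te)

    def test_test_fold_positive_rate_matches_global(self):
        y = np.array([1] * 100 + [0] * 900)
        for tr, te in stratified_cv_splits(y, CVConfig(5, 10, 0)):
            assert abs(y[te].sum() - 10) <= 1

    def test_iterations_use_different_seeds(self):
        y = np.array([1] * 50 + [0] * 450)
        splits = stratified_cv_splits(y, CVConfig(2, 10, 0))
        assert set(splits[0][1].tolist()) != set(splits[1][1].tolist())

    def test_too_few_positives_raises(self):
        y = np.array([1] * 3 + [0] * 97)
        with pytest.raises(ValueError, match="smaller"):
            stratified_cv_splits(y, CVConfig(1, 10, 0))


@pytest.fixture(scope="module")
def small_pairs(small_kb):
    return build_dataset(small_kb.all_compounds(), small_kb.all_pathways(),
                         coloring=ColoringConfig(max_rounds=1))


class TestRunCV:

    def test_report_rows_and_aggregates(self, small_pairs):
        rep = run_cv(small_pairs, FAST_MLP, CVConfig(2, 5, 0))
        assert len(rep.per_iteration) == 2
        mccs = [m["mcc"] for m in rep.per_iteration]
        agg = rep.aggregate("mcc")
        assert agg["mean"] == pytest.approx(np.mean(mccs))
        assert agg["median"] == pytest.approx(np.median(mccs))

    def test_per_kb_counts_partition_overall(self, small_pairs):
        rep = run_cv(small_pairs, FAST_MLP, CVConfig(1, 5, 0))
        summed = ConfusionCounts()
        for c in rep.per_kb_counts.values():
            summed = summed + c
        multi = sum(1 for m in small_pairs.compounds.row_meta
                    if len({kb for kb, _ in m}) > 1)
        if multi == 0:
            o = rep.overall_counts
            assert (summed.tp, summed.tn, summed.fp, summed.fn) == \
                (o.tp, o.tn, o.fp, o.fn)

    def test_same_seed_reproduces_report(self, small_pairs):
        r1 = run_cv(small_pairs, FAST_MLP, CVConfig(1, 5, 3))
        r2 = run_cv(small_pairs, FAST_MLP, CVConfig(1, 5, 3))
        assert r1.per_iteration == r2.per_iteration


def test_cross_kb_requires_two_knowledgebases(small_pairs):
    solo = small_pairs.restrict_to_kb(small_pairs.blocks[0].kb)
    with pytest.raises(ValueError, match="at least 2"):
        cross_kb_eval(solo, FAST_MLP)


def test_identical_twin_kbs_transfer_like_self(tmp_path):
    """Cross-KB evaluation on two byte-identical KBs: the off-diagonal MCC
    matches held-in performance closely (symmetry limit)."""
    kb = generate(SyntheticConfig(n_kbs=2, compounds_per_kb=30,
                                  pathways_per_kb=6, crossref_fraction=0.0,
                                  disjoint_kb_motifs=False,
                                  membership_noise=0.0, seed=13))
    # make KB2 an exact copy of KB1 (ids re-homed)
    from pathcolor.chem import CompoundRecord, PathwayRecord
    comps, paths = [], []
    for c in kb.compounds["KB1"]:
        comps.append(CompoundRecord(c.compound_id, "KB1", c.graph,
                                    set(c.pathway_ids)))
        comps.append(CompoundRecord(c.compound_id.replace("KB1", "KB2"),
                                    "KB2", c.graph,
                                    {p.replace("KB1", "KB2")
                                     for p in c.pathway_ids}))
    for p in kb.pathways["KB1"]:
        paths.append(PathwayRecord(p.pathway_id, "KB1",
                                   set(p.member_compound_ids)))
        paths.append(PathwayRecord(p.pathway_id.replace("KB1", "KB2"), "KB2",
                                   {m.replace("KB1", "KB2")
                                    for m in p.member_compound_ids}))
    pairs = build_dataset(comps, paths, coloring=ColoringConfig(max_rounds=1))
    out = cross_kb_eval(pairs, FAST_MLP, seed=0)
    # the two KBs collapse to the same merged rows, so the two transfer
    # directions are the same computation and transfer stays strong
    assert out["KB1"]["KB2"] == pytest.approx(out["KB2"]["KB1"], abs=1e-9)
    assert out["KB1"]["KB2"] > 0.4


class TestCrossReference:

    def test_identity_crossref_yields_zero_difference(self, small_kb,
                                                      small_pairs):
        idx = small_pairs.valid_indices()
        y = small_pairs.labels(idx)
        model = train(small_pairs, oversample_positives(idx, y), FAST_MLP,
                      train_prior=float(y.mean()))
        graphs = {(c.source_kb, c.compound_id): c.graph
                  for c in small_kb.all_compounds()}

        class Identity:
            def __init__(self, kb, cid):
                self.kb_a = self.kb_b = kb
                self.compound_id_a = self.compound_id_b = cid

        xrefs = [Identity(c.source_kb, c.compound_id)
                 for c in small_kb.all_compounds()[:30]]
        rep = cross_reference_analysis(
            model, small_pairs, xrefs, graphs,
            coloring=ColoringConfig(max_rounds=1),
            std=StandardizationConfig.none())
        assert rep.mcc_difference == 0.0
        assert rep.n_identical_feature_pairs == rep.n_pairs == 30

    def test_empty_crossref_table_rejected(self, small_pairs):
        with pytest.raises(ValueError, match="empty"):
            cross_reference_analysis(None, small_pairs, [], {})

    def test_unresolvable_pairs_skipped_with_manifest(self, small_kb,
                                                      small_pairs):
        idx = small_pairs.valid_indices()
        y = small_pairs.labels(idx)
        model = train(small_pairs, oversample_positives(idx, y), FAST_MLP,
                      train_prior=float(y.mean()))
        graphs = {(c.source_kb, c.compound_id): c.graph
                  for c in small_kb.all_compounds()}

        class X:
            kb_a, compound_id_a = "KB1", "KB1_C0000"
            kb_b, compound_id_b = "KB9", "missing"

        class Good:
            def __init__(self, c):
                self.kb_a = self.kb_b = c.source_kb
                self.compound_id_a = self.compound_id_b = c.compound_id

        rep = cross_reference_analysis(
            model, small_pairs, [X(), Good(small_kb.all_compounds()[0])],
            graphs, coloring=ColoringConfig(max_rounds=1),
            std=StandardizationConfig.none())
        assert rep.n_pairs == 1
        assert len(rep.skipped) == 1
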