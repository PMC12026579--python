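"""Cross-validation, confusion-count metrics, per- and cross-knowledgebase
evaluation, and the cross-reference prediction-consistency analysis.

Matthews correlation coefficient (MCC) is the primary metric throughout:
with the extreme class imbalance of compound-pathway pairs it is the only
one of the reported metrics that rewards all four confusion cells.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .chem import MolecularGraph
from .coloring import ColoringConfig, featurize
from .dataset import PairDataset, oversample_positives
from .mlp import MLPConfig, TrainedModel, project_new_compound, train
from .standardize import StandardizationConfig, standardize

logger = logging.getLogger(__name__)


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @staticmethod
    def from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                         ) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return ConfusionCounts(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))))


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    num = c.tp * c.tn - c.fp * c.fn
    den = ((c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn))
    if den == 0:
        return 0.0
    return num / math.sqrt(den)


def companion_metrics(c: ConfusionCounts) -> dict[str, float]:
    """F1, precision, recall, accuracy with the 0/0 → 0 convention."""
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) else 0.0)
    accuracy = (c.tp + c.tn) / c.total if c.total else 0.0
    return {"f1": f1, "precision": precision, "recall": recall,
            "accuracy": accuracy}


def all_metrics(c: ConfusionCounts) -> dict[str, float]:
    out = {"mcc": mcc(c)}
    out.update(companion_metrics(c))
    return out


@dataclass(frozen=True)
class CVConfig:
    n_iterations: int = 100
    k: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be at least 2")


def stratified_cv_splits(labels: np.ndarray, cv: CVConfig = CVConfig(),
                         ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independent label-stratified train/test splits.

    Each iteration i builds a fresh k-fold partition seeded with seed+i and
    tests exactly one fold, so test sets of different iterations are
    independent draws of size ~1/k.
    """
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    if n_pos < cv.k or (len(labels) - n_pos) < cv.k:
        raise ValueError(
            f"only {min(n_pos, len(labels) - n_pos)} samples in the rarer "
            f"class; use k smaller than that")
    splits = []
    idx = np.arange(len(labels))
    for i in range(cv.n_iterations):
        skf = StratifiedKFold(n_splits=cv.k, shuffle=True,
                              random_state=(cv.seed + i) % (2 ** 31))
        train_pos, test_pos = next(iter(skf.split(idx, labels)))
        splits.append((idx[train_pos], idx[test_pos]))
    return splits


@dataclass
class EvalReport:
    per_iteration: list[dict[str, float]]
    per_kb_counts: dict[str, ConfusionCounts]
    overall_counts: ConfusionCounts
    config_stamp: dict

    def aggregate(self, metric: str = "mcc") -> dict[str, float]:
        vals = np.array([m[metric] for m in self.per_iteration])
        return {"mean": float(vals.mean()),
                "median": float(np.median(vals)),
                "stdev": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}

    def per_kb_metrics(self) -> dict[str, dict[str, float]]:
        return {kb: all_metrics(c) for kb, c in self.per_kb_counts.items()}


def run_cv(pairs: PairDataset, model_config: MLPConfig = MLPConfig(),
           cv: CVConfig = CVConfig()) -> EvalReport:
    """CV protocol: per iteration, oversample positives in the train fold,
    train the MLP, predict the held-out fold, tally confusion counts overall
    and per knowledgebase (a pair counts toward every KB witnessed by both
    of its rows)."""
    indices = pairs.valid_indices()
    y = pairs.labels(indices)
    splits = stratified_cv_splits(y, cv)
    per_iteration = []
    per_kb: dict[str, ConfusionCounts] = {}
    overall = ConfusionCounts()
    for it, (train_pos, test_pos) in enumerate(splits):
        train_idx = indices[train_pos]
        test_idx = indices[test_pos]
        try:
            sampled = oversample_positives(train_idx, y[train_pos])
            cfg = MLPConfig(**{**model_config.__dict__,
                               "seed": (model_config.seed + it) % (2 ** 31)})
            model = train(pairs, sampled, cfg,
                          train_prior=float(y[train_pos].mean()))
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(f"CV iteration {it} failed: {exc}") from exc
        y_pred = model.predict_pairs(pairs, test_idx)
        y_true = y[test_pos]
        counts = ConfusionCounts.from_predictions(y_true, y_pred)
        per_iteration.append(all_metrics(counts))
        overall = overall + counts
        for g, t, p in zip(test_idx, y_true, y_pred):
            cell = ConfusionCounts(tp=int(t == 1 and p == 1),
                                   tn=int(t == 0 and p == 0),
                                   fp=int(t == 0 and p == 1),
                                   fn=int(t == 1 and p == 0))
            for kb in pairs.kb_witnesses(int(g)):
                per_kb[kb] = per_kb.get(kb, ConfusionCounts()) + cell
        logger.info("CV iteration %d: MCC %.4f", it, per_iteration[-1]["mcc"])
    stamp = {"model": model_config.__dict__, "cv": cv.__dict__}
    return EvalReport(per_iteration, per_kb, overall, stamp)


def cross_kb_eval(pairs: PairDataset, model_config: MLPConfig = MLPConfig(),
                  holdout_k: int = 10, seed: int = 0,
                  ) -> dict[str, dict[str, float]]:
    """MCC matrix over (train KB, test KB).

    Off-diagonal cells train on all of the train KB's pairs and test on all
    of the test KB's pairs. Diagonal cells are held-out sanity values: one
    stratified 1/holdout_k fold of the KB is kept out of training and
    tested.
    """
    kbs = sorted({b.kb for b in pairs.blocks})
    if len(kbs) < 2:
        raise ValueError("cross-KB evaluation requires at least 2 "
                         "knowledgebases")
    sub = {kb: pairs.restrict_to_kb(kb) for kb in kbs}
    sub_idx = {kb: sub[kb].valid_indices() for kb in kbs}
    sub_y = {kb: sub[kb].labels(sub_idx[kb]) for kb in kbs}
    out: dict[str, dict[str, float]] = {kb: {} for kb in kbs}
    for train_kb in kbs:
        ds = sub[train_kb]
        idx, y = sub_idx[train_kb], sub_y[train_kb]
        # full-KB model for off-diagonal prediction
        full_model = train(ds, oversample_positives(idx, y), model_config,
                           train_prior=float(y.mean()))
        for test_kb in kbs:
            if test_kb == train_kb:
                skf = StratifiedKFold(n_splits=holdout_k, shuffle=True,
                                      random_state=seed)
                tr, te = next(iter(skf.split(idx, y)))
                held_model = train(
                    ds, oversample_positives(idx[tr], y[tr]), model_config,
                    train_prior=float(y[tr].mean()))
                y_pred = held_model.predict_pairs(ds, idx[te])
                counts = ConfusionCounts.from_predictions(y[te], y_pred)
            else:
                tds = sub[test_kb]
                y_pred = full_model.predict_pairs(
                    tds, sub_idx[test_kb], override_fingerprint=True)
                counts = ConfusionCounts.from_predictions(
                    sub_y[test_kb], y_pred)
            out[train_kb][test_kb] = mcc(counts)
    return out


@dataclass
class CrossRefReport:
    train_counts: ConfusionCounts
    crossref_counts: ConfusionCounts
    n_pairs: int
    n_identical_feature_pairs: int
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def train_mcc(self) -> float:
        return mcc(self.train_counts)

    @property
    def crossref_mcc(self) -> float:
        return mcc(self.crossref_counts)

    @property
    def mcc_difference(self) -> float:
        return self.train_mcc - self.crossref_mcc


def cross_reference_analysis(
        model: TrainedModel,
        pairs: PairDataset,
        crossrefs: Sequence,   # objects with kb_a/compound_id_a/kb_b/compound_id_b
        graphs_b: dict[tuple[str, str], MolecularGraph],
        coloring: ColoringConfig = ColoringConfig(),
        std: StandardizationConfig = StandardizationConfig.none(),
        ) -> CrossRefReport:
    """Prediction consistency between training compounds and their
    cross-references.

    For each pair, the first compound's pathway predictions (over its KB's
    pathway rows, with its known labels) are evaluated twice: once from its
    stored feature row and once from the second compound's structure
    projected into the same feature space. Identical raw atom-color count
    vectors of the two members are tallied separately.
    """
    if not crossrefs:
        raise ValueError("empty cross-reference table")
    comp_idx = pairs.compounds.row_index()
    train_counts = ConfusionCounts()
    xref_counts = ConfusionCounts()
    n_identical = 0
    n_used = 0
    skipped: list[tuple[str, str]] = []
    block_by_kb = {b.kb: b for b in pairs.blocks}
    for x in crossrefs:
        key_a = (x.kb_a, x.compound_id_a)
        ci = comp_idx.get(key_a)
        blk = block_by_kb.get(x.kb_a)
        key_b = (x.kb_b, x.compound_id_b)
        graph_b = graphs_b.get(key_b)
        if ci is None or blk is None or graph_b is None:
            skipped.append((f"{x.kb_a}:{x.compound_id_a}",
                            f"{x.kb_b}:{x.compound_id_b}"))
            continue
        graph_a = graphs_b.get(key_a)
        prow_idx = blk.pathway_rows
        y_true = np.array([1 if (ci, int(pj)) in pairs.positives else 0
                           for pj in prow_idx], dtype=np.int8)
        P = pairs.pathways.X[prow_idx]
        P = P if isinstance(P, np.ndarray) else P.toarray()
        crow = pairs.compounds.X[ci]
        crow = crow if isinstance(crow, np.ndarray) else crow.toarray().ravel()
        _, labels_a = model.predict_rows(crow, P)
        proj, _oov = project_new_compound(graph_b, pairs.compounds,
                                         coloring, std)
        _, labels_b = model.predict_rows(proj, P)
        train_counts = train_counts + ConfusionCounts.from_predictions(
            y_true, labels_a)
        xref_counts = xref_counts + ConfusionCounts.from_predictions(
            y_true, labels_b)
        if graph_a is not None:
            fa = featurize(standardize(graph_a, std), coloring)
            fb = featurize(standardize(graph_b, std), coloring)
            if fa == fb:
                n_identical += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no resolvable cross-reference pairs")
    if skipped:
        logger.warning("cross-reference analysis skipped %d unresolvable "
                       "pairs", len(skipped))
    return CrossRefReport(train_counts, xref_counts, n_used, n_identical,
                          skipped)
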