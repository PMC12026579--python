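"""Binary pair classifier: a multi-layer perceptron over concatenated
compound+pathway feature rows, trained with Adam on minibatches gathered
from the virtual pair dataset (peak memory scales with batch size × feature
width, not with the total pair count).
"""

from __future__ import annotations

import hashlib
import logging
import pickle
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neural_network import MLPClassifier

from .chem import MolecularGraph
from .coloring import ColoringConfig, featurize
from .dataset import FeatureMatrix, PairDataset
from .standardize import StandardizationConfig, standardize

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MLPConfig:
    hidden_sizes: tuple[int, ...] = (512, 256)
    activation: str = "relu"
    alpha: float = 1e-4            # L2 regularization strength
    learning_rate: float = 1e-3
    batch_size: int = 256
    max_epochs: int = 50
    early_stop_patience: int = 5
    #: Probability cutoff for the positive label. The string "auto" applies
    #: the standard prior-shift correction for balanced oversampling: the
    #: cutoff becomes 1 - pi, with pi the positive rate of the training
    #: pairs before oversampling (computed at training time, never from
    #: test data).
    decision_threshold: float | str = 0.5
    seed: int = 0

    def __post_init__(self):
        if not all(isinstance(h, int) and h > 0 for h in self.hidden_sizes):
            raise ValueError("hidden_sizes must be positive integers")
        if self.decision_threshold != "auto" and not (
                0.0 <= self.decision_threshold <= 1.0):
            raise ValueError("decision_threshold must lie in [0, 1] or be "
                             "'auto'")


class PairMLPClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator wrapping an Adam-trained MLP.

    ``fit(X, y)`` takes ordinary 2-D arrays; :meth:`fit_pairs` streams
    minibatches out of a virtual :class:`~pathcolor.dataset.PairDataset`
    so the cross-join is never materialized. Training runs epoch-wise
    ``partial_fit`` with deterministic shuffling and stops early when the
    epoch loss stops improving.
    """

    def __init__(self, hidden_sizes=(512, 256), activation="relu",
                 alpha=1e-4, learning_rate=1e-3, batch_size=256,
                 max_epochs=50, early_stop_patience=5,
                 decision_threshold=0.5, seed=0):
        self.hidden_sizes = hidden_sizes
        self.activation = activation
        self.alpha = alpha
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.decision_threshold = decision_threshold
        self.seed = seed

    @property
    def config(self) -> MLPConfig:
        return MLPConfig(tuple(self.hidden_sizes), self.activation,
                         self.alpha, self.learning_rate, self.batch_size,
                         self.max_epochs, self.early_stop_patience,
                         self.decision_threshold, self.seed)

    # -- training ---------------------------------------------------------

    def _new_net(self) -> MLPClassifier:
        return MLPClassifier(hidden_layer_sizes=tuple(self.hidden_sizes),
                             activation=self.activation,
                             solver="adam",
                             alpha=self.alpha,
                             learning_rate_init=self.learning_rate,
                             batch_size=min(self.batch_size, 2 ** 14),
                             max_iter=1,
                             shuffle=False,
                             random_state=self.seed,
                             warm_start=False)

    def fit_pairs(self, pairs: PairDataset, train_indices: np.ndarray):
        """Train on (already oversampled) pair indices, batch-gathered."""
        train_indices = np.asarray(train_indices)
        y_all = pairs.labels(train_indices)
        return self._fit_batched(
            lambda idx: pairs.gather(train_indices[idx]),
            y_all, n=len(train_indices))

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        return self._fit_batched(lambda idx: X[idx], y, n=len(y))

    def _fit_batched(self, gather, y_all: np.ndarray, n: int):
        classes = np.unique(y_all)
        if len(classes) < 2:
            raise ValueError(
                f"training set contains a single class {classes.tolist()}; "
                "both positives and negatives are required")
        net = self._new_net()
        rng = np.random.default_rng(self.seed)
        best = np.inf
        stall = 0
        self.loss_curve_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                sel = order[start:start + self.batch_size]
                Xb = gather(sel)
                net.batch_size = len(sel)  # avoid clipping on the tail batch
                net.partial_fit(Xb, y_all[sel], classes=classes)
                losses.append(net.loss_)
            epoch_loss = float(np.mean(losses))
            if not np.isfinite(epoch_loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}; last batch size "
                    f"{len(sel)}, lr {self.learning_rate}")
            self.loss_curve_.append(epoch_loss)
            if epoch_loss < best - 1e-5:
                best = epoch_loss
                stall = 0
            else:
                stall += 1
                if stall >= self.early_stop_patience:
                    break
        self.net_ = net
        self.n_features_in_ = net.n_features_in_
        self.classes_ = net.classes_
        return self

    # -- inference --------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected feature width {self.n_features_in_}, "
                f"got shape {X.shape}")
        return self.net_.predict_proba(X)

    @property
    def effective_threshold(self) -> float:
        t = getattr(self, "threshold_", None)
        if t is not None:
            return t
        if self.decision_threshold == "auto":
            raise ValueError(
                "decision_threshold='auto' needs the training prior; fit "
                "via train(..., train_prior=...) or set threshold_")
        return float(self.decision_threshold)

    def predict(self, X) -> np.ndarray:
        p = self.predict_proba(X)[:, list(self.classes_).index(1)]
        return (p >= self.effective_threshold).astype(np.int8)

    def predict_pairs(self, pairs: PairDataset, indices: np.ndarray,
                      batch_size: int | None = None) -> np.ndarray:
        """Thresholded labels for pair indices, gathered in batches."""
        bs = batch_size or self.batch_size
        out = np.empty(len(indices), dtype=np.int8)
        indices = np.asarray(indices)
        for start in range(0, len(indices), bs):
            sel = indices[start:start + bs]
            out[start:start + bs] = self.predict(pairs.gather(sel))
        return out


@dataclass
class TrainedModel:
    """A fitted classifier bound to the feature space it was trained on."""

    classifier: PairMLPClassifier
    config: MLPConfig
    dataset_fingerprint: str

    def predict_pairs(self, pairs: PairDataset, indices: np.ndarray,
                      override_fingerprint: bool = False) -> np.ndarray:
        if not override_fingerprint and \
                pairs.fingerprint() != self.dataset_fingerprint:
            raise ValueError(
                "dataset fingerprint mismatch: this model was trained on a "
                "different feature store (pass override_fingerprint=True "
                "for deliberately projected inputs)")
        return self.classifier.predict_pairs(pairs, indices)

    def predict_rows(self, compound_row: np.ndarray, pathway_rows: np.ndarray,
                     ) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, labels) of one compound row against many pathway
        rows."""
        X = np.hstack([np.tile(compound_row, (len(pathway_rows), 1)),
                       pathway_rows]).astype(np.float32)
        p = self.classifier.predict_proba(X)[
            :, list(self.classifier.classes_).index(1)]
        labels = (p >= self.classifier.effective_threshold).astype(np.int8)
        return p, labels

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            return pickle.load(fh)


def train(pairs: PairDataset, train_indices: np.ndarray,
          config: MLPConfig = MLPConfig(),
          train_prior: float | None = None) -> TrainedModel:
    """Train on (typically oversampled) pair indices.

    ``train_prior`` is the positive rate of the training pairs *before*
    oversampling; it is required when ``config.decision_threshold='auto'``,
    which thresholds the balanced-trained posterior at 1 - prior.
    """
    if len(train_indices) == 0:
        raise ValueError("empty training index set")
    clf = PairMLPClassifier(config.hidden_sizes, config.activation,
                            config.alpha, config.learning_rate,
                            config.batch_size, config.max_epochs,
                            config.early_stop_patience,
                            config.decision_threshold, config.seed)
    if config.decision_threshold == "auto":
        if train_prior is None or not (0 < train_prior < 1):
            raise ValueError("decision_threshold='auto' requires the "
                             "pre-oversampling training positive rate")
        clf.threshold_ = 1.0 - float(train_prior)
    clf.fit_pairs(pairs, train_indices)
    return TrainedModel(clf, config, pairs.fingerprint())


def project_new_compound(graph: MolecularGraph,
                         compounds: FeatureMatrix,
                         coloring: ColoringConfig = ColoringConfig(),
                         std: StandardizationConfig = StandardizationConfig.none(),
                         ) -> tuple[np.ndarray, float]:
    """Project a novel structure into a trained compound feature space.

    The structure is standardized and colored with the training configs,
    counts outside the training vocabulary are dropped (their fraction is
    returned), and the stored softmax→min-max transform is applied using the
    training matrix's frozen per-column statistics — normalization is never
    refit on new compounds.
    """
    if not compounds.normalized or compounds.col_min is None:
        raise ValueError("projection needs a normalized compound matrix "
                         "with frozen column statistics")
    g = standardize(graph, std)
    counts = featurize(g, coloring)
    total = sum(counts.values())
    raw = np.zeros(compounds.n_cols, dtype=np.float64)
    kept = 0
    # Merged columns are looked up by their representative (first) color.
    col_lookup = {cols[0]: k for k, cols in enumerate(compounds.col_meta)}
    for color, c in counts.items():
        k = col_lookup.get(color)
        if k is not None:
            raw[k] = c
            kept += c
    oov = 1.0 - (kept / total) if total else 0.0
    if oov > 0:
        logger.debug("%s: %.1f%% of atom-color mass outside the training "
                     "vocabulary", graph.id, 100 * oov)
    z = raw - raw.max()
    e = np.exp(z)
    s = e / e.sum()
    span = compounds.col_max - compounds.col_min
    row = np.zeros_like(s)
    nz = span > 0
    row[nz] = (s[nz] - compounds.col_min[nz]) / span[nz]
    return np.clip(row, 0.0, 1.0), oov
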