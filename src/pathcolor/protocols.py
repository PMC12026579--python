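"""Study protocols: the fixed experiment configurations of this package.

Three reusable experiments, all on synthetic knowledgebases:

* ``learnability`` — stratified CV of the pair classifier on the combined
  multi-KB dataset (held-out MCC per iteration).
* ``cross_kb`` — train on one KB, test on another (generalization to
  foreign pathway definitions).
* ``standardization_effect`` — the cross-reference consistency analysis
  under no standardization vs InChI standardization: identical-feature
  pair fractions and the train-vs-crossref MCC drop.

The synthetic conditions are the generator defaults (3 KBs x 150 compounds
x 30 pathways, membership noise 0.05, cross-reference fraction 0.5, mix
dominated by tautomer/resonance rewrites). Coloring uses neighborhood
radius 1; the classifier is a (256, 128) MLP trained on balanced
oversampled pairs with a prior-corrected decision threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .coloring import ColoringConfig
from .dataset import PairDataset, build_dataset, oversample_positives
from .evaluate import (CVConfig, cross_kb_eval, cross_reference_analysis,
                       run_cv)
from .mlp import MLPConfig, train
from .standardize import StandardizationConfig, StandardizationMode
from .synth import SyntheticConfig, SyntheticKB, generate

#: Featurization for the synthetic studies: first-shell (radius-1) atom
#: environments. See docs/methods.md for the rationale.
STUDY_COLORING = ColoringConfig(atom_stereo=True, bond_stereo=True,
                                max_rounds=1)

#: Classifier settings for the CV / cross-KB studies.
STUDY_MODEL = MLPConfig(hidden_sizes=(256, 128), batch_size=2048,
                        learning_rate=3e-3, max_epochs=120,
                        early_stop_patience=12,
                        decision_threshold="auto", seed=0)

#: Classifier settings for cross-reference consistency runs (shorter
#: schedule: the quantity of interest is the *difference* between two
#: prediction passes of one model, evaluated per standardization mode on
#: an equal footing).
CROSSREF_MODEL = dataclasses.replace(STUDY_MODEL, max_epochs=40,
                                     early_stop_patience=6)


def build_study_dataset(seed: int, mode: str = "none",
                        coloring: ColoringConfig = STUDY_COLORING,
                        ) -> tuple[SyntheticKB, PairDataset]:
    kb = generate(SyntheticConfig(seed=seed))
    std = StandardizationConfig(StandardizationMode(mode))
    pairs = build_dataset(kb.all_compounds(), kb.all_pathways(),
                          coloring=coloring, std=std)
    return kb, pairs


def run_learnability(seed: int, n_iterations: int = 5,
                     model: MLPConfig | None = None) -> dict:
    """Held-out MCC of the pair MLP over stratified CV iterations."""
    _, pairs = build_study_dataset(seed)
    cfg = dataclasses.replace(model or STUDY_MODEL, seed=seed % (2 ** 31))
    rep = run_cv(pairs, cfg, CVConfig(n_iterations=n_iterations, k=10,
                                      seed=seed % (2 ** 31)))
    mccs = [m["mcc"] for m in rep.per_iteration]
    return {"mcc_per_iteration": mccs,
            "median_mcc": float(np.median(mccs)),
            "min_mcc": float(min(mccs)),
            "mean_mcc": float(np.mean(mccs)),
            "pairs": pairs, "report": rep}


def run_cross_kb(seed: int, model: MLPConfig | None = None,
                 pairs: PairDataset | None = None) -> dict:
    """Train-on-one-KB / test-on-another MCC matrix on the same dataset."""
    if pairs is None:
        _, pairs = build_study_dataset(seed)
    cfg = dataclasses.replace(model or STUDY_MODEL, seed=seed % (2 ** 31))
    matrix = cross_kb_eval(pairs, cfg, seed=seed % (2 ** 31))
    off = [matrix[a][b] for a in matrix for b in matrix[a] if a != b]
    diag = [matrix[a][a] for a in matrix]
    return {"matrix": matrix, "max_off_diagonal": float(max(off)),
            "min_held_in": float(min(diag))}


def run_standardization_effect(seed: int, n_seeds: int = 5,
                               model: MLPConfig | None = None) -> dict:
    """Cross-reference consistency with and without InChI standardization.

    For each derived seed and each mode, trains one model on every pair of
    the dataset, predicts each cross-referenced training compound's pathway
    slate twice (stored row vs the projected cross-reference structure),
    and tallies identical-raw-feature pairs and the MCC drop.
    """
    base = model or CROSSREF_MODEL
    out: dict = {"none": {"identical_fraction": [], "mcc_drop": [],
                          "train_mcc": [], "crossref_mcc": []},
                 "inchi": {"identical_fraction": [], "mcc_drop": [],
                           "train_mcc": [], "crossref_mcc": []}}
    for k in range(n_seeds):
        sub_seed = (seed + 1000 * (k + 1)) % (2 ** 31)
        for mode in ("none", "inchi"):
            kb, pairs = build_study_dataset(sub_seed, mode=mode)
            idx = pairs.valid_indices()
            y = pairs.labels(idx)
            cfg = dataclasses.replace(base, seed=sub_seed)
            m = train(pairs, oversample_positives(idx, y), cfg,
                      train_prior=float(y.mean()))
            graphs = {(c.source_kb, c.compound_id): c.graph
                      for c in kb.all_compounds()}
            std = StandardizationConfig(StandardizationMode(mode))
            rep = cross_reference_analysis(m, pairs, kb.crossrefs, graphs,
                                           coloring=STUDY_COLORING, std=std)
            out[mode]["identical_fraction"].append(
                rep.n_identical_feature_pairs / rep.n_pairs)
            out[mode]["mcc_drop"].append(rep.mcc_difference)
            out[mode]["train_mcc"].append(rep.train_mcc)
            out[mode]["crossref_mcc"].append(rep.crossref_mcc)
    for mode in out:
        out[mode]["median_mcc_drop"] = float(np.median(out[mode]["mcc_drop"]))
        out[mode]["median_identical_fraction"] = float(
            np.median(out[mode]["identical_fraction"]))
    return out
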