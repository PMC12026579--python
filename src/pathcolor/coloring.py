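"""Atom coloring: chemistry-aware Weisfeiler-Lehman label refinement.

Each heavy atom starts from a base label (element, formal charge, total
attached hydrogens, optionally tetrahedral parity) and is iteratively
relabelled with the sorted multiset of (bond label, neighbour label) pairs
until the induced partition of atoms stabilizes. The stabilized label — a
canonical string, digested to a fixed-width hash — is the atom's *color*,
and a molecule's feature vector is the multiset of its heavy-atom colors.

Two atoms receive the same color exactly when their depth-d rooted
neighbourhood unfolding trees agree (d = stabilization round count), which
makes the features invariant to atom-index permutation and to the
explicit/implicit hydrogen dialect of the source molfile.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import AtomStereo, BondStereo, MolecularGraph


@dataclass(frozen=True)
class ColoringConfig:
    atom_stereo: bool = True
    bond_stereo: bool = True
    max_rounds: int | str = "auto"  # "auto" = iterate to partition stability

    def __post_init__(self):
        if self.max_rounds != "auto" and (
                not isinstance(self.max_rounds, int) or self.max_rounds < 0):
            raise ValueError("max_rounds must be 'auto' or a non-negative int")


class ColorCollisionError(RuntimeError):
    """Two distinct label strings produced the same digest."""


# Digest registry: digest -> composition string it stands for. Content-based
# hashing makes colors stable across runs and corpora; the registry catches
# (vanishingly unlikely) 128-bit collisions, per the reproducibility-first
# design: on collision we refuse rather than silently merge colors.
_DIGESTS: dict[str, str] = {}


def _digest(label: str) -> str:
    h = hashlib.blake2b(label.encode(), digest_size=16,
                        key=b"pathcolor-wl").hexdigest()
    prev = _DIGESTS.setdefault(h, label)
    if prev != label:
        raise ColorCollisionError(
            f"digest collision between {prev!r} and {label!r}")
    return h


def expand_color(digest: str) -> str:
    """Return the (one-level) composition string behind a color digest."""
    return _DIGESTS[digest[digest.index(":") + 1:] if ":" in digest else digest]


def _base_labels(graph: MolecularGraph, config: ColoringConfig,
                 heavy: Sequence[int]) -> dict[int, str]:
    # Total H = implicit count + explicit H neighbours (folded).
    explicit_h = {i: 0 for i in heavy}
    for bond in graph.bonds:
        for i, j in ((bond.a, bond.b), (bond.b, bond.a)):
            if graph.atoms[i].element == "H" and j in explicit_h:
                explicit_h[j] += 1
    labels = {}
    for i in heavy:
        atom = graph.atoms[i]
        h_total = atom.implicit_h_count + explicit_h[i]
        parts = [atom.element, str(atom.formal_charge), str(h_total)]
        if config.atom_stereo and atom.stereo_parity is not AtomStereo.NONE:
            parts.append(atom.stereo_parity.value)
        labels[i] = _digest("A(" + ",".join(parts) + ")")
    return labels


def _edge_label(bond, config: ColoringConfig) -> str:
    if config.bond_stereo and bond.stereo is not BondStereo.NONE:
        return f"{bond.order.value}/{bond.stereo.value}"
    return bond.order.value


def _refinement_rounds(graph: MolecularGraph, config: ColoringConfig):
    """Yield (round, labels) starting at round 0 (base labels)."""
    graph.validate()
    heavy = graph.heavy_indices()
    heavy_set = set(heavy)
    adj: dict[int, list[tuple[str, int]]] = {i: [] for i in heavy}
    for bond in graph.bonds:
        if bond.a in heavy_set and bond.b in heavy_set:
            e = _edge_label(bond, config)
            adj[bond.a].append((e, bond.b))
            adj[bond.b].append((e, bond.a))
    labels = _base_labels(graph, config, heavy)
    yield 0, labels
    r = 0
    while True:
        r += 1
        new = {}
        for i in heavy:
            env = sorted(f"{e}:{labels[j]}" for e, j in adj[i])
            new[i] = _digest(f"({labels[i]}|{';'.join(env)})")
        yield r, new
        labels = new


def _partition(labels: dict[int, str]) -> dict[str, tuple[int, ...]]:
    groups: dict[str, list[int]] = {}
    for i, lab in labels.items():
        groups.setdefault(lab, []).append(i)
    return {k: tuple(sorted(v)) for k, v in groups.items()}


def color_atoms(graph: MolecularGraph,
                config: ColoringConfig = ColoringConfig(),
                ) -> list[str]:
    """Color every heavy atom; returns colors in heavy-atom index order.

    With ``max_rounds='auto'`` refinement runs until the induced partition
    stops changing (guaranteed within n_heavy rounds since partitions only
    refine); the returned color is ``"r{d}:{digest}"`` where d is the
    stabilization round count, so colors are comparable across molecules
    only at equal refinement depth.
    """
    heavy = graph.heavy_indices()
    if not heavy:
        return []
    rounds = _refinement_rounds(graph, config)
    if config.max_rounds == "auto":
        _, labels = next(rounds)
        prev_part = set(_partition(labels).values())
        d = 0
        for r, labels in rounds:
            part = set(_partition(labels).values())
            d = r
            if part == prev_part:
                break
            prev_part = part
    else:
        for r, labels in rounds:
            d = r
            if r >= config.max_rounds:
                break
    return [f"r{d}:{labels[i]}" for i in heavy]


def refinement_partitions(graph: MolecularGraph,
                          config: ColoringConfig = ColoringConfig(),
                          n_rounds: int | None = None):
    """Partitions of heavy atoms per refinement round (for diagnostics)."""
    heavy_n = graph.n_heavy()
    limit = heavy_n + 1 if n_rounds is None else n_rounds
    out = []
    for r, labels in _refinement_rounds(graph, config):
        out.append(frozenset(_partition(labels).values()))
        if r >= limit:
            break
    return out


def stabilization_depth(graph: MolecularGraph,
                        config: ColoringConfig = ColoringConfig()) -> int:
    """Round count at which the color partition stabilizes."""
    colors = color_atoms(graph, config)
    if not colors:
        return 0
    return int(colors[0].split(":", 1)[0][1:])


def featurize(graph: MolecularGraph,
              config: ColoringConfig = ColoringConfig()) -> Counter:
    """Sparse color-count vector; total count equals heavy-atom count."""
    return Counter(color_atoms(graph, config))


class AtomColorFeaturizer(BaseEstimator, TransformerMixin):
    """Vectorize molecular graphs as sparse atom-color count matrices.

    ``fit`` learns the color vocabulary from a corpus of graphs;
    ``transform`` tallies each graph over that vocabulary (unseen colors are
    dropped — use :meth:`transform_with_oov` to recover the dropped mass).
    Columns are sorted lexicographically by color string for determinism.
    """

    def __init__(self, atom_stereo: bool = True, bond_stereo: bool = True,
                 max_rounds: int | str = "auto"):
        self.atom_stereo = atom_stereo
        self.bond_stereo = bond_stereo
        self.max_rounds = max_rounds

    @property
    def config(self) -> ColoringConfig:
        return ColoringConfig(self.atom_stereo, self.bond_stereo,
                              self.max_rounds)

    def fit(self, X: Iterable[MolecularGraph], y=None):
        vocab: set[str] = set()
        for g in X:
            vocab.update(featurize(g, self.config))
        if not vocab:
            raise ValueError("no colors observed: empty corpus")
        self.vocabulary_ = sorted(vocab)
        self.vocabulary_index_ = {c: k for k, c in enumerate(self.vocabulary_)}
        return self

    def transform(self, X: Iterable[MolecularGraph]) -> sparse.csr_matrix:
        return self.transform_with_oov(X)[0]

    def transform_with_oov(self, X: Iterable[MolecularGraph]):
        rows, cols, vals, oov = [], [], [], []
        n = 0
        for r, g in enumerate(X):
            counts = featurize(g, self.config)
            total = sum(counts.values())
            dropped = 0
            for color, c in counts.items():
                k = self.vocabulary_index_.get(color)
                if k is None:
                    dropped += c
                else:
                    rows.append(r)
                    cols.append(k)
                    vals.append(c)
            oov.append(dropped / total if total else 0.0)
            n = r + 1
        mat = sparse.csr_matrix(
            (np.asarray(vals, dtype=np.int64), (rows, cols)),
            shape=(n, len(self.vocabulary_)))
        return mat, np.asarray(oov)
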