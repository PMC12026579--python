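"""Feature-matrix construction, de-duplication, normalization, and the
virtual block-diagonal compound×pathway pair dataset.

Compound rows are atom-color counts; pathway rows are sums of their member
compounds' raw count rows. Both matrices are de-duplicated entry-wise (rows
with identical counts merge, pooling the entities and annotations they
represent) and feature-wise (identical columns merge), then normalized with
a row-wise softmax followed by column-wise min-max scaling. Compounds and
pathways from the same knowledgebase are cross-joined into binary-labelled
pairs; the cross-join is kept virtual — features are gathered per batch,
never materialized for every pair at once.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import CompoundRecord, PathwayRecord
from .coloring import AtomColorFeaturizer, ColoringConfig
from .standardize import StandardizationConfig, Standardizer


@dataclass
class FeatureMatrix:
    entity_class: str                      # "compound" | "pathway"
    X: sparse.csr_matrix | np.ndarray      # raw counts (sparse) or normalized (dense)
    row_meta: list[frozenset[tuple[str, str]]]  # per row: {(kb, entity_id)}
    col_meta: list[tuple[str, ...]]        # per column: merged color strings
    normalized: bool = False
    col_min: np.ndarray | None = None      # softmax-stage stats frozen at
    col_max: np.ndarray | None = None      # normalization time (projection)

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_cols(self) -> int:
        return self.X.shape[1]

    def kbs_of_row(self, i: int) -> frozenset[str]:
        return frozenset(kb for kb, _ in self.row_meta[i])

    def row_index(self) -> dict[tuple[str, str], int]:
        idx = {}
        for i, meta in enumerate(self.row_meta):
            for key in meta:
                idx[key] = i
        return idx

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        arr = self.X.toarray() if sparse.issparse(self.X) else self.X
        h.update(np.ascontiguousarray(arr).tobytes())
        h.update(json.dumps([sorted(m) for m in self.row_meta]).encode())
        h.update(json.dumps(self.col_meta).encode())
        return h.hexdigest()


def build_compound_matrix(records: Sequence[CompoundRecord],
                          coloring: ColoringConfig = ColoringConfig(),
                          std: StandardizationConfig = StandardizationConfig.none(),
                          on_error: str = "raise",
                          ) -> FeatureMatrix:
    """Raw per-compound count matrix (one row per record, pre-dedup).

    Rows follow (source_kb, compound_id) order; columns are the distinct
    colors across the whole corpus, lexicographically sorted.
    """
    if not records:
        raise ValueError("no compound records supplied")
    records = sorted(records, key=lambda r: (r.source_kb, r.compound_id))
    stdzr = Standardizer(mode=std.mode.value, keep_stereo=std.keep_stereo,
                         on_error=on_error)
    graphs = stdzr.transform([r.graph for r in records])
    if len(graphs) != len(records):
        kept_ids = {g.id for g in graphs}
        records = [r for r in records if r.graph.id in kept_ids]
    feat = AtomColorFeaturizer(coloring.atom_stereo, coloring.bond_stereo,
                               coloring.max_rounds).fit(graphs)
    X = feat.transform(graphs)
    row_meta = [frozenset({(r.source_kb, r.compound_id)}) for r in records]
    col_meta = [(c,) for c in feat.vocabulary_]
    return FeatureMatrix("compound", X, row_meta, col_meta)


def aggregate_pathway_features(pathways: Sequence[PathwayRecord],
                               compound_matrix: FeatureMatrix,
                               ) -> FeatureMatrix:
    """Pathway rows as elementwise sums of member compounds' RAW count rows."""
    if compound_matrix.normalized:
        raise ValueError("pathway aggregation requires raw compound counts")
    if not pathways:
        raise ValueError("no pathway records supplied")
    comp_index = compound_matrix.row_index()
    pathways = sorted(pathways, key=lambda p: (p.source_kb, p.pathway_id))
    rows, row_meta = [], []
    for p in pathways:
        members = [comp_index[(p.source_kb, cid)]
                   for cid in sorted(p.member_compound_ids)
                   if (p.source_kb, cid) in comp_index]
        if not members:
            import logging
            logging.getLogger(__name__).warning(
                "dropping pathway %s:%s with no resolvable members",
                p.source_kb, p.pathway_id)
            continue
        rows.append(sparse.csr_matrix(
            compound_matrix.X[members].sum(axis=0)))
        row_meta.append(frozenset({(p.source_kb, p.pathway_id)}))
    if not rows:
        raise ValueError("all pathways dropped: no resolvable members")
    X = sparse.vstack(rows).tocsr().astype(np.int64)
    return FeatureMatrix("pathway", X, row_meta, list(compound_matrix.col_meta))


def dedup(matrix: FeatureMatrix) -> FeatureMatrix:
    """Merge identical rows (entity sets pooled) then identical columns.

    Row order: each merged row sits at the position of its first (sorted)
    representative. Column order stays lexicographic by the representative
    (smallest) color string.
    """
    if matrix.normalized:
        raise ValueError("dedup operates on raw counts")
    X = matrix.X.tocsr()
    # entry-wise
    seen: dict[bytes, int] = {}
    keep_rows: list[int] = []
    merged_meta: list[set[tuple[str, str]]] = []
    dense = X.toarray()
    for i in range(X.shape[0]):
        key = dense[i].tobytes()
        j = seen.get(key)
        if j is None:
            seen[key] = len(keep_rows)
            keep_rows.append(i)
            merged_meta.append(set(matrix.row_meta[i]))
        else:
            merged_meta[j] |= matrix.row_meta[i]
    dense = dense[keep_rows]
    # feature-wise
    col_seen: dict[bytes, int] = {}
    keep_cols: list[int] = []
    merged_cols: list[set[str]] = []
    for c in range(dense.shape[1]):
        key = np.ascontiguousarray(dense[:, c]).tobytes()
        j = col_seen.get(key)
        if j is None:
            col_seen[key] = len(keep_cols)
            keep_cols.append(c)
            merged_cols.append(set(matrix.col_meta[c]))
        else:
            merged_cols[j] |= set(matrix.col_meta[c])
    dense = dense[:, keep_cols]
    order = np.argsort([min(cols) for cols in merged_cols], kind="stable")
    dense = dense[:, order]
    col_meta = [tuple(sorted(merged_cols[k])) for k in order]
    return FeatureMatrix(matrix.entity_class,
                         sparse.csr_matrix(dense),
                         [frozenset(m) for m in merged_meta],
                         col_meta)


def softmax_rows(raw: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max subtraction for numerical stability."""
    z = raw.astype(np.float64)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def normalize(matrix: FeatureMatrix) -> FeatureMatrix:
    """Softmax each row over all columns, then min-max scale each column.

    Constant columns map to 0. Per-column min/max of the softmaxed matrix
    are frozen on the result so novel compounds can be projected with the
    training statistics. Not idempotent — renormalizing is an error.
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    raw = matrix.X.toarray() if sparse.issparse(matrix.X) else matrix.X
    S = softmax_rows(raw)
    lo = S.min(axis=0)
    hi = S.max(axis=0)
    span = hi - lo
    out = np.zeros_like(S)
    nz = span > 0
    out[:, nz] = (S[:, nz] - lo[nz]) / span[nz]
    return FeatureMatrix(matrix.entity_class, out, list(matrix.row_meta),
                         list(matrix.col_meta), normalized=True,
                         col_min=lo, col_max=hi)


class SoftmaxMinMaxScaler(BaseEstimator, TransformerMixin):
    """sklearn-style view of :func:`normalize` for raw count arrays."""

    def fit(self, X, y=None):
        S = softmax_rows(np.asarray(X, dtype=np.float64))
        self.col_min_ = S.min(axis=0)
        self.col_max_ = S.max(axis=0)
        return self

    def transform(self, X):
        S = softmax_rows(np.asarray(X, dtype=np.float64))
        span = self.col_max_ - self.col_min_
        out = np.zeros_like(S)
        nz = span > 0
        out[:, nz] = (S[:, nz] - self.col_min_[nz]) / span[nz]
        return np.clip(out, 0.0, 1.0) if (S < self.col_min_).any() or (
            S > self.col_max_).any() else out


@dataclass
class Block:
    kb: str
    compound_rows: np.ndarray
    pathway_rows: np.ndarray
    offset: int  # global index of this block's first pair

    @property
    def n_pairs(self) -> int:
        return len(self.compound_rows) * len(self.pathway_rows)


@dataclass
class PairDataset:
    """Virtual cross-join of compound rows × pathway rows per knowledgebase.

    A global pair index enumerates block-local Cartesian products; a pair
    whose (compound row, pathway row) already appeared in an earlier block
    (possible when a merged row spans KBs) is excluded from the valid index
    set so every pair counts once.
    """

    compounds: FeatureMatrix
    pathways: FeatureMatrix
    blocks: list[Block]
    positives: frozenset[tuple[int, int]]
    _duplicates: frozenset[int]
    _total_raw: int

    @property
    def width(self) -> int:
        return self.compounds.n_cols + self.pathways.n_cols

    def pair_of(self, g: int) -> tuple[int, int]:
        ci, pj = self.pairs_of(np.array([g]))
        return int(ci[0]), int(pj[0])

    def pairs_of(self, indices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized global index -> (compound row, pathway row)."""
        indices = np.asarray(indices, dtype=np.int64)
        if len(indices) and (indices.min() < 0 or
                             indices.max() >= self._total_raw):
            raise IndexError("pair index out of range")
        offsets = np.array([b.offset for b in self.blocks], dtype=np.int64)
        bi = np.searchsorted(offsets, indices, side="right") - 1
        ci = np.empty(len(indices), dtype=np.int64)
        pj = np.empty(len(indices), dtype=np.int64)
        for k, blk in enumerate(self.blocks):
            m = bi == k
            if not m.any():
                continue
            local = indices[m] - blk.offset
            c, p = np.divmod(local, len(blk.pathway_rows))
            ci[m] = blk.compound_rows[c]
            pj[m] = blk.pathway_rows[p]
        return ci, pj

    def block_of(self, g: int) -> Block:
        for blk in reversed(self.blocks):
            if g >= blk.offset:
                return blk
        raise IndexError(g)

    def valid_indices(self) -> np.ndarray:
        out = np.arange(self._total_raw)
        if self._duplicates:
            mask = np.ones(self._total_raw, dtype=bool)
            mask[sorted(self._duplicates)] = False
            out = out[mask]
        return out

    @property
    def n_pairs(self) -> int:
        return self._total_raw - len(self._duplicates)

    def labels(self, indices: np.ndarray) -> np.ndarray:
        ci, pj = self.pairs_of(np.asarray(indices))
        return np.fromiter(
            ((int(c), int(p)) in self.positives for c, p in zip(ci, pj)),
            dtype=np.int8, count=len(ci))

    def kb_witnesses(self, g: int) -> frozenset[str]:
        ci, pj = self.pair_of(int(g))
        return self.compounds.kbs_of_row(ci) & self.pathways.kbs_of_row(pj)

    def gather(self, indices: np.ndarray) -> np.ndarray:
        """Dense (len(indices), width) batch of concatenated features."""
        ci, pj = self.pairs_of(np.asarray(indices))
        cx = self.compounds.X[ci] if isinstance(self.compounds.X, np.ndarray) \
            else self.compounds.X[ci].toarray()
        px = self.pathways.X[pj] if isinstance(self.pathways.X, np.ndarray) \
            else self.pathways.X[pj].toarray()
        return np.hstack([cx, px]).astype(np.float32)

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.compounds.fingerprint().encode())
        h.update(self.pathways.fingerprint().encode())
        for blk in self.blocks:
            h.update(blk.kb.encode())
            h.update(np.asarray(blk.compound_rows).tobytes())
            h.update(np.asarray(blk.pathway_rows).tobytes())
        h.update(json.dumps(sorted(self.positives)).encode())
        return h.hexdigest()

    def restrict_to_kb(self, kb: str) -> "PairDataset":
        """Single-KB view sharing this dataset's feature space."""
        blocks = [b for b in self.blocks if b.kb == kb]
        if not blocks:
            raise ValueError(f"no block for knowledgebase {kb!r}")
        blk = blocks[0]
        new = Block(kb, blk.compound_rows, blk.pathway_rows, 0)
        return PairDataset(self.compounds, self.pathways, [new],
                           self.positives, frozenset(), new.n_pairs)


def cross_join(compounds: FeatureMatrix, pathways: FeatureMatrix,
               annotations: Iterable[tuple[str, str, str]],
               ) -> PairDataset:
    """Build the virtual pair dataset.

    ``annotations`` are (kb, compound_id, pathway_id) triples on original
    entity ids. A pair is positive when any represented compound of the row
    is annotated to any represented pathway of the other row (union
    semantics after dedup merging).
    """
    if not (compounds.normalized and pathways.normalized):
        raise ValueError("cross_join expects deduped+normalized matrices")
    comp_idx = compounds.row_index()
    path_idx = pathways.row_index()
    kbs = sorted({kb for meta in compounds.row_meta for kb, _ in meta} |
                 {kb for meta in pathways.row_meta for kb, _ in meta})
    blocks: list[Block] = []
    offset = 0
    seen_pairs: set[tuple[int, int]] = set()
    duplicates: set[int] = set()
    for kb in kbs:
        crows = np.array([i for i in range(compounds.n_rows)
                          if kb in compounds.kbs_of_row(i)], dtype=np.int64)
        prows = np.array([j for j in range(pathways.n_rows)
                          if kb in pathways.kbs_of_row(j)], dtype=np.int64)
        if len(crows) == 0 or len(prows) == 0:
            continue
        blk = Block(kb, crows, prows, offset)
        blocks.append(blk)
        spans_c = [i for i in crows if len(compounds.kbs_of_row(i)) > 1]
        spans_p = [j for j in prows if len(pathways.kbs_of_row(j)) > 1]
        if spans_c and spans_p:
            # Only multi-KB rows can repeat a pair across blocks.
            pmap = {int(j): k for k, j in enumerate(prows)}
            for ci_pos, i in enumerate(crows):
                if len(compounds.kbs_of_row(int(i))) == 1:
                    continue
                for j in spans_p:
                    pair = (int(i), int(j))
                    if pair in seen_pairs:
                        duplicates.add(offset + ci_pos * len(prows) + pmap[int(j)])
                    else:
                        seen_pairs.add(pair)
        offset += blk.n_pairs

    positives: set[tuple[int, int]] = set()
    for kb, cid, pid in annotations:
        ci = comp_idx.get((kb, cid))
        pj = path_idx.get((kb, pid))
        if ci is not None and pj is not None:
            positives.add((ci, pj))
    return PairDataset(compounds, pathways, blocks, frozenset(positives),
                       frozenset(duplicates), offset)


def oversample_positives(indices: np.ndarray, labels: np.ndarray,
                         ) -> np.ndarray:
    """Duplicate positive training pairs until roughly class-balanced.

    Each positive appears k = max(1, round(n_neg / n_pos)) times; negatives
    once. Applies to training folds only — never to test data.
    """
    labels = np.asarray(labels)
    pos = indices[labels == 1]
    neg = indices[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("degenerate training split: need both classes")
    k = max(1, int(round(len(neg) / len(pos))))
    return np.concatenate([neg, np.repeat(pos, k)])


def annotations_of(records: Sequence[CompoundRecord],
                   ) -> list[tuple[str, str, str]]:
    out = []
    for r in records:
        for pid in sorted(r.pathway_ids):
            out.append((r.source_kb, r.compound_id, pid))
    return out


def build_dataset(compound_records: Sequence[CompoundRecord],
                  pathway_records: Sequence[PathwayRecord],
                  coloring: ColoringConfig = ColoringConfig(),
                  std: StandardizationConfig = StandardizationConfig.none(),
                  on_error: str = "raise") -> PairDataset:
    """Full pipeline: featurize → aggregate → dedup → normalize → cross-join."""
    raw_c = build_compound_matrix(compound_records, coloring, std, on_error)
    raw_p = aggregate_pathway_features(pathway_records, raw_c)
    comp = normalize(dedup(raw_c))
    path = normalize(dedup(raw_p))
    return cross_join(comp, path, annotations_of(compound_records))
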