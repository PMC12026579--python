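"""HDF5 persistence for feature matrices and pair datasets."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
from scipy import sparse

from .dataset import Block, FeatureMatrix, PairDataset


def _save_matrix(grp: h5py.Group, m: FeatureMatrix) -> None:
    grp.attrs["entity_class"] = m.entity_class
    grp.attrs["normalized"] = m.normalized
    if sparse.issparse(m.X):
        X = m.X.tocsr()
        grp.attrs["format"] = "csr"
        grp.create_dataset("data", data=X.data)
        grp.create_dataset("indices", data=X.indices)
        grp.create_dataset("indptr", data=X.indptr)
        grp.attrs["shape"] = X.shape
    else:
        grp.attrs["format"] = "dense"
        grp.create_dataset("data", data=m.X)
    grp.create_dataset("row_meta", data=np.bytes_(
        json.dumps([sorted(list(s)) for s in m.row_meta])))
    grp.create_dataset("col_meta", data=np.bytes_(json.dumps(m.col_meta)))
    if m.col_min is not None:
        grp.create_dataset("col_min", data=m.col_min)
        grp.create_dataset("col_max", data=m.col_max)


def _load_matrix(grp: h5py.Group) -> FeatureMatrix:
    if grp.attrs["format"] == "csr":
        X = sparse.csr_matrix((grp["data"][...], grp["indices"][...],
                               grp["indptr"][...]),
                              shape=tuple(grp.attrs["shape"]))
    else:
        X = grp["data"][...]
    row_meta = [frozenset(tuple(t) for t in row)
                for row in json.loads(grp["row_meta"][()].decode())]
    col_meta = [tuple(c) for c in json.loads(grp["col_meta"][()].decode())]
    col_min = grp["col_min"][...] if "col_min" in grp else None
    col_max = grp["col_max"][...] if "col_max" in grp else None
    return FeatureMatrix(grp.attrs["entity_class"], X, row_meta, col_meta,
                         bool(grp.attrs["normalized"]), col_min, col_max)


def save_dataset(path: str | Path, pairs: PairDataset,
                 config_stamp: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        _save_matrix(fh.create_group("compounds"), pairs.compounds)
        _save_matrix(fh.create_group("pathways"), pairs.pathways)
        blocks = fh.create_group("blocks")
        for k, blk in enumerate(pairs.blocks):
            g = blocks.create_group(f"{k:03d}")
            g.attrs["kb"] = blk.kb
            g.attrs["offset"] = blk.offset
            g.create_dataset("compound_rows", data=blk.compound_rows)
            g.create_dataset("pathway_rows", data=blk.pathway_rows)
        pos = np.array(sorted(pairs.positives), dtype=np.int64).reshape(-1, 2)
        fh.create_dataset("positives", data=pos)
        fh.create_dataset("duplicates",
                          data=np.array(sorted(pairs._duplicates),
                                        dtype=np.int64))
        fh.attrs["total_raw"] = pairs._total_raw
        fh.attrs["config"] = json.dumps(config_stamp or {})


def load_dataset(path: str | Path) -> tuple[PairDataset, dict]:
    with h5py.File(path, "r") as fh:
        compounds = _load_matrix(fh["compounds"])
        pathways = _load_matrix(fh["pathways"])
        blocks = []
        for key in sorted(fh["blocks"]):
            g = fh["blocks"][key]
            blocks.append(Block(g.attrs["kb"],
                                g["compound_rows"][...],
                                g["pathway_rows"][...],
                                int(g.attrs["offset"])))
        positives = frozenset((int(a), int(b)) for a, b in fh["positives"][...])
        duplicates = frozenset(int(x) for x in fh["duplicates"][...])
        total_raw = int(fh.attrs["total_raw"])
        stamp = json.loads(fh.attrs["config"])
    return PairDataset(compounds, pathways, blocks, positives, duplicates,
                       total_raw), stamp
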