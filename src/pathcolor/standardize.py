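"""Chemical representation standardization by InChI (or SMILES) round trip.

Knowledgebases draw tautomeric, resonance and protonation forms of the same
compound differently; round-tripping each structure through InChI makes the
InChI algorithm pick one canonical tautomeric/resonance representative, so
that downstream atom-color features agree across sources. Encoding and
decoding delegate to the IUPAC InChI library bundled with RDKit; this module
owns only the round-trip orchestration, kekulization handling and error
policy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

from rdkit import Chem, RDLogger
from sklearn.base import BaseEstimator, TransformerMixin

from .chem import MolecularGraph, parse_molfile, write_molfile

RDLogger.DisableLog("rdApp.warning")
logger = logging.getLogger(__name__)


class StandardizationError(ValueError):
    def __init__(self, message: str, compound_id: str = ""):
        self.compound_id = compound_id
        super().__init__(f"{compound_id or 'structure'}: {message}")


class StandardizationMode(str, Enum):
    NONE = "none"
    INCHI = "inchi"
    SMILES = "smiles"


@dataclass(frozen=True)
class StandardizationConfig:
    mode: StandardizationMode = StandardizationMode.INCHI
    keep_stereo: bool = True

    @staticmethod
    def none() -> "StandardizationConfig":
        return StandardizationConfig(StandardizationMode.NONE)


def _to_rdkit(graph: MolecularGraph) -> Chem.Mol:
    mol = Chem.MolFromMolBlock(write_molfile(graph), sanitize=True,
                               removeHs=True)
    if mol is None:
        # Retry unsanitized + partial sanitize so e.g. pentavalent-N forms
        # survive long enough for InChI normalization to fix them.
        mol = Chem.MolFromMolBlock(write_molfile(graph), sanitize=False,
                                   removeHs=False)
        if mol is not None:
            try:
                Chem.SanitizeMol(mol)
            except Exception:
                mol = None
    if mol is None:
        raise StandardizationError(
            "structure not kekulizable / not sanitizable", graph.id)
    return mol


def to_inchi(graph: MolecularGraph, keep_stereo: bool = True) -> str:
    """Standard InChI string for a graph; identical for isomorphic inputs."""
    mol = _to_rdkit(graph)
    options = "" if keep_stereo else "/SNon"
    inchi = Chem.MolToInchi(mol, options=options, treatWarningAsError=False)
    if not inchi:
        raise StandardizationError("InChI encoding failed", graph.id)
    return inchi


def from_inchi(inchi: str, mol_id: str = "") -> MolecularGraph:
    """Decode an InChI into the canonical structure the algorithm selects."""
    if not inchi or not inchi.startswith("InChI="):
        raise StandardizationError(f"not an InChI string: {inchi!r}", mol_id)
    mol = Chem.MolFromInchi(inchi, sanitize=True, removeHs=True,
                            treatWarningAsError=False)
    if mol is None:
        raise StandardizationError(f"unparsable InChI {inchi!r}", mol_id)
    return parse_molfile(Chem.MolToMolBlock(mol), mol_id=mol_id)


def _smiles_roundtrip(graph: MolecularGraph) -> MolecularGraph:
    mol = _to_rdkit(graph)
    smiles = Chem.MolToSmiles(mol)
    back = Chem.MolFromSmiles(smiles)
    if back is None:
        raise StandardizationError(f"SMILES round trip failed: {smiles!r}",
                                   graph.id)
    return parse_molfile(Chem.MolToMolBlock(back), mol_id=graph.id)


def standardize(graph: MolecularGraph,
                config: StandardizationConfig = StandardizationConfig(),
                ) -> MolecularGraph:
    """Canonicalize one structure according to ``config.mode``.

    Idempotent: a second application cannot change downstream features,
    because the first already yields the canonical representative.
    """
    if config.mode is StandardizationMode.NONE:
        return graph
    if config.mode is StandardizationMode.INCHI:
        return from_inchi(to_inchi(graph, config.keep_stereo), mol_id=graph.id)
    return _smiles_roundtrip(graph)


class Standardizer(BaseEstimator, TransformerMixin):
    """Stateless sklearn-style transformer over lists of molecular graphs.

    ``transform`` returns the standardized graphs; structures that fail
    conversion are dropped (``on_error='skip'``) or abort (``'raise'``), and
    the skip manifest is kept on ``skipped_`` so standardized and
    non-standardized runs stay comparable on the intersection.
    """

    def __init__(self, mode: str = "inchi", keep_stereo: bool = True,
                 on_error: str = "raise"):
        self.mode = mode
        self.keep_stereo = keep_stereo
        self.on_error = on_error

    @property
    def config(self) -> StandardizationConfig:
        return StandardizationConfig(StandardizationMode(self.mode),
                                     self.keep_stereo)

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> list[MolecularGraph]:
        out, skipped = [], []
        for g in X:
            try:
                out.append(standardize(g, self.config))
            except StandardizationError as exc:
                if self.on_error != "skip":
                    raise
                logger.warning("standardization skipped %s: %s", g.id, exc)
                skipped.append((g.id, str(exc)))
        self.skipped_ = skipped
        return out
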