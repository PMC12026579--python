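"""MDL molfile (CTAB V2000) parsing/writing and knowledgebase record types.

The molecular graph kept here is deliberately faithful to the source text:
aromatic bonds stay aromatic (kekulization is the standardizer's job),
explicit hydrogens stay explicit (folding is the featurizer's job), and no
valence "repair" is attempted — atoms whose explicit bonds exceed a standard
valence are merely flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when a molfile cannot be parsed; carries a line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class AtomStereo(str, Enum):
    NONE = "none"
    ODD = "odd"
    EVEN = "even"
    EITHER = "either"


class BondOrder(str, Enum):
    SINGLE = "single"
    DOUBLE = "double"
    TRIPLE = "triple"
    AROMATIC = "aromatic"


class BondStereo(str, Enum):
    NONE = "none"
    UP = "up"
    DOWN = "down"
    CIS_TRANS = "cis_trans"


#: Default valences used to infer implicit hydrogen counts. Charge shifts the
#: effective valence for N/O/S-like elements (e.g. N+ binds 4, O- binds 1).
STANDARD_VALENCES = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
    "Se": 2, "As": 3,
}

#: Elements with accessible higher valence states (sulfones, phosphates...):
#: the smallest state that accommodates the explicit bonds is used.
HYPERVALENT_STATES = {"S": (2, 4, 6), "Se": (2, 4, 6),
                      "P": (3, 5), "As": (3, 5)}

#: Recognized element symbols (periodic table through element 103).
PERIODIC_TABLE = set(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr".split()
)

_ORDER_FROM_CODE = {1: BondOrder.SINGLE, 2: BondOrder.DOUBLE,
                    3: BondOrder.TRIPLE, 4: BondOrder.AROMATIC}
_CODE_FROM_ORDER = {v: k for k, v in _ORDER_FROM_CODE.items()}
_ORDER_VALENCE = {BondOrder.SINGLE: 1.0, BondOrder.DOUBLE: 2.0,
                  BondOrder.TRIPLE: 3.0, BondOrder.AROMATIC: 1.5}
_PARITY_FROM_CODE = {0: AtomStereo.NONE, 1: AtomStereo.ODD,
                     2: AtomStereo.EVEN, 3: AtomStereo.EITHER}
_CODE_FROM_PARITY = {v: k for k, v in _PARITY_FROM_CODE.items()}
# Legacy atom-block charge codes (superseded by M CHG when present).
_LEGACY_CHARGE = {0: 0, 1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


@dataclass
class Atom:
    element: str
    formal_charge: int = 0
    implicit_h_count: int = 0
    stereo_parity: AtomStereo = AtomStereo.NONE
    #: True when explicit bonds already exceed the standard valence; such
    #: atoms get implicit_h_count 0 rather than being rejected.
    valence_flagged: bool = False
    #: Opaque annotations (isotope mass shifts, radicals) carried through
    #: round trips but never used in coloring.
    annotations: dict = field(default_factory=dict)


@dataclass
class Bond:
    a: int
    b: int
    order: BondOrder
    stereo: BondStereo = BondStereo.NONE

    def key(self) -> tuple[int, int]:
        return (self.a, self.b) if self.a < self.b else (self.b, self.a)


@dataclass
class MolecularGraph:
    atoms: list[Atom]
    bonds: list[Bond]
    id: str = ""

    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(
                    f"{self.id or 'graph'}: bond ({bond.a},{bond.b}) "
                    f"references an atom outside 0..{n - 1}")
            if bond.a == bond.b:
                raise ValueError(f"{self.id or 'graph'}: self-bond on atom {bond.a}")
            if bond.key() in seen:
                raise ValueError(
                    f"{self.id or 'graph'}: duplicate bond {bond.key()}")
            seen.add(bond.key())
        for i, atom in enumerate(self.atoms):
            if atom.element not in PERIODIC_TABLE:
                raise ValueError(
                    f"{self.id or 'graph'}: unknown element {atom.element!r} "
                    f"at atom {i}")

    def neighbors(self, i: int) -> list[tuple[int, Bond]]:
        out = []
        for bond in self.bonds:
            if bond.a == i:
                out.append((bond.b, bond))
            elif bond.b == i:
                out.append((bond.a, bond))
        return out

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    def n_heavy(self) -> int:
        return len(self.heavy_indices())

    def permuted(self, perm: Sequence[int]) -> "MolecularGraph":
        """Return the graph with atom i moved to position perm[i]."""
        n = len(self.atoms)
        new_atoms: list[Atom | None] = [None] * n
        for i, atom in enumerate(self.atoms):
            new_atoms[perm[i]] = replace(atom, annotations=dict(atom.annotations))
        new_bonds = [Bond(perm[b.a], perm[b.b], b.order, b.stereo)
                     for b in self.bonds]
        return MolecularGraph(list(new_atoms), new_bonds, id=self.id)  # type: ignore[arg-type]


def effective_valence(element: str, charge: int) -> int | None:
    base = STANDARD_VALENCES.get(element)
    if base is None:
        return None
    if element in ("N", "P", "As"):
        return max(0, base + charge)
    if element in ("O", "S", "Se"):
        return max(0, base + charge)
    if element == "C":
        return max(0, base - abs(charge))
    if element == "B":
        return max(0, base + charge)
    return max(0, base - abs(charge))


def assign_implicit_hydrogens(graph: MolecularGraph) -> None:
    """Fill implicit_h_count from the standard valence table.

    Atoms bonded beyond their effective valence are flagged, not rejected.
    Explicit hydrogen neighbours count against the valence like any bond.
    """
    order_sum = [0.0] * len(graph.atoms)
    for bond in graph.bonds:
        v = _ORDER_VALENCE[bond.order]
        order_sum[bond.a] += v
        order_sum[bond.b] += v
    for i, atom in enumerate(graph.atoms):
        valence = effective_valence(atom.element, atom.formal_charge)
        if valence is None:
            atom.implicit_h_count = 0
            continue
        if atom.formal_charge == 0 and atom.element in HYPERVALENT_STATES:
            states = HYPERVALENT_STATES[atom.element]
            valence = next((v for v in states if v >= order_sum[i] - 1e-9),
                           states[-1])
        free = valence - order_sum[i]
        if free < -1e-9:
            atom.valence_flagged = True
            atom.implicit_h_count = 0
        else:
            atom.implicit_h_count = int(free + 1e-9)


def parse_molfile(text: str, mol_id: str = "") -> MolecularGraph:
    """Parse an MDL molfile (V2000) into a :class:`MolecularGraph`.

    Explicit hydrogens are retained as atoms; charges come from M CHG lines
    (which supersede legacy atom-block charge codes per the CTAB spec);
    V3000 input is rejected.
    """
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("molfile too short: no counts line", line=len(lines))
    counts = lines[3]
    if "V3000" in counts:
        raise ParseError("V3000 molfiles are not supported", line=4)
    try:
        n_atoms = int(counts[0:3])
        n_bonds = int(counts[3:6])
    except (ValueError, IndexError):
        raise ParseError(f"malformed counts line {counts!r}", line=4) from None
    if n_atoms < 0 or len(lines) < 4 + n_atoms + n_bonds:
        raise ParseError("counts line does not match block sizes", line=4)

    atoms: list[Atom] = []
    legacy_charges: list[int] = []
    for k in range(n_atoms):
        ln = 4 + k
        raw = lines[ln]
        symbol = raw[31:34].strip()
        if not symbol:
            parts = raw.split()
            symbol = parts[3] if len(parts) > 3 else ""
        if symbol not in PERIODIC_TABLE:
            raise ParseError(f"unknown element symbol {symbol!r}", line=ln + 1)

        def _intfield(lo: int, hi: int) -> int:
            chunk = raw[lo:hi].strip()
            try:
                return int(chunk) if chunk else 0
            except ValueError:
                return 0

        charge_code = _intfield(36, 39)
        parity_code = _intfield(39, 42)
        atom = Atom(element=symbol,
                    formal_charge=_LEGACY_CHARGE.get(charge_code, 0),
                    stereo_parity=_PARITY_FROM_CODE.get(parity_code,
                                                        AtomStereo.NONE))
        mass_diff = _intfield(34, 36)
        if mass_diff:
            atom.annotations["mass_diff"] = mass_diff
        atoms.append(atom)
        legacy_charges.append(atom.formal_charge)

    bonds: list[Bond] = []
    for k in range(n_bonds):
        ln = 4 + n_atoms + k
        raw = lines[ln]
        try:
            a = int(raw[0:3]) - 1
            b = int(raw[3:6]) - 1
            code = int(raw[6:9])
        except (ValueError, IndexError):
            raise ParseError(f"malformed bond line {raw!r}", line=ln + 1) from None
        stereo_chunk = raw[9:12].strip()
        scode = int(stereo_chunk) if stereo_chunk else 0
        if not (0 <= a < n_atoms and 0 <= b < n_atoms):
            raise ParseError(
                f"bond references atom {max(a, b) + 1} outside 1..{n_atoms}",
                line=ln + 1)
        if code not in _ORDER_FROM_CODE:
            raise ParseError(f"unsupported bond type {code}", line=ln + 1)
        order = _ORDER_FROM_CODE[code]
        if order is BondOrder.DOUBLE:
            stereo = BondStereo.CIS_TRANS if scode == 3 else BondStereo.NONE
        else:
            stereo = {1: BondStereo.UP, 6: BondStereo.DOWN}.get(
                scode, BondStereo.NONE)
        bonds.append(Bond(a, b, order, stereo))

    # Property block: M CHG resets all charges, M ISO/M RAD become annotations.
    chg_seen = False
    for k in range(4 + n_atoms + n_bonds, len(lines)):
        raw = lines[k]
        if raw.startswith("M  END"):
            break
        if raw.startswith("M  CHG"):
            if not chg_seen:
                for atom in atoms:
                    atom.formal_charge = 0
                chg_seen = True
            fields = raw.split()
            count = int(fields[2])
            vals = fields[3:3 + 2 * count]
            for idx, chg in zip(vals[0::2], vals[1::2]):
                atoms[int(idx) - 1].formal_charge = int(chg)
        elif raw.startswith("M  ISO"):
            fields = raw.split()
            for idx, iso in zip(fields[3::2], fields[4::2]):
                atoms[int(idx) - 1].annotations["isotope"] = int(iso)
        elif raw.startswith("M  RAD"):
            fields = raw.split()
            for idx, rad in zip(fields[3::2], fields[4::2]):
                atoms[int(idx) - 1].annotations["radical"] = int(rad)

    name = lines[0].strip()
    graph = MolecularGraph(atoms, bonds, id=mol_id or name)
    graph.validate()
    assign_implicit_hydrogens(graph)
    return graph


def write_molfile(graph: MolecularGraph) -> str:
    """Serialize a graph as an MDL molfile V2000 (charges via M CHG)."""
    graph.validate()
    n = len(graph.atoms)
    if n > 999:
        raise ValueError(
            f"{graph.id or 'graph'}: {n} atoms exceed the V2000 limit of 999")
    out = [graph.id, "  pathcolor", ""]
    out.append(f"{n:3d}{len(graph.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for atom in graph.atoms:
        parity = _CODE_FROM_PARITY[atom.stereo_parity]
        out.append(
            f"{0.0:10.4f}{0.0:10.4f}{0.0:10.4f} {atom.element:<3}"
            f" 0  0{parity:3d}  0  0  0  0  0  0  0  0  0")
    for bond in graph.bonds:
        code = _CODE_FROM_ORDER[bond.order]
        if bond.order is BondOrder.DOUBLE:
            scode = 3 if bond.stereo is BondStereo.CIS_TRANS else 0
        else:
            scode = {BondStereo.UP: 1, BondStereo.DOWN: 6}.get(bond.stereo, 0)
        out.append(f"{bond.a + 1:3d}{bond.b + 1:3d}{code:3d}{scode:3d}")
    charged = [(i, a.formal_charge) for i, a in enumerate(graph.atoms)
               if a.formal_charge]
    for start in range(0, len(charged), 8):
        chunk = charged[start:start + 8]
        line = f"M  CHG{len(chunk):3d}"
        for i, chg in chunk:
            line += f"{i + 1:4d}{chg:4d}"
        out.append(line)
    out.append("M  END")
    return "\n".join(out) + "\n"


def split_sdf(text: str) -> list[str]:
    """Split a concatenated SDF into individual molfile strings."""
    records = []
    for chunk in text.split("$$$$"):
        chunk = chunk.strip("\n")
        if chunk.strip():
            records.append(chunk + "\n")
    return records


@dataclass
class CompoundRecord:
    compound_id: str
    source_kb: str
    graph: MolecularGraph
    pathway_ids: set[str] = field(default_factory=set)


@dataclass
class PathwayRecord:
    pathway_id: str
    source_kb: str
    member_compound_ids: set[str] = field(default_factory=set)


def _read_annotations(path: Path) -> list[tuple[str, str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        for ln, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw.strip():
                continue
            parts = raw.split("\t")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{ln}: expected 2 tab-separated columns")
            if ln == 1 and parts[0].lower() in ("compound_id", "compound"):
                continue  # optional header
            rows.append((parts[0], parts[1]))
    return rows


def load_knowledgebase(structures_path: str | Path,
                       annotations_path: str | Path,
                       kb_name: str,
                       strict: bool = True,
                       ) -> tuple[list[CompoundRecord], list[PathwayRecord]]:
    """Load one knowledgebase from a directory of molfiles (or .sdf files)
    plus a two-column compound→pathway TSV.

    Pathway records are the inversion of the annotation table. Compounds
    without annotations are retained (they still produce negative pairs);
    pathways whose members all fail to resolve are dropped with a warning.
    With ``strict=False`` unparsable structures are skipped and logged
    instead of aborting the load.
    """
    structures_path = Path(structures_path)
    annotations_path = Path(annotations_path)
    graphs: dict[str, MolecularGraph] = {}
    files = sorted(structures_path.iterdir()) if structures_path.is_dir() else [structures_path]
    for f in files:
        if f.suffix.lower() not in (".mol", ".sdf", ".txt"):
            continue
        text = f.read_text(encoding="utf-8")
        blocks = split_sdf(text) if f.suffix.lower() == ".sdf" else [text]
        for block in blocks:
            cid = block.splitlines()[0].strip() or f.stem
            try:
                graphs[cid] = parse_molfile(block, mol_id=cid)
            except (ParseError, ValueError) as exc:
                if strict:
                    raise
                logger.warning("%s: skipping unparsable structure %s: %s",
                               kb_name, cid, exc)
    if not graphs:
        raise ValueError(f"knowledgebase {kb_name!r}: no structures found "
                         f"under {structures_path}")

    annotations = _read_annotations(annotations_path)
    missing = sorted({cid for cid, _ in annotations if cid not in graphs})
    if missing:
        raise ValueError(
            f"knowledgebase {kb_name!r}: annotations reference structures "
            f"with no molfile: {', '.join(missing)}")

    compounds = {cid: CompoundRecord(cid, kb_name, g)
                 for cid, g in sorted(graphs.items())}
    pathways: dict[str, PathwayRecord] = {}
    for cid, pid in annotations:
        compounds[cid].pathway_ids.add(pid)
        pathways.setdefault(pid, PathwayRecord(pid, kb_name)).member_compound_ids.add(cid)
    empty = [pid for pid, p in pathways.items() if not p.member_compound_ids]
    for pid in empty:
        logger.warning("%s: dropping pathway %s with no resolvable members",
                       kb_name, pid)
        del pathways[pid]
    return list(compounds.values()), [pathways[k] for k in sorted(pathways)]
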