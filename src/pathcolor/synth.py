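"""Synthetic multi-knowledgebase generator.

Emulates the situation the pipeline targets: several independently curated
knowledgebases whose compounds are valence-valid small molecules, whose
pathway memberships are driven by functional-group motifs (so involvement is
genuinely learnable from substructure counts), and whose cross-references
link entries that denote the same chemical entity but are drawn differently
— reordered atoms, explicit vs implicit hydrogens, alternate
charge-separated resonance forms, or tautomers. The last two are exactly the
inconsistencies an InChI round trip resolves; the first two are resolved by
the featurizer itself.

Every quantity is driven by a single seed; the same config and seed
reproduce a byte-identical molfile set.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from pathlib import Path

from .chem import (Atom, Bond, BondOrder, CompoundRecord, MolecularGraph,
                   PathwayRecord, assign_implicit_hydrogens, write_molfile)

PERTURBATION_KINDS = ("atom_reorder", "explicit_h",
                      "resonance_charge_form", "tautomer_swap")

#: Motif = (atoms as (element, charge), bonds as (i, j, order), attach index).
#: Attachment to the scaffold is always a single bond at the given local
#: atom. Every functional group is carried on a methylene (CH2) linker —
#: local atom 0 — so the group's own atoms sit in a stable first-shell
#: chemical environment regardless of where on the scaffold it lands.
def _linked(atoms, bonds):
    return ([("C", 0)] + atoms,
            [(0, 1, BondOrder.SINGLE)] +
            [(i + 1, j + 1, o) for i, j, o in bonds], 0)


MOTIFS: dict[str, tuple[list[tuple[str, int]], list[tuple[int, int, BondOrder]], int]] = {
    "carboxyl":  _linked([("C", 0), ("O", 0), ("O", 0)],
                         [(0, 1, BondOrder.DOUBLE), (0, 2, BondOrder.SINGLE)]),
    "hydroxyl":  _linked([("O", 0)], []),
    "amine":     _linked([("N", 0)], []),
    "thiol":     _linked([("S", 0)], []),
    "chloro":    _linked([("Cl", 0)], []),
    "fluoro":    _linked([("F", 0)], []),
    "bromo":     _linked([("Br", 0)], []),
    "nitrile":   _linked([("C", 0), ("N", 0)], [(0, 1, BondOrder.TRIPLE)]),
    "acetyl":    _linked([("C", 0), ("O", 0), ("C", 0)],
                         [(0, 1, BondOrder.DOUBLE), (0, 2, BondOrder.SINGLE)]),
    "methoxy":   _linked([("O", 0), ("C", 0)], [(0, 1, BondOrder.SINGLE)]),
    "phenyl":    _linked([("C", 0)] * 6,
                         [(0, 1, BondOrder.DOUBLE), (1, 2, BondOrder.SINGLE),
                          (2, 3, BondOrder.DOUBLE), (3, 4, BondOrder.SINGLE),
                          (4, 5, BondOrder.DOUBLE), (5, 0, BondOrder.SINGLE)]),
    "aldehyde":  _linked([("C", 0), ("O", 0)], [(0, 1, BondOrder.DOUBLE)]),
    "sulfonyl":  _linked([("S", 0), ("O", 0), ("O", 0), ("C", 0)],
                         [(0, 1, BondOrder.DOUBLE), (0, 2, BondOrder.DOUBLE),
                          (0, 3, BondOrder.SINGLE)]),
    "vinyl":     _linked([("C", 0), ("C", 0)], [(0, 1, BondOrder.DOUBLE)]),
    "isopropyl": _linked([("C", 0), ("C", 0), ("C", 0)],
                         [(0, 1, BondOrder.SINGLE), (0, 2, BondOrder.SINGLE)]),
    "iodo":      _linked([("I", 0)], []),
    "dimethylamino": _linked([("N", 0), ("C", 0), ("C", 0)],
                             [(0, 1, BondOrder.SINGLE),
                              (0, 2, BondOrder.SINGLE)]),
    "trifluoromethyl": _linked([("C", 0), ("F", 0), ("F", 0), ("F", 0)],
                               [(0, 1, BondOrder.SINGLE),
                                (0, 2, BondOrder.SINGLE),
                                (0, 3, BondOrder.SINGLE)]),
}

#: Default signature library: motifs whose color counts scale once per
#: occurrence. Groups with several equivalent atoms of one color (a phenyl
#: ring's CH carbons, CF3's fluorines) are excluded from the default —
#: their repeated colors would dominate aggregated pathway counts.
DEFAULT_LIBRARY = tuple(sorted(set(MOTIFS) - {"phenyl", "trifluoromethyl"}))

#: Decorations carried by a random subset of compounds; they host the
#: standardization-resolvable perturbation sites (amide -> tautomer swap,
#: charge-separated nitro -> resonance rewrite) and are never used as
#: pathway signature motifs.
DECORATIONS: dict[str, tuple[list[tuple[str, int]], list[tuple[int, int, BondOrder]], int]] = {
    "amide": ([("C", 0), ("O", 0), ("N", 0)],
              [(0, 1, BondOrder.DOUBLE), (0, 2, BondOrder.SINGLE)], 0),
    "nitro": ([("N", 1), ("O", 0), ("O", -1)],
              [(0, 1, BondOrder.DOUBLE), (0, 2, BondOrder.SINGLE)], 0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    n_kbs: int = 3
    compounds_per_kb: int = 150
    pathways_per_kb: int = 30
    motif_library: tuple[str, ...] = DEFAULT_LIBRARY
    membership_noise: float = 0.05
    crossref_fraction: float = 0.5
    perturbation_mix: tuple[tuple[str, float], ...] = (
        ("atom_reorder", 0.1), ("explicit_h", 0.1),
        ("resonance_charge_form", 0.4), ("tautomer_swap", 0.4))
    #: Partition signature motifs disjointly across knowledgebases, so each
    #: KB defines its pathways over its own chemistry (no two KBs share a
    #: pathway definition) — mirrors independently curated resources.
    disjoint_kb_motifs: bool = True
    seed: int = 0

    def __post_init__(self):
        if not self.motif_library:
            raise ValueError("motif_library must be nonempty")
        unknown = set(self.motif_library) - set(MOTIFS)
        if unknown:
            raise ValueError(f"unknown motifs: {sorted(unknown)}")
        if not (0 <= self.membership_noise < 0.5):
            raise ValueError("membership_noise must lie in [0, 0.5)")
        if not (0 <= self.crossref_fraction <= 1):
            raise ValueError("crossref_fraction must lie in [0, 1]")
        kinds = [k for k, _ in self.perturbation_mix]
        if set(kinds) - set(PERTURBATION_KINDS) or any(
                w < 0 for _, w in self.perturbation_mix):
            raise ValueError("invalid perturbation_mix")


@dataclass(frozen=True)
class CrossReference:
    kb_a: str
    compound_id_a: str
    kb_b: str
    compound_id_b: str
    perturbation: str


@dataclass
class SyntheticKB:
    compounds: dict[str, list[CompoundRecord]]
    pathways: dict[str, list[PathwayRecord]]
    crossrefs: list[CrossReference]
    #: kb -> {(compound_id, pathway_id): bool} prior to noise flips.
    membership_true: dict[str, dict[tuple[str, str], bool]]
    signatures: dict[str, dict[str, frozenset[str]]]
    compound_motifs: dict[str, dict[str, frozenset[str]]]
    config: SyntheticConfig

    def kb_names(self) -> list[str]:
        return sorted(self.compounds)

    def all_compounds(self) -> list[CompoundRecord]:
        return [c for kb in self.kb_names() for c in self.compounds[kb]]

    def all_pathways(self) -> list[PathwayRecord]:
        return [p for kb in self.kb_names() for p in self.pathways[kb]]

    def graph_of(self, kb: str, compound_id: str) -> MolecularGraph:
        for c in self.compounds[kb]:
            if c.compound_id == compound_id:
                return c.graph
        raise KeyError(f"{kb}:{compound_id}")

    def write_to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        for kb in self.kb_names():
            mol_dir = outdir / kb / "molfiles"
            mol_dir.mkdir(parents=True, exist_ok=True)
            for c in self.compounds[kb]:
                (mol_dir / f"{c.compound_id}.mol").write_text(
                    write_molfile(c.graph), encoding="utf-8")
            with open(outdir / kb / "annotations.tsv", "w",
                      encoding="utf-8") as fh:
                for c in self.compounds[kb]:
                    for pid in sorted(c.pathway_ids):
                        fh.write(f"{c.compound_id}\t{pid}\n")
        with open(outdir / "crossrefs.tsv", "w", encoding="utf-8") as fh:
            fh.write("kb_a\tcompound_id_a\tkb_b\tcompound_id_b\tperturbation\n")
            for x in self.crossrefs:
                fh.write(f"{x.kb_a}\t{x.compound_id_a}\t{x.kb_b}"
                         f"\t{x.compound_id_b}\t{x.perturbation}\n")


class InapplicablePerturbation(ValueError):
    pass


def _graft(graph: MolecularGraph, free: list[int], site: int,
           motif: tuple) -> None:
    atoms, bonds, attach = motif
    base = len(graph.atoms)
    for elem, chg in atoms:
        graph.atoms.append(Atom(element=elem, formal_charge=chg))
    for i, j, order in bonds:
        graph.bonds.append(Bond(base + i, base + j, order))
    graph.bonds.append(Bond(site, base + attach, BondOrder.SINGLE))
    free[site] -= 1


def _make_compound(rng: random.Random, motif_names: list[str],
                   decorations: list[str],
                   mol_id: str) -> tuple[MolecularGraph, frozenset[str]]:
    """Minimal alkyl scaffold (1-2 carbons) with the given motifs and
    decorations grafted at random carbons.

    The scaffold is deliberately small so that a pathway's aggregated color
    counts are dominated by its signature motifs rather than by generic
    chain-carbon colors — mirroring real pathway chemistry, where member
    compounds share characteristic functional groups, not bulk backbone."""
    length = rng.randint(1, 3)
    atoms = [Atom("C") for _ in range(length)]
    bonds = [Bond(i, i + 1, BondOrder.SINGLE) for i in range(length - 1)]
    graph = MolecularGraph(atoms, bonds, id=mol_id)
    free = [4 - sum(1 for b in bonds if i in (b.a, b.b))
            for i in range(length)]
    attachments = list(motif_names) + list(decorations)
    for name in attachments:
        sites = [i for i in range(length) if free[i] > 0]
        if not sites:
            raise RuntimeError("scaffold out of valence slots")
        site = rng.choice(sites)
        motif = MOTIFS.get(name) or DECORATIONS[name]
        _graft(graph, free, site, motif)
    assign_implicit_hydrogens(graph)
    graph.validate()
    return graph, frozenset(motif_names)


def _perturb_atom_reorder(graph: MolecularGraph,
                          rng: random.Random) -> MolecularGraph:
    perm = list(range(len(graph.atoms)))
    rng.shuffle(perm)
    return graph.permuted(perm)


def _perturb_explicit_h(graph: MolecularGraph) -> MolecularGraph:
    out = MolecularGraph(
        [replace(a, annotations=dict(a.annotations)) for a in graph.atoms],
        [Bond(b.a, b.b, b.order, b.stereo) for b in graph.bonds],
        id=graph.id)
    for i in range(len(graph.atoms)):
        for _ in range(out.atoms[i].implicit_h_count):
            out.atoms.append(Atom("H"))
            out.bonds.append(Bond(i, len(out.atoms) - 1, BondOrder.SINGLE))
        out.atoms[i].implicit_h_count = 0
    assign_implicit_hydrogens(out)
    return out


def _degree(graph: MolecularGraph, i: int) -> int:
    return sum(1 for b in graph.bonds if i in (b.a, b.b))


def _find_amide_site(graph: MolecularGraph):
    """Return (C=O bond, C-N bond) of an amide, or (C-O, C=N) of its imidic
    acid form — the two interconvert by swapping the bond orders."""
    for i, atom in enumerate(graph.atoms):
        if atom.element != "C":
            continue
        o_bond = n_bond = None
        for j, bond in graph.neighbors(i):
            other = graph.atoms[j]
            if other.element == "O" and other.formal_charge == 0 and \
                    _degree(graph, j) == 1:
                o_bond = bond
            elif other.element == "N" and other.formal_charge == 0 and \
                    _degree(graph, j) == 1:
                n_bond = bond
        if o_bond is None or n_bond is None:
            continue
        orders = {o_bond.order, n_bond.order}
        if orders == {BondOrder.SINGLE, BondOrder.DOUBLE}:
            return o_bond, n_bond
    return None


def _perturb_tautomer(graph: MolecularGraph) -> MolecularGraph:
    out = MolecularGraph(
        [replace(a, annotations=dict(a.annotations)) for a in graph.atoms],
        [Bond(b.a, b.b, b.order, b.stereo) for b in graph.bonds],
        id=graph.id)
    site = _find_amide_site(out)
    if site is None:
        raise InapplicablePerturbation(
            f"{graph.id}: no amide/imidic-acid site for tautomer_swap")
    o_bond, n_bond = site
    o_bond.order, n_bond.order = n_bond.order, o_bond.order
    assign_implicit_hydrogens(out)
    return out


def _find_nitro(graph: MolecularGraph):
    """(N index, double-O bond, single-O bond) of a nitro group, in either
    its charge-separated or pentavalent form."""
    for i, atom in enumerate(graph.atoms):
        if atom.element != "N":
            continue
        o_bonds = [(j, b) for j, b in graph.neighbors(i)
                   if graph.atoms[j].element == "O" and _degree(graph, j) == 1]
        if len(o_bonds) != 2:
            continue
        orders = sorted(b.order.value for _, b in o_bonds)
        if atom.formal_charge == 1 and orders == ["double", "single"]:
            dbl = next(x for x in o_bonds if x[1].order is BondOrder.DOUBLE)
            sgl = next(x for x in o_bonds if x[1].order is BondOrder.SINGLE)
            return i, dbl, sgl, "charged"
        if atom.formal_charge == 0 and orders == ["double", "double"]:
            a, b = sorted(o_bonds)
            return i, a, b, "pentavalent"
    return None


def _perturb_resonance(graph: MolecularGraph) -> MolecularGraph:
    """Toggle a nitro group between its charge-separated form
    ([O-]-[N+]=O) and the neutral pentavalent form (O=N=O)."""
    out = MolecularGraph(
        [replace(a, annotations=dict(a.annotations)) for a in graph.atoms],
        [Bond(b.a, b.b, b.order, b.stereo) for b in graph.bonds],
        id=graph.id)
    site = _find_nitro(out)
    if site is None:
        raise InapplicablePerturbation(
            f"{graph.id}: no nitro site for resonance_charge_form")
    n_idx, (j1, b1), (j2, b2), form = site
    if form == "charged":
        out.atoms[n_idx].formal_charge = 0
        out.atoms[j1].formal_charge = 0
        out.atoms[j2].formal_charge = 0
        b1.order = b2.order = BondOrder.DOUBLE
    else:
        out.atoms[n_idx].formal_charge = 1
        out.atoms[j1].formal_charge = 0
        out.atoms[j2].formal_charge = -1
        b1.order = BondOrder.DOUBLE
        b2.order = BondOrder.SINGLE
    assign_implicit_hydrogens(out)
    return out


def perturb_representation(graph: MolecularGraph, kind: str,
                           rng: random.Random | None = None,
                           ) -> MolecularGraph:
    """Rewrite a graph into an alternate representation of the same entity.

    ``atom_reorder`` and ``explicit_h`` are resolved by the featurizer
    alone; ``resonance_charge_form`` and ``tautomer_swap`` require InChI
    standardization to resolve.
    """
    if kind == "atom_reorder":
        return _perturb_atom_reorder(graph, rng or random.Random(0))
    if kind == "explicit_h":
        return _perturb_explicit_h(graph)
    if kind == "resonance_charge_form":
        return _perturb_resonance(graph)
    if kind == "tautomer_swap":
        return _perturb_tautomer(graph)
    raise ValueError(f"unknown perturbation kind {kind!r}")


def _assign_signatures(rng: random.Random, config: SyntheticConfig,
                       kb_names: list[str]):
    """Per KB: a motif subset and one signature combo per pathway.

    Signatures are single motifs (85%) or motif pairs (15%), sampled with
    replacement — distinct pathways can share a definition, as real
    knowledgebases do (duplicated pathway feature vectors are merged later
    by the dataset de-duplication or kept as near-identical rows)."""
    motifs = list(config.motif_library)
    per_kb: dict[str, list[str]] = {}
    if config.disjoint_kb_motifs:
        shuffled = motifs[:]
        rng.shuffle(shuffled)
        chunk = len(shuffled) // len(kb_names)
        if chunk < 2:
            raise ValueError("motif_library too small for disjoint KB subsets")
        for k, kb in enumerate(kb_names):
            per_kb[kb] = sorted(shuffled[k * chunk:(k + 1) * chunk])
    else:
        per_kb = {kb: motifs for kb in kb_names}
    signatures: dict[str, dict[str, frozenset[str]]] = {}
    for kb in kb_names:
        pool = per_kb[kb]
        sigs = {}
        for p in range(config.pathways_per_kb):
            if rng.random() < 0.85 or len(pool) < 2:
                sig = frozenset({rng.choice(pool)})
            else:
                sig = frozenset(rng.sample(pool, 2))
            sigs[f"{kb}_P{p:03d}"] = sig
        signatures[kb] = sigs
    return signatures, per_kb


def generate(config: SyntheticConfig = SyntheticConfig()) -> SyntheticKB:
    """Generate the full multi-knowledgebase fixture (deterministic in seed)."""
    rng = random.Random(config.seed)
    kb_names = [f"KB{k + 1}" for k in range(config.n_kbs)]
    signatures, motif_pools = _assign_signatures(rng, config, kb_names)

    compounds: dict[str, list[CompoundRecord]] = {kb: [] for kb in kb_names}
    compound_motifs: dict[str, dict[str, frozenset[str]]] = {kb: {} for kb in kb_names}

    decorated: dict[str, dict[str, list[str]]] = {kb: {} for kb in kb_names}
    for kb in kb_names:
        pool = motif_pools[kb]
        for c in range(config.compounds_per_kb):
            cid = f"{kb}_C{c:04d}"
            k = rng.randint(1, min(3, len(pool)))
            chosen = sorted(rng.sample(pool, k))
            u = rng.random()  # at most one decoration per compound
            decs = ["amide"] if u < 0.25 else (["nitro"] if u < 0.5 else [])
            graph, motifs = _make_compound(rng, chosen, decs, cid)
            compounds[kb].append(CompoundRecord(cid, kb, graph))
            compound_motifs[kb][cid] = motifs
            decorated[kb][cid] = decs

    # Cross-references: copy a fraction of each KB's compounds into the next
    # KB under a sampled representation perturbation. The perturbation kind
    # is drawn first; the source compound is drawn among those with an
    # applicable site (any compound for atom_reorder / explicit_h, one with
    # an amide for tautomer_swap, one with a nitro group for the resonance
    # rewrite).
    crossrefs: list[CrossReference] = []
    kinds = [k for k, w in config.perturbation_mix if w > 0]
    weights = [w for _, w in config.perturbation_mix if w > 0]
    _needs = {"tautomer_swap": "amide", "resonance_charge_form": "nitro"}
    for ki, kb in enumerate(kb_names):
        if config.n_kbs < 2 or config.crossref_fraction == 0:
            break
        target = kb_names[(ki + 1) % config.n_kbs]
        n_xref = int(round(config.crossref_fraction * config.compounds_per_kb))
        remaining = list(compounds[kb][:config.compounds_per_kb])
        for x in range(n_xref):
            src = None
            for _attempt in range(20):
                kind = rng.choices(kinds, weights=weights)[0]
                need = _needs.get(kind)
                eligible = [c for c in remaining
                            if need is None
                            or need in decorated[kb][c.compound_id]]
                if eligible:
                    src = rng.choice(eligible)
                    break
            if src is None:
                raise RuntimeError(
                    "no compound with an applicable perturbation site left")
            remaining.remove(src)
            twin_id = f"{target}_X{kb}{x:04d}"
            twin = perturb_representation(src.graph, kind, rng)
            twin.id = twin_id
            compounds[target].append(CompoundRecord(twin_id, target, twin))
            compound_motifs[target][twin_id] = compound_motifs[kb][src.compound_id]
            decorated[target][twin_id] = decorated[kb][src.compound_id]
            crossrefs.append(CrossReference(kb, src.compound_id, target,
                                            twin_id, kind))

    # Motif-containment memberships, then per-bit noise flips.
    pathways: dict[str, list[PathwayRecord]] = {}
    membership_true: dict[str, dict[tuple[str, str], bool]] = {}
    for kb in kb_names:
        truth: dict[tuple[str, str], bool] = {}
        recs = {pid: PathwayRecord(pid, kb) for pid in signatures[kb]}
        for comp in compounds[kb]:
            motifs = compound_motifs[kb][comp.compound_id]
            for pid, sig in signatures[kb].items():
                has = sig <= motifs
                truth[(comp.compound_id, pid)] = has
                if rng.random() < config.membership_noise:
                    has = not has
                if has:
                    comp.pathway_ids.add(pid)
                    recs[pid].member_compound_ids.add(comp.compound_id)
        membership_true[kb] = truth
        pathways[kb] = [recs[pid] for pid in sorted(recs)
                        if recs[pid].member_compound_ids]

    return SyntheticKB(compounds=compounds, pathways=pathways,
                       crossrefs=crossrefs, membership_true=membership_true,
                       signatures=signatures, compound_motifs=compound_motifs,
                       config=config)
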