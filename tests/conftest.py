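"""Shared fixtures: curated small molecules and synthetic knowledgebases."""

from __future__ import annotations

import random

import pytest

from pathcolor.chem import (Atom, Bond, BondOrder, AtomStereo, BondStereo,
                            MolecularGraph, assign_implicit_hydrogens)
from pathcolor.synth import SyntheticConfig, generate


def make_graph(atoms, bonds, mol_id="g") -> MolecularGraph:
    """Build a graph from (element, charge) tuples and (a, b, order) bonds
    and fill implicit hydrogens from the standard valence table."""
    g = MolecularGraph(
        [Atom(element=e, formal_charge=c) for e, c in atoms],
        [Bond(a, b, o) for a, b, o in bonds],
        id=mol_id)
    assign_implicit_hydrogens(g)
    g.validate()
    return g


S, D, T = BondOrder.SINGLE, BondOrder.DOUBLE, BondOrder.TRIPLE


@pytest.fixture
def methane():
    return make_graph([("C", 0)], [], "methane")


@pytest.fixture
def ethanol():
    return make_graph([("C", 0), ("C", 0), ("O", 0)],
                      [(0, 1, S), (1, 2, S)], "ethanol")


@pytest.fixture
def benzene():
    bonds = [(i, (i + 1) % 6, D if i % 2 == 0 else S) for i in range(6)]
    return make_graph([("C", 0)] * 6, bonds, "benzene")


@pytest.fixture
def acetamide():
    # CC(=O)N
    return make_graph([("C", 0), ("C", 0), ("O", 0), ("N", 0)],
                      [(0, 1, S), (1, 2, D), (1, 3, S)], "acetamide")


@pytest.fixture
def imidic_acid():
    # CC(O)=N — the amide's tautomer
    return make_graph([("C", 0), ("C", 0), ("O", 0), ("N", 0)],
                      [(0, 1, S), (1, 2, S), (1, 3, D)], "imidic")


@pytest.fixture
def nitro_charged():
    # C-[N+](=O)[O-]
    return make_graph([("C", 0), ("N", 1), ("O", 0), ("O", -1)],
                      [(0, 1, S), (1, 2, D), (1, 3, S)], "nitro_charged")


@pytest.fixture
def nitro_pentavalent():
    return make_graph([("C", 0), ("N", 0), ("O", 0), ("O", 0)],
                      [(0, 1, S), (1, 2, D), (1, 3, D)], "nitro_penta")


def stereo_pair_rs():
    """Two bromochlorofluoromethane-like graphs differing only in the
    tetrahedral parity flag of the central carbon."""
    atoms = [("C", 0), ("F", 0), ("Cl", 0), ("Br", 0)]
    bonds = [(0, 1, S), (0, 2, S), (0, 3, S)]
    a = make_graph(atoms, bonds, "rs_odd")
    b = make_graph(atoms, bonds, "rs_even")
    a.atoms[0].stereo_parity = AtomStereo.ODD
    b.atoms[0].stereo_parity = AtomStereo.EVEN
    return a, b


def stereo_pair_ez():
    """2-butene-like graphs differing only in the double-bond stereo flag."""
    atoms = [("C", 0), ("C", 0), ("C", 0), ("C", 0)]
    bonds = [(0, 1, S), (1, 2, D), (2, 3, S)]
    a = make_graph(atoms, bonds, "ez_flagged")
    b = make_graph(atoms, bonds, "ez_plain")
    a.bonds[1].stereo = BondStereo.CIS_TRANS
    return a, b


@pytest.fixture(scope="session")
def small_kb():
    """A compact 2-KB synthetic fixture for pipeline-level tests."""
    return generate(SyntheticConfig(n_kbs=2, compounds_per_kb=25,
                                    pathways_per_kb=8, seed=3))


@pytest.fixture(scope="session")
def fixture_molecules(small_kb):
    """Curated + generated molecules with at most 10 heavy atoms."""
    curated = [
        make_graph([("C", 0)], [], "methane"),
        make_graph([("C", 0), ("C", 0), ("O", 0)], [(0, 1, S), (1, 2, S)],
                   "ethanol"),
        make_graph([("C", 0)] * 6,
                   [(i, (i + 1) % 6, D if i % 2 == 0 else S)
                    for i in range(6)], "benzene"),
        make_graph([("C", 0), ("C", 0), ("O", 0), ("N", 0)],
                   [(0, 1, S), (1, 2, D), (1, 3, S)], "acetamide"),
        make_graph([("C", 0), ("N", 1), ("O", 0), ("O", -1)],
                   [(0, 1, S), (1, 2, D), (1, 3, S)], "nitromethane"),
    ]
    generated = [c.graph for c in small_kb.all_compounds()
                 if c.graph.n_heavy() <= 10]
    return curated + generated


@pytest.fixture(scope="session")
def molecule_batch():
    """A larger batch of synthetic molecules for property tests."""
    kb = generate(SyntheticConfig(n_kbs=3, compounds_per_kb=112,
                                  pathways_per_kb=8, seed=11))
    return [c.graph for c in kb.all_compounds()]
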