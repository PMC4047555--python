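"""Shared fixtures: tiny hand-written molecules and mol2 texts."""

from __future__ import annotations

import pytest
from hypothesis import settings

from somkit.chemio import Atom, Molecule, make_bond

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


def make_molecule(mol_id: str, types: list[str], bonds: list[tuple[int, int]]) -> Molecule:
    """Molecule from 1-based typed atoms and bond pairs."""
    atoms = tuple(
        Atom(index=i, element=t.split(".", 1)[0], sybyl_type=t)
        for i, t in enumerate(types, start=1)
    )
    return Molecule(
        mol_id=mol_id, atoms=atoms, bonds=frozenset(make_bond(a, b) for a, b in bonds)
    )


@pytest.fixture
def methane_mol2(tmp_path):
    text = """@<TRIPOS>MOLECULE
methane
5 4 0 0 0
SMALL
NO_CHARGES
@<TRIPOS>ATOM
1 C1 0.0 0.0 0.0 C.3 1 UNK 0.0
2 H1 0.6 0.6 0.6 H 1 UNK 0.0
3 H2 -0.6 -0.6 0.6 H 1 UNK 0.0
4 H3 -0.6 0.6 -0.6 H 1 UNK 0.0
5 H4 0.6 -0.6 -0.6 H 1 UNK 0.0
@<TRIPOS>BOND
1 1 2 1
2 1 3 1
3 1 4 1
4 1 5 1
"""
    path = tmp_path / "methane.mol2"
    path.write_text(text)
    return path


@pytest.fixture
def methane():
    return make_molecule("methane", ["C.3", "H", "H", "H", "H"], [(1, 2), (1, 3), (1, 4), (1, 5)])


@pytest.fixture
def ethanol():
    # CH3-CH2-OH with explicit hydrogens: C1(H4,H5,H6) C2(H7,H8) O3(H9)
    return make_molecule(
        "ethanol",
        ["C.3", "C.3", "O.3", "H", "H", "H", "H", "H", "H"],
        [(1, 2), (2, 3), (1, 4), (1, 5), (1, 6), (2, 7), (2, 8), (3, 9)],
    )


@pytest.fixture
def benzene():
    types = ["C.ar"] * 6 + ["H"] * 6
    ring = [(i, i % 6 + 1) for i in range(1, 7)]
    hs = [(i, i + 6) for i in range(1, 7)]
    return make_molecule("benzene", types, ring + hs)


@pytest.fixture
def para_xylene():
    # heavy atoms only: aromatic ring 1-6, methyls 7 (on C1) and 8 (on C4)
    types = ["C.ar"] * 6 + ["C.3", "C.3"]
    ring = [(i, i % 6 + 1) for i in range(1, 7)]
    return make_molecule("para_xylene", types, ring + [(1, 7), (4, 8)])
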