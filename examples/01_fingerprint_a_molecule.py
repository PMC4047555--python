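"""Circular fingerprints and equivalent-atom detection on small molecules.

Builds ethanol and benzene as typed graphs, prints the layered type-count
fingerprint of each heavy atom, and shows how topologically equivalent
positions collapse to a single ranked entry.
"""

from somkit.chemio import Atom, Molecule, make_bond
from somkit.fingerprints import build_alphabet, circular_fingerprint, equivalence_classes


def molecule(mol_id, types, bonds):
    atoms = tuple(
        Atom(index=i, element=t.split(".", 1)[0], sybyl_type=t)
        for i, t in enumerate(types, start=1)
    )
    return Molecule(mol_id, atoms, frozenset(make_bond(a, b) for a, b in bonds))


ethanol = molecule(
    "ethanol",
    ["C.3", "C.3", "O.3", "H", "H", "H", "H", "H", "H"],
    [(1, 2), (2, 3), (1, 4), (1, 5), (1, 6), (2, 7), (2, 8), (3, 9)],
)
benzene = molecule(
    "benzene",
    ["C.ar"] * 6 + ["H"] * 6,
    [(i, i % 6 + 1) for i in range(1, 7)] + [(i, i + 6) for i in range(1, 7)],
)

alphabet = build_alphabet([ethanol, benzene])
print(f"alphabet ({alphabet.size} types): {', '.join(alphabet.types)}")

depth = 2
print(f"\nethanol fingerprints at depth {depth} (layer-major, L={alphabet.vector_length(depth)}):")
for atom in ethanol.heavy_atoms():
    fp = circular_fingerprint(ethanol, atom.index, depth, alphabet)
    print(f"  atom {atom.index} ({atom.sybyl_type}): {fp.tolist()}")
# each layer k sums to the number of atoms exactly k bonds away

print("\nequivalence classes (whole-molecule fingerprints):")
for mol in (ethanol, benzene):
    classes = equivalence_classes(mol, alphabet=alphabet)
    print(f"  {mol.mol_id}: {classes}")
# benzene's six carbons form one class -> they count once in any ranking
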