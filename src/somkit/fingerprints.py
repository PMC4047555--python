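"""Atom-centred 2D topological circular fingerprints.

An atomic site is described by counting SYBYL atom types in concentric
bond-distance shells around it: layer ``k`` of the fingerprint holds, for
each type ``t`` of a fixed alphabet, the number of atoms at topological
distance exactly ``k`` (minimum bond count) carrying type ``t``.  For bond
depth ``d`` and an alphabet of ``A`` types the vector has length
``L = (d + 1) * A``, laid out layer-major (all layer-0 type counts first,
then layer 1, ...).  Only 2D connectivity enters: no coordinates, charges
or perceived chemistry.

Topologically equivalent atoms (e.g. the six carbons of benzene) are
detected by comparing whole-molecule-spanning fingerprints, i.e. circular
fingerprints computed to the graph diameter: atoms whose full fingerprints
are identical are interchangeable for ranking purposes.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .chemio import (
    NONSOM,
    SOM,
    Molecule,
    SiteRecord,
    SoMAnnotation,
)

__all__ = [
    "TypeAlphabet",
    "AlphabetError",
    "ConsistencyError",
    "build_alphabet",
    "topological_distances",
    "graph_diameter",
    "circular_fingerprint",
    "equivalence_classes",
    "candidate_atoms",
    "build_dataset",
]


class AlphabetError(KeyError):
    """An atom type outside the alphabet was encountered.

    Signals that the alphabet was built from a different corpus than the
    molecule being fingerprinted.
    """


class ConsistencyError(ValueError):
    """Annotations and molecules disagree (missing molecule or atom)."""


@dataclass(frozen=True)
class TypeAlphabet:
    """Ordered, duplicate-free list of SYBYL atom-type strings.

    The ordering is fixed (lexicographic when built by
    :func:`build_alphabet`) and must be persisted with any dataset, since
    it defines the meaning of every feature index.
    """

    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.types)) != len(self.types):
            raise ValueError("alphabet contains duplicate types")

    @property
    def size(self) -> int:
        return len(self.types)

    def index(self, sybyl_type: str) -> int:
        try:
            return self._index_map[sybyl_type]
        except KeyError:
            raise AlphabetError(
                f"atom type {sybyl_type!r} not in alphabet (built from a different corpus?)"
            ) from None

    @property
    def _index_map(self) -> Mapping[str, int]:
        cached = self.__dict__.get("_index_cache")
        if cached is None:
            cached = {t: i for i, t in enumerate(self.types)}
            object.__setattr__(self, "_index_cache", cached)
        return cached

    def vector_length(self, depth: int) -> int:
        return (depth + 1) * self.size


def build_alphabet(molecules: Iterable[Molecule]) -> TypeAlphabet:
    """Union of SYBYL types over a corpus, sorted lexicographically."""
    types = sorted({a.sybyl_type for mol in molecules for a in mol.atoms})
    return TypeAlphabet(types=tuple(types))


def topological_distances(molecule: Molecule, centre_atom: int) -> dict[int, int]:
    """Breadth-first bond distances from ``centre_atom``.

    Atoms in other connected components (counter-ions in salt entries) are
    absent from the map; they contribute nothing to any fingerprint layer.
    """
    molecule.atom(centre_atom)  # raises KeyError if absent
    dist = {centre_atom: 0}
    queue = deque([centre_atom])
    adjacency = molecule.adjacency
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def graph_diameter(molecule: Molecule) -> int:
    """Largest shortest-path distance within any connected component."""
    best = 0
    for atom in molecule.atoms:
        d = topological_distances(molecule, atom.index)
        best = max(best, max(d.values()))
    return best


def circular_fingerprint(
    molecule: Molecule,
    centre_atom: int,
    depth: int,
    alphabet: TypeAlphabet,
) -> np.ndarray:
    """Layered type-count vector for one atomic site.

    ``counts[k * A + t] = #{atoms at distance exactly k with type t}``.
    Layer 0 is the centre atom itself (sums to 1); layers beyond the
    molecule's diameter are all zero.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    counts = np.zeros(alphabet.vector_length(depth), dtype=np.int64)
    A = alphabet.size
    for atom_index, d in topological_distances(molecule, centre_atom).items():
        if d > depth:
            continue
        t = alphabet.index(molecule.atom(atom_index).sybyl_type)
        counts[d * A + t] += 1
    return counts


def candidate_atoms(molecule: Molecule, include_h_sites: bool = False) -> tuple[int, ...]:
    """Atoms eligible as rankable/labelable sites.

    By default only heavy atoms are candidates (hydrogen abstraction is
    attributed to the attached heavy atom); hydrogens still contribute
    counts *inside* every fingerprint.
    """
    if include_h_sites:
        return tuple(a.index for a in molecule.atoms)
    return tuple(a.index for a in molecule.atoms if a.is_heavy)


def equivalence_classes(
    molecule: Molecule,
    candidates: Sequence[int] | None = None,
    alphabet: TypeAlphabet | None = None,
) -> list[tuple[int, ...]]:
    """Partition candidate atoms by identical whole-molecule fingerprints.

    Fingerprints are computed at depth = graph diameter, the smallest depth
    guaranteed to span the entire ligand, so symmetric positions (benzene
    carbons, para-substituted ring pairs) land in one group.  Groups are
    returned sorted by their lowest member index; members sorted ascending.
    """
    if candidates is None:
        candidates = candidate_atoms(molecule)
    if alphabet is None:
        alphabet = build_alphabet([molecule])
    depth = graph_diameter(molecule)
    groups: dict[bytes, list[int]] = {}
    for idx in candidates:
        fp = circular_fingerprint(molecule, idx, depth, alphabet)
        groups.setdefault(fp.tobytes(), []).append(idx)
    return sorted((tuple(sorted(g)) for g in groups.values()), key=lambda g: g[0])


def build_dataset(
    molecules: Sequence[Molecule],
    annotations: Sequence[SoMAnnotation],
    depth: int,
    alphabet: TypeAlphabet | None = None,
    include_h_sites: bool = False,
) -> tuple[list[SiteRecord], TypeAlphabet]:
    """Fingerprint every candidate atom and label it SoM / non-SoM.

    One record per candidate atom per molecule, in molecule input order and
    ascending atom index — the output is therefore byte-stable across runs.
    The alphabet defaults to the sorted type union over the corpus.
    Molecules without an annotation entry contribute only non-SoM records.
    """
    if alphabet is None:
        alphabet = build_alphabet(molecules)
    by_id = {m.mol_id: m for m in molecules}
    som_map: dict[str, frozenset[int]] = {}
    for ann in annotations:
        if ann.mol_id not in by_id:
            raise ConsistencyError(f"annotation references missing molecule {ann.mol_id!r}")
        som_map[ann.mol_id] = som_map.get(ann.mol_id, frozenset()) | ann.som_atoms
    records: list[SiteRecord] = []
    for mol in molecules:
        cands = candidate_atoms(mol, include_h_sites=include_h_sites)
        som_atoms = som_map.get(mol.mol_id, frozenset())
        known = {a.index for a in mol.atoms}
        missing = som_atoms - known
        if missing:
            raise ConsistencyError(
                f"{mol.mol_id}: annotated atoms {sorted(missing)} do not exist"
            )
        stray = som_atoms - set(cands)
        if stray:
            raise ConsistencyError(
                f"{mol.mol_id}: annotated atoms {sorted(stray)} are not candidate sites "
                "(hydrogens? pass include_h_sites=True)"
            )
        for idx in sorted(cands):
            fp = circular_fingerprint(mol, idx, depth, alphabet)
            records.append(
                SiteRecord(
                    mol_id=mol.mol_id,
                    atom_index=idx,
                    label=SOM if idx in som_atoms else NONSOM,
                    features=tuple(int(v) for v in fp),
                )
            )
    return records, alphabet
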