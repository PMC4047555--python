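"""Synthetic corpora with a plantable local SoM signal.

The generator produces random connected molecular graphs (uniform random
spanning tree plus a few chord edges, degree capped at 4) with SYBYL-like
atom types sampled i.i.d. from a small alphabet.  A *motif* — an optional
centre type plus required neighbour-type counts at given bond distances —
defines which atoms carry the planted signal: motif-matching atoms become
SoMs with one probability, all other atoms with a (usually much lower)
background probability.

Because the motif is expressed as per-shell type counts, it is exactly
representable in circular-fingerprint space at any depth at or above the
motif depth, and invisible below it.  With the default wildcard centre and
i.i.d. types, depth-0 fingerprints (the centre type alone) carry no class
information at all, so depth-0 classifiers sit at chance by construction.

No chemical realism is claimed: no valence rules beyond the degree cap,
no aromaticity, no real SoM chemotypes.  The corpora exist to make every
pipeline stage testable without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .chemio import Atom, Molecule, SiteRecord, SoMAnnotation, make_bond
from .fingerprints import TypeAlphabet, build_dataset, topological_distances

__all__ = [
    "Motif",
    "SynthConfig",
    "GenerationError",
    "default_config",
    "generate_molecule",
    "matches_motif",
    "generate_corpus",
    "generate_site_dataset",
]

#: SYBYL-like types used by the default generator (heavy atoms only; the
#: signal is topological, hydrogens would only dilute the shells)
DEFAULT_ALPHABET: tuple[str, ...] = ("C.2", "C.3", "C.ar", "N.3", "O.2", "O.3")


class GenerationError(RuntimeError):
    """The generator could not satisfy its contract (e.g. empty corpus)."""


@dataclass(frozen=True)
class Motif:
    """A local topological pattern: centre type + required shell counts.

    ``layers`` maps bond distance -> {type: minimum count}.  An atom
    matches when its own type equals ``centre_type`` (or always, when
    ``centre_type`` is None) and every shell requirement is met.  The
    motif depth is the largest constrained distance.
    """

    centre_type: str | None = None
    layers: Mapping[int, Mapping[str, int]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return max(self.layers.keys(), default=0)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic corpus.

    Defaults define the planted-signal benchmark: 60 molecules of 10–16
    atoms, a depth-2 motif (≥1 N.3 at distance 1 and ≥1 O.2 at distance 2,
    any centre type), deterministic labels (motif probability 1, background
    0).  All fields are free to vary for other studies.
    """

    n_molecules: int = 60
    min_atoms: int = 10
    max_atoms: int = 16
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    motif: Motif = field(
        default_factory=lambda: Motif(
            centre_type=None, layers={1: {"N.3": 1}, 2: {"O.2": 1}}
        )
    )
    motif_som_prob: float = 1.0
    background_som_prob: float = 0.0
    extra_edge_prob: float = 0.15
    max_degree: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.motif_som_prob <= 1.0):
            raise ValueError("motif_som_prob must lie in [0, 1]")
        if not (0.0 <= self.background_som_prob <= 1.0):
            raise ValueError("background_som_prob must lie in [0, 1]")
        if self.min_atoms < 2 or self.max_atoms < self.min_atoms:
            raise ValueError("need max_atoms >= min_atoms >= 2")
        required = {
            t for layer in self.motif.layers.values() for t in layer
        }
        if self.motif.centre_type is not None:
            required.add(self.motif.centre_type)
        missing = required - set(self.alphabet)
        if missing:
            raise ValueError(
                f"motif requires types absent from the alphabet: {sorted(missing)}"
            )


def default_config(seed: int = 0, **overrides) -> SynthConfig:
    """The canonical planted-signal study conditions, reseeded."""
    return SynthConfig(seed=seed, **overrides)


def generate_molecule(
    rng: np.random.Generator,
    mol_id: str,
    n_atoms: int,
    alphabet: Sequence[str],
    extra_edge_prob: float = 0.15,
    max_degree: int = 4,
) -> Molecule:
    """One random connected typed graph.

    A random spanning tree guarantees connectivity (each new atom bonds to
    a uniformly chosen earlier atom with spare valence); chord edges are
    then added independently with ``extra_edge_prob`` per eligible pair,
    respecting the degree cap.
    """
    types = [alphabet[int(rng.integers(len(alphabet)))] for _ in range(n_atoms)]
    degree = [0] * (n_atoms + 1)
    bonds: set[tuple[int, int]] = set()
    for i in range(2, n_atoms + 1):
        open_atoms = [a for a in range(1, i) if degree[a] < max_degree]
        if not open_atoms:  # unreachable with max_degree >= 2, kept defensive
            raise GenerationError("no atom with spare valence for the spanning tree")
        parent = int(open_atoms[int(rng.integers(len(open_atoms)))])
        bonds.add(make_bond(parent, i))
        degree[parent] += 1
        degree[i] += 1
    for a in range(1, n_atoms + 1):
        for b in range(a + 1, n_atoms + 1):
            if make_bond(a, b) in bonds:
                continue
            if degree[a] >= max_degree or degree[b] >= max_degree:
                continue
            if rng.random() < extra_edge_prob:
                bonds.add(make_bond(a, b))
                degree[a] += 1
                degree[b] += 1
    atoms = tuple(
        Atom(index=i, element=types[i - 1].split(".", 1)[0], sybyl_type=types[i - 1])
        for i in range(1, n_atoms + 1)
    )
    return Molecule(mol_id=mol_id, atoms=atoms, bonds=frozenset(bonds))


def matches_motif(molecule: Molecule, atom_index: int, motif: Motif) -> bool:
    """Does the atom's local environment satisfy every motif requirement?"""
    atom = molecule.atom(atom_index)
    if motif.centre_type is not None and atom.sybyl_type != motif.centre_type:
        return False
    dist = topological_distances(molecule, atom_index)
    for d, requirement in motif.layers.items():
        shell = [molecule.atom(i).sybyl_type for i, dd in dist.items() if dd == d]
        for t, min_count in requirement.items():
            if shell.count(t) < min_count:
                return False
    return True


def generate_corpus(
    config: SynthConfig,
) -> tuple[list[Molecule], list[SoMAnnotation]]:
    """Molecules plus SoM annotations, reproducible from the config seed.

    Each atom is labelled SoM with ``motif_som_prob`` if it matches the
    planted motif, else with ``background_som_prob``.  Molecules whose SoM
    set comes out empty get no annotation entry (they still contribute
    non-SoM sites downstream).
    """
    if config.n_molecules < 1:
        raise GenerationError("n_molecules must be >= 1")
    rng = np.random.default_rng(config.seed)
    molecules: list[Molecule] = []
    annotations: list[SoMAnnotation] = []
    for m in range(1, config.n_molecules + 1):
        n_atoms = int(rng.integers(config.min_atoms, config.max_atoms + 1))
        mol = generate_molecule(
            rng,
            f"synth{m:04d}",
            n_atoms,
            config.alphabet,
            extra_edge_prob=config.extra_edge_prob,
            max_degree=config.max_degree,
        )
        molecules.append(mol)
        som: set[int] = set()
        for atom in mol.atoms:
            p = (
                config.motif_som_prob
                if matches_motif(mol, atom.index, config.motif)
                else config.background_som_prob
            )
            if rng.random() < p:
                som.add(atom.index)
        if som:
            annotations.append(SoMAnnotation(mol_id=mol.mol_id, som_atoms=frozenset(som)))
    return molecules, annotations


def generate_site_dataset(
    config: SynthConfig, depth: int, max_attempts: int = 100
) -> tuple[list[SiteRecord], TypeAlphabet]:
    """Fingerprinted, labelled site records for a generated corpus.

    Guarantees both classes non-empty: if a draw yields no SoM (or no
    non-SoM) site, the corpus is regenerated with an incremented sub-seed,
    up to ``max_attempts`` times.
    """
    if depth < config.motif.depth:
        # legal, but the planted signal is not encodable at this depth;
        # callers probing depth-dependence do this deliberately
        pass
    for attempt in range(max_attempts):
        cfg = (
            config
            if attempt == 0
            else SynthConfig(**{**config.__dict__, "seed": config.seed + attempt})
        )
        molecules, annotations = generate_corpus(cfg)
        records, alphabet = build_dataset(molecules, annotations, depth)
        labels = {r.label for r in records}
        if len(labels) == 2:
            return records, alphabet
    raise GenerationError(
        f"could not realise both classes in {max_attempts} attempts "
        "(probabilities too extreme for the corpus size?)"
    )
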