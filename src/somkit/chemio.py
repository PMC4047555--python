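"""Readers and writers for the formats the toolkit touches.

Three kinds of input/output live here:

* TRIPOS mol2 files carrying the substrate structures.  Only the
  ``@<TRIPOS>MOLECULE``, ``ATOM`` and ``BOND`` blocks are interpreted; the
  SYBYL atom type is taken verbatim from column 6 of each ATOM record.
  Coordinates and partial charges are parsed but unused — the method is
  purely topological.
* Site-of-metabolism (SoM) annotations: a tab-separated sidecar file keyed
  by molecule id and 1-based atom index (mol2 files stay standard).
* Per-site fingerprint datasets: a TSV with one row per atomic site,
  a ``SOM``/``NONSOM`` label column and ``L`` integer feature columns, plus
  a comment header recording bond depth and the atom-type alphabet so that
  externally produced files can be adapted by a thin mapping.

Atom indices are 1-based throughout, following the mol2 convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Molecule",
    "SoMAnnotation",
    "SiteRecord",
    "SiteDataset",
    "SOM",
    "NONSOM",
    "Mol2ParseError",
    "Mol2StructureError",
    "AnnotationFormatError",
    "SiteDatasetError",
    "read_mol2",
    "write_mol2",
    "read_annotations",
    "write_annotations",
    "read_site_dataset",
    "write_site_dataset",
]

#: class labels: omega_0 = SoM (positive class), omega_1 = non-SoM
SOM = "SOM"
NONSOM = "NONSOM"


class Mol2ParseError(ValueError):
    """Malformed mol2 syntax; message names the offending line number."""


class Mol2StructureError(ValueError):
    """Structurally invalid molecule (e.g. bond to a missing atom)."""


class AnnotationFormatError(ValueError):
    """Malformed SoM annotation line."""


class SiteDatasetError(ValueError):
    """Malformed or inconsistent site-dataset file."""


@dataclass(frozen=True)
class Atom:
    """One atom of a molecular graph.

    ``index`` is the 1-based position in the mol2 ATOM block; ``sybyl_type``
    is the SYBYL atom-type string (e.g. ``"C.3"``, ``"N.ar"``, ``"H"``).
    """

    index: int
    element: str
    sybyl_type: str

    def __post_init__(self) -> None:
        if not self.sybyl_type:
            raise ValueError("sybyl_type must be non-empty")
        if self.index < 1:
            raise ValueError("atom indices are 1-based")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class Molecule:
    """A typed atom/bond graph.  Bonds are unordered 1-based index pairs."""

    mol_id: str
    atoms: tuple[Atom, ...]
    bonds: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        indices = [a.index for a in self.atoms]
        if len(set(indices)) != len(indices):
            raise Mol2StructureError(f"{self.mol_id}: duplicate atom indices")
        known = set(indices)
        for a, b in self.bonds:
            if a == b:
                raise Mol2StructureError(f"{self.mol_id}: self-loop bond on atom {a}")
            if a not in known or b not in known:
                raise Mol2StructureError(
                    f"{self.mol_id}: bond ({a},{b}) references a missing atom"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def atom(self, index: int) -> Atom:
        try:
            return self._atom_map[index]
        except KeyError:
            raise KeyError(f"{self.mol_id}: no atom with index {index}") from None

    @property
    def _atom_map(self) -> Mapping[int, Atom]:
        # cached on first use; frozen dataclass so stash via object.__setattr__
        cached = self.__dict__.get("_atom_map_cache")
        if cached is None:
            cached = {a.index: a for a in self.atoms}
            object.__setattr__(self, "_atom_map_cache", cached)
        return cached

    def neighbors(self, index: int) -> tuple[int, ...]:
        return self.adjacency.get(index, ())

    @property
    def adjacency(self) -> Mapping[int, tuple[int, ...]]:
        cached = self.__dict__.get("_adjacency_cache")
        if cached is None:
            adj: dict[int, list[int]] = {a.index: [] for a in self.atoms}
            for a, b in sorted(self.bonds):
                adj[a].append(b)
                adj[b].append(a)
            cached = {k: tuple(sorted(v)) for k, v in adj.items()}
            object.__setattr__(self, "_adjacency_cache", cached)
        return cached

    def heavy_atoms(self) -> tuple[Atom, ...]:
        return tuple(a for a in self.atoms if a.is_heavy)


def make_bond(a: int, b: int) -> tuple[int, int]:
    """Canonical (sorted) unordered bond pair."""
    if a == b:
        raise Mol2StructureError(f"self-loop bond on atom {a}")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class SoMAnnotation:
    """Experimentally observed sites of metabolism for one molecule."""

    mol_id: str
    som_atoms: frozenset[int]

    def __post_init__(self) -> None:
        if any(i < 1 for i in self.som_atoms):
            raise AnnotationFormatError(f"{self.mol_id}: atom indices are 1-based")


@dataclass(frozen=True)
class SiteRecord:
    """One atomic site: provenance, class label and integer feature vector."""

    mol_id: str
    atom_index: int
    label: str
    features: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.label not in (SOM, NONSOM):
            raise SiteDatasetError(f"unknown label {self.label!r}")
        if any(f < 0 for f in self.features):
            raise SiteDatasetError(
                f"{self.mol_id}/{self.atom_index}: negative feature count"
            )


@dataclass(frozen=True)
class SiteDataset:
    """A collection of site records plus the metadata needed to interpret them."""

    records: tuple[SiteRecord, ...]
    depth: int | None = None
    alphabet: tuple[str, ...] | None = None

    @property
    def n_features(self) -> int | None:
        return len(self.records[0].features) if self.records else None


# ---------------------------------------------------------------------------
# mol2
# ---------------------------------------------------------------------------


def _element_from_sybyl(sybyl_type: str) -> str:
    return sybyl_type.split(".", 1)[0]


def read_mol2(path: str | Path) -> list[Molecule]:
    """Parse a TRIPOS mol2 file into molecules, one per ``@<TRIPOS>MOLECULE``.

    SYBYL atom types come verbatim from column 6 of the ATOM records; bonds
    from the BOND block.  Coordinates/charges are ignored.
    """
    lines = Path(path).read_text().splitlines()
    # locate MOLECULE block starts
    starts = [i for i, ln in enumerate(lines) if ln.strip() == "@<TRIPOS>MOLECULE"]
    if not starts:
        raise Mol2ParseError("no @<TRIPOS>MOLECULE block found")
    molecules: list[Molecule] = []
    for bi, start in enumerate(starts):
        end = starts[bi + 1] if bi + 1 < len(starts) else len(lines)
        molecules.append(_parse_molecule_block(lines, start, end))
    return molecules


def _parse_molecule_block(lines: Sequence[str], start: int, end: int) -> Molecule:
    if start + 2 >= end:
        raise Mol2ParseError(f"line {start + 1}: truncated MOLECULE block")
    mol_id = lines[start + 1].strip()
    counts = lines[start + 2].split()
    try:
        n_atoms = int(counts[0])
        n_bonds = int(counts[1]) if len(counts) > 1 else 0
    except (IndexError, ValueError):
        raise Mol2ParseError(
            f"line {start + 3}: malformed MOLECULE counts record"
        ) from None

    atoms: list[Atom] = []
    bonds: set[tuple[int, int]] = set()
    section = None
    for lineno in range(start + 1, end):
        raw = lines[lineno]
        stripped = raw.strip()
        if stripped.startswith("@<TRIPOS>"):
            section = stripped[len("@<TRIPOS>") :]
            continue
        if not stripped or stripped.startswith("#"):
            continue
        if section == "ATOM":
            cols = stripped.split()
            if len(cols) < 6:
                raise Mol2ParseError(
                    f"line {lineno + 1}: ATOM record has {len(cols)} columns, expected >= 6"
                )
            try:
                idx = int(cols[0])
            except ValueError:
                raise Mol2ParseError(
                    f"line {lineno + 1}: non-integer atom id {cols[0]!r}"
                ) from None
            sybyl = cols[5]
            atoms.append(Atom(index=idx, element=_element_from_sybyl(sybyl), sybyl_type=sybyl))
        elif section == "BOND":
            cols = stripped.split()
            if len(cols) < 3:
                raise Mol2ParseError(
                    f"line {lineno + 1}: BOND record has {len(cols)} columns, expected >= 3"
                )
            try:
                a, b = int(cols[1]), int(cols[2])
            except ValueError:
                raise Mol2ParseError(
                    f"line {lineno + 1}: non-integer bond endpoint"
                ) from None
            bonds.add(make_bond(a, b))
        # other sections ignored
    if len(atoms) != n_atoms:
        raise Mol2ParseError(
            f"molecule {mol_id!r}: MOLECULE record declares {n_atoms} atoms, "
            f"found {len(atoms)}"
        )
    if len(bonds) != n_bonds:
        # duplicate bond lines collapse; declared count is advisory then
        pass
    return Molecule(mol_id=mol_id, atoms=tuple(atoms), bonds=frozenset(bonds))


def write_mol2(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as a minimal mol2 file (zero coordinates and charges).

    Round-trips the atom/bond graph losslessly: id, SYBYL types and bonds.
    """
    out: list[str] = []
    for mol in molecules:
        bonds = sorted(mol.bonds)
        out.append("@<TRIPOS>MOLECULE")
        out.append(mol.mol_id)
        out.append(f"{mol.n_atoms} {len(bonds)} 0 0 0")
        out.append("SMALL")
        out.append("NO_CHARGES")
        out.append("@<TRIPOS>ATOM")
        for a in sorted(mol.atoms, key=lambda x: x.index):
            out.append(
                f"{a.index} {a.element}{a.index} 0.0000 0.0000 0.0000 {a.sybyl_type} 1 UNK 0.0000"
            )
        out.append("@<TRIPOS>BOND")
        for i, (a, b) in enumerate(bonds, start=1):
            out.append(f"{i} {a} {b} 1")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# SoM annotations
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> list[SoMAnnotation]:
    """Read the sidecar annotation TSV: ``mol_id<TAB>i,j,k`` per line.

    Duplicate mol_id lines are merged by set union.  Blank lines and ``#``
    comments are allowed.
    """
    merged: dict[str, set[int]] = {}
    order: list[str] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise AnnotationFormatError(
                f"line {lineno}: expected 'mol_id<TAB>indices', got {raw!r}"
            )
        mol_id, idx_field = parts[0].strip(), parts[1].strip()
        indices: set[int] = set()
        for tok in idx_field.split(","):
            tok = tok.strip()
            try:
                value = int(tok)
            except ValueError:
                raise AnnotationFormatError(
                    f"line {lineno}: atom index {tok!r} is not an integer"
                ) from None
            if value < 1:
                raise AnnotationFormatError(
                    f"line {lineno}: atom index {value} is not a positive "
                    "1-based index"
                )
            indices.add(value)
        if mol_id not in merged:
            merged[mol_id] = set()
            order.append(mol_id)
        merged[mol_id] |= indices
    return [SoMAnnotation(mol_id=m, som_atoms=frozenset(merged[m])) for m in order]


def write_annotations(annotations: Iterable[SoMAnnotation], path: str | Path) -> None:
    out = []
    for ann in annotations:
        idx = ",".join(str(i) for i in sorted(ann.som_atoms))
        out.append(f"{ann.mol_id}\t{idx}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# site datasets
# ---------------------------------------------------------------------------

_DATASET_MAGIC = "# somkit-site-dataset v1"


def write_site_dataset(
    records: Sequence[SiteRecord],
    path: str | Path,
    *,
    depth: int | None = None,
    alphabet: Sequence[str] | None = None,
) -> None:
    """Write site records as TSV (UTF-8, Unix newlines, bit-exact round-trip).

    The comment header records the bond depth and the atom-type alphabet in
    layer-major order so that files can be interpreted without the code that
    produced them.
    """
    lengths = {len(r.features) for r in records}
    if len(lengths) > 1:
        raise SiteDatasetError(f"records have inconsistent feature lengths {sorted(lengths)}")
    n_features = lengths.pop() if lengths else 0
    lines = [_DATASET_MAGIC]
    if depth is not None:
        lines.append(f"# depth={depth}")
    if alphabet is not None:
        lines.append("# alphabet=" + ",".join(alphabet))
    header = ["mol_id", "atom_index", "label"] + [f"f{i}" for i in range(1, n_features + 1)]
    lines.append("\t".join(header))
    for r in records:
        row = [r.mol_id, str(r.atom_index), r.label] + [str(f) for f in r.features]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_site_dataset(path: str | Path) -> SiteDataset:
    """Read a site-dataset TSV written by :func:`write_site_dataset`.

    Externally produced fingerprint tables can be adapted to this dialect
    by a thin mapping (columns: mol_id, atom_index, label in {SOM, NONSOM},
    then the L feature columns).
    """
    depth: int | None = None
    alphabet: tuple[str, ...] | None = None
    header: list[str] | None = None
    records: list[SiteRecord] = []
    n_features: int | None = None
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if raw.startswith("#"):
            body = raw[1:].strip()
            if body.startswith("depth="):
                depth = int(body[len("depth=") :])
            elif body.startswith("alphabet="):
                alphabet = tuple(t for t in body[len("alphabet=") :].split(",") if t)
            continue
        if not raw.strip():
            continue
        cols = raw.split("\t")
        if header is None:
            header = cols
            if cols[:3] != ["mol_id", "atom_index", "label"]:
                raise SiteDatasetError(
                    f"line {lineno}: header must start with mol_id, atom_index, label"
                )
            n_features = len(cols) - 3
            continue
        if len(cols) != len(header):
            raise SiteDatasetError(
                f"line {lineno}: ragged row ({len(cols)} columns, header has {len(header)})"
            )
        mol_id, idx_s, label = cols[0], cols[1], cols[2]
        try:
            atom_index = int(idx_s)
        except ValueError:
            raise SiteDatasetError(f"line {lineno}: bad atom index {idx_s!r}") from None
        feats: list[int] = []
        for tok in cols[3:]:
            try:
                v = int(tok)
            except ValueError:
                raise SiteDatasetError(f"line {lineno}: non-integer feature {tok!r}") from None
            if v < 0:
                raise SiteDatasetError(f"line {lineno}: negative feature count {v}")
            feats.append(v)
        records.append(
            SiteRecord(mol_id=mol_id, atom_index=atom_index, label=label, features=tuple(feats))
        )
    if header is None:
        raise SiteDatasetError("missing header row")
    return SiteDataset(records=tuple(records), depth=depth, alphabet=alphabet)


def records_to_matrices(
    records: Sequence[SiteRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Split records into (X_som, X_nonsom) integer matrices.

    Either matrix may be empty (shape ``(0, L)``); downstream training
    rejects empty classes.
    """
    lengths = {len(r.features) for r in records}
    if len(lengths) > 1:
        raise SiteDatasetError("records have inconsistent feature lengths")
    L = lengths.pop() if lengths else 0
    som = [r.features for r in records if r.label == SOM]
    non = [r.features for r in records if r.label == NONSOM]
    X0 = np.asarray(som, dtype=np.int64).reshape(len(som), L)
    X1 = np.asarray(non, dtype=np.int64).reshape(len(non), L)
    return X0, X1
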