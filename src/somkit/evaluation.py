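"""Molecule-level evaluation of site-of-metabolism predictions.

The protocol is leave-one-out cross-validation at the *molecule* level:
every molecule in turn is held out entirely (all of its atomic sites),
an ensemble is trained on the sites of the remaining molecules, and the
held-out sites are scored.  Per molecule, sites are ranked by SoM
probability after collapsing topologically equivalent atoms (identical
whole-ligand circular fingerprints) to a single entry, so a six-fold
symmetric ring counts once.

Metrics:

* MCC at the majority-vote operating point (probability > 0.5 -> SoM;
  exact half-votes conservatively called non-SoM), pooled over all folds.
* ROC curve / AUC by threshold sweep over the achievable vote-fraction
  grid, pooled over folds into a single curve; trapezoidal integration.
  Probability ties are handled by the threshold sweep itself, which is
  equivalent to half-credit pair counting (Mann-Whitney U).
* top-k%: the percentage of evaluated molecules for which at least one
  true SoM appears among the k highest-ranked equivalence classes.

A similarity-split analysis is also provided: a random 20% test set (TS1)
and its most-dissimilar half (TS2), with dissimilarity measured by the
maximum path-based Tanimoto similarity of a test molecule to any training
molecule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .chemio import NONSOM, SOM, Molecule, SiteRecord, SoMAnnotation
from .classifiers import OMEGA0, OMEGA1
from .ensemble import EnsembleConfig, EnsembleModel, train_ensemble
from .fingerprints import TypeAlphabet, build_dataset, candidate_atoms, equivalence_classes

__all__ = [
    "RankedSite",
    "ConfusionCounts",
    "MetricsReport",
    "FoldError",
    "CoverageError",
    "UndefinedAUCError",
    "loo_folds",
    "rank_sites",
    "best_som_rank",
    "top_k_percent",
    "confusion_counts",
    "mcc",
    "roc_points",
    "roc_auc",
    "evaluate_loo",
    "evaluate_records",
    "evaluate_holdout",
    "scan_q",
    "linear_paths",
    "tanimoto",
    "similarity_split",
    "max_similarity_to_set",
]


class FoldError(ValueError):
    """Cross-validation is impossible (fewer than two molecules)."""


class CoverageError(ValueError):
    """A candidate atom has no predicted probability."""


class UndefinedAUCError(ValueError):
    """ROC/AUC requested with only one class present."""


@dataclass(frozen=True)
class RankedSite:
    """One ranked equivalence class of atoms in a molecule.

    ``atom_index`` is the representative (lowest member index); ``members``
    the full equivalence class; ``rank`` starts at 1 for the most likely
    SoM.
    """

    mol_id: str
    atom_index: int
    members: tuple[int, ...]
    probability: float
    rank: int


@dataclass(frozen=True)
class ConfusionCounts:
    """Site-level confusion counts at the 0.5 vote-fraction threshold."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Per-configuration evaluation summary.

    ``best_ranks`` maps each evaluated molecule to the rank of its
    best-ranked true SoM equivalence class.  ``top1/top2/top3`` are
    percentages of molecules.  The config echo pins down exactly what was
    run.
    """

    mcc: float
    auc: float
    top1: float
    top2: float
    top3: float
    n_molecules: int
    n_sites: int
    confusion: ConfusionCounts
    best_ranks: tuple[tuple[str, int], ...]
    roc: tuple[tuple[float, float], ...]  # (fpr, tpr) points
    base: str
    depth: int | None
    q: int | str
    j: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "mcc": self.mcc,
            "auc": self.auc,
            "top1": self.top1,
            "top2": self.top2,
            "top3": self.top3,
            "n_molecules": self.n_molecules,
            "n_sites": self.n_sites,
            "confusion": {
                "tp": self.confusion.tp,
                "fp": self.confusion.fp,
                "tn": self.confusion.tn,
                "fn": self.confusion.fn,
            },
            "best_ranks": dict(self.best_ranks),
            "base": self.base,
            "depth": self.depth,
            "q": self.q,
            "j": self.j,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# folds and ranking
# ---------------------------------------------------------------------------


def loo_folds(
    records: Sequence[SiteRecord],
    eval_mol_ids: Sequence[str] | None = None,
) -> Iterator[tuple[list[SiteRecord], str, list[SiteRecord]]]:
    """Yield ``(train_records, held_out_mol_id, test_records)`` per molecule.

    All sites of the held-out molecule are excluded from training in its
    fold.  ``eval_mol_ids`` restricts which molecules get their own fold
    (e.g. only annotated ones); molecules outside the list still
    contribute training records to every fold.
    """
    mol_order: list[str] = []
    seen: set[str] = set()
    for r in records:
        if r.mol_id not in seen:
            seen.add(r.mol_id)
            mol_order.append(r.mol_id)
    if len(mol_order) < 2:
        raise FoldError("leave-one-out needs at least two molecules")
    targets = list(eval_mol_ids) if eval_mol_ids is not None else mol_order
    for mol_id in targets:
        if mol_id not in seen:
            raise FoldError(f"no records for molecule {mol_id!r}")
        train = [r for r in records if r.mol_id != mol_id]
        test = [r for r in records if r.mol_id == mol_id]
        assert not any(r.mol_id == mol_id for r in train)
        yield train, mol_id, test


def rank_sites(
    mol_id: str,
    probabilities: Mapping[int, float],
    eq_classes: Sequence[Sequence[int]],
) -> list[RankedSite]:
    """Collapse equivalent atoms and rank classes by SoM probability.

    Equivalent atoms share fingerprints, hence identical probabilities at
    the modelled depth — asserted here.  Descending probability; ties
    broken by ascending representative atom index (deterministic).
    """
    entries: list[tuple[float, int, tuple[int, ...]]] = []
    for group in eq_classes:
        members = tuple(sorted(group))
        rep = members[0]
        for m in members:
            if m not in probabilities:
                raise CoverageError(f"{mol_id}: no probability for atom {m}")
        p = probabilities[rep]
        if any(abs(probabilities[m] - p) > 1e-12 for m in members):
            raise AssertionError(
                f"{mol_id}: equivalent atoms {members} carry different probabilities"
            )
        entries.append((p, rep, members))
    entries.sort(key=lambda e: (-e[0], e[1]))
    return [
        RankedSite(mol_id=mol_id, atom_index=rep, members=members, probability=p, rank=i)
        for i, (p, rep, members) in enumerate(entries, start=1)
    ]


def best_som_rank(ranked: Sequence[RankedSite], som_atoms: Iterable[int]) -> int | None:
    """Rank of the best-ranked equivalence class containing a true SoM."""
    som = set(som_atoms)
    hits = [r.rank for r in ranked if som & set(r.members)]
    return min(hits) if hits else None


def top_k_percent(best_ranks: Sequence[int], k: int) -> float:
    """Percentage of molecules whose best true-SoM rank is <= k."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not best_ranks:
        raise ValueError("no molecules to evaluate")
    hits = sum(1 for r in best_ranks if r <= k)
    return 100.0 * hits / len(best_ranks)


# ---------------------------------------------------------------------------
# classification metrics
# ---------------------------------------------------------------------------


def confusion_counts(
    labels: Sequence[int], probabilities: Sequence[float], threshold: float = 0.5
) -> ConfusionCounts:
    """Confusion counts with SoM called iff probability strictly exceeds the
    threshold (an exact half-vote tie goes to non-SoM, the conservative
    call)."""
    tp = fp = tn = fn = 0
    for y, p in zip(labels, probabilities, strict=True):
        pred_som = p > threshold
        if y == OMEGA0:
            tp += pred_som
            fn += not pred_som
        else:
            fp += pred_som
            tn += not pred_som
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; zero-denominator convention -> 0."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def roc_points(
    probabilities: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float]]:
    """ROC (FPR, TPR) points from a descending threshold sweep.

    Thresholds are the distinct achieved probabilities (the vote-fraction
    grid, multiples of ``1/(2j)``) plus the endpoints (0,0) and (1,1);
    probability ties are resolved by the sweep, never by per-site order.
    """
    labels = list(labels)
    probabilities = list(probabilities)
    n_pos = sum(1 for y in labels if y == OMEGA0)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("ROC needs both classes present")
    points = [(0.0, 0.0)]
    tp = fp = 0
    order = sorted(zip(probabilities, labels), key=lambda t: -t[0])
    i = 0
    while i < len(order):
        p = order[i][0]
        while i < len(order) and order[i][0] == p:
            if order[i][1] == OMEGA0:
                tp += 1
            else:
                fp += 1
            i += 1
        points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def roc_auc(probabilities: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, trapezoidal rule over the sweep points."""
    pts = roc_points(probabilities, labels)
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    return float(np.trapezoid(ys, xs))


# ---------------------------------------------------------------------------
# end-to-end evaluation
# ---------------------------------------------------------------------------


def _fold_seed(master_seed: int, fold_index: int) -> int:
    """Deterministic per-fold seed below 2**31 derived from the master seed."""
    state = np.random.SeedSequence([master_seed, fold_index]).generate_state(1)[0]
    return int(state % (2**31))


def _evaluate_prepared(
    records: Sequence[SiteRecord],
    eq_by_mol: Mapping[str, Sequence[Sequence[int]]],
    som_by_mol: Mapping[str, frozenset[int]],
    config: EnsembleConfig,
    depth: int | None,
) -> MetricsReport:
    eval_mols = [m for m in dict.fromkeys(r.mol_id for r in records) if som_by_mol.get(m)]
    if not eval_mols:
        raise FoldError("no molecule has a non-empty SoM annotation")
    pooled_labels: list[int] = []
    pooled_probs: list[float] = []
    best_ranks: list[tuple[str, int]] = []
    n_sites = 0
    for fold_index, (train, mol_id, test) in enumerate(loo_folds(records, eval_mols)):
        fold_cfg = replace(config, seed=_fold_seed(config.seed, fold_index))
        model = train_ensemble(train, fold_cfg, depth=depth)
        probs: dict[int, float] = {}
        for rec in test:
            p, _ = model.predict(np.asarray(rec.features))
            probs[rec.atom_index] = p
            pooled_labels.append(OMEGA0 if rec.label == SOM else OMEGA1)
            pooled_probs.append(p)
            n_sites += 1
        ranked = rank_sites(mol_id, probs, eq_by_mol[mol_id])
        rank = best_som_rank(ranked, som_by_mol[mol_id])
        if rank is None:  # annotation invariant guarantees this cannot happen
            raise CoverageError(f"{mol_id}: no ranked class contains a true SoM")
        best_ranks.append((mol_id, rank))
    counts = confusion_counts(pooled_labels, pooled_probs)
    ranks_only = [r for _, r in best_ranks]
    return MetricsReport(
        mcc=mcc(counts),
        auc=roc_auc(pooled_probs, pooled_labels),
        top1=top_k_percent(ranks_only, 1),
        top2=top_k_percent(ranks_only, 2),
        top3=top_k_percent(ranks_only, 3),
        n_molecules=len(eval_mols),
        n_sites=n_sites,
        confusion=counts,
        best_ranks=tuple(best_ranks),
        roc=tuple(roc_points(pooled_probs, pooled_labels)),
        base=config.base,
        depth=depth,
        q=config.q,
        j=config.j,
        seed=config.seed,
    )


def evaluate_loo(
    molecules: Sequence[Molecule],
    annotations: Sequence[SoMAnnotation],
    depth: int,
    config: EnsembleConfig,
    *,
    include_h_sites: bool = False,
    alphabet: TypeAlphabet | None = None,
) -> MetricsReport:
    """Molecule-level LOO evaluation from structures + annotations.

    Molecules with an empty/missing annotation are never held out (their
    SoM status is unknown) but their sites always augment the non-SoM
    training pool.  Equivalent-atom collapsing uses exact whole-ligand
    fingerprints.
    """
    records, alpha = build_dataset(
        molecules, annotations, depth, alphabet=alphabet, include_h_sites=include_h_sites
    )
    eq_by_mol = {
        m.mol_id: equivalence_classes(
            m, candidate_atoms(m, include_h_sites=include_h_sites), alpha
        )
        for m in molecules
    }
    som_by_mol = {a.mol_id: a.som_atoms for a in annotations if a.som_atoms}
    return _evaluate_prepared(records, eq_by_mol, som_by_mol, config, depth)


def evaluate_records(
    records: Sequence[SiteRecord],
    config: EnsembleConfig,
    *,
    depth: int | None = None,
) -> MetricsReport:
    """LOO evaluation from a site dataset alone (no molecular graphs).

    Without structures, equivalent sites are proxied by identical feature
    vectors at the dataset depth — a coarser collapse than whole-ligand
    fingerprints when the dataset depth is below the graph diameter.
    """
    eq_by_mol: dict[str, list[tuple[int, ...]]] = {}
    som_by_mol: dict[str, set[int]] = {}
    for mol_id in dict.fromkeys(r.mol_id for r in records):
        mol_records = [r for r in records if r.mol_id == mol_id]
        groups: dict[tuple[int, ...], list[int]] = {}
        for r in mol_records:
            groups.setdefault(r.features, []).append(r.atom_index)
        eq_by_mol[mol_id] = sorted(
            (tuple(sorted(g)) for g in groups.values()), key=lambda g: g[0]
        )
        som = {r.atom_index for r in mol_records if r.label == SOM}
        if som:
            som_by_mol[mol_id] = som
    som_frozen = {m: frozenset(s) for m, s in som_by_mol.items()}
    return _evaluate_prepared(records, eq_by_mol, som_frozen, config, depth)


def scan_q(
    molecules: Sequence[Molecule],
    annotations: Sequence[SoMAnnotation],
    depth: int,
    base: str,
    q_grid: Sequence[int | str],
    j: int,
    seed: int,
    *,
    h: float = 0.1,
    include_h_sites: bool = False,
) -> list[MetricsReport]:
    """Full LOO evaluation at every subsample length on the grid.

    The conventional grid runs from 5 to L in steps of 5; plateau or
    collapse behaviour is reported, never enforced.
    """
    reports = []
    for q in q_grid:
        cfg = EnsembleConfig(base=base, q=q, j=j, seed=seed, h=h)  # type: ignore[arg-type]
        reports.append(
            evaluate_loo(
                molecules, annotations, depth, cfg, include_h_sites=include_h_sites
            )
        )
    return reports


def evaluate_holdout(
    train_molecules: Sequence[Molecule],
    test_molecules: Sequence[Molecule],
    annotations: Sequence[SoMAnnotation],
    depth: int,
    config: EnsembleConfig,
    *,
    include_h_sites: bool = False,
) -> MetricsReport:
    """Train once on one molecule set, score another (similarity-split use).

    Only annotated test molecules are evaluated; metrics are computed
    exactly as in :func:`evaluate_loo` but with a single train/test split.
    """
    corpus = list(train_molecules) + list(test_molecules)
    ann_by_mol = {a.mol_id: a for a in annotations}
    train_ids = {m.mol_id for m in train_molecules}
    records, alpha = build_dataset(
        corpus,
        [a for a in annotations if a.mol_id in {m.mol_id for m in corpus}],
        depth,
        include_h_sites=include_h_sites,
    )
    train_records = [r for r in records if r.mol_id in train_ids]
    model = train_ensemble(train_records, config, depth=depth)
    pooled_labels: list[int] = []
    pooled_probs: list[float] = []
    best_ranks: list[tuple[str, int]] = []
    n_sites = 0
    eval_mols = [
        m for m in test_molecules if ann_by_mol.get(m.mol_id) and ann_by_mol[m.mol_id].som_atoms
    ]
    if not eval_mols:
        raise FoldError("no annotated test molecules")
    for mol in eval_mols:
        probs: dict[int, float] = {}
        for rec in (r for r in records if r.mol_id == mol.mol_id):
            p, _ = model.predict(np.asarray(rec.features))
            probs[rec.atom_index] = p
            pooled_labels.append(OMEGA0 if rec.label == SOM else OMEGA1)
            pooled_probs.append(p)
            n_sites += 1
        eq = equivalence_classes(
            mol, candidate_atoms(mol, include_h_sites=include_h_sites), alpha
        )
        ranked = rank_sites(mol.mol_id, probs, eq)
        rank = best_som_rank(ranked, ann_by_mol[mol.mol_id].som_atoms)
        if rank is None:
            raise CoverageError(f"{mol.mol_id}: no ranked class contains a true SoM")
        best_ranks.append((mol.mol_id, rank))
    counts = confusion_counts(pooled_labels, pooled_probs)
    ranks_only = [r for _, r in best_ranks]
    try:
        auc = roc_auc(pooled_probs, pooled_labels)
    except UndefinedAUCError:
        auc = float("nan")
    return MetricsReport(
        mcc=mcc(counts),
        auc=auc,
        top1=top_k_percent(ranks_only, 1),
        top2=top_k_percent(ranks_only, 2),
        top3=top_k_percent(ranks_only, 3),
        n_molecules=len(eval_mols),
        n_sites=n_sites,
        confusion=counts,
        best_ranks=tuple(best_ranks),
        roc=(),
        base=config.base,
        depth=depth,
        q=config.q,
        j=config.j,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# molecular similarity split
# ---------------------------------------------------------------------------


def linear_paths(molecule: Molecule, max_len: int = 7) -> frozenset[tuple[str, ...]]:
    """Set of linear atom-type paths up to ``max_len`` bonds.

    Every simple path is recorded as its SYBYL-type sequence, canonicalised
    to the lexicographically smaller of the sequence and its reverse — the
    whole-molecule path fingerprint used for Tanimoto similarity.
    """
    paths: set[tuple[str, ...]] = set()
    adjacency = molecule.adjacency

    def extend(path: list[int]) -> None:
        seq = tuple(molecule.atom(i).sybyl_type for i in path)
        paths.add(min(seq, seq[::-1]))
        if len(path) > max_len:  # path of n atoms has n-1 bonds
            return
        for nxt in adjacency[path[-1]]:
            if nxt not in path:
                extend(path + [nxt])

    for atom in molecule.atoms:
        extend([atom.index])
    return frozenset(paths)


def tanimoto(a: frozenset, b: frozenset) -> float:
    """Tanimoto (Jaccard) coefficient of two feature sets."""
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def max_similarity_to_set(
    molecule: Molecule, references: Sequence[Molecule], max_len: int = 7
) -> float:
    """Maximum path-fingerprint Tanimoto of a molecule to any reference."""
    fp = linear_paths(molecule, max_len)
    return max(tanimoto(fp, linear_paths(ref, max_len)) for ref in references)


def similarity_split(
    molecules: Sequence[Molecule],
    fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[Molecule], list[Molecule], list[Molecule]]:
    """Random test split plus its most-dissimilar half.

    TS1 is a seeded random ``fraction`` of the corpus (remainder trains);
    each TS1 molecule is scored by its maximum path-Tanimoto similarity to
    any training molecule, and TS2 is the half of TS1 with the lowest
    scores (ties broken by mol_id for determinism).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    if len(molecules) < 10:
        raise ValueError("similarity split needs at least 10 molecules")
    rng = np.random.default_rng(seed)
    n_test = int(round(fraction * len(molecules)))
    n_test = max(1, min(n_test, len(molecules) - 1))
    test_idx = set(rng.choice(len(molecules), size=n_test, replace=False).tolist())
    train = [m for i, m in enumerate(molecules) if i not in test_idx]
    ts1 = [m for i, m in enumerate(molecules) if i in test_idx]
    scored = sorted(
        ts1, key=lambda m: (max_similarity_to_set(m, train), m.mol_id)
    )
    ts2 = scored[: len(ts1) // 2]
    return train, ts1, ts2
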