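"""Cross-validation folds, ranking, metrics and the similarity split."""

import itertools
import math

import numpy as np
import pytest

from somkit import synthdata
from somkit.chemio import NONSOM, SOM, SiteRecord, SoMAnnotation
from somkit.classifiers import OMEGA0, OMEGA1
from somkit.ensemble import EnsembleConfig
from somkit.evaluation import (
    ConfusionCounts,
    CoverageError,
    FoldError,
    UndefinedAUCError,
    best_som_rank,
    confusion_counts,
    evaluate_loo,
    evaluate_records,
    linear_paths,
    loo_folds,
    max_similarity_to_set,
    mcc,
    rank_sites,
    roc_auc,
    roc_points,
    similarity_split,
    tanimoto,
    top_k_percent,
)

from conftest import make_molecule


def toy_records(n_mols=10, sites=3):
    recs = []
    for m in range(n_mols):
        for a in range(1, sites + 1):
            recs.append(
                SiteRecord(f"m{m}", a, SOM if a == 1 else NONSOM, (m, a))
            )
    return recs


class TestLooFolds:
    def test_one_fold_per_molecule_partition(self):
        recs = toy_records(10)
        folds = list(loo_folds(recs))
        assert len(folds) == 10
        held_out = [mol for _, mol, _ in folds]
        assert sorted(held_out) == sorted({r.mol_id for r in recs})

    def test_no_test_molecule_leaks_into_training(self):
        for train, mol, test in loo_folds(toy_records(5)):
            assert all(r.mol_id != mol for r in train)
            assert all(r.mol_id == mol for r in test)
            assert len(train) + len(test) == 15

    def test_single_molecule_rejected(self):
        with pytest.raises(FoldError):
            list(loo_folds(toy_records(1)))


class TestRankSites:
    def test_collapse_and_sort(self):
        probs = {1: 0.9, 2: 0.9, 3: 0.9, 4: 0.9, 5: 0.9, 6: 0.9, 7: 0.4, 8: 0.1}
        eq = [tuple(range(1, 7)), (7,), (8,)]
        ranked = rank_sites("m", probs, eq)
        assert [r.rank for r in ranked] == [1, 2, 3]
        assert ranked[0].members == tuple(range(1, 7))
        assert ranked[0].atom_index == 1

    def test_all_equal_probabilities_rank_by_atom_index(self):
        probs = {1: 0.5, 2: 0.5, 3: 0.5}
        ranked = rank_sites("m", probs, [(1,), (2,), (3,)])
        assert [r.atom_index for r in ranked] == [1, 2, 3]

    def test_matches_sort_oracle(self):
        rng = np.random.default_rng(0)
        grid = [k / 10 for k in range(11)]
        probs = {i: grid[int(rng.integers(11))] for i in range(1, 9)}
        ranked = rank_sites("m", probs, [(i,) for i in range(1, 9)])
        oracle = sorted(probs, key=lambda i: (-probs[i], i))
        assert [r.atom_index for r in ranked] == oracle

    def test_missing_probability_is_coverage_error(self):
        with pytest.raises(CoverageError):
            rank_sites("m", {1: 0.5}, [(1,), (2,)])


class TestTopK:
    def test_single_molecule_hit(self):
        assert top_k_percent([1], 2) == 100.0

    def test_hand_counted_ranks(self):
        ranks = [1, 2, 3, 5]
        assert top_k_percent(ranks, 2) == 50.0
        assert top_k_percent(ranks, 3) == 75.0

    def test_monotone_in_k(self):
        rng = np.random.default_rng(1)
        ranks = list(rng.integers(1, 8, size=30))
        values = [top_k_percent(ranks, k) for k in (1, 2, 3)]
        assert values == sorted(values)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            top_k_percent([1], 0)

    def test_best_som_rank(self):
        from somkit.evaluation import RankedSite

        ranked = [
            RankedSite("m", 1, (1, 2), 0.9, 1),
            RankedSite("m", 3, (3,), 0.5, 2),
        ]
        assert best_som_rank(ranked, {3}) == 2
        assert best_som_rank(ranked, {2}) == 1
        assert best_som_rank(ranked, {9}) is None


class TestMCC:
    def test_perfect_predictions(self):
        assert mcc(ConfusionCounts(tp=5, fp=0, tn=7, fn=0)) == 1.0

    def test_all_one_class_is_zero_by_convention(self):
        assert mcc(ConfusionCounts(tp=0, fp=0, tn=12, fn=4)) == 0.0

    def test_formula_oracle(self):
        got = mcc(ConfusionCounts(tp=3, fp=1, tn=5, fn=1))
        expected = (3 * 5 - 1 * 1) / math.sqrt((3 + 1) * (3 + 1) * (5 + 1) * (5 + 1))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.5833, abs=1e-4)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=80)
        pred = rng.integers(0, 2, size=80)
        counts = ConfusionCounts(
            tp=int(((y == 0) & (pred == 0)).sum()),
            fp=int(((y == 1) & (pred == 0)).sum()),
            tn=int(((y == 1) & (pred == 1)).sum()),
            fn=int(((y == 0) & (pred == 1)).sum()),
        )
        # sklearn treats 1 as positive; MCC is symmetric under joint relabel
        assert mcc(counts) == pytest.approx(matthews_corrcoef(1 - y, 1 - pred))

    def test_confusion_threshold_half_votes_to_nonsom(self):
        labels = [OMEGA0, OMEGA0, OMEGA1]
        counts = confusion_counts(labels, [0.6, 0.5, 0.5])
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 1, 1, 0)


class TestROC:
    def test_perfect_separation(self):
        labels = [OMEGA0] * 3 + [OMEGA1] * 5
        probs = [0.9, 0.8, 0.7, 0.3, 0.2, 0.2, 0.1, 0.0]
        assert roc_auc(probs, labels) == pytest.approx(1.0)

    def test_matches_mann_whitney_pair_counting(self):
        """AUC equals exhaustive pair counting with half-credit for ties."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = 30
            labels = [OMEGA0 if v else OMEGA1 for v in rng.integers(0, 2, size=n)]
            if len(set(labels)) < 2:
                continue
            probs = [round(float(p), 1) for p in rng.random(n)]  # force ties
            pos = [p for p, y in zip(probs, labels) if y == OMEGA0]
            neg = [p for p, y in zip(probs, labels) if y == OMEGA1]
            u = sum(
                1.0 if pp > pn else 0.5 if pp == pn else 0.0
                for pp in pos
                for pn in neg
            )
            assert roc_auc(probs, labels) == pytest.approx(u / (len(pos) * len(neg)))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        labels = [OMEGA0 if v else OMEGA1 for v in rng.integers(0, 2, size=60)]
        probs = [float(p) for p in rng.random(60)]
        y_true = [1 if y == OMEGA0 else 0 for y in labels]
        assert roc_auc(probs, labels) == pytest.approx(roc_auc_score(y_true, probs))

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedAUCError):
            roc_points([0.5, 0.4], [OMEGA0, OMEGA0])

    def test_null_probabilities_near_half(self):
        rng = np.random.default_rng(5)
        n = 4000
        labels = [OMEGA0 if v else OMEGA1 for v in rng.integers(0, 2, size=n)]
        probs = [float(p) for p in rng.random(n)]
        sigma = 1.0 / math.sqrt(12 * n / 4)  # rough U-statistic scale
        assert abs(roc_auc(probs, labels) - 0.5) < 4 * sigma


class TestEvaluateLoo:
    def test_planted_signal_beats_permuted_labels_paired_over_seeds(self):
        """MCC and AUC with the real labels exceed label-permuted runs."""
        wins_mcc = wins_auc = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = synthdata.default_config(
                seed=seed, n_molecules=14, min_atoms=8, max_atoms=12
            )
            mols, anns = synthdata.generate_corpus(cfg)
            ecfg = EnsembleConfig(base="rascal", q=5, j=11, seed=seed)
            real = evaluate_loo(mols, anns, 2, ecfg)
            rng = np.random.default_rng(1000 + seed)
            permuted = []
            for mol in mols:
                ann = next((a for a in anns if a.mol_id == mol.mol_id), None)
                if ann is None:
                    continue
                k = len(ann.som_atoms)
                heavy = [a.index for a in mol.atoms]
                fake = rng.choice(heavy, size=min(k, len(heavy)), replace=False)
                permuted.append(
                    SoMAnnotation(mol.mol_id, frozenset(int(i) for i in fake))
                )
            null = evaluate_loo(mols, permuted, 2, ecfg)
            wins_mcc += real.mcc > null.mcc
            wins_auc += real.auc > null.auc
        assert wins_mcc >= 16 and wins_auc >= 16

    def test_report_structure_and_invariants(self):
        cfg = synthdata.default_config(seed=3, n_molecules=15)
        mols, anns = synthdata.generate_corpus(cfg)
        rep = evaluate_loo(mols, anns, 2, EnsembleConfig(base="nb", q=5, j=11, seed=0))
        assert -1.0 <= rep.mcc <= 1.0
        assert 0.0 <= rep.auc <= 1.0
        assert rep.top1 <= rep.top2 <= rep.top3 <= 100.0
        assert rep.confusion.total == rep.n_sites
        assert dict(rep.best_ranks).keys() == {
            a.mol_id for a in anns if a.som_atoms
        }

    def test_records_only_evaluation_matches_structure_path_metrics(self):
        """Evaluating from the site TSV alone reproduces the pooled MCC/AUC
        (ranking may differ only through the equivalence proxy)."""
        cfg = synthdata.default_config(seed=9, n_molecules=15)
        mols, anns = synthdata.generate_corpus(cfg)
        ecfg = EnsembleConfig(base="rascal", q=5, j=11, seed=4)
        from somkit.fingerprints import build_dataset

        records, _ = build_dataset(mols, anns, 2)
        a = evaluate_loo(mols, anns, 2, ecfg)
        b = evaluate_records(records, ecfg, depth=2)
        assert a.mcc == pytest.approx(b.mcc)
        assert a.auc == pytest.approx(b.auc)


class TestSimilaritySplit:
    def _corpus(self, n=20, seed=6):
        cfg = synthdata.default_config(seed=seed, n_molecules=n)
        mols, _ = synthdata.generate_corpus(cfg)
        return mols

    def test_split_sizes(self):
        mols = self._corpus(20)
        train, ts1, ts2 = similarity_split(mols, fraction=0.2, seed=0)
        assert (len(train), len(ts1), len(ts2)) == (16, 4, 2)

    def test_identical_molecule_never_most_dissimilar(self):
        mols = self._corpus(19)
        clone = make_molecule(
            "clone", [a.sybyl_type for a in mols[0].atoms], list(mols[0].bonds)
        )
        train, ts1, ts2 = similarity_split(mols + [clone], fraction=0.2, seed=1)
        if clone in ts1 and mols[0] in train:
            assert max_similarity_to_set(clone, train) == 1.0
            scores = {m.mol_id: max_similarity_to_set(m, train) for m in ts1}
            if any(s < 1.0 for s in scores.values()):
                assert clone not in ts2

    def test_fraction_bounds_rejected(self):
        mols = self._corpus(12)
        for bad in (0.0, 1.0, -0.3, 2.0):
            with pytest.raises(ValueError):
                similarity_split(mols, fraction=bad, seed=0)

    def test_path_sets_match_hand_enumeration(self):
        chain = make_molecule("chain", ["C.3", "N.3", "O.3"], [(1, 2), (2, 3)])
        got = linear_paths(chain, max_len=7)
        expected = {
            ("C.3",),
            ("N.3",),
            ("O.3",),
            ("C.3", "N.3"),
            ("N.3", "O.3"),
            ("C.3", "N.3", "O.3"),
        }
        assert got == frozenset(expected)

    def test_tanimoto_identity_and_bounds(self):
        a = frozenset({("C.3",), ("C.3", "N.3")})
        b = frozenset({("C.3",)})
        assert tanimoto(a, a) == 1.0
        assert tanimoto(a, b) == 0.5
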