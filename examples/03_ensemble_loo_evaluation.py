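"""Full pipeline: synthetic corpus -> subspace ensembles -> LOO metrics.

Generates 60 molecules with a planted depth-2 SoM motif, then evaluates
all three classifiers as 51-subclassifier voting ensembles (q=5 features
per subclassifier) with molecule-level leave-one-out cross-validation.
MCC/AUC summarise site-level classification; top-k% is the fraction of
molecules with a true SoM among the k best-ranked positions.
"""

from somkit import synthdata
from somkit.ensemble import EnsembleConfig
from somkit.evaluation import evaluate_loo

mols, anns = synthdata.generate_corpus(synthdata.default_config(seed=1))
print(f"corpus: {len(mols)} molecules, {sum(1 for a in anns if a.som_atoms)} annotated")

for depth in (2, 0):
    print(f"\nbond depth {depth}:")
    for base in ("rascal", "prw", "nb"):
        rep = evaluate_loo(
            mols, anns, depth, EnsembleConfig(base=base, q=5, j=51, seed=7)
        )
        print(
            f"  {base:6s} MCC={rep.mcc:5.2f}  AUC={rep.auc:.3f}  "
            f"top-1%={rep.top1:5.1f}  top-2%={rep.top2:5.1f}  top-3%={rep.top3:5.1f}"
        )
# depth 2 sees the planted motif (near-perfect ranking); depth 0 carries
# no class signal by construction, so AUC sits at ~0.5 and MCC at ~0
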