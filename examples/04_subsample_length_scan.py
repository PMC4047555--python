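"""Sensitivity to the subsample length q: RASCAL collapses, PRW does not.

RASCAL votes require an exact match of the q selected features against
some training vector; as q grows toward the full length L, matches vanish
and every subclassifier becomes undetermined (MCC -> 0).  PRW measures a
distance instead, so it degrades gracefully.
"""

from somkit import synthdata
from somkit.evaluation import scan_q

mols, anns = synthdata.generate_corpus(
    synthdata.default_config(seed=2, n_molecules=40)
)
depth = 4  # L = (4+1) * 6 types = 30
grid = [5, 10, 15, 20, 25, 30]

for base in ("rascal", "prw"):
    reports = scan_q(mols, anns, depth, base, grid, j=33, seed=11)
    row = "  ".join(f"q={q:2d}: {r.mcc:5.2f}" for q, r in zip(grid, reports))
    print(f"{base:6s} MCC  {row}")
# expected shape: rascal high at small q then 0 at q ~ L; prw roughly flat
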