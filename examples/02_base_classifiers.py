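"""The three base classifiers on a toy two-class problem.

Ten SoM-class and ten non-SoM-class integer vectors differ in their first
feature.  Each classifier turns class-conditional density estimates into
an equal-prior posterior; note how RASCAL (exact matching) returns an
undetermined 0.5/0.5 for a vector it has never seen, while PRW measures a
distance and NB never hits zero thanks to the (C+1)/(N+2) correction.
"""

import numpy as np

from somkit.classifiers import (
    KernelSpec,
    kernel_class_conditional,
    nb_class_conditional,
    posterior,
)

rng = np.random.default_rng(0)
som = np.column_stack([rng.integers(2, 4, 10), rng.integers(0, 2, (10, 3))])
nonsom = np.column_stack([rng.integers(0, 2, 10), rng.integers(0, 2, (10, 3))])

seen = som[0]  # a vector present in the SoM class
unseen = np.array([9, 9, 9, 9])  # far from everything

for name, x in (("seen SoM-like vector", seen), ("unseen vector", unseen)):
    print(f"\n{name}: {x.tolist()}")
    nb = posterior(nb_class_conditional(x, som), nb_class_conditional(x, nonsom))
    print(f"  NB     p(SoM|x) = {nb.p_som:.3f}")
    dirac = KernelSpec("dirac")
    ras = posterior(
        kernel_class_conditional(x, som, dirac),
        kernel_class_conditional(x, nonsom, dirac),
    )
    print(f"  RASCAL p(SoM|x) = {ras.p_som:.3f}" + ("  (undetermined)" if ras.undetermined else ""))
    prw = KernelSpec("gaussian", h=0.1)
    pz = posterior(
        kernel_class_conditional(x, som, prw),
        kernel_class_conditional(x, nonsom, prw),
    )
    print(f"  PRW    p(SoM|x) = {pz.p_som:.3f}")
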