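"""The three base probabilistic classifiers: NB, PRW and RASCAL.

All three estimate the class-conditional density ``p(x | omega_a)`` of an
integer feature vector ``x`` for the two classes (omega_0 = SoM,
omega_1 = non-SoM) and convert to posteriors by Bayes' rule with equal
priors, so the posterior is just the normalised ratio of conditionals.

* Naive Bayesian (NB): per-feature conditional ``(C_l + 1) / (N_a + 2)``
  where ``C_l`` counts training vectors of the class whose feature ``l``
  equals the test value exactly — a Laplace-style correction that keeps
  every conditional strictly positive — multiplied over features under the
  independence assumption.
* Kernel classifiers: the conditional is the mean kernel similarity of the
  test vector to all training vectors of the class.  RASCAL uses the Dirac
  kernel (1 iff the vectors match exactly, else 0); PRW uses an isotropic
  Gaussian kernel with bandwidth ``h`` (default 0.1) on the raw integer
  counts — no feature scaling is applied.

Products over up to a few hundred features underflow double precision, so
conditionals are carried in the log domain throughout and exponentiated
only for reporting.  The Gaussian normalisation constant ``(1/(h*sqrt(2*pi)))**q``
cancels between the two classes but is included for fidelity to the
density definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "OMEGA0",
    "OMEGA1",
    "KernelSpec",
    "ClassConditional",
    "Posterior",
    "EmptyClassError",
    "nb_feature_prob",
    "nb_class_conditional",
    "dirac_kernel",
    "gaussian_kernel",
    "kernel_class_conditional",
    "posterior",
    "posterior_from_log",
    "classify",
]

#: integer class symbols: 0 = SoM, 1 = non-SoM
OMEGA0 = 0
OMEGA1 = 1


class EmptyClassError(ValueError):
    """A classifier was given a class with no training vectors."""


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice for the kernel-based classifiers.

    ``dirac`` is the exact-match kernel (RASCAL); ``gaussian`` is the
    Parzen-Rosenblatt window with smoothing bandwidth ``h``.
    """

    kind: Literal["dirac", "gaussian"] = "dirac"
    h: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("dirac", "gaussian"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        if self.h <= 0:
            raise ValueError("bandwidth h must be > 0")


@dataclass(frozen=True)
class ClassConditional:
    """A class-conditional density value, carried as a log."""

    log_value: float

    def __post_init__(self) -> None:
        if math.isnan(self.log_value):
            raise ValueError("class conditional is NaN")

    @property
    def value(self) -> float:
        return math.exp(self.log_value)

    @property
    def is_zero(self) -> bool:
        return self.log_value == -math.inf


@dataclass(frozen=True)
class Posterior:
    """Two-class posterior; ``undetermined`` marks the 0/0 degenerate case."""

    p_som: float
    p_nonsom: float
    undetermined: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_som <= 1.0 and 0.0 <= self.p_nonsom <= 1.0):
            raise ValueError("posterior components must lie in [0, 1]")


def nb_feature_prob(c_l: int, n_alpha: int) -> float:
    """Corrected per-feature match probability ``(C_l + 1) / (N_a + 2)``.

    ``c_l`` is the number of training vectors of the class whose feature
    assumes the test value; ``n_alpha`` is the class size.  The correction
    keeps the value strictly inside (0, 1), so NB conditionals never
    vanish.
    """
    if c_l < 0 or n_alpha < 0:
        raise ValueError("counts must be non-negative")
    if c_l > n_alpha:
        raise ValueError(f"match count {c_l} exceeds class size {n_alpha}")
    return (c_l + 1) / (n_alpha + 2)


def _as_matrix(vectors: Sequence[Sequence[int]] | np.ndarray) -> np.ndarray:
    X = np.asarray(vectors)
    if X.ndim != 2:
        raise ValueError("training class must be a 2-D collection of vectors")
    return X


def nb_class_conditional(
    x: Sequence[int] | np.ndarray, class_vectors: Sequence[Sequence[int]] | np.ndarray
) -> ClassConditional:
    """Naive-Bayes conditional: product over features of per-feature matches.

    Accumulated in the log domain; ``C_l`` is an exact value-match count
    per feature position.
    """
    X = _as_matrix(class_vectors)
    x = np.asarray(x)
    if x.shape[0] != X.shape[1]:
        raise ValueError(f"vector length {x.shape[0]} != class width {X.shape[1]}")
    if X.shape[0] == 0:
        raise EmptyClassError("NB requires at least one training vector")
    n_alpha = X.shape[0]
    counts = (X == x[np.newaxis, :]).sum(axis=0)
    log_p = float(np.log(counts + 1.0).sum() - x.shape[0] * math.log(n_alpha + 2.0))
    return ClassConditional(log_value=log_p)


def dirac_kernel(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> int:
    """Exact-match kernel: 1 iff the vectors are component-wise equal."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"vector shapes differ: {a.shape} vs {b.shape}")
    return int(np.array_equal(a, b))


def gaussian_kernel(
    a: Sequence[float] | np.ndarray, b: Sequence[float] | np.ndarray, h: float
) -> float:
    """Isotropic Gaussian kernel ``(1/(h*sqrt(2*pi)))**q * exp(-||a-b||^2 / (2 h^2))``."""
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"vector shapes differ: {a.shape} vs {b.shape}")
    q = a.shape[0]
    d2 = float(np.dot(a - b, a - b))
    log_k = -q * math.log(h * math.sqrt(2.0 * math.pi)) - d2 / (2.0 * h * h)
    return math.exp(log_k)


def kernel_class_conditional(
    x: Sequence[int] | np.ndarray,
    class_vectors: Sequence[Sequence[int]] | np.ndarray,
    kernel: KernelSpec,
) -> ClassConditional:
    """Mean kernel similarity of ``x`` to all training vectors of the class.

    For the Dirac kernel this is the exact-match fraction (zero is
    possible); for the Gaussian kernel the mean is evaluated with a
    log-sum-exp so distant training sets cannot underflow to zero.
    """
    X = _as_matrix(class_vectors)
    if X.shape[0] == 0:
        raise EmptyClassError("kernel classifier requires a non-empty class")
    x = np.asarray(x)
    if x.shape[0] != X.shape[1]:
        raise ValueError(f"vector length {x.shape[0]} != class width {X.shape[1]}")
    n_alpha = X.shape[0]
    q = x.shape[0]
    if kernel.kind == "dirac":
        matches = int((X == x[np.newaxis, :]).all(axis=1).sum())
        log_p = math.log(matches / n_alpha) if matches else -math.inf
        return ClassConditional(log_value=log_p)
    diff = X.astype(float) - x.astype(float)[np.newaxis, :]
    log_terms = -(diff * diff).sum(axis=1) / (2.0 * kernel.h * kernel.h)
    log_p = float(
        logsumexp(log_terms)
        - math.log(n_alpha)
        - q * math.log(kernel.h * math.sqrt(2.0 * math.pi))
    )
    return ClassConditional(log_value=log_p)


def posterior(
    cond_som: ClassConditional | float, cond_nonsom: ClassConditional | float
) -> Posterior:
    """Equal-prior posterior: normalised ratio of the two conditionals.

    If both conditionals are exactly zero (possible only for the Dirac
    kernel), the posterior is flagged undetermined and both classes get
    0.5 — in the ensemble this becomes a half-vote to each class.
    """
    l0 = cond_som.log_value if isinstance(cond_som, ClassConditional) else _log_of(cond_som)
    l1 = (
        cond_nonsom.log_value
        if isinstance(cond_nonsom, ClassConditional)
        else _log_of(cond_nonsom)
    )
    return posterior_from_log(l0, l1)


def _log_of(value: float) -> float:
    if value < 0:
        raise ValueError("class conditional must be non-negative")
    return math.log(value) if value > 0 else -math.inf


def posterior_from_log(log_som: float, log_nonsom: float) -> Posterior:
    if math.isnan(log_som) or math.isnan(log_nonsom):
        raise ValueError("log conditional is NaN")
    if log_som == -math.inf and log_nonsom == -math.inf:
        return Posterior(p_som=0.5, p_nonsom=0.5, undetermined=True)
    # p0 = e^l0 / (e^l0 + e^l1), computed stably
    if log_som >= log_nonsom:
        r = math.exp(log_nonsom - log_som)
        p0 = 1.0 / (1.0 + r)
    else:
        r = math.exp(log_som - log_nonsom)
        p0 = r / (1.0 + r)
    return Posterior(p_som=p0, p_nonsom=1.0 - p0)


def classify(post: Posterior, tie_break: Literal["omega0", "omega1"] = "omega1") -> int:
    """Arg-max class; exact ties go to the configured class.

    The default prefers omega_1 (non-SoM), the conservative choice for a
    SoM call.  Deterministic across runs by construction.
    """
    if post.p_som > post.p_nonsom:
        return OMEGA0
    if post.p_som < post.p_nonsom:
        return OMEGA1
    return OMEGA0 if tie_break == "omega0" else OMEGA1
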