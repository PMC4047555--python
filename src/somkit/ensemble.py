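"""Random attribute-subspace ensembles over the base classifiers.

Each of ``j`` subclassifiers sees a random subset of ``q`` of the ``L``
fingerprint features (drawn without replacement within a subclassifier;
independent draws across subclassifiers, so duplicates across the ``j``
sets are allowed).  Every subclassifier casts one vote — SoM or non-SoM —
from its restricted posterior, and the ensemble SoM probability for a site
is the vote fraction ``votes_som / j``.  A subclassifier whose two class
conditionals are both exactly zero (Dirac kernel with no match in either
class) is undetermined and contributes half a vote to each class, so the
tally always sums to ``j`` exactly.

The number of training items is never subsampled — only descriptor space —
which raises the effective sample size relative to the subspace dimension.
A ``q="full"`` mode runs a single subclassifier over all ``L`` features
(useful for PRW and NB, which gain little from subsampling).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.special import logsumexp

from .chemio import SiteRecord, records_to_matrices
from .classifiers import OMEGA0, OMEGA1, EmptyClassError, Posterior, posterior_from_log

__all__ = [
    "EnsembleConfig",
    "VoteTally",
    "EnsembleModel",
    "draw_subsamples",
    "train_ensemble",
    "save_model",
    "load_model",
]

_LOG_ROOT_2PI = math.log(math.sqrt(2.0 * math.pi))

BaseName = Literal["nb", "prw", "rascal"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Ensemble hyper-parameters.

    ``q`` is the subsample length (or ``"full"`` for a single classifier on
    all features); ``j`` the number of subclassifiers (odd values reduce
    exact vote ties); ``h`` the PRW bandwidth; ``tie_break`` the class that
    wins an exact posterior tie inside a subclassifier.
    """

    base: BaseName = "rascal"
    q: int | Literal["full"] = 5
    j: int = 201
    seed: int = 0
    h: float = 0.1
    tie_break: Literal["omega0", "omega1"] = "omega1"

    def __post_init__(self) -> None:
        if self.base not in ("nb", "prw", "rascal"):
            raise ValueError(f"unknown base classifier {self.base!r}")
        if self.q != "full" and self.q < 1:
            raise ValueError("q must be >= 1 or 'full'")
        if self.j < 1:
            raise ValueError("j must be >= 1")
        if self.h <= 0:
            raise ValueError("h must be > 0")


@dataclass(frozen=True)
class VoteTally:
    """Vote counts over the ``j`` subclassifiers; halves come from
    undetermined subclassifiers.  ``votes_som + votes_nonsom == j`` always."""

    votes_som: float
    votes_nonsom: float
    j: int

    def __post_init__(self) -> None:
        if abs(self.votes_som + self.votes_nonsom - self.j) > 1e-9:
            raise ValueError("votes must sum to j exactly")


def draw_subsamples(L: int, q: int, j: int, seed: int) -> np.ndarray:
    """``(j, q)`` matrix of feature indices, each row ``q`` distinct draws.

    Reproducible: identical ``(L, q, j, seed)`` give an identical array.
    Rows are sorted for a canonical form (order within a subsample is
    irrelevant to every base classifier).
    """
    if q > L:
        raise ValueError(f"subsample length q={q} exceeds feature count L={L}")
    if q < 1 or j < 1:
        raise ValueError("q and j must be >= 1")
    rng = np.random.default_rng(seed)
    rows = [np.sort(rng.choice(L, size=q, replace=False)) for _ in range(j)]
    return np.stack(rows).astype(np.int64)


@dataclass(frozen=True)
class EnsembleModel:
    """Immutable trained ensemble: training matrices + subsample indices.

    Predictions are deterministic given (model, x); all randomness is
    consumed at training time when the subsamples are drawn.
    """

    config: EnsembleConfig
    subsamples: np.ndarray  # (j_eff, q_eff)
    X_som: np.ndarray  # (N0, L)
    X_nonsom: np.ndarray  # (N1, L)
    alphabet: tuple[str, ...] | None = None
    depth: int | None = None

    @property
    def n_features(self) -> int:
        return self.X_som.shape[1]

    @property
    def n_subclassifiers(self) -> int:
        return self.subsamples.shape[0]

    # -- log class-conditionals per subclassifier ------------------------

    def _log_conditionals(self, x: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Vector of ``log p(x^q | class)`` over the j subclassifiers."""
        S = self.subsamples
        n = X.shape[0]
        q = S.shape[1]
        sub = X[:, S]  # (N, j, q)
        xs = x[S]  # (j, q)
        base = self.config.base
        if base == "nb":
            counts = (sub == xs[np.newaxis, :, :]).sum(axis=0)  # (j, q)
            return np.log(counts + 1.0).sum(axis=1) - q * math.log(n + 2.0)
        if base == "rascal":
            matches = (sub == xs[np.newaxis, :, :]).all(axis=2).sum(axis=0)  # (j,)
            with np.errstate(divide="ignore"):
                return np.log(matches / n)
        # prw
        diff = sub.astype(np.float64) - xs[np.newaxis, :, :].astype(np.float64)
        log_k = -(diff * diff).sum(axis=2) / (2.0 * self.config.h**2)  # (N, j)
        return (
            logsumexp(log_k, axis=0)
            - math.log(n)
            - q * (math.log(self.config.h) + _LOG_ROOT_2PI)
        )

    def subclassifier_posteriors(self, x: Sequence[int] | np.ndarray) -> list[Posterior]:
        """Restricted two-class posterior of every subclassifier for ``x``."""
        x = self._check_vector(x)
        l0 = self._log_conditionals(x, self.X_som)
        l1 = self._log_conditionals(x, self.X_nonsom)
        return [posterior_from_log(a, b) for a, b in zip(l0, l1)]

    def predict(self, x: Sequence[int] | np.ndarray) -> tuple[float, VoteTally]:
        """SoM probability of a site = fraction of subclassifier votes for SoM."""
        x = self._check_vector(x)
        l0 = self._log_conditionals(x, self.X_som)
        l1 = self._log_conditionals(x, self.X_nonsom)
        j = self.n_subclassifiers
        undet = np.isneginf(l0) & np.isneginf(l1)
        som_votes = (l0 > l1).sum() + 0.5 * undet.sum()
        ties = (l0 == l1) & ~undet
        if self.config.tie_break == "omega0":
            som_votes += ties.sum()
        tally = VoteTally(
            votes_som=float(som_votes), votes_nonsom=float(j - som_votes), j=j
        )
        return tally.votes_som / j, tally

    def predict_many(self, X: Sequence[Sequence[int]] | np.ndarray) -> np.ndarray:
        """SoM probabilities for a batch of site vectors."""
        return np.array([self.predict(x)[0] for x in np.asarray(X)])

    def _check_vector(self, x: Sequence[int] | np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim != 1 or x.shape[0] != self.n_features:
            raise ValueError(
                f"expected a length-{self.n_features} vector, got shape {x.shape}"
            )
        return x


def train_ensemble(
    records: Sequence[SiteRecord],
    config: EnsembleConfig,
    *,
    alphabet: Sequence[str] | None = None,
    depth: int | None = None,
) -> EnsembleModel:
    """Build an immutable ensemble model from labelled site records.

    Duplicate training vectors are retained — they carry frequency
    information for both the NB match counts and the kernel means.
    """
    X0, X1 = records_to_matrices(records)
    if X0.shape[0] == 0:
        raise EmptyClassError("no SoM (omega_0) training records")
    if X1.shape[0] == 0:
        raise EmptyClassError("no non-SoM (omega_1) training records")
    L = X0.shape[1]
    if config.q == "full":
        subsamples = np.arange(L, dtype=np.int64)[np.newaxis, :]
    else:
        subsamples = draw_subsamples(L, config.q, config.j, config.seed)
    return EnsembleModel(
        config=config,
        subsamples=subsamples,
        X_som=X0,
        X_nonsom=X1,
        alphabet=tuple(alphabet) if alphabet is not None else None,
        depth=depth,
    )


# ---------------------------------------------------------------------------
# serialisation (versioned JSON schema)
# ---------------------------------------------------------------------------

_SCHEMA = "somkit-ensemble-model/1"


def save_model(model: EnsembleModel, path: str | Path) -> None:
    payload = {
        "schema": _SCHEMA,
        "config": {
            "base": model.config.base,
            "q": model.config.q,
            "j": model.config.j,
            "seed": model.config.seed,
            "h": model.config.h,
            "tie_break": model.config.tie_break,
        },
        "subsamples": model.subsamples.tolist(),
        "X_som": model.X_som.tolist(),
        "X_nonsom": model.X_nonsom.tolist(),
        "alphabet": list(model.alphabet) if model.alphabet is not None else None,
        "depth": model.depth,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> EnsembleModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != _SCHEMA:
        raise ValueError(f"unrecognised model schema {payload.get('schema')!r}")
    cfg = payload["config"]
    config = EnsembleConfig(
        base=cfg["base"],
        q=cfg["q"] if cfg["q"] == "full" else int(cfg["q"]),
        j=int(cfg["j"]),
        seed=int(cfg["seed"]),
        h=float(cfg["h"]),
        tie_break=cfg["tie_break"],
    )
    return EnsembleModel(
        config=config,
        subsamples=np.asarray(payload["subsamples"], dtype=np.int64),
        X_som=np.asarray(payload["X_som"], dtype=np.int64),
        X_nonsom=np.asarray(payload["X_nonsom"], dtype=np.int64),
        alphabet=tuple(payload["alphabet"]) if payload["alphabet"] is not None else None,
        depth=payload["depth"],
    )
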