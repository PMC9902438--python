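"""Codon influence ranking: lasso regularization path, random-forest
importance, and their top-n consensus.

The lasso ranking one-hot encodes the class labels and fits, for every
penalty value alpha on a dense grid, one lasso regression per class on
the 64 codon-frequency features.  Codons whose coefficients survive
(stay nonzero) across more (class, alpha) fits explain more of the
class signal; the *survival count* — the l0 norm of a codon's
coefficient path — is its score.  The random-forest ranking uses
mean-decrease-in-impurity importances normalized to sum to 1.  The
consensus of the two systems is the intersection of their top-n
prefixes, a voting step that keeps only codons both methods call
influential.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path
from sklearn.preprocessing import LabelBinarizer

from .codon_core import CODON_ALPHABET, CODON_INDEX

__all__ = [
    "LassoPathResult",
    "ImportanceRanking",
    "ConsensusResult",
    "lasso_path_rank",
    "rf_importance_rank",
    "consensus_top",
    "RF_RANKING_PRESET",
]

#: Random-forest configuration tuned for kingdom classification, reused
#: for importance ranking: 1200 trees, minimum split 2, minimum leaf 1,
#: depth cap 100, no bootstrap.
RF_RANKING_PRESET: dict = dict(
    n_estimators=1200,
    min_samples_split=2,
    min_samples_leaf=1,
    max_depth=100,
    bootstrap=False,
    max_features="sqrt",
)


def _validate_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[1] != 64:
        raise ValueError("X must be an organisms x 64 frequency matrix")
    if not np.isfinite(X).all():
        raise ValueError("X contains non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("at least 2 classes are required")
    if len(y) != len(X):
        raise ValueError("X and y lengths differ")
    return X, y


@dataclass(frozen=True)
class LassoPathResult:
    """Survival-count ranking from the lasso regularization path."""

    alphas: np.ndarray  # increasing penalty grid
    survival_counts: Mapping[str, int]  # codon -> l0 norm of its coefficient path
    last_alpha: Mapping[str, float]  # codon -> largest alpha with a nonzero coefficient
    ranking: tuple[str, ...]  # codons, most influential first

    def rank_of(self, codon: str) -> int:
        return self.ranking.index(codon) + 1


def lasso_path_rank(
    X: np.ndarray,
    y: np.ndarray,
    alpha_start: float = 1e-8,
    alpha_step: float = 1e-6,
    alpha_stop: float = 0.01,
    zero_tol: float = 1e-12,
    coarse: bool = False,
    n_coarse: int = 60,
) -> LassoPathResult:
    """Rank codons by how long their lasso coefficients survive the penalty sweep.

    Labels are one-hot encoded and each class column is fit one-vs-rest
    with a lasso at every alpha on the grid ``alpha_start`` to
    ``alpha_stop`` in steps of ``alpha_step`` (about 10^4 points by
    default; ``coarse=True`` substitutes a ``n_coarse``-point
    logarithmic grid covering the same range).  A coefficient counts as
    surviving when ``|beta| > zero_tol``; the score of a codon is its
    total number of surviving (class, alpha) entries.  Ties are broken
    by the larger last-dropout alpha, then canonical codon order.

    Alphas are in scikit-learn's convention (objective
    ``1/(2n) ||y - X beta||^2 + alpha ||beta||_1``).  Features and
    targets are mean-centered (an intercept): without it the class-mean
    component of the one-hot target keeps every coefficient nonzero
    across the grid and survival counts stop discriminating.
    """
    X, y = _validate_xy(X, y)
    if coarse:
        alphas = np.logspace(np.log10(alpha_start), np.log10(alpha_stop), n_coarse)
    else:
        n_steps = int(np.floor((alpha_stop - alpha_start) / alpha_step + 1e-9)) + 1
        alphas = alpha_start + alpha_step * np.arange(n_steps)
    alphas = np.asarray(sorted(set(alphas.tolist())))

    binarized = LabelBinarizer().fit_transform(y)
    if binarized.shape[1] == 1:  # two classes: complete the one-hot pair
        binarized = np.hstack([1 - binarized, binarized])

    Xc = X - X.mean(axis=0)
    desc = alphas[::-1]  # lasso_path wants decreasing alphas (warm starts)
    survival = np.zeros(64, dtype=np.int64)
    last_alpha = np.zeros(64, dtype=np.float64)
    for c in range(binarized.shape[1]):
        yc = binarized[:, c].astype(np.float64)
        yc -= yc.mean()
        with warnings.catch_warnings():
            # the sweep deliberately reaches near-zero penalties, where the
            # coordinate-descent duality gap stalls; survival counting only
            # needs the support, not a fully converged solution
            warnings.simplefilter("ignore", ConvergenceWarning)
            _, coefs, _ = lasso_path(Xc, yc, alphas=desc, max_iter=3000)
        nonzero = np.abs(coefs) > zero_tol  # (64, n_alphas), alphas decreasing
        survival += nonzero.sum(axis=1)
        alive_at = np.where(nonzero.any(axis=1), desc[np.argmax(nonzero, axis=1)], 0.0)
        last_alpha = np.maximum(last_alpha, alive_at)

    order = sorted(
        range(64), key=lambda i: (-survival[i], -last_alpha[i], i)
    )
    return LassoPathResult(
        alphas=alphas,
        survival_counts={c: int(survival[CODON_INDEX[c]]) for c in CODON_ALPHABET},
        last_alpha={c: float(last_alpha[CODON_INDEX[c]]) for c in CODON_ALPHABET},
        ranking=tuple(CODON_ALPHABET[i] for i in order),
    )


@dataclass(frozen=True)
class ImportanceRanking:
    """A scored codon ranking (scores non-negative; RF scores sum to 1)."""

    method: str
    scores: Mapping[str, float]
    ranking: tuple[str, ...]

    def rank_of(self, codon: str) -> int:
        return self.ranking.index(codon) + 1


def rf_importance_rank(
    X: np.ndarray,
    y: np.ndarray,
    rf_config: Mapping | None = None,
    seed: int = 0,
) -> ImportanceRanking:
    """Rank codons by random-forest mean-decrease-in-impurity importance.

    The default forest is the tuned kingdom-classification preset
    (:data:`RF_RANKING_PRESET`); pass ``rf_config`` overrides (e.g. a
    smaller ``n_estimators``) for faster, noisier rankings.  Scores are
    normalized to sum to 1; ties are broken by canonical codon order.
    """
    X, y = _validate_xy(X, y)
    config = dict(RF_RANKING_PRESET)
    if rf_config:
        config.update(rf_config)
    forest = RandomForestClassifier(random_state=seed, **config)
    forest.fit(X, y)
    importances = forest.feature_importances_.astype(np.float64)
    total = importances.sum()
    if total > 0:
        importances = importances / total
    order = sorted(range(64), key=lambda i: (-importances[i], i))
    return ImportanceRanking(
        method="random_forest",
        scores={c: float(importances[CODON_INDEX[c]]) for c in CODON_ALPHABET},
        ranking=tuple(CODON_ALPHABET[i] for i in order),
    )


@dataclass(frozen=True)
class ConsensusResult:
    """Intersection of two rankings' top-n prefixes, in canonical order."""

    n: int
    set_a_top: tuple[str, ...]
    set_b_top: tuple[str, ...]
    consensus: tuple[str, ...]


def consensus_top(
    rank_a: Sequence[str],
    rank_b: Sequence[str],
    n: int = 20,
) -> ConsensusResult:
    """Codons in the top ``n`` of both rankings.

    ``rank_a`` and ``rank_b`` must be orderings of the same codon set;
    the consensus is reported as an unordered set in canonical codon
    order.  Symmetric in its arguments.
    """
    if set(rank_a) != set(rank_b):
        raise ValueError("rankings must cover the same codon set")
    if not 1 <= n <= len(rank_a):
        raise ValueError(f"n must be in 1..{len(rank_a)}")
    top_a = tuple(rank_a[:n])
    top_b = tuple(rank_b[:n])
    common = set(top_a) & set(top_b)
    consensus = tuple(c for c in CODON_ALPHABET if c in common) or tuple(sorted(common))
    return ConsensusResult(n=n, set_a_top=top_a, set_b_top=top_b, consensus=consensus)
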