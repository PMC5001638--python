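"""Candidate classification: exclusion criterion and RUSBoost.

The candidate extractor deliberately over-generates: on real fundus images
the ratio of non-lesion to lesion candidates can exceed 400:1.  Two defences
are applied.  First, a hard exclusion criterion drops candidates whose
segmented area falls outside [2, 150] px (at the reference resolution;
scaled by rho^2 otherwise) or whose minor/major axis ratio r1 is below 0.3 —
shapes no microaneurysm takes.  Second, a RUSBoost ensemble is trained:
AdaBoost.M2 boosting in which each round trains a shallow decision tree on
the minority class plus a fresh uniform random undersample of the majority
class of equal size, while the boosting weight distribution and pseudo-loss
are maintained over the FULL training set.  Undersampling inside the
boosting loop lets every round see a balanced problem without discarding
majority information overall, which is what makes boosting usable at
extreme class imbalance.

Binary specialization of AdaBoost.M2 used here: with h(x) the weak learner's
probability for the positive class and y in {0, 1},

    pseudo-loss   eps_t = sum_i D_t(i) * (1 - h_t(x_i, y_i))
    beta_t        = eps_t / (1 - eps_t)
    weight update D_{t+1}(i) proportional to D_t(i) * beta_t ** h_t(x_i, y_i)

and the final score is the normalized weighted vote
sum_t log(1/beta_t) h_t(x, 1) / sum_t log(1/beta_t), in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .config import DEFAULT_CONFIG, DetectConfig
from .errors import InvalidInputError

_BETA_FLOOR = 1e-10


def exclusion_filter(
    areas: np.ndarray,
    r1: np.ndarray,
    rho: float = 1.0,
    config: DetectConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Boolean mask of candidates surviving the geometric exclusion criterion.

    Retains candidates with area in [2, 150] * rho^2 (inclusive) and
    r1 >= 0.3.
    """
    areas = np.asarray(areas, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    lo = config.area_min * rho * rho
    hi = config.area_max * rho * rho
    return (areas >= lo) & (areas <= hi) & (r1 >= config.r1_min)


@dataclass
class RUSBoostModel:
    """T weak trees with per-round combination weights log(1/beta_t)."""

    trees: list[DecisionTreeClassifier]
    alphas: np.ndarray                       # log(1 / beta_t), > 0
    n_features: int
    seed: int
    feature_layout_version: str = ""
    config_hash: str = ""

    @property
    def n_rounds(self) -> int:
        return len(self.trees)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "RUSBoostModel":
        return joblib.load(path)


def _positive_proba(tree: DecisionTreeClassifier, X: np.ndarray) -> np.ndarray:
    proba = tree.predict_proba(X)
    if proba.shape[1] == 1:                  # tree saw a single class
        return np.full(X.shape[0], float(tree.classes_[0]))
    return proba[:, list(tree.classes_).index(1)]


def rusboost_train(
    X: np.ndarray,
    y: np.ndarray,
    T: int = DEFAULT_CONFIG.n_rounds,
    seed: int = 0,
    max_depth: int = DEFAULT_CONFIG.tree_max_depth,
    max_features: int | None = DEFAULT_CONFIG.tree_max_features,
    feature_layout_version: str = "",
    config_hash: str = "",
) -> RUSBoostModel:
    """Train a RUSBoost ensemble of ``T`` depth-limited trees.

    Rounds whose pseudo-loss reaches 0.5 are redrawn (up to 10 times) with a
    fresh undersample, then skipped; reproducible given ``seed``.
    """
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise InvalidInputError("X must be 2-D with one label per row")
    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise InvalidInputError("training data needs both classes")
    minority, majority = pos_idx, neg_idx
    if len(minority) > len(majority):
        minority, majority = majority, minority

    rng = np.random.default_rng(seed)
    n = X.shape[0]
    D = np.full(n, 1.0 / n)
    trees: list[DecisionTreeClassifier] = []
    alphas: list[float] = []
    for t in range(T):
        for _attempt in range(10):
            if len(majority) <= len(minority):
                sub = majority                     # degenerate: nothing to drop
            else:
                sub = rng.choice(majority, size=len(minority), replace=False)
            idx = np.concatenate([minority, sub])
            w = D[idx]
            w = w / w.sum()
            tree = DecisionTreeClassifier(
                max_depth=max_depth,
                max_features=max_features,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[idx], y[idx], sample_weight=w)
            h_pos = _positive_proba(tree, X)
            h_true = np.where(y == 1, h_pos, 1.0 - h_pos)
            eps = float(np.sum(D * (1.0 - h_true)))
            if eps < 0.5:
                break
        else:
            continue                               # skip unlearnable round
        beta = max(eps / (1.0 - eps), _BETA_FLOOR)
        D = D * np.power(beta, h_true)
        D = D / D.sum()
        trees.append(tree)
        alphas.append(float(np.log(1.0 / beta)))
    return RUSBoostModel(
        trees=trees,
        alphas=np.asarray(alphas),
        n_features=X.shape[1],
        seed=seed,
        feature_layout_version=feature_layout_version,
        config_hash=config_hash,
    )


def rusboost_score(model: RUSBoostModel, X: np.ndarray) -> np.ndarray:
    """Normalized weighted vote for the positive class, in [0, 1]."""
    X = np.atleast_2d(np.asarray(X))
    if X.shape[1] != model.n_features:
        raise InvalidInputError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    if model.n_rounds == 0:
        return np.zeros(X.shape[0])
    total = np.zeros(X.shape[0])
    for tree, alpha in zip(model.trees, model.alphas):
        total += alpha * _positive_proba(tree, X)
    return np.clip(total / model.alphas.sum(), 0.0, 1.0)


def adaboost_train(X: np.ndarray, y: np.ndarray, T: int, seed: int = 0,
                   max_depth: int = DEFAULT_CONFIG.tree_max_depth,
                   max_features: int | None = None) -> RUSBoostModel:
    """The same boosting loop without undersampling (comparison baseline)."""
    X = np.asarray(X)
    y = np.asarray(y).astype(int)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    D = np.full(n, 1.0 / n)
    trees, alphas = [], []
    for t in range(T):
        tree = DecisionTreeClassifier(
            max_depth=max_depth, max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X, y, sample_weight=D)
        h_pos = _positive_proba(tree, X)
        h_true = np.where(y == 1, h_pos, 1.0 - h_pos)
        eps = float(np.sum(D * (1.0 - h_true)))
        if eps >= 0.5:
            continue
        beta = max(eps / (1.0 - eps), _BETA_FLOOR)
        D = D * np.power(beta, h_true)
        D = D / D.sum()
        trees.append(tree)
        alphas.append(float(np.log(1.0 / beta)))
    return RUSBoostModel(trees=trees, alphas=np.asarray(alphas),
                         n_features=X.shape[1], seed=seed)
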