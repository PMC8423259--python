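"""Single-forest baseline selectors sharing the ranked-feature contract.

* ``rf`` — plain random forest, the zero baseline.
* ``rf-cw`` — cost-sensitive forest: per-class weights inversely proportional
  to class frequency (weight_c ∝ n / (k · n_c)), applied globally.
* ``rf-bcw`` — per-tree bootstrap with class weights recomputed from each
  bootstrap's realized class counts.
* ``rf-u`` — per-tree undersampling: each tree trains on a fresh balanced
  draw of n_min samples per class, majority classes drawn with replacement.

Each selector returns the top-d features of one forest's normalized
mean-decrease-in-impurity importances, positions 1..d, so the output is
directly comparable with the integrated selector's ranked list.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

from .aggregation import RankedFeatureList, top_d
from .io import ExpressionMatrix, LabelVector, derive_seeds

__all__ = [
    "select_rf",
    "select_rf_cw",
    "select_rf_bcw",
    "select_rf_u",
    "balanced_tree_draws",
    "SELECTORS",
]


def _check(X: ExpressionMatrix, labels: LabelVector, T: int, d: int) -> None:
    if labels.n != X.n:
        raise ValueError("labels and matrix disagree on sample count")
    if T < 1:
        raise ValueError("T must be ≥ 1")
    if not 1 <= d <= X.m:
        raise ValueError(f"d must be in [1, m={X.m}]")


def _ranked_from_importances(importances: np.ndarray, d: int, feature_names) -> RankedFeatureList:
    total = importances.sum()
    if total > 0:
        importances = importances / total
    ranking = top_d(importances, d, feature_names)
    return RankedFeatureList(
        feature_names=list(ranking.feature_names),
        mean_positions=[float(p) for p in ranking.positions],
        mean_importances=list(ranking.importances),
    )


def _forest_select(X, labels, T, d, seed, class_weight) -> RankedFeatureList:
    forest = RandomForestClassifier(
        n_estimators=T, random_state=int(seed), class_weight=class_weight, n_jobs=1
    )
    forest.fit(X.values, labels.labels.astype(str))
    return _ranked_from_importances(np.asarray(forest.feature_importances_), d, X.feature_names)


def select_rf(X: ExpressionMatrix, labels: LabelVector, T: int, d: int, seed: int = 0) -> RankedFeatureList:
    """Plain random forest selection (no imbalance handling)."""
    _check(X, labels, T, d)
    return _forest_select(X, labels, T, d, seed, None)


def select_rf_cw(X: ExpressionMatrix, labels: LabelVector, T: int, d: int, seed: int = 0) -> RankedFeatureList:
    """Class-weighted forest: global inverse-frequency misclassification costs."""
    _check(X, labels, T, d)
    return _forest_select(X, labels, T, d, seed, "balanced")


def select_rf_bcw(X: ExpressionMatrix, labels: LabelVector, T: int, d: int, seed: int = 0) -> RankedFeatureList:
    """Bootstrap-class-weighted forest: weights recomputed per tree bootstrap."""
    _check(X, labels, T, d)
    return _forest_select(X, labels, T, d, seed, "balanced_subsample")


def balanced_tree_draws(labels: LabelVector, T: int, seed: int) -> Iterator[np.ndarray]:
    """Yield T per-tree balanced index draws (n_min per class).

    The smallest class contributes all its samples; larger classes are
    undersampled *with replacement*, so per-tree draws need not cover the
    majority classes — the designed contrast with the round-based balanced
    sampling plan.
    """
    n_min = labels.n_min
    rng = np.random.default_rng(seed)
    for _ in range(T):
        draw: list[int] = []
        for c in labels.class_set:
            members = labels.indices_of(c)
            if len(members) == n_min:
                draw.extend(int(i) for i in members)
            else:
                draw.extend(int(members[i]) for i in rng.integers(len(members), size=n_min))
        yield np.asarray(draw)


def select_rf_u(X: ExpressionMatrix, labels: LabelVector, T: int, d: int, seed: int = 0) -> RankedFeatureList:
    """Per-tree undersampling forest.

    Each of the T trees trains on a fresh balanced draw; tree importances
    (each normalized by construction) are averaged and renormalized before
    taking the top d.
    """
    _check(X, labels, T, d)
    draw_seed, tree_root = derive_seeds(seed, 2)
    tree_seeds = derive_seeds(tree_root, T)
    importances = np.zeros(X.m)
    y = labels.labels.astype(str)
    for t, draw in enumerate(balanced_tree_draws(labels, T, draw_seed)):
        tree = DecisionTreeClassifier(max_features="sqrt", random_state=tree_seeds[t])
        tree.fit(X.values[draw], y[draw])
        importances += np.asarray(tree.feature_importances_)
    return _ranked_from_importances(importances / T, d, X.feature_names)


SELECTORS = {
    "rf": select_rf,
    "rf-cw": select_rf_cw,
    "rf-bcw": select_rf_bcw,
    "rf-u": select_rf_u,
}
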