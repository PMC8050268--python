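"""Effort classification from the two trial-space score dimensions.

A CART tree with Gini impurity and axis-aligned splits is fit on the
(gate, fine) — usually (PC1, PC2) — scores of the K trials. The minimum
leaf size is chosen by stratified cross-validation over a small grid
(ties resolved toward the larger, more regularized leaf); generalization
is estimated as the mean misclassification over repeated stratified
70/30 hold-out splits. A uniform-random guesser over the three balanced
effort classes errs at 2/3, the reference baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.tree import DecisionTreeClassifier

from .exceptions import DegenerateInputError

__all__ = [
    "TreeModel",
    "fit_tree",
    "evaluate_holdout",
    "baseline_error",
    "decision_regions",
]

FEATURE_NAMES = ("PC1", "PC2")


@dataclass
class TreeModel:
    """Fitted axis-aligned classification tree over the two score axes."""

    splits: list[dict]            # internal nodes: feature, threshold, children
    leaf_labels: dict[int, int]   # node id -> effort class
    min_leaf_size: int
    training_error: float
    cv_errors: dict[int, float]   # leaf-size grid -> CV error
    holdout_error_mean: float | None = None
    holdout_repeats: int = 0
    estimator: DecisionTreeClassifier = field(default=None, compare=False,
                                              repr=False)

    @property
    def depth(self) -> int:
        return int(self.estimator.get_depth())

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(scores, dtype=float))


def _extract_structure(est: DecisionTreeClassifier) -> tuple[list[dict], dict[int, int]]:
    t = est.tree_
    splits, leaves = [], {}
    for node in range(t.node_count):
        if t.children_left[node] == -1:
            leaves[node] = int(est.classes_[np.argmax(t.value[node])])
        else:
            splits.append({
                "node": node,
                "feature": FEATURE_NAMES[int(t.feature[node])],
                "threshold": float(t.threshold[node]),
                "left": int(t.children_left[node]),
                "right": int(t.children_right[node]),
            })
    return splits, leaves


def fit_tree(
    scores: np.ndarray,
    labels: np.ndarray,
    min_leaf_grid: range | list[int] = range(1, 11),
    cv_folds: int = 5,
    seed: int = 0,
) -> TreeModel:
    """CART with leaf size selected by stratified cross-validation.

    Ties in CV error resolve toward the larger leaf size; the final tree
    is refit on all trials.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise DegenerateInputError("classification needs at least two classes")
    folds = min(cv_folds, int(counts.min()))
    cv_errors: dict[int, float] = {}
    for leaf in min_leaf_grid:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        errs = []
        for train, test in skf.split(scores, labels):
            est = DecisionTreeClassifier(
                criterion="gini", min_samples_leaf=leaf, random_state=seed)
            est.fit(scores[train], labels[train])
            errs.append(np.mean(est.predict(scores[test]) != labels[test]))
        cv_errors[int(leaf)] = float(np.mean(errs))
    best = min(cv_errors.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    est = DecisionTreeClassifier(
        criterion="gini", min_samples_leaf=best, random_state=seed)
    est.fit(scores, labels)
    splits, leaves = _extract_structure(est)
    return TreeModel(
        splits=splits,
        leaf_labels=leaves,
        min_leaf_size=best,
        training_error=float(np.mean(est.predict(scores) != labels)),
        cv_errors=cv_errors,
        estimator=est,
    )


def evaluate_holdout(
    scores: np.ndarray,
    labels: np.ndarray,
    fraction: float = 0.30,
    repeats: int = 100,
    seed: int = 0,
    min_leaf_size: int = 1,
) -> float:
    """Mean misclassification over repeated stratified hold-out splits.

    Each repeat refits a tree with the given leaf size on the (1 -
    fraction) training part and scores the held-out part. Deterministic
    given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _, counts = np.unique(labels, return_counts=True)
    n_test = int(np.ceil(fraction * labels.size))
    if counts.min() < 2 or n_test < np.unique(labels).size:
        raise DegenerateInputError("stratified split infeasible for these labels")
    sss = StratifiedShuffleSplit(
        n_splits=repeats, test_size=fraction, random_state=seed)
    errs = []
    for train, test in sss.split(scores, labels):
        est = DecisionTreeClassifier(
            criterion="gini", min_samples_leaf=min_leaf_size, random_state=seed)
        est.fit(scores[train], labels[train])
        errs.append(np.mean(est.predict(scores[test]) != labels[test]))
    return float(np.mean(errs))


def baseline_error(class_counts: np.ndarray | list[int]) -> float:
    """Expected error of a uniform-random guesser over the observed classes.

    With class proportions p_c over C classes the guesser is correct with
    probability sum_c p_c / C, so the error is 1 - 1/C for balanced
    classes (2/3, printed 0.67, for three).
    """
    counts = np.asarray(class_counts, dtype=float)
    counts = counts[counts > 0]
    total = counts.sum()
    if total <= 0:
        raise ValueError("class counts must sum to a positive total")
    C = counts.size
    return float(1.0 - np.sum(counts / total) / C)


def decision_regions(
    tree: TreeModel,
    bounds: tuple[float, float, float, float],
    grid_step: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class label on a regular grid over ``(x_min, x_max, y_min, y_max)``.

    Returns ``(grid_x, grid_y, labels)`` with ``labels[i, j]`` the class
    at ``(grid_x[j], grid_y[i])``; the axis-aligned rectangles of equal
    label are the plotted decision regions.
    """
    x_min, x_max, y_min, y_max = bounds
    gx = np.arange(x_min, x_max + grid_step / 2, grid_step)
    gy = np.arange(y_min, y_max + grid_step / 2, grid_step)
    xx, yy = np.meshgrid(gx, gy)
    labels = tree.predict(np.column_stack([xx.ravel(), yy.ravel()]))
    return gx, gy, labels.reshape(xx.shape)
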