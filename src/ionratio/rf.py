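"""Random-forest benchmark for the ratio-selection workflow.

The comparison method: a random forest on all ordered ratios, with the
number of trees and per-split candidate features tuned by out-of-bag
accuracy, out-of-bag permutation importance to rank ratios, and reduced
forests refit on the top-ranked ratios. Each model is reported with the
same three accuracies as the GA+LDA fingerprint: learning-set accuracy,
repeated 2-fold CV accuracy, and independent-validation accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import (
    _generate_unsampled_indices,
    _get_n_samples_bootstrap,
)

from .discriminant import accuracy, stratified_splits
from .features import RatioFeatureSet

__all__ = ["RFGrid", "RFReport", "rf_full", "rf_reduced", "oob_permutation_importance"]


@dataclass
class RFGrid:
    """Hyperparameter grid searched by out-of-bag accuracy.

    ``mtry_rules`` name per-split candidate counts as functions of the
    feature count p: "sqrt" -> sqrt(p), "tenth" -> p/10, "third" -> p/3.
    """

    n_trees: tuple[int, ...] = (250, 500, 1000)
    mtry_rules: tuple[str, ...] = ("sqrt", "tenth", "third")

    def mtry_values(self, p: int) -> list[int]:
        rules = {
            "sqrt": int(round(np.sqrt(p))),
            "tenth": p // 10,
            "third": p // 3,
        }
        vals = []
        for r in self.mtry_rules:
            v = max(1, rules[r] if r in rules else int(r))
            if v not in vals:
                vals.append(min(v, p))
        return vals


@dataclass
class RFReport:
    """Benchmark record for one random forest."""

    n_ratios_in_model: int
    learning_accuracy: float
    cv2_accuracy: float
    validation_accuracy: float | None
    top_ratios_by_importance: list[tuple[int, int]]
    n_trees: int
    mtry: int
    importances: np.ndarray = field(repr=False, default=None)
    ratio_indices: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_ratios_in_model": self.n_ratios_in_model,
            "learning_accuracy": self.learning_accuracy,
            "cv2_accuracy": self.cv2_accuracy,
            "validation_accuracy": self.validation_accuracy,
            "top_ratios_by_importance": [list(p) for p in self.top_ratios_by_importance],
            "n_trees": self.n_trees,
            "mtry": self.mtry,
        }


def _as_matrix(ratios):
    if isinstance(ratios, RatioFeatureSet):
        return ratios.ratio_matrix, ratios.pairs
    return np.asarray(ratios, float), None


def oob_permutation_importance(
    forest: RandomForestClassifier, X: np.ndarray, y: np.ndarray, seed: int = 0
) -> np.ndarray:
    """Out-of-bag permutation importance per feature.

    For each tree, accuracy on its out-of-bag samples is compared before and
    after permuting one feature column; the importance is the mean accuracy
    drop over trees. One permutation per feature is shared across trees.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = X.shape[0]
    try:  # sklearn >= 1.9 added a sample_weight argument
        n_boot = _get_n_samples_bootstrap(n, forest.max_samples, None)
        oob = [
            np.unique(_generate_unsampled_indices(est.random_state, n, n_boot, None))
            for est in forest.estimators_
        ]
    except TypeError:
        n_boot = _get_n_samples_bootstrap(n, forest.max_samples)
        oob = [
            np.unique(_generate_unsampled_indices(est.random_state, n, n_boot))
            for est in forest.estimators_
        ]
    classes = forest.classes_
    base = []
    for est, idx in zip(forest.estimators_, oob):
        if idx.size == 0:
            base.append(np.nan)
            continue
        pred = classes[np.argmax(est.predict_proba(X[idx]), axis=1)]
        base.append(float(np.mean(pred == y[idx])))
    base = np.asarray(base)

    imp = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        perm = rng.permutation(n)
        Xp = X.copy()
        Xp[:, j] = X[perm, j]
        drops = []
        for t, (est, idx) in enumerate(zip(forest.estimators_, oob)):
            if idx.size == 0 or np.isnan(base[t]):
                continue
            pred = classes[np.argmax(est.predict_proba(Xp[idx]), axis=1)]
            drops.append(base[t] - float(np.mean(pred == y[idx])))
        imp[j] = float(np.mean(drops)) if drops else 0.0
    return imp


def _oob_grid_search(X, y, grid: RFGrid, seed: int):
    """Pick (n_trees, mtry) maximizing OOB accuracy; ties -> smaller model."""
    best = None
    for mtry in grid.mtry_values(X.shape[1]):
        for n_trees in sorted(grid.n_trees):
            rf = RandomForestClassifier(
                n_estimators=n_trees,
                max_features=mtry,
                oob_score=True,
                bootstrap=True,
                random_state=seed,
                n_jobs=1,
            )
            rf.fit(X, y)
            key = (rf.oob_score_, -n_trees, -mtry)
            if best is None or key > best[0]:
                best = (key, rf, n_trees, mtry)
    return best[1], best[2], best[3]


def _cv2_accuracy(X, y, n_trees, mtry, n_repeats, seed):
    splits = stratified_splits(y, 2, n_repeats, seed)
    y = np.asarray(y)
    accs = []
    for folds in splits:
        fold_acc = []
        for train, test in folds:
            rf = RandomForestClassifier(
                n_estimators=n_trees, max_features=min(mtry, X.shape[1]),
                random_state=seed, n_jobs=1,
            )
            rf.fit(X[train], y[train])
            fold_acc.append(accuracy(y[test], rf.predict(X[test])))
        accs.append(float(np.mean(fold_acc)))
    return float(np.mean(accs))


def rf_full(
    ratios,
    y,
    grid: RFGrid | None = None,
    valid=None,
    n_cv_repeats: int = 30,
    top_k_report: int = 10,
    seed: int = 0,
    compute_importance: bool = True,
) -> RFReport:
    """Fit and benchmark a random forest on all supplied ratios.

    Hyperparameters are tuned by OOB accuracy over ``grid``; the report
    carries the learning accuracy, the ``n_cv_repeats``-repeat 2-fold CV
    accuracy, validation accuracy (when ``valid=(ratios_v, y_v)`` is given),
    and the top ratios by OOB permutation importance.
    """
    if grid is None:
        grid = RFGrid()
    X, pairs = _as_matrix(ratios)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    rf, n_trees, mtry = _oob_grid_search(X, y, grid, seed)
    learn_acc = accuracy(y, rf.predict(X))
    cv2 = _cv2_accuracy(X, y, n_trees, mtry, n_cv_repeats, seed)
    val_acc = None
    if valid is not None:
        Xv, _ = _as_matrix(valid[0])
        val_acc = accuracy(valid[1], rf.predict(Xv))
    importances = None
    top = []
    order = []
    if compute_importance:
        importances = oob_permutation_importance(rf, X, y, seed)
        order = np.argsort(-importances, kind="stable")[:top_k_report].tolist()
        if pairs is not None:
            top = [pairs[j] for j in order]
        else:
            top = [(j, j) for j in order]
    return RFReport(
        n_ratios_in_model=X.shape[1],
        learning_accuracy=learn_acc,
        cv2_accuracy=cv2,
        validation_accuracy=val_acc,
        top_ratios_by_importance=top,
        n_trees=n_trees,
        mtry=mtry,
        importances=importances,
        ratio_indices=order,
    )


def rf_reduced(
    ratios,
    y,
    top_k: int,
    full_report: RFReport | None = None,
    grid: RFGrid | None = None,
    valid=None,
    n_cv_repeats: int = 30,
    seed: int = 0,
) -> RFReport:
    """Refit a random forest on the top-k ratios of the full model's ranking."""
    X, pairs = _as_matrix(ratios)
    if full_report is None:
        full_report = rf_full(
            ratios, y, grid=grid, valid=valid, n_cv_repeats=1,
            top_k_report=max(top_k, 10), seed=seed,
        )
    if full_report.importances is None:
        raise ValueError("full_report lacks importances")
    if top_k > X.shape[1]:
        raise ValueError("top_k exceeds the number of available ratios")
    order = np.argsort(-full_report.importances, kind="stable")[:top_k]
    cols = order.tolist()
    Xr = X[:, cols]
    if grid is None:
        grid = RFGrid()
    y = np.asarray(y)
    rf, n_trees, mtry = _oob_grid_search(Xr, y, grid, seed)
    learn_acc = accuracy(y, rf.predict(Xr))
    cv2 = _cv2_accuracy(Xr, y, n_trees, mtry, n_cv_repeats, seed)
    val_acc = None
    if valid is not None:
        Xv, _ = _as_matrix(valid[0])
        val_acc = accuracy(valid[1], rf.predict(Xv[:, cols]))
    top = [pairs[j] for j in cols] if pairs is not None else [(j, j) for j in cols]
    return RFReport(
        n_ratios_in_model=top_k,
        learning_accuracy=learn_acc,
        cv2_accuracy=cv2,
        validation_accuracy=val_acc,
        top_ratios_by_importance=top,
        n_trees=n_trees,
        mtry=mtry,
        importances=full_report.importances[order],
        ratio_indices=cols,
    )
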