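"""Linear discriminant analysis with repeated stratified k-fold accuracy.

The classifier is the Gaussian equal-covariance discriminant: per-class mean
vectors, a pooled within-class covariance with a small ridge for
invertibility, and empirical priors. Its repeated 2-fold cross-validated
accuracy is both the genetic algorithm's fitness function and the final
evaluation statistic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LDAModel",
    "CVResult",
    "fit_lda",
    "predict",
    "cross_validate",
    "stratified_splits",
    "accuracy",
]

RIDGE = 1e-8  # relative ridge: eps = RIDGE * trace(cov) / n_features


@dataclass
class LDAModel:
    """Fitted linear discriminant: class means, pooled covariance, priors."""

    classes: np.ndarray
    class_means: np.ndarray       # (n_classes, n_features)
    pooled_covariance: np.ndarray  # (n_features, n_features), ridge included
    priors: np.ndarray
    _weights: np.ndarray = field(repr=False, default=None)  # (d, K)
    _consts: np.ndarray = field(repr=False, default=None)   # (K,)

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": [str(c) for c in self.classes],
                "class_means": self.class_means.tolist(),
                "pooled_covariance": self.pooled_covariance.tolist(),
                "priors": self.priors.tolist(),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "LDAModel":
        d = json.loads(s)
        model = cls(
            classes=np.asarray(d["classes"]),
            class_means=np.asarray(d["class_means"], dtype=float),
            pooled_covariance=np.asarray(d["pooled_covariance"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
        )
        model._finalize()
        return model

    def _finalize(self) -> None:
        try:
            W = np.linalg.solve(self.pooled_covariance, self.class_means.T)
        except np.linalg.LinAlgError:
            W = np.linalg.pinv(self.pooled_covariance) @ self.class_means.T
        self._weights = W
        self._consts = np.log(self.priors) - 0.5 * np.einsum(
            "kd,dk->k", self.class_means, W
        )


def fit_lda(X: np.ndarray, y, ridge: float = RIDGE) -> LDAModel:
    """Fit the equal-covariance Gaussian discriminant.

    Requires >=2 classes with >=2 samples each. A ridge of
    ``ridge * trace(cov) / n_features`` is added to the covariance diagonal;
    at the 2-10 feature scale of ratio fingerprints it is numerically
    negligible. Warns when features outnumber samples.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    counts = np.bincount(y_codes)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has fewer than 2 samples")
    n, d = X.shape
    if d > n:
        warnings.warn(
            f"{d} features for {n} samples: LDA estimate will be unstable",
            stacklevel=2,
        )
    means = np.zeros((classes.size, d))
    for c in range(classes.size):
        means[c] = X[y_codes == c].mean(axis=0)
    Xc = X - means[y_codes]
    cov = (Xc.T @ Xc) / (n - classes.size)
    tr = np.trace(cov)
    cov[np.diag_indices(d)] += ridge * tr / d
    model = LDAModel(
        classes=classes,
        class_means=means,
        pooled_covariance=cov,
        priors=counts / n,
    )
    model._finalize()
    return model


def predict(model: LDAModel, X: np.ndarray):
    """Classify rows by the linear discriminant score.

    score_k(x) = log(prior_k) + x . Sigma^-1 mu_k - 1/2 mu_k . Sigma^-1 mu_k;
    ties break deterministically toward the earlier class label.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.class_means.shape[1]:
        raise ValueError(
            f"model expects {model.class_means.shape[1]} features, got {X.shape[1]}"
        )
    if model._weights is None:
        model._finalize()
    scores = X @ model._weights + model._consts
    return model.classes[np.argmax(scores, axis=1)]


def accuracy(y_true, y_pred) -> float:
    """Fraction of correctly classified samples."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    return float(np.mean(y_true == y_pred))


@dataclass
class CVResult:
    """Repeated stratified k-fold accuracy record."""

    fold_accuracies: np.ndarray  # (n_repeats, k)
    mean_accuracy: float
    n_repeats: int
    seed: int


def stratified_splits(y, k: int, n_repeats: int, seed: int):
    """Repeated stratified k-fold index splits.

    For each repeat, each class's indices are shuffled and dealt into k
    near-equal chunks; fold f's test set is the union of chunk f over
    classes, so no fold ever loses a class. Returns a list (per repeat) of
    lists of (train_idx, test_idx). Deterministic for fixed seed.
    """
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    counts = np.bincount(y_codes)
    if counts.min() < k:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has fewer than k={k} samples")
    rng = np.random.default_rng(seed)
    by_class = [np.nonzero(y_codes == c)[0] for c in range(classes.size)]
    all_idx = np.arange(y.size)
    splits = []
    for _ in range(n_repeats):
        chunks = [[] for _ in range(k)]
        for idx in by_class:
            perm = rng.permutation(idx)
            for f, chunk in enumerate(np.array_split(perm, k)):
                chunks[f].append(chunk)
        folds = []
        for f in range(k):
            test = np.sort(np.concatenate(chunks[f]))
            train = np.setdiff1d(all_idx, test, assume_unique=True)
            folds.append((train, test))
        splits.append(folds)
    return splits


# --- fast path used by the GA fitness (avoids model-object overhead) -------

def _fit_fast(X: np.ndarray, y_codes: np.ndarray, n_classes: int, ridge: float = RIDGE):
    n, d = X.shape
    means = np.empty((n_classes, d))
    for c in range(n_classes):
        means[c] = X[y_codes == c].mean(axis=0)
    Xc = X - means[y_codes]
    # a fold can degenerate to one sample per class (0 dof); the centred
    # residuals are then all zero and the guard only avoids 0/0
    cov = (Xc.T @ Xc) / max(n - n_classes, 1)
    tr = cov.trace()
    cov.flat[:: d + 1] += ridge * tr / d
    counts = np.bincount(y_codes, minlength=n_classes)
    try:
        W = np.linalg.solve(cov, means.T)
    except np.linalg.LinAlgError:
        W = np.linalg.pinv(cov) @ means.T
    consts = np.log(counts / n) - 0.5 * np.einsum("kd,dk->k", means, W)
    return W, consts


def _cv_accuracy(X: np.ndarray, y_codes: np.ndarray, n_classes: int, splits) -> np.ndarray:
    """Per-repeat fold-averaged accuracies for precomputed splits."""
    out = np.empty(len(splits))
    for r, folds in enumerate(splits):
        acc = 0.0
        for train, test in folds:
            W, consts = _fit_fast(X[train], y_codes[train], n_classes)
            pred = np.argmax(X[test] @ W + consts, axis=1)
            acc += float(np.mean(pred == y_codes[test]))
        out[r] = acc / len(folds)
    return out


def cross_validate(
    X: np.ndarray, y, k: int = 2, n_repeats: int = 1, seed: int = 0
) -> CVResult:
    """Repeated stratified k-fold cross-validated LDA accuracy.

    Per repeat: random stratified k-fold split, fit on each training fold,
    score the held-out fold, average over folds; the reported mean is the
    average of the per-repeat fold means. Deterministic for fixed seed.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y)
    _, y_codes = np.unique(y, return_inverse=True)
    n_classes = int(y_codes.max()) + 1
    splits = stratified_splits(y, k, n_repeats, seed)
    fold_acc = np.empty((n_repeats, k))
    for r, folds in enumerate(splits):
        for f, (train, test) in enumerate(folds):
            W, consts = _fit_fast(X[train], y_codes[train], n_classes)
            pred = np.argmax(X[test] @ W + consts, axis=1)
            fold_acc[r, f] = float(np.mean(pred == y_codes[test]))
    return CVResult(
        fold_accuracies=fold_acc,
        mean_accuracy=float(fold_acc.mean(axis=1).mean()),
        n_repeats=n_repeats,
        seed=seed,
    )
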