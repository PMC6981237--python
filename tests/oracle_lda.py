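"""Independent closed-form LDA ranking oracle for small ratio subsets.

Used by the test suite to cross-check the package's GA + rank_and_select
against exhaustive enumeration of all 1- and 2-ratio subsets. The LDA math
here is written from the closed-form scalar / 2x2 formulas (no shared code
with ionratio.discriminant beyond the split generator, which must be shared
so cross-validation estimates are computed on identical folds).

The ranking procedure mirrors the package's multi-stage rule: repeated
2-fold CV accuracy on the learning set, an accuracy floor, validation
accuracy of survivors, ties toward fewest molecules then fewest ratios.
"""

from __future__ import annotations

import itertools

import numpy as np

from ionratio.discriminant import stratified_splits

RIDGE = 1e-8  # must match the package's relative ridge definition


def _accuracies_one_fold(Xtr, ytr_codes, K, Xte, yte_codes, I2, J2):
    """Fold accuracies of every 1-column and 2-column LDA.

    Returns (acc1, acc2): acc1[j] for the single column j, acc2[s] for the
    column pair (I2[s], J2[s]). Closed-form scalar / 2x2 discriminants.
    """
    n, m = Xtr.shape
    counts = np.bincount(ytr_codes, minlength=K).astype(float)
    logpri = np.log(counts / n)
    M = np.zeros((K, m))
    np.add.at(M, ytr_codes, Xtr)
    M /= counts[:, None]
    R = Xtr - M[ytr_codes]
    C = (R.T @ R) / (n - K)

    # --- all size-1 subsets ------------------------------------------------
    var = np.diag(C) * (1.0 + RIDGE)  # ridge: eps = RIDGE * trace / d = RIDGE * var
    # scores[k, j, t] = logpri_k + x_tj mu_kj / var_j - mu_kj^2 / (2 var_j)
    w = M / var  # (K, m)
    const = logpri[:, None] - 0.5 * M * w  # (K, m)
    scores1 = w[:, :, None] * Xte.T[None, :, :] + const[:, :, None]
    pred1 = np.argmax(scores1, axis=0)  # (m, n_te)
    acc1 = (pred1 == yte_codes[None, :]).mean(axis=1)

    # --- all size-2 subsets ------------------------------------------------
    a = C[I2, I2]
    d = C[J2, J2]
    b = C[I2, J2]
    eps = RIDGE * (a + d) / 2.0
    a = a + eps
    d = d + eps
    det = a * d - b * b
    scores2 = np.empty((K, Xte.shape[0], I2.size))
    xi = Xte[:, I2]
    xj = Xte[:, J2]
    for k in range(K):
        m1 = M[k, I2]
        m2 = M[k, J2]
        w1 = (d * m1 - b * m2) / det
        w2 = (-b * m1 + a * m2) / det
        ck = logpri[k] - 0.5 * (m1 * w1 + m2 * w2)
        scores2[k] = xi * w1 + xj * w2 + ck
    pred2 = np.argmax(scores2, axis=0)  # (n_te, S)
    acc2 = (pred2 == yte_codes[:, None]).mean(axis=0)
    return acc1, acc2


def oracle_rank(Xl, yl, Xv, yv, pairs, seed, n_cv_repeats=30, floor=0.80):
    """Exhaustively rank all 1- and 2-ratio subsets; return the optimum.

    Returns (subset, key) where key = (validation accuracy, -n_molecules,
    -n_ratios) is the ranking-objective tuple the package's selection
    maximizes (its last tie-break, CV accuracy, is not part of the match
    criterion). ``seed`` must equal the seed given to rank_and_select so the
    CV splits coincide.
    """
    Xl = np.asarray(Xl, float)
    Xv = np.asarray(Xv, float)
    yl = np.asarray(yl)
    classes, yl_codes = np.unique(yl, return_inverse=True)
    yv_codes = np.searchsorted(classes, np.asarray(yv))
    K = classes.size
    m = Xl.shape[1]
    I2, J2 = map(
        np.asarray, zip(*itertools.combinations(range(m), 2))
    )

    splits = stratified_splits(yl, 2, n_cv_repeats, seed)
    cv1 = np.zeros(m)
    cv2 = np.zeros(I2.size)
    n_folds = 0
    for folds in splits:
        for train, test in folds:
            a1, a2 = _accuracies_one_fold(
                Xl[train], yl_codes[train], K, Xl[test], yl_codes[test], I2, J2
            )
            cv1 += a1
            cv2 += a2
            n_folds += 1
    cv1 /= n_folds
    cv2 /= n_folds

    val1, val2 = _accuracies_one_fold(Xl, yl_codes, K, Xv, yv_codes, I2, J2)

    def n_molecules(subset):
        return len({f for k in subset for f in pairs[k]})

    candidates = []
    for j in range(m):
        candidates.append(((j,), cv1[j], val1[j]))
    for s in range(I2.size):
        candidates.append(((int(I2[s]), int(J2[s])), cv2[s], val2[s]))

    survivors = [c for c in candidates if c[1] > floor]
    if not survivors:
        survivors = [max(candidates, key=lambda c: c[1])]
    best = max(
        survivors,
        key=lambda c: (c[2], -n_molecules(c[0]), -len(c[0]), c[1]),
    )
    subset, _, val = best
    return subset, (round(float(val), 12), -n_molecules(subset), -len(subset))
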