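"""Ordered ion-intensity-ratio features and search-space combinatorics.

A ratio feature is the quotient of two peak intensities within one spectrum.
Because a per-injection global intensity factor multiplies every peak of a
spectrum equally, all pairwise ratios are invariant to it — ratios act as a
normalization-free representation. Ordered pairs (i, j) and (j, i) are kept
as distinct features, so p peaks yield exactly p*(p-1) ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignment import AlignedMatrix

__all__ = [
    "RatioFeatureSet",
    "build_ratios",
    "count_ordered_ratios",
    "count_subsets",
]


@dataclass
class RatioFeatureSet:
    """All ordered intensity ratios over a feature subset.

    ``pairs[k] = (i, j)`` gives the source-matrix column indices whose
    quotient forms ratio column k; ``ratio_matrix`` is samples x pairs and
    strictly positive after imputation. ``pair_labels`` are human-readable
    "mzNum/mzDen" headers.
    """

    pairs: list[tuple[int, int]]
    ratio_matrix: np.ndarray
    source_feature_ids: list[int]
    pair_labels: list[str]
    sample_ids: list[str]
    class_labels: list[str]

    @property
    def n_ratios(self) -> int:
        return len(self.pairs)

    def columns(self, subset) -> np.ndarray:
        """Ratio sub-matrix for a subset of ratio indices."""
        return self.ratio_matrix[:, list(subset)]

    def molecules(self, subset) -> set[int]:
        """Distinct source features used by a subset of ratio indices."""
        out: set[int] = set()
        for k in subset:
            out.update(self.pairs[k])
        return out


def _impute_zeros(X: np.ndarray) -> np.ndarray:
    """Replace zeros by half the smallest positive value in their column."""
    X = X.astype(float, copy=True)
    for j in range(X.shape[1]):
        col = X[:, j]
        zero = col <= 0
        if not zero.any():
            continue
        pos = col[col > 0]
        if pos.size == 0:
            raise ValueError(f"feature column {j} has no positive intensity")
        col[zero] = pos.min() / 2.0
    return X


def build_ratios(
    matrix: AlignedMatrix,
    feature_subset: list[int] | None = None,
    log_ratios: bool = False,
) -> RatioFeatureSet:
    """Build all ordered pairwise intensity ratios over a feature subset.

    Zero (missing) intensities are first imputed with half the smallest
    positive value of their column, keeping every ratio finite and positive.
    With ``log_ratios`` the natural log of each ratio is returned instead
    (off by default; the discriminant operates on raw ratios).
    """
    if feature_subset is None:
        feature_subset = list(range(matrix.n_features))
    feature_subset = [int(i) for i in feature_subset]
    if len(feature_subset) < 2:
        raise ValueError("need at least two features to form ratios")
    X = _impute_zeros(matrix.intensities[:, feature_subset])
    p = len(feature_subset)
    pairs: list[tuple[int, int]] = []
    labels: list[str] = []
    cols = []
    mzs = matrix.feature_mz[feature_subset]
    for a in range(p):
        for b in range(p):
            if a == b:
                continue
            pairs.append((feature_subset[a], feature_subset[b]))
            labels.append(f"{mzs[a]:.4f}/{mzs[b]:.4f}")
            cols.append(X[:, a] / X[:, b])
    R = np.column_stack(cols)
    if log_ratios:
        R = np.log(R)
    return RatioFeatureSet(
        pairs=pairs,
        ratio_matrix=R,
        source_feature_ids=feature_subset,
        pair_labels=labels,
        sample_ids=list(matrix.sample_ids),
        class_labels=list(matrix.class_labels),
    )


def count_ordered_ratios(p: int) -> int:
    """Number of ordered intensity ratios formable from p peaks: p*(p-1)."""
    if p < 2:
        raise ValueError("need at least 2 peaks")
    return p * (p - 1)


def count_subsets(n_ratios: int, kmin: int, kmax: int) -> int:
    """Exact count of ratio subsets of size kmin..kmax (big-integer sum).

    This is the size of the space a wrapper feature-selection search faces:
    sum over k of C(n_ratios, k).
    """
    if not (1 <= kmin <= kmax <= n_ratios):
        raise ValueError("require 1 <= kmin <= kmax <= n_ratios")
    return sum(math.comb(n_ratios, k) for k in range(kmin, kmax + 1))
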