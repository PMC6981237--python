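"""Cross-sample peak alignment by complete-linkage clustering on m/z.

Peaks from all spectra are pooled and clustered on absolute m/z difference
(Th). Complete linkage bounds the within-cluster m/z spread by the cut
height, so each cluster becomes one consensus feature whose spread never
exceeds the chosen cutoff. The cutoff is selected to minimize co-clustering
of distinct ions from the same spectrum, and technical replicates are then
averaged into one row per biological sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

from .preprocessing import PeakTable

__all__ = [
    "AlignedMatrix",
    "align_peaks",
    "choose_cutoff",
    "average_replicates",
    "default_cutoff_grid",
]


@dataclass
class AlignedMatrix:
    """Samples x consensus-feature intensity matrix.

    ``feature_mz`` is the mean m/z of each cluster's member peaks, strictly
    increasing across columns. ``intensities`` holds 0 where a sample
    contributed no member peak (pre-imputation). Before replicate averaging
    there is one row per injection (``replicate_ids`` set); afterwards one row
    per biological sample (``replicate_ids`` is None).
    """

    sample_ids: list[str]
    class_labels: list[str]
    feature_mz: np.ndarray
    intensities: np.ndarray
    replicate_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, p = self.intensities.shape
        if len(self.sample_ids) != n or len(self.class_labels) != n:
            raise ValueError("row metadata length does not match the matrix")
        if self.feature_mz.size != p:
            raise ValueError("feature_mz length does not match the matrix")
        if p > 1 and np.any(np.diff(self.feature_mz) <= 0):
            raise ValueError("feature_mz must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]


def default_cutoff_grid() -> np.ndarray:
    """Logarithmic candidate cutoff grid, 0.001-0.5 Th, 20 points."""
    return np.geomspace(0.001, 0.5, 20)


def _pool_peaks(tables: list[PeakTable]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pool all peaks, sorted by m/z; returns (mz, height, table_index)."""
    mz = np.concatenate([t.mz for t in tables])
    height = np.concatenate([t.height for t in tables])
    origin = np.concatenate(
        [np.full(len(t), i, dtype=int) for i, t in enumerate(tables)]
    )
    order = np.argsort(mz, kind="stable")
    return mz[order], height[order], origin[order]


def _cluster_labels_multi(
    mz_sorted: np.ndarray, cutoffs: list[float]
) -> dict[float, np.ndarray]:
    """Complete-linkage cluster labels of sorted 1-D points at several cutoffs.

    The pooled list is split into segments wherever the gap between
    consecutive m/z values exceeds the largest cutoff: complete linkage can
    never merge across such a gap at any of the requested cut heights, so
    exact linkage within each segment reproduces the full-linkage result
    while staying tractable for tens of thousands of peaks.
    """
    cutoffs = sorted(set(float(c) for c in cutoffs))
    n = mz_sorted.size
    out = {c: np.empty(n, dtype=int) for c in cutoffs}
    if n == 0:
        return out
    max_cut = cutoffs[-1]
    gaps = np.diff(mz_sorted)
    seg_starts = np.concatenate([[0], np.nonzero(gaps > max_cut)[0] + 1, [n]])
    next_label = {c: 0 for c in cutoffs}
    for s, e in zip(seg_starts[:-1], seg_starts[1:]):
        seg = mz_sorted[s:e]
        if seg.size == 1:
            for c in cutoffs:
                out[c][s:e] = next_label[c]
                next_label[c] += 1
            continue
        Z = linkage(seg[:, None], method="complete")
        for c in cutoffs:
            labels = fcluster(Z, t=c, criterion="distance") - 1
            out[c][s:e] = labels + next_label[c]
            next_label[c] += labels.max() + 1
    return out


def _co_clustering_count(labels: np.ndarray, origin: np.ndarray) -> int:
    """Number of clusters containing >=2 peaks from the same spectrum."""
    bad = 0
    order = np.argsort(labels, kind="stable")
    lab_sorted = labels[order]
    org_sorted = origin[order]
    starts = np.concatenate(
        [[0], np.nonzero(np.diff(lab_sorted))[0] + 1, [labels.size]]
    )
    for s, e in zip(starts[:-1], starts[1:]):
        members = org_sorted[s:e]
        if members.size > 1 and np.unique(members).size < members.size:
            bad += 1
    return bad


def choose_cutoff(
    tables: list[PeakTable], candidate_cutoffs: np.ndarray | list[float] | None = None
) -> float:
    """Pick the cutoff minimizing within-spectrum co-clustering.

    Distinct ions of one spectrum falling into the same consensus feature
    indicate over-merging; the objective counts clusters in which that
    happens. Ties are broken toward the larger cutoff (fewer split features).
    """
    if candidate_cutoffs is None:
        candidate_cutoffs = default_cutoff_grid()
    candidates = sorted(set(float(c) for c in candidate_cutoffs))
    if len(candidates) < 1:
        raise ValueError("need at least one candidate cutoff")
    if not tables:
        raise ValueError("need at least one peak table")
    mz, _, origin = _pool_peaks(tables)
    labels_by_cut = _cluster_labels_multi(mz, candidates)
    best, best_count = None, None
    for c in candidates:  # ascending: '<=' keeps the largest tied cutoff
        count = _co_clustering_count(labels_by_cut[c], origin)
        if best_count is None or count <= best_count:
            best, best_count = c, count
    return float(best)


def align_peaks(
    tables: list[PeakTable],
    cutoff: float | str = "auto",
    candidate_cutoffs: np.ndarray | list[float] | None = None,
    class_labels: dict[str, str] | None = None,
) -> AlignedMatrix:
    """Merge per-spectrum peak tables into a consensus feature matrix.

    Parameters
    ----------
    tables : per-injection peak tables (>=2).
    cutoff : cut height in Th, or "auto" to call :func:`choose_cutoff`.
    class_labels : optional mapping sample_id -> class label.

    Each cluster of pooled peak m/z values becomes one feature; a spectrum's
    feature intensity is its member peak height, summed if several of its
    peaks fall in one cluster (the event the cutoff objective penalizes).
    """
    if len(tables) < 2:
        raise ValueError("need at least two peak tables to align")
    if all(len(t) == 0 for t in tables):
        raise ValueError("no peaks to align")
    if cutoff == "auto":
        cutoff = choose_cutoff(tables, candidate_cutoffs)
    cutoff = float(cutoff)
    mz, height, origin = _pool_peaks(tables)
    labels = _cluster_labels_multi(mz, [cutoff])[cutoff]

    n_clusters = labels.max() + 1
    feature_mz = np.zeros(n_clusters)
    counts = np.zeros(n_clusters)
    np.add.at(feature_mz, labels, mz)
    np.add.at(counts, labels, 1.0)
    feature_mz /= counts

    order = np.argsort(feature_mz)
    rank = np.empty(n_clusters, dtype=int)
    rank[order] = np.arange(n_clusters)

    intensities = np.zeros((len(tables), n_clusters))
    np.add.at(intensities, (origin, rank[labels]), height)

    sample_ids = [t.sample_id for t in tables]
    replicate_ids = [t.replicate_id for t in tables]
    labels_out = [
        (class_labels or {}).get(sid, "") for sid in sample_ids
    ]
    return AlignedMatrix(
        sample_ids=sample_ids,
        class_labels=labels_out,
        feature_mz=feature_mz[order],
        intensities=intensities,
        replicate_ids=replicate_ids,
    )


def average_replicates(
    matrix: AlignedMatrix, replicate_map: dict | None = None
) -> AlignedMatrix:
    """Average technical replicates into one row per biological sample.

    ``replicate_map`` maps (sample_id, replicate_id) -> biological sample id;
    by default rows sharing ``sample_id`` are treated as replicates. Rows are
    averaged arithmetically per feature; output rows keep first-appearance
    order. A row whose key is missing from an explicit map is an error.
    """
    rep_ids = matrix.replicate_ids or [""] * matrix.n_samples
    keys = []
    for sid, rid in zip(matrix.sample_ids, rep_ids):
        if replicate_map is not None:
            if (sid, rid) not in replicate_map:
                raise KeyError(f"replicate ({sid!r}, {rid!r}) missing from replicate_map")
            keys.append(replicate_map[(sid, rid)])
        else:
            keys.append(sid)
    uniq: list = []
    seen = {}
    for k in keys:
        if k not in seen:
            seen[k] = len(uniq)
            uniq.append(k)
    out = np.zeros((len(uniq), matrix.n_features))
    counts = np.zeros(len(uniq))
    rows = np.array([seen[k] for k in keys])
    np.add.at(out, rows, matrix.intensities)
    np.add.at(counts, rows, 1.0)
    out /= counts[:, None]
    class_by_key = {}
    for k, lab in zip(keys, matrix.class_labels):
        class_by_key.setdefault(k, lab)
    return AlignedMatrix(
        sample_ids=[str(k) for k in uniq],
        class_labels=[class_by_key[k] for k in uniq],
        feature_mz=matrix.feature_mz,
        intensities=out,
        replicate_ids=None,
    )
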