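"""Exact-mass annotation of consensus features against a compound database.

Features are matched to database entries by relative mass error in parts per
million, with the signed convention

    ppm = (theoretical - experimental) / theoretical * 1e6

so a feature measured *below* its theoretical mass has a positive error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .alignment import AlignedMatrix

__all__ = ["CompoundDB", "Annotation", "ppm_error", "annotate"]

logger = logging.getLogger(__name__)


@dataclass
class CompoundDB:
    """In-house compound list: unique names with theoretical m/z (Th)."""

    names: list[str]
    theoretical_mz: np.ndarray

    def __post_init__(self) -> None:
        self.theoretical_mz = np.asarray(self.theoretical_mz, dtype=float)
        if len(self.names) != self.theoretical_mz.size:
            raise ValueError("names and theoretical_mz must have the same length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("compound names must be unique")
        if np.any(self.theoretical_mz <= 0):
            raise ValueError("theoretical m/z must be > 0")

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class Annotation:
    """One feature-to-compound match with its signed mass error."""

    feature_id: int
    feature_mz: float
    name: str
    ppm: float
    ambiguous: bool = False


def ppm_error(experimental_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in ppm: (theo - exp) / theo * 1e6."""
    if experimental_mz <= 0 or theoretical_mz <= 0:
        raise ValueError("m/z values must be > 0")
    return (theoretical_mz - experimental_mz) / theoretical_mz * 1e6


def annotate(
    matrix: AlignedMatrix, db: CompoundDB, tol_ppm: float = 10.0
) -> list[Annotation]:
    """Match consensus features to database compounds within a ppm tolerance.

    Every (feature, compound) pair with |ppm error| <= tol_ppm is reported;
    features matching more than one compound are flagged ambiguous, and
    unmatched features are omitted. The result is independent of database row
    order (matches are sorted by feature, then compound name).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if len(db) == 0:
        logger.warning("empty compound database: nothing annotated")
        return []
    results: list[Annotation] = []
    for fid, fmz in enumerate(matrix.feature_mz):
        errs = (db.theoretical_mz - fmz) / db.theoretical_mz * 1e6
        hits = np.nonzero(np.abs(errs) <= tol_ppm)[0]
        matches = sorted(
            ((db.names[j], float(errs[j])) for j in hits), key=lambda t: t[0]
        )
        ambiguous = len(matches) > 1
        for name, err in matches:
            results.append(Annotation(fid, float(fmz), name, err, ambiguous))
    return results


def annotated_feature_ids(annotations: list[Annotation]) -> list[int]:
    """Sorted unique feature ids having at least one annotation."""
    return sorted({a.feature_id for a in annotations})
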