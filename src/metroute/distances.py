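"""Pairwise genetic distance, Jaccard similarity and route distance ratios.

Genetic distance between two samples is the Hamming count of discordant
variant presences (the symmetric difference of their mutation sets); the
Jaccard index is |A ∩ B| / |A ∪ B|.  The distance-ratio statistic for an
anchor sample A against reference classes B and C is
``d(A,B) / d(A,C) - 1``: positive means A is genomically closer to C,
negative closer to B.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .types import BinaryMutationMatrix

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray  # symmetric, nonnegative, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T) or (np.diag(v) != 0).any() or (v < 0).any():
            raise ValueError("distances must be symmetric, nonnegative, "
                             "zero on the diagonal")
        self.values = v

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.values[i, j])


@dataclass
class SimilarityMatrix:
    sample_ids: list[str]
    jaccard: np.ndarray  # symmetric, in [0,1], unit diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.jaccard, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("similarity matrix shape mismatch")
        if (not np.allclose(v, v.T) or (v < 0).any() or (v > 1).any()
                or not np.allclose(np.diag(v), 1.0)):
            raise ValueError("Jaccard matrix must be symmetric in [0,1] "
                             "with unit diagonal")
        self.jaccard = v

    def get(self, a: str, b: str) -> float:
        i, j = self.sample_ids.index(a), self.sample_ids.index(b)
        return float(self.jaccard[i, j])


def pairwise_distance(matrix: BinaryMutationMatrix) -> DistanceMatrix:
    """Hamming distance between sample presence profiles."""
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    P = matrix.presence.astype(int)
    d = (P[:, None, :] != P[None, :, :]).sum(axis=2).astype(float)
    return DistanceMatrix(list(matrix.sample_ids), d)


def jaccard_matrix(matrix: BinaryMutationMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard indices of sample mutation sets.

    Two samples with empty union get J = 1 by convention (flagged with a
    warning): identical, if vacuously so.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    P = matrix.presence
    inter = (P[:, None, :] & P[None, :, :]).sum(axis=2).astype(float)
    union = (P[:, None, :] | P[None, :, :]).sum(axis=2).astype(float)
    empty = union == 0
    if empty.any():
        warnings.warn("sample pair(s) with empty mutation union; Jaccard "
                      "set to 1 by convention")
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(empty, 1.0, inter / np.where(empty, 1.0, union))
    return SimilarityMatrix(list(matrix.sample_ids), J)


def distance_ratio(d_ab: float, d_ac: float) -> float:
    """``d_ab / d_ac - 1``; > 0 means the anchor is closer to C, < 0
    closer to B.  Undefined (error) when d_ac = 0."""
    if d_ac == 0:
        raise ValueError("distance_ratio undefined for d_ac = 0")
    return d_ab / d_ac - 1.0


def _class_distance(dist: DistanceMatrix, anchor: str,
                    members: list[str]) -> float:
    """Mean distance from the anchor to the members of a class."""
    return float(np.mean([dist.get(anchor, m) for m in members]))


def route_ratio_summary(patients: dict[str, tuple[DistanceMatrix, dict[str, str]]],
                        anchor_class: str, class_b: str,
                        class_c: str) -> dict:
    """Distance ratios of anchor-class samples against two reference
    classes, across a cohort.

    ``patients`` maps patient id to (distance matrix, sample -> class
    labels).  For each anchor sample A the class-to-class distance is the
    mean over member pairs; patients lacking any of the three classes are
    skipped and logged.  Returns per-patient ratio lists plus a pooled
    summary (median, mean, n).
    """
    per_patient: dict[str, list[float]] = {}
    pooled: list[float] = []
    for pid, (dist, classes) in patients.items():
        by_class: dict[str, list[str]] = {}
        for sid, cls in classes.items():
            if sid in dist.sample_ids:
                by_class.setdefault(cls, []).append(sid)
        if not all(by_class.get(c) for c in (anchor_class, class_b, class_c)):
            logger.info("patient %s lacks a class among (%s, %s, %s); skipped",
                        pid, anchor_class, class_b, class_c)
            continue
        ratios = []
        for anchor in by_class[anchor_class]:
            b_members = [m for m in by_class[class_b] if m != anchor]
            c_members = [m for m in by_class[class_c] if m != anchor]
            if not b_members or not c_members:
                continue
            d_ab = _class_distance(dist, anchor, b_members)
            d_ac = _class_distance(dist, anchor, c_members)
            if d_ac == 0:
                logger.info("patient %s anchor %s: zero distance to class "
                            "%s; ratio skipped", pid, anchor, class_c)
                continue
            ratios.append(distance_ratio(d_ab, d_ac))
        if ratios:
            per_patient[pid] = ratios
            pooled.extend(ratios)
    if not pooled:
        raise ValueError("no eligible patient for the requested route "
                         "ratio comparison")
    return {
        "anchor_class": anchor_class, "class_b": class_b, "class_c": class_c,
        "per_patient": per_patient,
        "n_ratios": len(pooled),
        "median_ratio": float(np.median(pooled)),
        "mean_ratio": float(np.mean(pooled)),
    }


def mean_patient_jaccard(similarity: SimilarityMatrix,
                         tumor_samples: list[str]) -> float:
    """Mean off-diagonal Jaccard index over the given tumor samples —
    the per-patient genomic similarity summary."""
    idx = [similarity.sample_ids.index(s) for s in tumor_samples]
    if len(idx) < 2:
        raise ValueError("need at least 2 tumor samples")
    sub = similarity.jaccard[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())
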