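"""Representational dissimilarity matrices: the pipeline's universal currency.

An :class:`RDM` is a labeled, square, symmetric, zero-diagonal matrix of
pairwise dissimilarities between experimental conditions, with provenance
metadata.  One shared vectorization routine (lower triangle excluding the
diagonal, row-major) is used everywhere so neural and model vectors can never
be silently misaligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidArgumentError, InvalidInputError, UndefinedDistanceError

__all__ = ["RDM", "vectorize", "average_rdms", "feature_rdm"]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class RDM:
    """Labeled square dissimilarity matrix.

    Parameters
    ----------
    matrix : (n, n) array of dissimilarities; must be symmetric with a zero
        diagonal (within 1e-8; stored exactly symmetric and zero-diagonal).
    labels : condition labels, one per row/column.
    meta : free-form provenance (source kind, participant, block, convention).
    """

    matrix: np.ndarray
    labels: tuple[str, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InvalidInputError(f"RDM matrix must be square, got shape {m.shape}")
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != m.shape[0]:
            raise InvalidInputError(
                f"{len(labels)} labels for a {m.shape[0]}x{m.shape[0]} matrix"
            )
        if len(set(labels)) != len(labels):
            raise InvalidInputError("RDM labels must be unique")
        if not np.all(np.isfinite(m)):
            raise InvalidInputError("RDM contains non-finite entries")
        if np.abs(m - m.T).max(initial=0.0) > _SYM_TOL:
            raise InvalidInputError("RDM is asymmetric beyond tolerance 1e-8")
        if np.abs(np.diag(m)).max(initial=0.0) > _SYM_TOL:
            raise InvalidInputError("RDM diagonal is nonzero beyond tolerance 1e-8")
        m = (m + m.T) / 2.0
        np.fill_diagonal(m, 0.0)
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def vector(self) -> np.ndarray:
        """Lower triangle (excluding diagonal), row-major. Shared everywhere."""
        return vectorize(self.matrix)

    def submatrix(self, labels: Sequence[str]) -> "RDM":
        """RDM restricted to ``labels``, in the given order."""
        idx = self._indices(labels)
        return RDM(self.matrix[np.ix_(idx, idx)], tuple(labels), dict(self.meta))

    def permuted(self, perm: Sequence[int]) -> "RDM":
        """Apply one permutation simultaneously to rows and columns.

        Labels are left in place (the matrix content moves under them), which
        is the convention needed for condition-label permutation nulls.
        """
        perm = np.asarray(perm)
        if sorted(perm.tolist()) != list(range(self.n)):
            raise InvalidArgumentError("perm must be a permutation of 0..n-1")
        return RDM(self.matrix[np.ix_(perm, perm)], self.labels, dict(self.meta))

    def _indices(self, labels: Sequence[str]) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        try:
            return np.array([pos[str(x)] for x in labels], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise InvalidInputError(f"unknown condition label {e.args[0]!r}") from None


def vectorize(matrix: np.ndarray) -> np.ndarray:
    """Lower-triangle (k=-1) vectorization, row-major order."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InvalidInputError("vectorize expects a square matrix")
    return m[np.tril_indices(m.shape[0], k=-1)]


def _check_same_labels(rdms: Sequence[RDM]) -> tuple[str, ...]:
    labels = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels:
            raise InvalidInputError("RDMs have mismatching condition labels")
    return labels


def average_rdms(rdms: Sequence[RDM], meta: dict | None = None) -> RDM:
    """Elementwise mean of RDMs sharing one stimulus ordering."""
    rdms = list(rdms)
    if not rdms:
        raise InvalidArgumentError("need at least one RDM to average")
    labels = _check_same_labels(rdms)
    mean = np.mean([r.matrix for r in rdms], axis=0)
    out_meta = {"source": "average", "n_averaged": len(rdms)}
    if meta:
        out_meta.update(meta)
    return RDM(mean, labels, out_meta)


def feature_rdm(
    features: dict[str, np.ndarray],
    metric: str = "correlation",
    meta: dict | None = None,
) -> RDM:
    """Pairwise-distance RDM from per-stimulus feature vectors.

    ``metric`` is one of ``correlation`` (1 - Pearson r), ``cosine``
    (1 - cosine similarity), or ``euclidean``.  Feature vectors (for example
    motion-energy filter outputs) are consumed as-is; no extraction happens
    here.
    """
    if metric not in ("correlation", "cosine", "euclidean"):
        raise InvalidArgumentError(f"unknown metric {metric!r}")
    labels = tuple(features)
    mat = np.asarray([np.asarray(features[k], dtype=float).ravel() for k in labels])
    if mat.ndim != 2:
        raise InvalidInputError("feature vectors must share one length")
    if not np.all(np.isfinite(mat)):
        raise InvalidInputError("non-finite feature values")
    if metric == "cosine":
        norms = np.linalg.norm(mat, axis=1)
        if np.any(norms == 0):
            bad = labels[int(np.argmin(norms))]
            raise UndefinedDistanceError(f"zero-norm vector for {bad!r} under cosine")
    if metric == "correlation":
        if np.any(mat.std(axis=1) == 0):
            bad = labels[int(np.argmin(mat.std(axis=1)))]
            raise UndefinedDistanceError(
                f"constant vector for {bad!r} under correlation distance"
            )
    d = squareform(pdist(mat, metric=metric))
    # pdist can leave tiny negative/diagonal noise for degenerate inputs
    np.fill_diagonal(d, 0.0)
    out_meta = {"source": "feature", "metric": metric}
    if meta:
        out_meta.update(meta)
    return RDM(d, labels, out_meta)
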