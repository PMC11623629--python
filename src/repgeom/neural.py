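"""Response patterns and split-data neural RDMs.

A subject contributes one condition x unit response matrix per scanning
session.  Response profiles are z-scored per unit across conditions; the
neural RDM correlates each condition's pattern in session 1 with each
condition's pattern in session 2 (split-data RDM), so its off-diagonal
structure reflects signal geometry rather than shared within-session noise,
and its raw diagonal is a split-half pattern-reliability estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, InvalidInputError, UndefinedCorrelationError
from .rdm import RDM

__all__ = ["ResponsePatterns", "zscore_profiles", "splitdata_rdm"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResponsePatterns:
    """One subject-session's condition x unit response matrix."""

    subject_id: str
    session_id: str
    matrix: np.ndarray  # (n_conditions, n_units)
    conditions: tuple[str, ...]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise InvalidInputError("response matrix must be 2-D (conditions x units)")
        conds = tuple(str(c) for c in self.conditions)
        if len(conds) != m.shape[0]:
            raise InvalidInputError(
                f"{len(conds)} condition labels for {m.shape[0]} rows"
            )
        if len(set(conds)) != len(conds):
            raise InvalidInputError("condition labels must be unique")
        if not np.all(np.isfinite(m)):
            raise InvalidInputError("response matrix contains non-finite entries")
        m = m.copy()
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "conditions", conds)

    @property
    def n_conditions(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_units(self) -> int:
        return self.matrix.shape[1]


def zscore_profiles(patterns: ResponsePatterns, ddof: int = 1) -> ResponsePatterns:
    """Z-score each unit's response profile across conditions.

    Constant-profile units (zero variance, undefined z-score) are dropped with
    a logged warning.  Idempotent on already-z-scored input.
    """
    if patterns.n_conditions < 2:
        raise InvalidArgumentError("z-scoring needs at least 2 conditions")
    m = patterns.matrix
    sd = m.std(axis=0, ddof=ddof)
    keep = sd > 0
    if not np.all(keep):
        n_bad = int((~keep).sum())
        logger.warning(
            "dropping %d constant-profile unit(s) in %s/%s (z-score undefined)",
            n_bad, patterns.subject_id, patterns.session_id,
        )
        m = m[:, keep]
        sd = sd[keep]
    z = (m - m.mean(axis=0)) / sd
    meta = dict(patterns.meta)
    meta["zscored"] = True
    return ResponsePatterns(
        patterns.subject_id, patterns.session_id, z, patterns.conditions, meta
    )


def splitdata_rdm(s1: ResponsePatterns, s2: ResponsePatterns) -> RDM:
    """Cross-session split-data RDM.

    M[i, j] is the Pearson correlation across units between condition i's
    session-1 pattern and condition j's session-2 pattern.  The returned RDM
    is ``1 - (M + M.T)/2`` with the diagonal forced to zero; the raw diagonal
    correlations (split-half pattern reliability per condition) are kept in
    ``meta["reliability"]``.
    """
    if s1.conditions != s2.conditions:
        raise InvalidInputError("sessions have different condition labels")
    if s1.n_units != s2.n_units:
        raise InvalidInputError(
            f"unit-count mismatch: {s1.n_units} vs {s2.n_units}"
        )
    if s1.n_units < 2:
        raise InvalidArgumentError("need at least 2 units for pattern correlations")
    a = s1.matrix - s1.matrix.mean(axis=1, keepdims=True)
    b = s2.matrix - s2.matrix.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    for name, norms, pat in (("session 1", na, s1), ("session 2", nb, s2)):
        if np.any(norms == 0):
            cond = pat.conditions[int(np.argmin(norms))]
            raise UndefinedCorrelationError(
                f"zero-variance pattern for condition {cond!r} in {name}"
            )
    m = (a @ b.T) / np.outer(na, nb)
    reliability = np.diag(m).copy()
    d = 1.0 - (m + m.T) / 2.0
    np.fill_diagonal(d, 0.0)
    meta = {
        "source": "splitdata",
        "subject_id": s1.subject_id,
        "sessions": (s1.session_id, s2.session_id),
        "convention": "1 - r, symmetrized",
        "reliability": reliability,
        "negative_reliability": bool(np.any(reliability < 0)),
    }
    return RDM(d, s1.conditions, meta)
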