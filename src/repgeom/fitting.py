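"""Fitting model RDMs to neural RDMs.

Per-model fits are Spearman rank correlations between vectorized RDMs.
Joint fits rank-transform and standardize the response and all predictors,
then run ordinary least-squares with intercept and report in-sample R^2 —
so a single-model joint fit equals the squared Spearman correlation.
Variance partitioning subtracts nested from full fits (unique R^2 =
full R^2 - nested R^2).  The noise ceiling is the leave-one-out intersubject
correlation of RDMs, averaged on the Fisher-z scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    InvalidArgumentError,
    RankDeficiencyError,
    UndefinedCorrelationError,
)
from .rdm import RDM

__all__ = [
    "FitResult",
    "PartitionTable",
    "spearman_fit",
    "joint_fit",
    "variance_partition",
    "isc_noise_ceiling",
    "ceiling_fraction",
    "rank_standardize",
]


@dataclass(frozen=True)
class FitResult:
    """Per-subject fit statistics with a Fisher-z-aware group mean."""

    statistic: str  # spearman_rho | r_squared | unique_r_squared | isc
    values: np.ndarray  # per-subject
    label: str = ""
    neighborhood: str = ""
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)

    @property
    def group_mean(self) -> float:
        """Fisher-z mean back-transformed for correlations; native-scale mean
        for R^2 statistics.  Correlations of exactly +/-1 are clipped to the
        nearest representable value (tanh saturates, so the result is exact)."""
        if self.statistic in ("spearman_rho", "isc"):
            eps = np.finfo(float).eps
            v = np.clip(self.values, -1 + eps, 1 - eps)
            return float(np.tanh(np.mean(np.arctanh(v))))
        return float(np.mean(self.values))


@dataclass(frozen=True)
class PartitionTable:
    """Unique-variance decomposition: partition label -> (unique, full, nested)."""

    full_r2: float
    nested_r2: dict[str, float]
    unique_r2: dict[str, float]
    meta: dict = field(default_factory=dict, compare=False)


def _matched_vectors(neural: RDM, model: RDM) -> tuple[np.ndarray, np.ndarray]:
    if neural.labels != model.labels:
        raise InvalidArgumentError(
            "neural and model RDMs have mismatching condition labels"
        )
    return neural.vector(), model.vector()


def spearman_fit(neural: RDM, model: RDM) -> float:
    """Spearman rank correlation between vectorized RDMs (average ranks)."""
    x, y = _matched_vectors(neural, model)
    return spearman_vec(x, y)


def spearman_vec(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho on raw vectors; shared by RDM fits and bootstrap paths."""
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("Spearman undefined for constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def rank_standardize(v: np.ndarray) -> np.ndarray:
    """Average ranks, then standardize to mean 0 and sd 1 (ddof=1)."""
    r = stats.rankdata(v, method="average")
    sd = r.std(ddof=1)
    if sd == 0:
        raise UndefinedCorrelationError("rank-standardization undefined for ties-only vector")
    return (r - r.mean()) / sd


def _joint_r2_from_vectors(y: np.ndarray, xs: Sequence[np.ndarray],
                           labels: Sequence[str] | None = None,
                           allow_collinear: bool = False) -> float:
    yr = rank_standardize(y)
    xr = np.column_stack([rank_standardize(x) for x in xs])
    n, p = xr.shape
    x_design = np.column_stack([np.ones(n), xr])
    if not allow_collinear and np.linalg.matrix_rank(x_design) < p + 1:
        dep = _dependent_columns(xr, labels)
        raise RankDeficiencyError(
            f"perfectly collinear predictors: {dep}", dependent=dep
        )
    # R^2 is well defined under rank deficiency (minimum-norm least squares)
    beta, *_ = np.linalg.lstsq(x_design, yr, rcond=None)
    resid = yr - x_design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((yr - yr.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def _dependent_columns(xr: np.ndarray, labels: Sequence[str] | None) -> tuple[str, ...]:
    """Name predictors involved in an exact linear dependency (QR pivoting)."""
    labels = list(labels) if labels else [f"model{i}" for i in range(xr.shape[1])]
    _, r = np.linalg.qr(xr)
    small = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return tuple(lab for lab, bad in zip(labels, small) if bad) or tuple(labels)


def joint_fit(neural: RDM, models: Sequence[RDM]) -> float:
    """In-sample R^2 of the rank-standardized OLS of the neural RDM on all
    model RDMs jointly."""
    models = list(models)
    if not models:
        raise InvalidArgumentError("need at least one model RDM")
    vecs = [_matched_vectors(neural, m)[1] for m in models]
    y = neural.vector()
    labels = [m.meta.get("name", f"model{i}") for i, m in enumerate(models)]
    return _joint_r2_from_vectors(y, vecs, labels)


def variance_partition(
    neural: RDM,
    models: Mapping[str, RDM],
    partitions: Sequence[Sequence[str]],
) -> PartitionTable:
    """Unique R^2 per partition via full-vs-nested regression.

    The full fit uses every model; each partition's nested fit drops that
    partition's models; unique R^2 = full - nested (nonnegative up to
    floating point by in-sample OLS monotonicity; values are stored raw).
    """
    names = list(models)
    if not names:
        raise InvalidArgumentError("need at least one model")
    for part in partitions:
        if not part:
            raise InvalidArgumentError("empty partition")
        unknown = set(part) - set(names)
        if unknown:
            raise InvalidArgumentError(f"unknown model label(s): {sorted(unknown)}")
    y = neural.vector()
    vecs = {k: _matched_vectors(neural, models[k])[1] for k in names}
    full = _joint_r2_from_vectors(y, [vecs[k] for k in names], names,
                                  allow_collinear=True)
    nested: dict[str, float] = {}
    unique: dict[str, float] = {}
    for part in partitions:
        key = "+".join(part)
        keep = [k for k in names if k not in set(part)]
        if keep:
            nested_r2 = _joint_r2_from_vectors(y, [vecs[k] for k in keep], keep,
                                               allow_collinear=True)
        else:
            nested_r2 = 0.0  # intercept-only nested model
        nested[key] = nested_r2
        unique[key] = full - nested_r2
    return PartitionTable(full, nested, unique, {"models": tuple(names)})


def isc_noise_ceiling(subject_rdms: Sequence[RDM]) -> FitResult:
    """Leave-one-out intersubject correlation of RDMs.

    Each subject's RDM is Spearman-correlated with the elementwise mean of
    all other subjects' RDMs; per-subject values are averaged on the Fisher-z
    scale (the ``group_mean`` of the returned result).
    """
    rdms = list(subject_rdms)
    if len(rdms) < 2:
        raise InvalidArgumentError("ISC needs at least 2 subjects")
    labels = rdms[0].labels
    for r in rdms[1:]:
        if r.labels != labels:
            raise InvalidArgumentError("subject RDMs have mismatching labels")
    mats = np.stack([r.matrix for r in rdms])
    total = mats.sum(axis=0)
    values = []
    for i, r in enumerate(rdms):
        others = (total - mats[i]) / (len(rdms) - 1)
        values.append(spearman_fit(r, RDM(others, labels)))
    return FitResult("isc", np.array(values), label="noise_ceiling")


def ceiling_fraction(model_r2: float, ceiling_r: float) -> float:
    """Percentage of ceiling-indexed meaningful variance a model explains:
    ``100 * model_r2 / ceiling_r**2``."""
    if not 0.0 <= model_r2 <= 1.0:
        raise InvalidArgumentError("model_r2 must be in [0, 1]")
    if not 0.0 < ceiling_r <= 1.0:
        raise InvalidArgumentError("ceiling_r must be in (0, 1]")
    return 100.0 * model_r2 / ceiling_r**2
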