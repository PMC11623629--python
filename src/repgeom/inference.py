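"""Group-level resampling inference for RDM fits.

Sign-flip permutation tests for subject-level correlations (Fisher-z
averaged), re-centered bootstrap tests for positively biased R^2 statistics,
condition-label permutation nulls for single-RDM fits, percentile bootstrap
intervals resampling subjects or subjects+stimuli, and Benjamini-Hochberg
FDR control.  All p-values use the add-one (observed-included) convention
with ties counted against rejection, so no p-value is ever 0 and every
p-value respects the 1/(n_resamples+1) floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .errors import InvalidArgumentError, InvalidInputError
from .fitting import spearman_fit
from .rdm import RDM, vectorize

__all__ = [
    "TestResult",
    "IntervalResult",
    "fisher_z",
    "fisher_z_inverse",
    "signflip_permutation_test",
    "recentered_bootstrap_test",
    "label_permutation_null",
    "bootstrap_ci",
    "fdr_bh",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    observed: float
    p_value: float
    method: str
    n_resamples: int
    seed: int | None
    null_summary: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class IntervalResult:
    estimate: float
    lower: float
    upper: float
    level: float
    scheme: str
    n_resamples: int
    seed: int | None


def fisher_z(r):
    """Fisher z-transform (arctanh); domain |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise InvalidArgumentError("Fisher z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def fisher_z_inverse(z):
    """Inverse Fisher transform (tanh)."""
    z = np.asarray(z, dtype=float)
    out = np.tanh(z)
    return float(out) if out.ndim == 0 else out


def _add_one_p(null: np.ndarray, observed: float) -> float:
    return float((1 + np.sum(null >= observed)) / (len(null) + 1))


def _null_summary(null: np.ndarray) -> dict:
    return {
        "count": int(len(null)),
        "mean": float(np.mean(null)),
        "quantiles": {
            q: float(np.quantile(null, q)) for q in (0.025, 0.5, 0.95, 0.975)
        },
    }


def signflip_permutation_test(
    values: Sequence[float], n_perms: int = 10_000, seed: int = 0
) -> TestResult:
    """Group-level sign-flip permutation test on subject correlations.

    The observed statistic is the back-transformed mean of Fisher-z values;
    each permutation independently flips each subject's sign before the
    Fisher-z average.  One-tailed (greater) with add-one correction.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise InvalidArgumentError("need at least 2 subject values")
    if n_perms < 1:
        raise InvalidArgumentError("n_perms must be >= 1")
    z = fisher_z(v)  # raises on |r| >= 1
    observed = float(np.tanh(z.mean()))
    rng = substream(seed, "signflip")
    flips = rng.integers(0, 2, size=(n_perms, len(z))) * 2 - 1
    null = np.tanh((flips * z).mean(axis=1))
    return TestResult(
        observed,
        _add_one_p(null, observed),
        "signflip_permutation",
        n_perms,
        seed,
        _null_summary(null),
    )


def recentered_bootstrap_test(
    values: Sequence[float], n_boot: int = 10_000, seed: int = 0
) -> TestResult:
    """Bootstrap hypothesis test for positively biased statistics (R^2).

    Subject values are resampled with replacement; the distribution of
    bootstrap means is re-centered by subtracting the observed mean, and the
    one-tailed add-one p-value compares the observed mean to that null.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise InvalidArgumentError("need at least 2 subject values")
    if n_boot < 1:
        raise InvalidArgumentError("n_boot must be >= 1")
    observed = float(v.mean())
    rng = substream(seed, "recentered_bootstrap")
    idx = rng.integers(0, len(v), size=(n_boot, len(v)))
    null = v[idx].mean(axis=1) - observed
    return TestResult(
        observed,
        _add_one_p(null, observed),
        "recentered_bootstrap",
        n_boot,
        seed,
        _null_summary(null),
    )


def label_permutation_null(
    neural: RDM,
    model: RDM,
    statistic: Callable[[RDM, RDM], float] = spearman_fit,
    n_perms: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Condition-label permutation null for a single RDM fit.

    Each permutation shuffles the model RDM's rows and columns with one
    shared permutation and recomputes the statistic.
    """
    if n_perms < 1:
        raise InvalidArgumentError("n_perms must be >= 1")
    observed = float(statistic(neural, model))
    rng = substream(seed, "label_permutation")
    null = np.empty(n_perms)
    for k in range(n_perms):
        perm = rng.permutation(model.n)
        null[k] = statistic(neural, model.permuted(perm))
    return TestResult(
        observed,
        _add_one_p(null, observed),
        "label_permutation",
        n_perms,
        seed,
        _null_summary(null),
    )


def _stimulus_resample_stat(
    subject_rdms: Sequence[RDM],
    model: RDM,
    cond_idx: np.ndarray,
    statistic_vec: Callable[[np.ndarray, np.ndarray], float],
) -> float | None:
    """Mean over subjects of the statistic on condition-resampled RDMs.

    Pairs formed by a condition and its own duplicate have no defined
    dissimilarity structure and are excluded from the vectorization; returns
    None when every pair is degenerate.
    """
    n = len(cond_idx)
    dup = vectorize(cond_idx[:, None] == cond_idx[None, :])
    keep = ~dup
    if not keep.any():
        return None
    mvec = vectorize(model.matrix[np.ix_(cond_idx, cond_idx)])[keep]
    if np.ptp(mvec) == 0:
        return None
    vals = []
    for r in subject_rdms:
        nvec = vectorize(r.matrix[np.ix_(cond_idx, cond_idx)])[keep]
        if np.ptp(nvec) == 0:
            return None
        vals.append(statistic_vec(nvec, mvec))
    return float(np.mean(vals))


def bootstrap_ci(
    subject_values: Sequence[float] | None = None,
    *,
    subject_rdms: Sequence[RDM] | None = None,
    model: RDM | None = None,
    statistic_vec: Callable[[np.ndarray, np.ndarray], float] | None = None,
    scheme: str = "subjects",
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int = 0,
    max_retries: int = 100,
) -> IntervalResult:
    """Percentile bootstrap confidence interval.

    ``scheme="subjects"`` resamples subjects with replacement and averages
    their values.  ``scheme="subjects+stimuli"`` additionally resamples
    condition indices with replacement, rebuilds each resampled subject's
    RDM on that index set (degenerate duplicate pairs excluded from the
    vectorization), and recomputes ``statistic_vec`` (default Spearman) per
    subject before averaging; fully degenerate resamples are redrawn with a
    bounded retry budget.
    """
    if scheme not in ("subjects", "subjects+stimuli"):
        raise InvalidArgumentError(f"unknown scheme {scheme!r}")
    if not 0 < level < 1:
        raise InvalidArgumentError("level must be in (0, 1)")
    if n_boot < 1:
        raise InvalidArgumentError("n_boot must be >= 1")
    rng = substream(seed, "bootstrap_ci")
    if scheme == "subjects":
        if subject_values is None:
            raise InvalidArgumentError("subjects scheme needs subject_values")
        v = np.asarray(subject_values, dtype=float)
        if len(v) < 2:
            raise InvalidArgumentError("need at least 2 subjects")
        estimate = float(v.mean())
        idx = rng.integers(0, len(v), size=(n_boot, len(v)))
        stats_ = v[idx].mean(axis=1)
    else:
        if subject_rdms is None or model is None:
            raise InvalidArgumentError(
                "subjects+stimuli scheme needs subject_rdms and model"
            )
        rdms = list(subject_rdms)
        if len(rdms) < 2:
            raise InvalidArgumentError("need at least 2 subjects")
        if statistic_vec is None:
            from .fitting import spearman_vec
            statistic_vec = spearman_vec
        n_cond = model.n
        estimate = float(
            np.mean([
                statistic_vec(r.vector(), model.vector()) for r in rdms
            ])
        )
        stats_ = np.empty(n_boot)
        for b in range(n_boot):
            stat = None
            for _ in range(max_retries):
                subj_idx = rng.integers(0, len(rdms), size=len(rdms))
                cond_idx = rng.integers(0, n_cond, size=n_cond)
                stat = _stimulus_resample_stat(
                    [rdms[i] for i in subj_idx], model, cond_idx, statistic_vec
                )
                if stat is not None:
                    break
                logger.info("degenerate stimulus resample redrawn (iteration %d)", b)
            if stat is None:
                raise InvalidInputError(
                    "all stimulus resamples degenerate after retry budget"
                )
            stats_[b] = stat
    alpha = 1 - level
    lower, upper = np.percentile(stats_, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return IntervalResult(
        estimate, float(lower), float(upper), level, scheme, n_boot, seed
    )


def fdr_bh(p_values: Sequence[float], q: float = 0.001):
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject_flags, adjusted_p)``; flags are ``adjusted <= q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise InvalidInputError("p_values must be a nonempty 1-D sequence")
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidInputError("p-values must lie in (0, 1]")
    if not 0 < q < 1:
        raise InvalidArgumentError("q must be in (0, 1)")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    reject = adjusted <= q
    return reject, adjusted
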