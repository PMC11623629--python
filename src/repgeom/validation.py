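"""Planted-truth validation experiments for the pipeline.

These experiments exercise the full stack against known ground truth: (1)
convergence of simulated split-data correlations to the analytic target
``S_ij / (1 + sigma^2)``; (2) recovery of a planted dominant model by the
group-level Spearman fits and by unique-variance partitioning; (3) type-I
error calibration of the sign-flip permutation test on null cohorts.  They
back both the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .fitting import spearman_fit, variance_partition
from .inference import signflip_permutation_test
from .neural import splitdata_rdm
from .synthetic import (
    GroundTruth,
    blend_similarity,
    simulate_model_rdms,
    simulate_subject_patterns,
)

__all__ = [
    "splitdata_convergence_error",
    "RecoveryResult",
    "dominant_model_recovery",
    "signflip_rejection_rate",
]


def splitdata_convergence_error(
    n_units: int = 50_000,
    noise_sd: float = 0.0,
    n_categories: int = 18,
    n_exemplars: int = 5,
    seed: int = 0,
) -> float:
    """Max elementwise deviation of split-data correlations from the
    generative law.

    Simulates one subject's two sessions at ``n_units`` units from a single
    planted model (raw patterns; the law predates the per-unit z-scoring
    normalization) and returns ``max_ij |r_ij - S_ij/(1+sigma^2)|`` over
    off-diagonal condition pairs.
    """
    truth = GroundTruth(
        n_subjects=1,
        n_categories=n_categories,
        n_exemplars=n_exemplars,
        n_units_per_neighborhood=n_units,
        noise_sd=noise_sd,
        model_kinds=("category", "random", "random"),
        mixture_weights={"probe": (1.0, 0.0, 0.0)},
        seed=seed,
    )
    stimuli = truth.stimuli()
    models = simulate_model_rdms(stimuli, truth)
    s = blend_similarity(models, (1.0, 0.0, 0.0))
    (s1, s2), = simulate_subject_patterns(
        truth, "probe", model_rdms=models, zscore=False
    )
    observed = 1.0 - splitdata_rdm(s1, s2).matrix
    expected = s / (1.0 + noise_sd**2)
    off = ~np.eye(stimuli.n, dtype=bool)
    return float(np.abs(observed[off] - expected[off]).max())


@dataclass(frozen=True)
class RecoveryResult:
    spearman_rate: float      # fraction of neighborhoods won by group Spearman
    unique_r2_rate: float     # fraction won by mean unique R^2
    n_neighborhoods: int
    n_subjects: int
    n_units: int
    noise_sd: float


def dominant_model_recovery(
    n_neighborhoods: int = 200,
    n_subjects: int = 20,
    n_units: int = 500,
    noise_sd: float = 0.5,
    dominant_weight: float = 0.7,
    background_weight: float = 0.15,
    n_categories: int = 18,
    n_exemplars: int = 5,
    seed: int = 0,
) -> RecoveryResult:
    """Recover a planted dominant model across simulated neighborhoods.

    Each neighborhood's geometry mixes all candidate models with one dominant
    weight (cycling the dominant model across neighborhoods).  A neighborhood
    counts as recovered when the dominant model attains (a) the largest
    group-level Spearman fit (Fisher-z averaged across subjects) and (b) the
    largest subject-mean unique R^2.
    """
    kinds = ("category", "random", "random")
    n_models = len(kinds)
    weights = {}
    dominant = {}
    for k in range(n_neighborhoods):
        w = np.full(n_models, background_weight)
        d = k % n_models
        w[d] = dominant_weight
        weights[f"nbhd{k:03d}"] = tuple(w)
        dominant[f"nbhd{k:03d}"] = d
    truth = GroundTruth(
        n_subjects=n_subjects,
        n_categories=n_categories,
        n_exemplars=n_exemplars,
        n_units_per_neighborhood=n_units,
        noise_sd=noise_sd,
        model_kinds=kinds,
        mixture_weights=weights,
        seed=seed,
    )
    stimuli = truth.stimuli()
    models = simulate_model_rdms(stimuli, truth)
    names = [m.meta["name"] for m in models]
    named = dict(zip(names, models))
    partitions = [[n] for n in names]
    spearman_wins = 0
    unique_wins = 0
    for center, d in dominant.items():
        pairs = simulate_subject_patterns(truth, center, model_rdms=models)
        rdms = [splitdata_rdm(s1, s2) for s1, s2 in pairs]
        rhos = np.array([[spearman_fit(r, m) for m in models] for r in rdms])
        group = np.tanh(np.arctanh(rhos).mean(axis=0))
        if int(np.argmax(group)) == d:
            spearman_wins += 1
        uniq = np.array([
            [variance_partition(r, named, partitions).unique_r2[n] for n in names]
            for r in rdms
        ])
        if int(np.argmax(uniq.mean(axis=0))) == d:
            unique_wins += 1
    return RecoveryResult(
        spearman_wins / n_neighborhoods,
        unique_wins / n_neighborhoods,
        n_neighborhoods,
        n_subjects,
        n_units,
        noise_sd,
    )


def signflip_rejection_rate(
    n_cohorts: int = 2000,
    n_subjects: int = 20,
    n_perms: int = 1000,
    alpha: float = 0.05,
    value_sd: float = 0.2,
    seed: int = 0,
) -> float:
    """Type-I error of the sign-flip permutation test on null cohorts.

    Subject correlations are drawn from a zero-mean normal (symmetric, so the
    sign-flip null holds exactly); returns the fraction of cohorts rejected
    at ``alpha``.
    """
    rng = substream(seed, "calibration")
    rejections = 0
    for k in range(n_cohorts):
        values = np.clip(
            rng.normal(0.0, value_sd, size=n_subjects), -0.999, 0.999
        )
        res = signflip_permutation_test(values, n_perms=n_perms, seed=int(rng.integers(2**31)))
        if res.p_value <= alpha:
            rejections += 1
    return rejections / n_cohorts
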