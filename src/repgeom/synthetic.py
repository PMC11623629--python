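"""Synthetic data with planted ground truth for the full pipeline.

Emulates the study's data layout — 23 subjects x 2 sessions x 90 conditions
(18 categories x 5 exemplars) — without any download.  Local neural
geometries are noisy mixtures of known model RDMs: the target similarity is
``S = sum_k w_k (1 - Dhat_k)`` over min-max-rescaled model RDMs, repaired to
a valid correlation matrix; each unit's condition profile is an independent
MVN(0, S) draw, with independent per-session noise of sd sigma, so the
expected cross-session pattern correlation between conditions i != j is
``S_ij / (1 + sigma^2)``.  Behavioral arrangements, gaze trajectories, and
word annotations are simulated with matching structure so every downstream
stage is exercised end-to-end.

All randomness flows from one root seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from ._rng import substream
from .arrangements import ArrangementRecord, SubsetDesign, mds_embed
from .errors import GenerationError, InvalidArgumentError
from .gaze import GazeTrajectory
from .neural import ResponsePatterns, zscore_profiles
from .rdm import RDM
from .semantics import AnnotationTable
from .fitting import spearman_fit

__all__ = [
    "StimulusSet",
    "GroundTruth",
    "make_stimulus_set",
    "simulate_model_rdms",
    "blend_similarity",
    "simulate_subject_patterns",
    "simulate_arrangement_session",
    "simulate_gaze_session",
    "simulate_annotations",
]

SCREEN_W, SCREEN_H = 1280, 1024
GAZE_HZ = 1000
GAZE_DURATION_MS = 2500


@dataclass(frozen=True)
class StimulusSet:
    """Ordered stimulus labels with category structure and sociality flags."""

    stimulus_ids: tuple[str, ...]
    category: tuple[str, ...]
    sociality_flag: tuple[bool, ...]

    def __post_init__(self):
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise InvalidArgumentError("stimulus ids must be unique")
        if not (len(self.stimulus_ids) == len(self.category) == len(self.sociality_flag)):
            raise InvalidArgumentError("stimulus fields must share one length")

    @property
    def n(self) -> int:
        return len(self.stimulus_ids)

    @property
    def categories(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.category)
        return tuple(seen)


def make_stimulus_set(n_categories: int = 18, n_exemplars: int = 5) -> StimulusSet:
    """Deterministic stimulus set: ``n_categories x n_exemplars`` labeled
    stimuli, categories alternating social/nonsocial."""
    if n_categories < 1 or n_exemplars < 1:
        raise InvalidArgumentError("counts must be >= 1")
    ids, cats, social = [], [], []
    for c in range(n_categories):
        for e in range(n_exemplars):
            ids.append(f"cat{c:02d}_ex{e + 1}")
            cats.append(f"cat{c:02d}")
            social.append(c % 2 == 0)
    return StimulusSet(tuple(ids), tuple(cats), tuple(social))


@dataclass(frozen=True)
class GroundTruth:
    """Planted generative configuration for one synthetic dataset.

    ``mixture_weights`` maps neighborhood label -> nonnegative weights over
    the model RDMs (internally normalized to sum 1; an all-zero vector plants
    pure-noise geometry).  ``noise_sd`` is the session-noise sd relative to
    the unit-variance signal.  The seed fully determines every draw.
    """

    n_subjects: int = 23
    n_categories: int = 18
    n_exemplars: int = 5
    n_units_per_neighborhood: int = 200
    noise_sd: float = 1.0
    model_kinds: tuple[str, ...] = ("category", "random", "random")
    mixture_weights: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {"nbhd00": (1.0, 0.0, 0.0)}
    )
    max_model_spearman: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidArgumentError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        weights = {}
        for k, w in self.mixture_weights.items():
            w = np.asarray(w, dtype=float)
            if len(w) != len(self.model_kinds):
                raise InvalidArgumentError(
                    f"neighborhood {k!r}: {len(w)} weights for "
                    f"{len(self.model_kinds)} models"
                )
            if np.any(w < 0):
                raise InvalidArgumentError("mixture weights must be nonnegative")
            weights[str(k)] = tuple(float(x) for x in w)
        object.__setattr__(self, "mixture_weights", weights)

    @property
    def n_conditions(self) -> int:
        return self.n_categories * self.n_exemplars

    def stimuli(self) -> StimulusSet:
        return make_stimulus_set(self.n_categories, self.n_exemplars)


# ---------------------------------------------------------------------------
# model RDMs


def _category_rdm(stimuli: StimulusSet, rng: np.random.Generator) -> np.ndarray:
    """Within-category distances stochastically smaller than between."""
    n = stimuli.n
    same = np.equal.outer(stimuli.category, stimuli.category)
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    within = same[iu]
    vals = np.empty(len(within))
    vals[within] = np.abs(rng.normal(0.3, 0.08, size=int(within.sum())))
    vals[~within] = np.abs(rng.normal(1.0, 0.15, size=int((~within).sum())))
    d[iu] = vals
    return d + d.T


def _sociality_rdm(stimuli: StimulusSet, rng: np.random.Generator) -> np.ndarray:
    """Two-block structure by social/nonsocial flag."""
    n = stimuli.n
    same = np.equal.outer(stimuli.sociality_flag, stimuli.sociality_flag)
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    within = same[iu]
    vals = np.empty(len(within))
    vals[within] = np.abs(rng.normal(0.5, 0.15, size=int(within.sum())))
    vals[~within] = np.abs(rng.normal(1.0, 0.15, size=int((~within).sum())))
    d[iu] = vals
    return d + d.T


def _random_rdm(stimuli: StimulusSet, rng: np.random.Generator, dim: int = 5) -> np.ndarray:
    """Unstructured geometry: Euclidean distances of random Gaussian points."""
    pts = rng.normal(size=(stimuli.n, dim))
    diff = pts[:, None, :] - pts[None, :, :]
    return np.linalg.norm(diff, axis=-1)


_MODEL_BUILDERS = {
    "category": _category_rdm,
    "sociality": _sociality_rdm,
    "random": _random_rdm,
}


def simulate_model_rdms(
    stimuli: StimulusSet,
    config: GroundTruth,
    max_retries: int = 50,
) -> list[RDM]:
    """Planted candidate model RDMs, pairwise distinguishable.

    Each requested kind (``category``, ``sociality``, ``random``) is drawn
    and accepted only if its Spearman correlation with every already-accepted
    model is at most ``config.max_model_spearman``; an unsatisfiable request
    (e.g. two copies of the same block structure) exhausts the retry budget
    and raises :class:`GenerationError`.
    """
    if stimuli.n != config.n_conditions:
        raise InvalidArgumentError(
            f"stimulus set has {stimuli.n} stimuli; config expects "
            f"{config.n_conditions}"
        )
    rng = substream(config.seed, "model_rdms")
    accepted: list[RDM] = []
    for k, kind in enumerate(config.model_kinds):
        builder = _MODEL_BUILDERS.get(kind)
        if builder is None:
            raise InvalidArgumentError(
                f"unknown model kind {kind!r}; expected one of {sorted(_MODEL_BUILDERS)}"
            )
        for attempt in range(max_retries):
            cand = RDM(
                builder(stimuli, rng),
                stimuli.stimulus_ids,
                {"source": "planted_model", "kind": kind,
                 "name": f"model{k:02d}_{kind}"},
            )
            if all(
                abs(spearman_fit(cand, prev)) <= config.max_model_spearman
                for prev in accepted
            ):
                accepted.append(cand)
                break
        else:
            raise GenerationError(
                f"model {k} (kind {kind!r}) cannot be made distinguishable "
                f"(Spearman <= {config.max_model_spearman}) within "
                f"{max_retries} retries"
            )
    return accepted


# ---------------------------------------------------------------------------
# response patterns


def _rescale_offdiag(d: np.ndarray) -> np.ndarray:
    """Min-max rescale off-diagonal dissimilarities to [0, 1]."""
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    lo, hi = d[off].min(), d[off].max()
    out = np.zeros_like(d)
    if hi > lo:
        out[off] = (d[off] - lo) / (hi - lo)
    return out


def blend_similarity(model_rdms: Sequence[RDM], weights: Sequence[float]) -> np.ndarray:
    """Target condition-similarity matrix from weighted model RDMs.

    ``S = sum_k w_k (1 - Dhat_k)`` with each model min-max rescaled to [0, 1]
    off-diagonal, then projected to the nearest valid correlation matrix
    (negative eigenvalues clipped, unit diagonal restored).  All-zero weights
    plant the identity (pure noise geometry).
    """
    w = np.asarray(weights, dtype=float)
    if len(w) != len(model_rdms):
        raise InvalidArgumentError("one weight per model RDM required")
    if np.any(w < 0):
        raise InvalidArgumentError("weights must be nonnegative")
    n = model_rdms[0].n
    if w.sum() == 0:
        return np.eye(n)
    s = np.zeros((n, n))
    for wk, m in zip(w, model_rdms):
        s += wk * (1.0 - _rescale_offdiag(m.matrix))
    # PSD repair: clip negative eigenvalues, restore unit diagonal
    s = (s + s.T) / 2.0
    lam, v = np.linalg.eigh(s)
    s = (v * np.clip(lam, 0.0, None)) @ v.T
    d = np.diag(s).copy()
    if np.any(d <= 1e-12):
        raise GenerationError("similarity target not repairable to a correlation matrix")
    s = s / np.sqrt(np.outer(d, d))
    np.fill_diagonal(s, 1.0)
    return s


def simulate_subject_patterns(
    truth: GroundTruth,
    neighborhood: str,
    model_rdms: Sequence[RDM] | None = None,
    n_units: int | None = None,
    zscore: bool = True,
) -> list[tuple[ResponsePatterns, ResponsePatterns]]:
    """Two-session response patterns for every subject in one neighborhood.

    Each unit's 90-long condition profile is an independent MVN(0, S) draw
    (S from :func:`blend_similarity` on the neighborhood's planted weights);
    independent N(0, sigma^2) noise is added per session, and profiles are
    z-scored per unit across conditions.
    """
    if neighborhood not in truth.mixture_weights:
        raise InvalidArgumentError(
            f"no mixture weights defined for neighborhood {neighborhood!r}"
        )
    stimuli = truth.stimuli()
    if model_rdms is None:
        model_rdms = simulate_model_rdms(stimuli, truth)
    s = blend_similarity(model_rdms, truth.mixture_weights[neighborhood])
    lam, v = np.linalg.eigh((s + s.T) / 2.0)
    factor = v * np.sqrt(np.clip(lam, 0.0, None))  # factor @ factor.T == S
    n_units = n_units or truth.n_units_per_neighborhood
    rng = substream(truth.seed, f"patterns/{neighborhood}")
    sigma = truth.noise_sd
    out = []
    for subj in range(truth.n_subjects):
        signal = rng.standard_normal((n_units, stimuli.n)) @ factor.T
        sessions = []
        for sess in (1, 2):
            noisy = signal + sigma * rng.standard_normal(signal.shape)
            pat = ResponsePatterns(
                f"sub{subj:02d}",
                f"ses{sess}",
                noisy.T,  # conditions x units
                stimuli.stimulus_ids,
                {"neighborhood": neighborhood, "synthetic": True},
            )
            sessions.append(zscore_profiles(pat) if zscore else pat)
        out.append(tuple(sessions))
    return out


# ---------------------------------------------------------------------------
# behavior


def simulate_arrangement_session(
    rdm: RDM,
    subsets: SubsetDesign,
    jitter_sd: float = 0.0,
    seed: int = 0,
    participant_id: str = "p00",
    task_label: str = "sociality",
) -> list[ArrangementRecord]:
    """Simulated multiple-arrangement session for one planted RDM.

    Record 0 arranges the full stimulus set; each subset record embeds its
    sub-RDM with classical 2-D metric MDS and adds isotropic Gaussian jitter
    of sd ``jitter_sd`` (screen pixels) in the embedded coordinates.
    """
    if jitter_sd < 0:
        raise InvalidArgumentError("jitter_sd must be >= 0")
    known = set(rdm.labels)
    for i, sub in enumerate(subsets.subsets):
        unknown = set(sub) - known
        if unknown:
            raise InvalidArgumentError(
                f"subset {i} references unknown stimulus {sorted(unknown)[0]!r}"
            )
    rng = substream(seed, f"arrangement/{participant_id}/{task_label}")
    center = np.array([SCREEN_W / 2, SCREEN_H / 2])
    records = []
    sets: list[tuple[int, tuple[str, ...]]] = [(0, rdm.labels)]
    sets += [(i + 1, sub) for i, sub in enumerate(subsets.subsets)]
    for set_index, ids in sets:
        sub = rdm.submatrix(ids) if set_index else rdm
        coords = mds_embed(sub, 2)
        coords = coords + rng.normal(0.0, jitter_sd, size=coords.shape) + center
        records.append(
            ArrangementRecord(participant_id, task_label, set_index, ids, coords)
        )
    return records


def _stimulus_attractors(
    stimulus_id: str, attractor_seed: int, k: int = 4
) -> np.ndarray:
    """Stimulus-specific gaze attractor points, shared across blocks and
    participants (keyed by the stimulus id, not the participant seed)."""
    rng = substream(attractor_seed, f"gaze_attractors/{stimulus_id}")
    pts = rng.uniform([0.2 * SCREEN_W, 0.2 * SCREEN_H],
                      [0.8 * SCREEN_W, 0.8 * SCREEN_H], size=(k, 2))
    return pts


def simulate_gaze_session(
    stimuli: StimulusSet,
    n_blocks: int = 4,
    blink_rate: float = 0.0,
    seed: int = 0,
    participant_id: str = "p00",
    attractor_seed: int | None = None,
    walk_sd: float = 2.0,
    pull: float = 0.01,
) -> list[GazeTrajectory]:
    """Simulated eye-tracking session: ``n_blocks`` x one trial per stimulus.

    Each trial is a 2500-sample (1000 Hz x 2.5 s) random walk pulled toward
    stimulus-specific attractor points, so trajectories for the same stimulus
    correlate across blocks more than across stimuli.  With probability
    ``blink_rate`` a trial contains one blink span flagged invalid.
    """
    if n_blocks < 1:
        raise InvalidArgumentError("n_blocks must be >= 1")
    if not 0.0 <= blink_rate <= 1.0:
        raise InvalidArgumentError("blink_rate must be in [0, 1]")
    if attractor_seed is None:
        attractor_seed = seed
    rng = substream(seed, f"gaze/{participant_id}")
    t_ms = np.arange(GAZE_DURATION_MS, dtype=float)
    n = len(t_ms)
    out = []
    for block in range(n_blocks):
        for stim in stimuli.stimulus_ids:
            attractors = _stimulus_attractors(stim, attractor_seed)
            k = len(attractors)
            # attractor schedule: equal spans over the trial
            target = attractors[np.minimum((np.arange(n) * k) // n, k - 1)]
            steps = rng.normal(0.0, walk_sd, size=(n, 2))
            # AR(1) recursion pos[i] = (1-pull) pos[i-1] + pull target[i] + steps[i]
            u = pull * target + steps
            u[0] = [SCREEN_W / 2, SCREEN_H / 2]
            pos = lfilter([1.0], [1.0, -(1.0 - pull)], u, axis=0)
            valid = np.ones(n, dtype=bool)
            if blink_rate > 0 and rng.random() < blink_rate:
                span = int(rng.integers(50, 300))
                start = int(rng.integers(0, n - span))
                valid[start:start + span] = False
            out.append(
                GazeTrajectory(
                    participant_id, block, stim, t_ms, pos[:, 0], pos[:, 1],
                    valid, {"synthetic": True},
                )
            )
    return out


def simulate_annotations(
    stimuli: StimulusSet,
    dim: int = 300,
    seed: int = 0,
    annotator_noise_sd: float = 0.1,
    within_category_sd: float = 0.3,
) -> tuple[AnnotationTable, AnnotationTable]:
    """Two synthetic annotators' word-embedding tables.

    Per stimulus, 2-5 verb and 3-6 nonverb vectors are drawn around
    category-level class means; annotator 2's vectors are noisy copies of
    annotator 1's (exact copies at ``annotator_noise_sd=0``).
    """
    if dim < 2:
        raise InvalidArgumentError("dim must be >= 2")
    if annotator_noise_sd < 0:
        raise InvalidArgumentError("annotator_noise_sd must be >= 0")
    rng = substream(seed, "annotations")
    class_means = {
        (cat, cls): rng.normal(size=dim) / np.sqrt(dim)
        for cat in stimuli.categories
        for cls in ("verb", "nonverb")
    }
    a_entries: dict[str, list] = {}
    b_entries: dict[str, list] = {}
    for stim, cat in zip(stimuli.stimulus_ids, stimuli.category):
        rows_a, rows_b = [], []
        n_verbs = int(rng.integers(2, 6))      # 2-5 verbs per stimulus
        n_nonverbs = int(rng.integers(3, 7))   # 3-6 nonverbs per stimulus
        for cls, count in (("verb", n_verbs), ("nonverb", n_nonverbs)):
            mean = class_means[(cat, cls)]
            for w in range(count):
                vec = mean + rng.normal(0.0, within_category_sd, size=dim) / np.sqrt(dim)
                word = f"{stim}_{cls[0]}{w}"
                rows_a.append((word, cls, vec))
                noisy = vec + rng.normal(0.0, annotator_noise_sd, size=dim) / np.sqrt(dim)
                rows_b.append((word, cls, noisy))
        a_entries[stim] = tuple(rows_a)
        b_entries[stim] = tuple(rows_b)
    return (
        AnnotationTable(a_entries, {"annotator": "A", "synthetic": True}),
        AnnotationTable(b_entries, {"annotator": "B", "synthetic": True}),
    )
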