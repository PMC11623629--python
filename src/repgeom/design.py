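"""Serially counterbalanced, efficiency-optimized event-related designs.

The experiment treats each of 90 video clips as a condition, grouped into 18
categories x 5 exemplars.  Trial order is a serially balanced sequence over
20 trial types (18 categories + null fixation + semantic probe): a cyclic
sequence of n^2 = 400 trials in which every ordered pair of types, including
self-pairs, occurs exactly once among the cyclic adjacencies — an Eulerian
circuit of the complete directed graph with self-loops.  Probe trials that
would follow a fixation or another probe are replaced by fixation trials.
Sessions split into runs; each run is prepended with the previous run's last
three trials (drawn from a separate preparatory exemplar pool) to reinstate
temporal context.  Interstimulus intervals are jittered from a floored,
truncated exponential, sum-constrained so every run has the same duration,
and the most estimation-efficient of many candidate onset schedules is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._rng import substream
from .errors import (
    GenerationError,
    InvalidArgumentError,
    NumericalError,
)

__all__ = [
    "FIXATION",
    "PROBE",
    "Trial",
    "TrialSequence",
    "DesignMatrixSpec",
    "OnsetResult",
    "default_trial_types",
    "generate_type1_sequence",
    "repair_probe_constraints",
    "build_session",
    "build_experiment",
    "generate_onsets",
    "canonical_hrf",
    "build_design_matrix",
    "design_efficiency",
    "run_duration",
]

FIXATION = "fixation"
PROBE = "probe"

STIM_DURATION_S = 2.5
LEAD_FIX_S = 5.0
TRAIL_FIX_S = 15.0
N_PREPENDED = 3


def default_trial_types(n_categories: int = 18) -> tuple[str, ...]:
    """Category labels plus the fixation and probe trial types."""
    if n_categories < 1:
        raise InvalidArgumentError("n_categories must be >= 1")
    return tuple(f"cat{i:02d}" for i in range(n_categories)) + (FIXATION, PROBE)


# ---------------------------------------------------------------------------
# serially balanced sequences


def _random_eulerian_circuit(n: int, rng: np.random.Generator) -> list[int]:
    """Random Eulerian circuit on the complete digraph with self-loops
    (Hierholzer with shuffled adjacency); returns the n^2 visited vertices."""
    adj = [list(rng.permutation(n)) for _ in range(n)]
    stack = [int(rng.integers(n))]
    circuit: list[int] = []
    while stack:
        v = stack[-1]
        if adj[v]:
            stack.append(int(adj[v].pop()))
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    return circuit[:-1]  # closing vertex repeats the first


def _balanced_circuit_attempt(
    n: int, n_runs: int, rng: np.random.Generator, max_steps: int
) -> list[int] | None:
    """One randomized DFS attempt at an Eulerian circuit whose runs
    (consecutive n^2/n_runs trials) each contain every type n/n_runs times."""
    L = n * n
    run_len = L // n_runs
    cap = n // n_runs
    rem = [set(range(n)) for _ in range(n)]
    seq = [0]
    counts = np.zeros((n_runs, n), dtype=np.int64)
    counts[0, 0] = 1

    def candidates(p: int) -> list[int]:
        if p == L:
            return []
        r = p // run_len
        cands = [u for u in rem[seq[-1]] if counts[r, u] < cap]
        rng.shuffle(cands)
        return cands

    stack = [candidates(1)]
    steps = 0
    while stack:
        steps += 1
        if steps > max_steps:
            return None
        if len(seq) == L and seq[0] in rem[seq[-1]]:
            return seq
        cands = stack[-1]
        if not cands:
            stack.pop()
            if len(seq) > 1:
                u = seq.pop()
                counts[len(seq) // run_len, u] -= 1
                rem[seq[-1]].add(u)
            continue
        u = cands.pop()
        rem[seq[-1]].discard(u)
        seq.append(u)
        counts[(len(seq) - 1) // run_len, u] += 1
        stack.append(candidates(len(seq)))
    return None


def generate_type1_sequence(
    n_types: int,
    seed: int = 0,
    labels: Sequence[str] | None = None,
    balance_runs: int | None = None,
    max_attempts: int = 200,
    max_steps: int = 200_000,
) -> list[str]:
    """Serially balanced trial-type sequence of length ``n_types**2``.

    Every ordered pair of trial types (self-pairs included) occurs exactly
    once among the n^2 cyclic adjacencies.  With ``balance_runs=k`` the
    sequence additionally contains each type exactly ``n_types/k`` times in
    every consecutive block of ``n_types**2/k`` trials, so exemplars can be
    assigned once-per-run; this variant uses a randomized backtracking search
    with restarts and raises :class:`GenerationError` if the budget is
    exhausted (not observed in practice for the 20-type, 4-run design).
    """
    if n_types < 2:
        raise InvalidArgumentError("n_types must be >= 2")
    if labels is None:
        labels = [f"type{i:02d}" for i in range(n_types)]
    labels = [str(x) for x in labels]
    if len(labels) != n_types or len(set(labels)) != n_types:
        raise InvalidArgumentError(f"need {n_types} distinct labels")
    rng = substream(seed, "type1_sequence")
    if balance_runs is None:
        idx = _random_eulerian_circuit(n_types, rng)
        return [labels[i] for i in idx]
    if balance_runs < 1 or n_types % balance_runs != 0:
        raise InvalidArgumentError(
            f"balance_runs must divide n_types ({n_types})"
        )
    for _ in range(max_attempts):
        idx = _balanced_circuit_attempt(n_types, balance_runs, rng, max_steps)
        if idx is not None:
            return [labels[i] for i in idx]
    raise GenerationError(
        f"no run-balanced serially balanced sequence found for n={n_types}, "
        f"runs={balance_runs} within {max_attempts} attempts"
    )


def repair_probe_constraints(
    seq: Sequence[str], probe: str = PROBE, fixation: str = FIXATION
) -> list[str]:
    """Replace probe trials that follow a fixation or probe trial by fixation.

    A probe needs a preceding stimulus to probe; the serially balanced
    sequence necessarily contains one fixation->probe and one probe->probe
    adjacency, and those trailing probes become fixation trials.  All other
    trials are untouched; the pass is idempotent.
    """
    out = list(seq)
    for i in range(1, len(out)):
        if out[i] == probe and out[i - 1] in (probe, fixation):
            out[i] = fixation
    return out


# ---------------------------------------------------------------------------
# trials, sessions, timing


@dataclass(frozen=True)
class Trial:
    trial_type: str
    exemplar_id: str | None
    onset_s: float
    stim_duration_s: float
    isi_s: float
    prepended: bool = False


@dataclass(frozen=True)
class TrialSequence:
    """One run's ordered trials with onsets and timing."""

    trials: tuple[Trial, ...]
    session_id: int
    run_id: int
    n_types: int

    def __post_init__(self):
        onsets = [t.onset_s for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InvalidArgumentError("trial onsets must be strictly increasing")
        if any(t.isi_s < 0 for t in self.trials):
            raise InvalidArgumentError("ISIs must be nonnegative")
        object.__setattr__(self, "trials", tuple(self.trials))

    @property
    def main_trials(self) -> tuple[Trial, ...]:
        return tuple(t for t in self.trials if not t.prepended)


def run_duration(
    run: TrialSequence,
    lead_fix_s: float = LEAD_FIX_S,
    trail_fix_s: float = TRAIL_FIX_S,
) -> float:
    """Total run duration: lead fixation + all trial (stim + ISI) time +
    trailing fixation."""
    event_time = sum(t.stim_duration_s + t.isi_s for t in run.trials)
    return lead_fix_s + event_time + trail_fix_s


@dataclass(frozen=True)
class DesignMatrixSpec:
    """Recipe for an HRF-convolved indicator design matrix.

    ``trial_types`` gives the type of each trial in presentation order;
    ``modeled_types`` the types receiving a regressor column (fixation is the
    implicit baseline by default).  ``contrasts`` rows are taken over the
    modeled-type columns (identity by default).  Sampling grid is the
    acquisition TR.
    """

    trial_types: tuple[str, ...]
    modeled_types: tuple[str, ...] = ()
    contrasts: np.ndarray | None = None
    tr_s: float = 1.0
    stim_duration_s: float = STIM_DURATION_S
    hrf_length_s: float = 32.0

    def __post_init__(self):
        tt = tuple(str(x) for x in self.trial_types)
        object.__setattr__(self, "trial_types", tt)
        modeled = tuple(self.modeled_types) or tuple(
            sorted({t for t in tt if t != FIXATION})
        )
        object.__setattr__(self, "modeled_types", modeled)

    @property
    def n_columns(self) -> int:
        return len(self.modeled_types)


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peaks ~6 s and ~16 s,
    undershoot ratio 1:6), unit peak."""
    t = np.asarray(t, dtype=float)
    h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
    peak = h.max()
    return h / peak if peak > 0 else h


def build_design_matrix(
    spec: DesignMatrixSpec,
    onsets_s: np.ndarray,
    total_duration_s: float | None = None,
) -> np.ndarray:
    """HRF-convolved boxcar design matrix sampled on the TR grid.

    Boxcars are laid down with fractional coverage of each TR bin, convolved
    with the canonical HRF; an intercept column is NOT included (the
    efficiency computation adds contrasts over these columns only).
    """
    onsets = np.asarray(onsets_s, dtype=float)
    if len(onsets) != len(spec.trial_types):
        raise InvalidArgumentError(
            f"{len(onsets)} onsets for {len(spec.trial_types)} trials"
        )
    tr = spec.tr_s
    if total_duration_s is None:
        total_duration_s = float(onsets.max() + spec.stim_duration_s + spec.hrf_length_s)
    n_frames = int(np.ceil(total_duration_s / tr))
    col = {t: k for k, t in enumerate(spec.modeled_types)}
    u = np.zeros((n_frames, spec.n_columns))
    for onset, ttype in zip(onsets, spec.trial_types):
        k = col.get(ttype)
        if k is None:
            continue
        a, b = onset / tr, (onset + spec.stim_duration_s) / tr
        i0, i1 = int(np.floor(a)), min(int(np.ceil(b)), n_frames)
        for i in range(i0, i1):
            u[i, k] += max(0.0, min(b, i + 1) - max(a, i))
    hrf = canonical_hrf(np.arange(0, spec.hrf_length_s, tr))
    x = np.empty_like(u)
    for k in range(u.shape[1]):
        x[:, k] = np.convolve(u[:, k], hrf)[:n_frames]
    return x


def design_efficiency(x: np.ndarray, contrasts: np.ndarray | None = None) -> float:
    """Estimation efficiency ``1 / trace(C (X'X)^-1 C')``.

    Larger is better; invariant to the row order of ``contrasts`` (identity
    over columns by default).  Raises :class:`NumericalError` for a
    rank-deficient design matrix.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise InvalidArgumentError("design matrix must be 2-D")
    c = np.eye(x.shape[1]) if contrasts is None else np.atleast_2d(np.asarray(contrasts, float))
    if c.shape[1] != x.shape[1]:
        raise InvalidArgumentError(
            f"contrast has {c.shape[1]} columns for a {x.shape[1]}-column design"
        )
    g = x.T @ x
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise NumericalError(
            f"design matrix is rank deficient (rank "
            f"{np.linalg.matrix_rank(x)} < {x.shape[1]} columns)"
        )
    y = np.linalg.solve(g, c.T)
    return float(1.0 / np.trace(c @ y))


@dataclass(frozen=True)
class OnsetResult:
    onsets_s: np.ndarray
    isis_s: np.ndarray
    chosen_index: int
    efficiencies: np.ndarray
    start_offset_s: float = 0.0


def _draw_isis(
    n: int, mean_isi_s: float, min_isi_s: float, total_null_s: float,
    rng: np.random.Generator, trunc_mult: float = 4.0,
) -> np.ndarray:
    """Floored, truncated-exponential ISIs rescaled to sum to total_null_s."""
    budget = total_null_s - n * min_isi_s
    if budget == 0:
        return np.full(n, min_isi_s)
    scale = max(mean_isi_s - min_isi_s, 1e-12)
    upper = trunc_mult  # in units of scale
    extras = stats.truncexpon.rvs(upper, scale=scale, size=n, random_state=rng)
    extras *= budget / extras.sum()
    return min_isi_s + extras


def generate_onsets(
    n_trials: int,
    mean_isi_s: float = 2.5,
    min_isi_s: float = 2.0,
    total_null_s: float | None = None,
    n_candidates: int = 1000,
    spec: DesignMatrixSpec | None = None,
    seed: int = 0,
    stim_duration_s: float = STIM_DURATION_S,
    start_offset_s: float = 0.0,
) -> OnsetResult:
    """Jittered onset schedule chosen for design efficiency.

    Each candidate draws ISIs as ``min_isi_s`` plus truncated-exponential
    jitter, rescaled so the ISIs sum exactly to ``total_null_s`` (fixing run
    duration; default ``n_trials * mean_isi_s``).  Among ``n_candidates``
    candidates the one maximizing :func:`design_efficiency` on ``spec`` is
    returned (the single candidate when ``spec`` is None or
    ``n_candidates == 1``).
    """
    if n_trials < 1:
        raise InvalidArgumentError("n_trials must be >= 1")
    if n_candidates < 1:
        raise InvalidArgumentError("n_candidates must be >= 1")
    if mean_isi_s < min_isi_s:
        raise InvalidArgumentError("mean_isi_s must be >= min_isi_s")
    if total_null_s is None:
        total_null_s = n_trials * mean_isi_s
    if total_null_s < n_trials * min_isi_s - 1e-9:
        raise InvalidArgumentError(
            f"total_null_s={total_null_s} cannot accommodate "
            f"{n_trials} ISIs of at least {min_isi_s}s"
        )
    rng = substream(seed, "onsets")
    best: tuple[float, int, np.ndarray] | None = None
    efficiencies = np.full(n_candidates, np.nan)
    for k in range(n_candidates):
        isis = _draw_isis(n_trials, mean_isi_s, min_isi_s, total_null_s, rng)
        if spec is None:
            eff = 0.0
        else:
            onsets = start_offset_s + np.concatenate(
                [[0.0], np.cumsum(stim_duration_s + isis[:-1])]
            )
            eff = design_efficiency(
                build_design_matrix(spec, onsets), spec.contrasts
            )
        efficiencies[k] = eff
        if best is None or eff > best[0]:
            best = (eff, k, isis)
    _, chosen, isis = best
    onsets = start_offset_s + np.concatenate(
        [[0.0], np.cumsum(stim_duration_s + isis[:-1])]
    )
    return OnsetResult(onsets, isis, chosen, efficiencies, start_offset_s)


def _assign_exemplars(
    run_types: Sequence[str],
    n_exemplars: int,
    rng: np.random.Generator,
) -> list[str | None]:
    """Per run, sample category exemplars without replacement so each
    exemplar occurs at most once (exactly once when counts equal the pool)."""
    counts: dict[str, int] = {}
    for t in run_types:
        if t not in (FIXATION, PROBE):
            counts[t] = counts.get(t, 0) + 1
    draws: dict[str, list[int]] = {}
    for cat, c in counts.items():
        if c > n_exemplars:
            raise InvalidArgumentError(
                f"exemplar pool exhausted: category {cat!r} occurs {c} times "
                f"in one run but has only {n_exemplars} exemplars"
            )
        draws[cat] = list(rng.choice(n_exemplars, size=c, replace=False))
    out: list[str | None] = []
    for t in run_types:
        if t in (FIXATION, PROBE):
            out.append(None)
        else:
            out.append(f"{t}_ex{draws[t].pop() + 1}")
    return out


def build_session(
    seq: Sequence[str],
    n_exemplars: int = 5,
    n_runs: int = 4,
    seed: int = 0,
    session_id: int = 0,
    mean_isi_s: float = 2.5,
    min_isi_s: float = 2.0,
    onset_candidates: int = 100,
    prepended_isi_s: float = 2.5,
) -> list[TrialSequence]:
    """Split a repaired trial-type sequence into runs with exemplars and timing.

    Each run carries ``len(seq)/n_runs`` main trials; category occurrences
    are filled by sampling that category's exemplars without replacement
    within the run.  The previous run's last three trials (the final run's
    for run 0) are prepended using a separate per-category preparatory
    exemplar pool, so no exemplar repeats within a run.  Onsets are jittered
    and efficiency-selected per run.
    """
    seq = [str(t) for t in seq]
    if n_runs < 1 or len(seq) % n_runs != 0:
        raise InvalidArgumentError(
            f"sequence length {len(seq)} not divisible by n_runs={n_runs}"
        )
    if n_exemplars < 1:
        raise InvalidArgumentError("n_exemplars must be >= 1")
    rng = substream(seed, f"session{session_id}/exemplars")
    per_run = len(seq) // n_runs
    run_types = [seq[r * per_run:(r + 1) * per_run] for r in range(n_runs)]
    run_exemplars = [_assign_exemplars(rt, n_exemplars, rng) for rt in run_types]
    n_types = len(set(seq))
    runs: list[TrialSequence] = []
    for r in range(n_runs):
        prev = (r - 1) % n_runs
        prep_types = run_types[prev][-N_PREPENDED:]
        prep_exemplars = [
            None if t in (FIXATION, PROBE) else f"{t}_prep" for t in prep_types
        ]
        spec = DesignMatrixSpec(trial_types=tuple(run_types[r]))
        onset_res = generate_onsets(
            per_run,
            mean_isi_s=mean_isi_s,
            min_isi_s=min_isi_s,
            n_candidates=onset_candidates,
            spec=spec,
            seed=seed * 1009 + session_id * 31 + r,
        )
        trials: list[Trial] = []
        t0 = LEAD_FIX_S
        for t, ex in zip(prep_types, prep_exemplars):
            trials.append(
                Trial(t, ex, t0, STIM_DURATION_S, prepended_isi_s, prepended=True)
            )
            t0 += STIM_DURATION_S + prepended_isi_s
        for ttype, ex, isi in zip(run_types[r], run_exemplars[r], onset_res.isis_s):
            trials.append(Trial(ttype, ex, t0, STIM_DURATION_S, float(isi)))
            t0 += STIM_DURATION_S + float(isi)
        runs.append(TrialSequence(tuple(trials), session_id, r, n_types))
    return runs


def build_experiment(
    n_categories: int = 18,
    n_exemplars: int = 5,
    n_runs: int = 4,
    n_sessions: int = 2,
    seed: int = 0,
    onset_candidates: int = 100,
) -> list[list[TrialSequence]]:
    """Full multi-session design: one serially balanced, run-balanced, probe-
    repaired sequence per session, split into runs with exemplars and timing."""
    labels = default_trial_types(n_categories)
    sessions = []
    for s in range(n_sessions):
        seq = generate_type1_sequence(
            len(labels), seed=seed * 37 + s, labels=labels, balance_runs=n_runs
        )
        seq = repair_probe_constraints(seq)
        sessions.append(
            build_session(
                seq, n_exemplars, n_runs, seed=seed, session_id=s,
                onset_candidates=onset_candidates,
            )
        )
    return sessions
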