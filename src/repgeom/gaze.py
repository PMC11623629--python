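"""Gaze-trajectory preprocessing, gaze RDMs, and reliability screening.

Raw eye-tracking samples (1000 Hz over a 2.5 s clip) are blink-censored and
linearly interpolated, median filtered (84 ms rolling window), and decimated
to one sample per video frame (60 samples at 24 Hz).  The dissimilarity
between two stimuli is the sum over frames of the Euclidean distance between
the two gaze positions.  Participants whose block-wise gaze RDMs do not
replicate (mean inter-block Pearson r < .1) are excluded before averaging
into a single group gaze RDM.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    EmptyCohortError,
    InvalidArgumentError,
    InvalidInputError,
    TrialExcludedError,
)
from .rdm import RDM, average_rdms

__all__ = ["GazeTrajectory", "gaze_preprocess", "gaze_rdm", "gaze_reliability_screen"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GazeTrajectory:
    """One trial's time-stamped 2-D gaze samples with validity flags."""

    participant_id: str
    block_index: int
    stimulus_id: str
    t_ms: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        t = np.asarray(self.t_ms, dtype=float)
        x = np.asarray(self.x_px, dtype=float)
        y = np.asarray(self.y_px, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if not (len(t) == len(x) == len(y) == len(v)):
            raise InvalidInputError("gaze sample arrays must share one length")
        if len(t) == 0:
            raise InvalidInputError("empty gaze trajectory")
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("gaze timestamps must be strictly increasing")
        for arr, name in ((t, "t_ms"), (x, "x_px"), (y, "y_px")):
            a = arr.copy()
            a.flags.writeable = False
            object.__setattr__(self, name, a)
        v = v.copy()
        v.flags.writeable = False
        object.__setattr__(self, "valid", v)

    @property
    def n_samples(self) -> int:
        return len(self.t_ms)


def _interpolate_invalid(t: np.ndarray, s: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Censor invalid spans and linearly interpolate from flanking valid
    samples; edge spans are extended from the nearest valid sample."""
    if valid.all():
        return s
    # np.interp holds edge values constant outside the valid range
    return np.interp(t, t[valid], s[valid])


def _rolling_median(s: np.ndarray, window: int) -> np.ndarray:
    """Centered rolling median with shrinking windows at the boundaries."""
    return (
        pd.Series(s).rolling(window=window, center=True, min_periods=1).median().to_numpy()
    )


def gaze_preprocess(
    traj: GazeTrajectory, window_ms: float = 84.0, out_samples: int = 60
) -> GazeTrajectory:
    """Interpolate blinks, median filter, and decimate to frame rate.

    Raises :class:`TrialExcludedError` when no sample is valid (eyes closed
    for the entire stimulus).
    """
    if out_samples < 1:
        raise InvalidArgumentError("out_samples must be >= 1")
    if window_ms <= 0:
        raise InvalidArgumentError("window_ms must be positive")
    if not traj.valid.any():
        raise TrialExcludedError(
            f"no valid samples for {traj.participant_id}/{traj.stimulus_id} "
            f"block {traj.block_index}"
        )
    t = traj.t_ms
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    window = max(1, int(round(window_ms / dt)))
    x = _rolling_median(_interpolate_invalid(t, traj.x_px, traj.valid), window)
    y = _rolling_median(_interpolate_invalid(t, traj.y_px, traj.valid), window)
    # decimate: nearest sample to each output frame time over the trial span
    n = len(t)
    duration = t[-1] - t[0] + dt
    frame_times = t[0] + np.arange(out_samples) * duration / out_samples
    idx = np.clip(np.round((frame_times - t[0]) / dt).astype(int), 0, n - 1)
    meta = dict(traj.meta)
    meta.update({"preprocessed": True, "window_samples": window})
    return GazeTrajectory(
        traj.participant_id,
        traj.block_index,
        traj.stimulus_id,
        frame_times,
        x[idx],
        y[idx],
        np.ones(out_samples, dtype=bool),
        meta,
    )


def gaze_rdm(trials: dict[str, GazeTrajectory], meta: dict | None = None) -> RDM:
    """Gaze RDM for one block: summed per-frame Euclidean distances.

    ``trials`` maps stimulus id -> preprocessed trajectory; all trajectories
    must share one sample count.
    """
    labels = tuple(trials)
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 stimuli for a gaze RDM")
    lengths = {trials[k].n_samples for k in labels}
    if len(lengths) != 1:
        raise InvalidInputError(f"trajectory length mismatch: {sorted(lengths)}")
    g = np.stack(
        [np.column_stack([trials[k].x_px, trials[k].y_px]) for k in labels]
    )  # (S, F, 2)
    diff = g[:, None, :, :] - g[None, :, :, :]
    d = np.linalg.norm(diff, axis=-1).sum(axis=-1)
    np.fill_diagonal(d, 0.0)
    out_meta = {"source": "gaze"}
    if meta:
        out_meta.update(meta)
    return RDM(d, labels, out_meta)


def gaze_reliability_screen(
    block_rdms: dict[str, list[RDM]], threshold: float = 0.1
) -> tuple[list[str], RDM, dict[str, float]]:
    """Screen participants by inter-block gaze-RDM reliability and average.

    For each participant, reliability is the mean pairwise Pearson
    correlation between vectorized block RDMs; participants below
    ``threshold`` are dropped.  Survivors' RDMs are averaged within
    participant (across blocks), then across participants.

    Returns ``(retained_participants, group_rdm, reliability_by_participant)``.
    """
    reliabilities: dict[str, float] = {}
    retained: list[str] = []
    per_participant: list[RDM] = []
    for pid, rdms in block_rdms.items():
        if len(rdms) < 2:
            raise InvalidArgumentError(
                f"participant {pid!r} has {len(rdms)} block(s); need >= 2"
            )
        vecs = [r.vector() for r in rdms]
        corrs = [
            float(np.corrcoef(a, b)[0, 1])
            for a, b in itertools.combinations(vecs, 2)
        ]
        rel = float(np.mean(corrs))
        reliabilities[pid] = rel
        if rel < threshold:
            logger.info("excluding participant %s: inter-block r=%.3f < %.3f",
                        pid, rel, threshold)
            continue
        retained.append(pid)
        per_participant.append(
            average_rdms(rdms, meta={"participant_id": pid, "source": "gaze"})
        )
    if not retained:
        raise EmptyCohortError(
            f"all {len(block_rdms)} participants below reliability {threshold}"
        )
    group = average_rdms(
        per_participant,
        meta={"source": "gaze", "participants": tuple(retained), "threshold": threshold},
    )
    return retained, group, reliabilities
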