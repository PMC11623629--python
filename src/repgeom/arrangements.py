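"""Multiple-arrangements behavioral similarity: subset design and aggregation.

Participants drag stimuli inside a circular arena so that on-screen distance
encodes perceived dissimilarity.  One full-set arrangement guarantees every
pair is measured at least once; additional sparse 30-stimulus subsets refine
the estimate.  Pairwise Euclidean screen distances from all sets are averaged
per pair into a behavioral RDM, and RDMs are averaged across participants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._rng import substream
from .errors import IncompleteCoverageError, InvalidArgumentError, InvalidInputError
from .rdm import RDM

__all__ = [
    "SubsetDesign",
    "ArrangementRecord",
    "design_subsets",
    "arrangement_distances",
    "aggregate_arrangements",
    "mds_embed",
]

ARRANGEMENT_TASKS = ("sociality", "transitivity", "person", "object", "scene")


@dataclass(frozen=True)
class SubsetDesign:
    """Pseudo-random stimulus subsets for the arrangement task."""

    subsets: tuple[tuple[str, ...], ...]
    n_stimuli: int
    subset_size: int
    n_subsets: int
    unique_pair_count: int
    seed: int

    def __post_init__(self):
        for i, s in enumerate(self.subsets):
            if len(set(s)) != len(s):
                raise InvalidInputError(f"subset {i} contains duplicate stimuli")
            if len(s) != self.subset_size:
                raise InvalidInputError(
                    f"subset {i} has {len(s)} stimuli, expected {self.subset_size}"
                )


@dataclass(frozen=True)
class ArrangementRecord:
    """Final 2-D screen coordinates of one arranged stimulus set.

    Coordinates are native screen pixels (origin top-left, y increasing
    downward); ``set_index`` 0 is the full-set arrangement.
    """

    participant_id: str
    task_label: str
    set_index: int
    stimulus_ids: tuple[str, ...]
    coords: np.ndarray  # (k, 2) pixels

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        ids = tuple(str(s) for s in self.stimulus_ids)
        if c.ndim != 2 or c.shape[1] != 2:
            raise InvalidInputError("coords must be (k, 2)")
        if c.shape[0] != len(ids):
            raise InvalidInputError(
                f"{len(ids)} stimulus ids for {c.shape[0]} coordinate rows"
            )
        if len(set(ids)) != len(ids):
            raise InvalidInputError(
                f"duplicate stimulus id in set {self.set_index} "
                f"of participant {self.participant_id!r}"
            )
        if not np.all(np.isfinite(c)):
            raise InvalidInputError("non-finite coordinates")
        c = c.copy()
        c.flags.writeable = False
        object.__setattr__(self, "coords", c)
        object.__setattr__(self, "stimulus_ids", ids)


def _pair_union(subsets: Sequence[Sequence[str]]) -> set[frozenset]:
    pairs: set[frozenset] = set()
    for s in subsets:
        pairs.update(frozenset(p) for p in itertools.combinations(s, 2))
    return pairs


def design_subsets(
    stimulus_ids: Sequence[str] | int,
    n_subsets: int,
    subset_size: int,
    n_candidates: int = 1000,
    seed: int = 0,
) -> SubsetDesign:
    """Select the candidate subset design covering the most unique pairs.

    Each candidate draws each subset as the head of a fresh random
    permutation of the stimulus list; among ``n_candidates`` candidates the
    one with the largest count of distinct unordered pairs wins, first
    occurrence breaking ties.
    """
    if isinstance(stimulus_ids, int):
        stimulus_ids = [f"stim{i:03d}" for i in range(stimulus_ids)]
    ids = [str(s) for s in stimulus_ids]
    n = len(ids)
    if n < 2 or subset_size < 2 or subset_size > n:
        raise InvalidArgumentError(
            f"invalid sizes: {n} stimuli, subset_size {subset_size}"
        )
    if n_subsets < 1 or n_candidates < 1:
        raise InvalidArgumentError("n_subsets and n_candidates must be >= 1")
    rng = substream(seed, "design_subsets")
    best = None
    best_count = -1
    for _ in range(n_candidates):
        cand = tuple(
            tuple(rng.permutation(ids)[:subset_size]) for _ in range(n_subsets)
        )
        count = len(_pair_union(cand))
        if count > best_count:
            best, best_count = cand, count
    return SubsetDesign(best, n, subset_size, n_subsets, best_count, seed)


def arrangement_distances(
    record: ArrangementRecord,
) -> tuple[tuple[tuple[str, str], ...], np.ndarray]:
    """Pairwise Euclidean screen distances for one arranged set.

    Returns ``(pairs, distances)`` with k(k-1)/2 unordered pairs in
    itertools.combinations order over the record's stimulus order.
    """
    if len(record.stimulus_ids) < 2:
        raise InvalidArgumentError("need at least 2 stimuli to compute distances")
    d = pdist(record.coords, metric="euclidean")
    pairs = tuple(itertools.combinations(record.stimulus_ids, 2))
    return pairs, d


def aggregate_arrangements(
    records: Sequence[ArrangementRecord],
    labels: Sequence[str] | None = None,
    normalize: bool = False,
) -> RDM:
    """Average sparse pairwise distances across arrangement sets into an RDM.

    Every observation of a pair is weighted equally (the plain averaging the
    task prescribes).  ``normalize=True`` divides each record's distances by
    that record's RMS distance before averaging — useful when arrangements
    were made at incommensurate zoom levels — and is off by default.
    Raises :class:`IncompleteCoverageError` if some pair is never observed.
    """
    records = list(records)
    if not records:
        raise InvalidArgumentError("no arrangement records")
    if labels is None:
        labels = sorted(set(itertools.chain.from_iterable(r.stimulus_ids for r in records)))
    labels = [str(x) for x in labels]
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    for rec in records:
        pairs, d = arrangement_distances(rec)
        if normalize:
            rms = float(np.sqrt(np.mean(d**2)))
            if rms > 0:
                d = d / rms
        for (a, b), dist in zip(pairs, d):
            try:
                i, j = pos[a], pos[b]
            except KeyError as e:
                raise InvalidInputError(
                    f"record set {rec.set_index} references unknown stimulus {e.args[0]!r}"
                ) from None
            sums[i, j] += dist
            sums[j, i] += dist
            counts[i, j] += 1
            counts[j, i] += 1
    iu = np.triu_indices(n, k=1)
    missing = counts[iu] == 0
    if np.any(missing):
        k = int(np.flatnonzero(missing)[0])
        a, b = labels[iu[0][k]], labels[iu[1][k]]
        raise IncompleteCoverageError(
            f"pair ({a!r}, {b!r}) never observed in any arrangement set"
        )
    mean = np.zeros((n, n))
    off = counts > 0
    mean[off] = sums[off] / counts[off]
    task = records[0].task_label
    return RDM(
        mean,
        tuple(labels),
        {"source": "arrangement", "task": task, "n_records": len(records),
         "normalized": normalize},
    )


def mds_embed(rdm: RDM, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) metric MDS embedding of an RDM.

    Double-centers the squared dissimilarities and projects onto the top
    ``n_dims`` eigenvectors; negative eigenvalues are clipped to zero.
    Minimizes strain among rank-``n_dims`` configurations.
    """
    n = rdm.n
    if n_dims < 1 or n_dims > n - 1:
        raise InvalidArgumentError(f"n_dims must be in 1..{n - 1}")
    d2 = rdm.matrix**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    w, v = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1][:n_dims]
    lam = np.clip(w[order], 0.0, None)
    return v[:, order] * np.sqrt(lam)
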