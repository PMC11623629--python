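"""Semantic model RDMs from word-embedding annotations.

Each stimulus carries a handful of annotator-assigned labels, split into
verbs and nonverbs (person/object/scene nouns and adjectives), with one
pretrained embedding vector per label.  The per-class mean vector represents
the stimulus, and pairwise cosine distances between mean vectors form the
verb and nonverb RDMs.  Inter-annotator agreement is the per-stimulus
Pearson correlation between the two annotators' mean vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import InvalidArgumentError, InvalidInputError, UndefinedCorrelationError
from .rdm import RDM

__all__ = ["AnnotationTable", "semantic_rdm", "annotator_agreement"]

WORD_CLASSES = ("verb", "nonverb")


@dataclass(frozen=True)
class AnnotationTable:
    """Per-stimulus word annotations with embedding vectors.

    ``entries`` maps stimulus id -> list of ``(word, word_class, vector)``.
    All vectors must share one dimensionality.
    """

    entries: dict[str, tuple[tuple[str, str, np.ndarray], ...]]
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        dims = set()
        clean: dict[str, tuple] = {}
        for stim, rows in self.entries.items():
            out = []
            for word, cls, vec in rows:
                if cls not in WORD_CLASSES:
                    raise InvalidInputError(
                        f"unknown word class {cls!r} for {stim!r} (expected verb/nonverb)"
                    )
                v = np.asarray(vec, dtype=float).ravel()
                if not np.all(np.isfinite(v)):
                    raise InvalidInputError(f"non-finite vector for word {word!r}")
                dims.add(v.shape[0])
                v = v.copy()
                v.flags.writeable = False
                out.append((str(word), cls, v))
            clean[str(stim)] = tuple(out)
        if len(dims) > 1:
            raise InvalidInputError(f"mixed embedding dimensions: {sorted(dims)}")
        object.__setattr__(self, "entries", clean)

    @property
    def stimuli(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def dim(self) -> int:
        for rows in self.entries.values():
            if rows:
                return rows[0][2].shape[0]
        raise InvalidInputError("annotation table has no words")

    def mean_vector(self, stimulus: str, word_class: str | None = None) -> np.ndarray:
        """Mean embedding over the stimulus's words (optionally one class)."""
        rows = self.entries.get(stimulus)
        if rows is None:
            raise InvalidInputError(f"unknown stimulus {stimulus!r}")
        vecs = [v for _, c, v in rows if word_class is None or c == word_class]
        if not vecs:
            raise InvalidInputError(
                f"stimulus {stimulus!r} has no {word_class or 'any'} words"
            )
        return np.mean(vecs, axis=0)


def semantic_rdm(annotations: AnnotationTable, word_class: str) -> RDM:
    """Cosine-distance RDM over per-stimulus mean embeddings of one class."""
    if word_class not in WORD_CLASSES:
        raise InvalidArgumentError(f"word_class must be one of {WORD_CLASSES}")
    labels = annotations.stimuli
    if len(labels) < 2:
        raise InvalidArgumentError("need at least 2 stimuli")
    means = np.asarray([annotations.mean_vector(s, word_class) for s in labels])
    norms = np.linalg.norm(means, axis=1)
    if np.any(norms == 0):
        bad = labels[int(np.argmin(norms))]
        raise InvalidInputError(f"zero-norm mean vector for stimulus {bad!r}")
    d = squareform(pdist(means, metric="cosine"))
    np.fill_diagonal(d, 0.0)
    return RDM(d, labels, {"source": "semantic", "word_class": word_class})


def annotator_agreement(
    a: AnnotationTable, b: AnnotationTable
) -> tuple[dict[str, float], float, float]:
    """Per-stimulus Pearson correlation between two annotators' mean vectors.

    Each annotator's stimulus representation is the mean over all of that
    annotator's labels for the stimulus.  Returns
    ``(per_stimulus, mean, sd)`` with the summary computed across stimuli.
    """
    shared = [s for s in a.stimuli if s in b.entries]
    if not shared:
        raise InvalidInputError("annotators share no stimuli")
    per_stimulus: dict[str, float] = {}
    for stim in shared:
        va = a.mean_vector(stim)
        vb = b.mean_vector(stim)
        if va.std() == 0 or vb.std() == 0:
            raise UndefinedCorrelationError(
                f"constant mean vector for stimulus {stim!r}"
            )
        per_stimulus[stim] = float(np.corrcoef(va, vb)[0, 1])
    vals = np.array(list(per_stimulus.values()))
    return per_stimulus, float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
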