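"""Plain-text readers and writers for every pipeline data type.

All formats are delimited text with headers; numeric fields are written with
17 significant digits so write -> read round-trips are bitwise lossless.
Readers validate schemas eagerly and raise :class:`SchemaError` naming the
offending row/column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .arrangements import ArrangementRecord
from .design import TrialSequence
from .errors import SchemaError
from .gaze import GazeTrajectory
from .neural import ResponsePatterns
from .rdm import RDM
from .semantics import AnnotationTable

__all__ = [
    "write_rdm", "read_rdm",
    "write_patterns", "read_patterns",
    "write_arrangements", "read_arrangements",
    "write_gaze", "read_gaze",
    "write_annotations", "read_annotations",
    "write_timing", "write_json",
]

_FLOAT_FMT = "%.17g"


def _fmt(x: float) -> str:
    return _FLOAT_FMT % x


def write_rdm(rdm: RDM, path: str | Path) -> None:
    """Square matrix with a header row and label column, tab-separated."""
    path = Path(path)
    with path.open("w") as f:
        f.write("\t".join(("label", *rdm.labels)) + "\n")
        for lab, row in zip(rdm.labels, rdm.matrix):
            f.write(lab + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_rdm(path: str | Path, meta: dict | None = None) -> RDM:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    labels = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != labels:
        raise SchemaError(f"{path}: row labels do not match column labels")
    m = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m))[0]
        raise SchemaError(
            f"{path}: non-finite entry at row {labels[bad[0]]!r}, "
            f"column {labels[bad[1]]!r}"
        )
    if np.abs(m - m.T).max(initial=0.0) > 1e-8:
        i, j = np.unravel_index(np.argmax(np.abs(m - m.T)), m.shape)
        raise SchemaError(
            f"{path}: asymmetric beyond tolerance at ({labels[i]!r}, {labels[j]!r})"
        )
    if np.abs(np.diag(m)).max(initial=0.0) > 1e-8:
        k = int(np.argmax(np.abs(np.diag(m))))
        raise SchemaError(f"{path}: nonzero diagonal at {labels[k]!r}")
    return RDM(m, labels, meta or {"source": str(path)})


def write_patterns(patterns: ResponsePatterns, path: str | Path) -> None:
    """Conditions x units table with labeled condition rows."""
    path = Path(path)
    with path.open("w") as f:
        f.write("subject_id\t" + patterns.subject_id + "\n")
        f.write("session_id\t" + patterns.session_id + "\n")
        units = "\t".join(f"unit{j}" for j in range(patterns.n_units))
        f.write("condition\t" + units + "\n")
        for cond, row in zip(patterns.conditions, patterns.matrix):
            f.write(cond + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_patterns(path: str | Path) -> ResponsePatterns:
    path = Path(path)
    with path.open() as f:
        header1 = f.readline().rstrip("\n").split("\t")
        header2 = f.readline().rstrip("\n").split("\t")
    if header1[0] != "subject_id" or header2[0] != "session_id":
        raise SchemaError(f"{path}: missing subject_id/session_id header lines")
    df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0, float_precision="round_trip")
    m = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(m)):
        bad = np.argwhere(~np.isfinite(m))[0]
        raise SchemaError(
            f"{path}: non-finite value at condition {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return ResponsePatterns(
        header1[1], header2[1], m, tuple(str(i) for i in df.index)
    )


def write_arrangements(records: Sequence[ArrangementRecord], path: str | Path) -> None:
    """One row per placed stimulus: participant_id, task, set_index,
    stimulus_id, x_px, y_px."""
    rows = []
    for rec in records:
        for sid, (x, y) in zip(rec.stimulus_ids, rec.coords):
            rows.append((rec.participant_id, rec.task_label, rec.set_index,
                         sid, _fmt(x), _fmt(y)))
    pd.DataFrame(
        rows, columns=["participant_id", "task", "set_index", "stimulus_id",
                       "x_px", "y_px"],
    ).to_csv(path, index=False)


def read_arrangements(path: str | Path) -> list[ArrangementRecord]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"participant_id", "task", "set_index", "stimulus_id", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    records = []
    for (pid, task, set_index), grp in df.groupby(
        ["participant_id", "task", "set_index"], sort=True
    ):
        ids = [str(s) for s in grp["stimulus_id"]]
        if len(set(ids)) != len(ids):
            dup = next(s for s in ids if ids.count(s) > 1)
            raise SchemaError(
                f"{path}: duplicated stimulus {dup!r} in set {set_index} "
                f"of participant {pid!r}"
            )
        records.append(
            ArrangementRecord(
                str(pid), str(task), int(set_index), tuple(ids),
                grp[["x_px", "y_px"]].to_numpy(dtype=float),
            )
        )
    return records


def write_gaze(trajectories: Sequence[GazeTrajectory], path: str | Path) -> None:
    """Long-format samples: participant_id, block, stimulus_id, t_ms, x_px,
    y_px, valid."""
    frames = []
    for tr in trajectories:
        frames.append(pd.DataFrame({
            "participant_id": tr.participant_id,
            "block": tr.block_index,
            "stimulus_id": tr.stimulus_id,
            "t_ms": tr.t_ms,
            "x_px": tr.x_px,
            "y_px": tr.y_px,
            "valid": tr.valid.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_gaze(path: str | Path) -> list[GazeTrajectory]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"participant_id", "block", "stimulus_id", "t_ms", "x_px", "y_px", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for (pid, block, stim), grp in df.groupby(
        ["participant_id", "block", "stimulus_id"], sort=True
    ):
        out.append(GazeTrajectory(
            str(pid), int(block), str(stim),
            grp["t_ms"].to_numpy(dtype=float),
            grp["x_px"].to_numpy(dtype=float),
            grp["y_px"].to_numpy(dtype=float),
            grp["valid"].to_numpy().astype(bool),
        ))
    return out


def write_annotations(table: AnnotationTable, path: str | Path) -> None:
    """TSV: stimulus_id, word, class, then the d embedding columns."""
    d = table.dim
    cols = [f"v{j}" for j in range(d)]
    rows = []
    for stim, entries in table.entries.items():
        for word, cls, vec in entries:
            rows.append((stim, word, cls, *(_fmt(v) for v in vec)))
    pd.DataFrame(rows, columns=["stimulus_id", "word", "class", *cols]).to_csv(
        path, sep="\t", index=False
    )


def read_annotations(path: str | Path) -> AnnotationTable:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in ("stimulus_id", "word", "class"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    vec_cols = [c for c in df.columns if c.startswith("v")]
    if not vec_cols:
        raise SchemaError(f"{path}: no embedding columns (v0..)")
    entries: dict[str, list] = {}
    for _, row in df.iterrows():
        vec = row[vec_cols].to_numpy(dtype=float)
        entries.setdefault(str(row["stimulus_id"]), []).append(
            (str(row["word"]), str(row["class"]), vec)
        )
    return AnnotationTable({k: tuple(v) for k, v in entries.items()},
                           {"source": str(path)})


def write_timing(run: TrialSequence, path: str | Path) -> None:
    """Per-run timing file: onset_s, duration_s, trial_type, exemplar_id
    (tab-separated, run-relative seconds)."""
    rows = [
        (_fmt(t.onset_s), _fmt(t.stim_duration_s), t.trial_type,
         t.exemplar_id or "n/a")
        for t in run.trials
    ]
    pd.DataFrame(
        rows, columns=["onset_s", "duration_s", "trial_type", "exemplar_id"]
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
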