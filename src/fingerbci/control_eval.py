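"""Prosthesis command mapping and decoder evaluation.

The prosthesis has two motors — one driving the thumb, one driving the
fingers. Each decoded movement maps to a fixed pair of motor states:

=========  ===========  ============
class      thumb motor  finger motor
=========  ===========  ============
thumb      On           Off
index      Off          On
fist       On           On
=========  ===========  ============

Commands are emitted as structured records (the hardware drive circuitry
is out of scope). Evaluation artifacts are the 3x3 confusion matrix,
per-class recall in integer percent, and the macro (unweighted) mean
accuracy, with half-away-from-zero rounding throughout.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_streaming import CLASSES

#: Motor states per decoded class (thumb motor, finger motor).
MOTOR_TABLE: dict[str, tuple[str, str]] = {
    "thumb": ("On", "Off"),
    "index": ("Off", "On"),
    "fist": ("On", "On"),
}


@dataclass(frozen=True)
class MotorCommand:
    motor_thumb: str
    motor_finger: str
    source_label: str


def to_motor_command(label: str) -> MotorCommand:
    """Look up the motor-state pair for a decoded movement class."""
    try:
        thumb_state, finger_state = MOTOR_TABLE[label]
    except KeyError:
        raise ValueError(f"unknown movement class {label!r}") from None
    return MotorCommand(motor_thumb=thumb_state, motor_finger=finger_state,
                        source_label=label)


@dataclass
class ConfusionMatrix:
    """3x3 counts; rows are true classes, columns predicted, in ``CLASSES`` order."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASSES

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (3, 3):
            raise ValueError(f"confusion matrix must be 3x3; got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a 3x3 matrix."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences must have equal length")
    index = {cls: i for i, cls in enumerate(CLASSES)}
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts=counts)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def per_class_accuracy(cm: ConfusionMatrix) -> dict[str, int]:
    """Recall per class: diagonal / row sum, as integer percent.

    Rounding is half away from zero (so 20/31 -> 65, 24/31 -> 77).
    """
    row_sums = cm.counts.sum(axis=1)
    if (row_sums == 0).any():
        empty = [cls for cls, s in zip(cm.class_order, row_sums) if s == 0]
        raise ValueError(f"no test examples for class(es) {empty}")
    return {
        cls: _round_half_away(100.0 * cm.counts[i, i] / row_sums[i])
        for i, cls in enumerate(cm.class_order)
    }


def mean_accuracy(cm: ConfusionMatrix) -> int:
    """Macro mean of the three un-rounded per-class recalls, in integer percent.

    Unweighted over classes, so imbalance in per-class test counts does
    not bias the summary.
    """
    row_sums = cm.counts.sum(axis=1)
    if (row_sums == 0).any():
        raise ValueError("every class needs at least one test example")
    recalls = 100.0 * np.diag(cm.counts) / row_sums
    return _round_half_away(float(np.mean(recalls)))


def evaluation_report(cm: ConfusionMatrix) -> dict:
    """JSON-ready summary: confusion counts, per-class %, macro mean %."""
    return {
        "classes": list(cm.class_order),
        "confusion": cm.counts.tolist(),
        "per_class_accuracy_pct": per_class_accuracy(cm),
        "mean_accuracy_pct": mean_accuracy(cm),
        "n_evaluated": cm.total,
    }


def format_report(cm: ConfusionMatrix) -> str:
    """Human-readable evaluation summary."""
    rep = evaluation_report(cm)
    width = max(len(c) for c in cm.class_order) + 2
    lines = ["confusion matrix (rows true, cols predicted):"]
    lines.append(" " * width + "".join(f"{c:>{width}}" for c in cm.class_order))
    for cls, row in zip(cm.class_order, cm.counts):
        lines.append(f"{cls:>{width}}" + "".join(f"{v:>{width}d}" for v in row))
    lines.append("per-class accuracy: " + ", ".join(
        f"{cls} {pct}%" for cls, pct in rep["per_class_accuracy_pct"].items()))
    lines.append(f"mean accuracy: {rep['mean_accuracy_pct']}%")
    return "\n".join(lines)


def write_command_trace(
    records: Sequence[tuple[str, str]],
    path: str | os.PathLike,
) -> None:
    """Write a CSV trace of (chunk_id, decoded label, motor states)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chunk_id,label,motor_thumb,motor_finger\n")
        for chunk_id, label in records:
            cmd = to_motor_command(label)
            fh.write(f"{chunk_id},{label},{cmd.motor_thumb},{cmd.motor_finger}\n")


def write_report(cm: ConfusionMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(evaluation_report(cm), fh, indent=2)
        fh.write("\n")
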