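"""Trial file I/O and chunked streaming.

EEG trials are stored as plain-text CSV files: one self-describing header
line (sampling rate, movement label, subject category, channel names),
then one row per sample with 14 comma-separated values in microvolts.
``stream_chunks`` replays a trial the way the embedded decoder consumed
it: consecutive non-overlapping 250 ms blocks (32 samples at 128 Hz),
discarding any trailing partial block.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

#: Canonical Emotiv electrode order (international 10-20 sites). Feature
#: indices throughout the package refer to this order.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

N_CHANNELS = 14

#: Movement classes the decoder distinguishes.
CLASSES: tuple[str, ...] = ("thumb", "index", "fist")

DEFAULT_FS = 128.0

#: Samples per 250 ms processing block at 128 Hz.
CHUNK_SAMPLES = 32


class TrialParseError(ValueError):
    """Raised when a trial file is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class EEGTrial:
    """One labeled acquisition: 14 channels x N samples of scalp EEG.

    Parameters
    ----------
    data
        ``(14, n_samples)`` array in microvolts, channels in ``CHANNELS`` order.
    fs
        Sampling rate in Hz (128 for the Emotiv headset).
    label
        Movement class, one of ``CLASSES``.
    subject_category
        ``"I"`` (high involuntary blink rate), ``"II"`` (others) or
        ``"unknown"``.
    """

    data: np.ndarray
    fs: float = DEFAULT_FS
    label: str = "thumb"
    subject_category: str = "unknown"
    channels: tuple[str, ...] = CHANNELS
    trial_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != N_CHANNELS:
            raise ValueError(
                f"trial data must be ({N_CHANNELS}, n_samples); got {self.data.shape}"
            )
        if tuple(self.channels) != CHANNELS:
            raise ValueError("channels must be the canonical Emotiv order")
        if self.data.shape[1] < CHUNK_SAMPLES:
            raise ValueError(
                f"trial must hold at least {CHUNK_SAMPLES} samples (one 250 ms chunk); "
                f"got {self.data.shape[1]}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("trial contains non-finite samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.label not in CLASSES:
            raise ValueError(f"unknown movement label {self.label!r}")
        if self.subject_category not in ("I", "II", "unknown"):
            raise ValueError(f"unknown subject category {self.subject_category!r}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.fs


@dataclass
class Chunk:
    """One 250 ms processing block: 14 channels x 32 samples."""

    data: np.ndarray
    trial_id: str = ""
    index: int = 0
    label: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (N_CHANNELS, CHUNK_SAMPLES):
            raise ValueError(
                f"chunk must be ({N_CHANNELS}, {CHUNK_SAMPLES}); got {self.data.shape}"
            )


def _parse_header(line: str) -> dict:
    if not line.startswith("#"):
        raise TrialParseError("missing '#'-prefixed header line", line=1)
    fields = {}
    for item in line[1:].strip().split(","):
        if "=" not in item:
            raise TrialParseError(f"malformed header item {item!r}", line=1)
        key, _, value = item.partition("=")
        fields[key.strip()] = value.strip()
    for required in ("fs", "label", "channels"):
        if required not in fields:
            raise TrialParseError(f"header missing {required!r}", line=1)
    return fields


def read_trial(path: str | os.PathLike) -> EEGTrial:
    """Read a trial text file, normalizing channel order to ``CHANNELS``.

    Raises
    ------
    TrialParseError
        On a malformed header, wrong channel count, or non-numeric sample;
        the message names the offending line.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header_line = fh.readline()
        if not header_line:
            raise TrialParseError("empty file", line=1)
        header = _parse_header(header_line)
        try:
            fs = float(header["fs"])
        except ValueError:
            raise TrialParseError(f"non-numeric fs {header['fs']!r}", line=1) from None
        file_channels = tuple(header["channels"].split(";"))
        if sorted(file_channels) != sorted(CHANNELS):
            raise TrialParseError(
                f"expected the {N_CHANNELS} Emotiv channels, got {len(file_channels)}: "
                f"{';'.join(file_channels)}",
                line=1,
            )
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != N_CHANNELS:
                raise TrialParseError(
                    f"expected {N_CHANNELS} values, got {len(parts)}", line=lineno
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError:
                raise TrialParseError(f"non-numeric sample in {line!r}", line=lineno) from None
    data = np.asarray(rows, dtype=float).T  # file rows are samples
    # normalize channel order
    order = [file_channels.index(ch) for ch in CHANNELS]
    data = data[order]
    return EEGTrial(
        data=data,
        fs=fs,
        label=header["label"],
        subject_category=header.get("category", "unknown"),
        trial_id=header.get("id", os.path.splitext(os.path.basename(path))[0]),
    )


def write_trial(trial: EEGTrial, path: str | os.PathLike, precision: int = 6) -> None:
    """Write ``trial`` in the text dialect read by :func:`read_trial`.

    Samples are formatted with ``precision`` significant digits (default 6,
    ample for microvolt-scale EEG).
    """
    header = (
        f"#fs={trial.fs:g},label={trial.label},category={trial.subject_category},"
        f"channels={';'.join(CHANNELS)}"
    )
    if trial.trial_id:
        header += f",id={trial.trial_id}"
    fmt = f"%.{precision}g"
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for row in trial.data.T:
            fh.write(",".join(fmt % v for v in row) + "\n")


def stream_chunks(trial: EEGTrial, chunk_samples: int = CHUNK_SAMPLES) -> Iterator[Chunk]:
    """Yield consecutive non-overlapping chunks, embedded-loop style.

    Yields ``floor(n_samples / chunk_samples)`` chunks; a trailing partial
    block is discarded (the embedded loop only ever processed full 250 ms
    reads).
    """
    n_chunks = trial.n_samples // chunk_samples
    for i in range(n_chunks):
        yield Chunk(
            data=trial.data[:, i * chunk_samples:(i + 1) * chunk_samples],
            trial_id=trial.trial_id,
            index=i,
            label=trial.label,
        )


def count_dataset_samples(n_trials: int, samples_per_movement: int, n_movements: int) -> int:
    """Total sample count of a recording campaign (bookkeeping/manifest check).

    E.g. 47 retained trials x 1280 samples x 3 movements = 180480 samples
    per subject.
    """
    for name, v in (("n_trials", n_trials),
                    ("samples_per_movement", samples_per_movement),
                    ("n_movements", n_movements)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return int(n_trials) * int(samples_per_movement) * int(n_movements)


def write_manifest(entries: Sequence[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write a dataset manifest: one ``path,label`` line per trial."""
    with open(path, "w", encoding="utf-8") as fh:
        for trial_path, label in entries:
            fh.write(f"{trial_path},{label}\n")


def read_manifest(path: str | os.PathLike) -> list[tuple[str, str]]:
    entries = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            trial_path, sep, label = line.rpartition(",")
            if not sep or label not in CLASSES:
                raise TrialParseError(f"malformed manifest entry {line!r}", line=lineno)
            entries.append((trial_path, label))
    return entries
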