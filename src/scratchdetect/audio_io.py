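"""Audio and interval-label I/O.

Recordings are one- or two-microphone PCM WAV files; ground truth is a CSV of
behavior intervals (``onset_s,offset_s,behavior``). Samples are rescaled to
[-1, 1] on read so that the detection threshold ``h`` has a consistent scale
regardless of bit depth. All timestamps are 0-based seconds from recording
start and intervals are closed-open ``[onset, offset)``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioRecording",
    "LabeledInterval",
    "LabelTrack",
    "AudioFormatError",
    "LabelValidationError",
    "read_audio",
    "write_audio",
    "read_labels",
    "write_labels",
]

MAX_CHANNELS = 2


class AudioFormatError(ValueError):
    """Unreadable, compressed, or unsupported audio file."""


class LabelValidationError(ValueError):
    """Malformed or inconsistent interval-label file."""


@dataclass
class AudioRecording:
    """Multi-channel audio held as float arrays in [-1, 1].

    Parameters
    ----------
    channels : list of ndarray
        Equal-length 1-D float arrays, one per microphone (at most two).
    sample_rate_hz : int
        Sampling rate in Hz.
    bit_depth : int
        Bit depth of the source file (16 for the PCM recordings this
        pipeline targets; 32 for float WAV).
    id : str
        Identifier, by default the file stem.
    """

    channels: list[np.ndarray]
    sample_rate_hz: int
    bit_depth: int = 16
    id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("recording must have at least one channel")
        if len(self.channels) > MAX_CHANNELS:
            raise AudioFormatError(
                f"{len(self.channels)} channels unsupported (max {MAX_CHANNELS})"
            )
        n = len(self.channels[0])
        if any(len(c) != n for c in self.channels):
            raise ValueError("all channels must have identical length")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        self.channels = [np.asarray(c, dtype=np.float64) for c in self.channels]

    @property
    def n_samples(self) -> int:
        return len(self.channels[0])

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz


@dataclass(frozen=True)
class LabeledInterval:
    """A behavior interval ``[onset_s, offset_s)`` with a tag such as
    ``"scratch"``, ``"grooming"`` or ``"walking"``."""

    onset_s: float
    offset_s: float
    behavior: str

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise LabelValidationError(
                f"onset {self.onset_s} must precede offset {self.offset_s}"
            )
        if self.onset_s < 0:
            raise LabelValidationError(f"negative onset {self.onset_s}")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s

    def overlap_s(self, other: "LabeledInterval") -> float:
        return max(
            0.0,
            min(self.offset_s, other.offset_s) - max(self.onset_s, other.onset_s),
        )


@dataclass
class LabelTrack:
    """Onset-sorted list of labeled intervals.

    Scratch intervals must be pairwise non-overlapping (a mouse scratches one
    bout at a time); confounder intervals may overlap anything.
    """

    intervals: list[LabeledInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.onset_s)
        scratch = self.scratch_intervals()
        for a, b in zip(scratch, scratch[1:]):
            if a.overlap_s(b) > 0:
                raise LabelValidationError(
                    f"overlapping scratch intervals: [{a.onset_s}, {a.offset_s}) "
                    f"and [{b.onset_s}, {b.offset_s})"
                )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, LabelTrack) and self.intervals == other.intervals

    def scratch_intervals(self) -> list[LabeledInterval]:
        return [iv for iv in self.intervals if iv.behavior == "scratch"]

    def with_behavior(self, behavior: str) -> "LabelTrack":
        return LabelTrack([iv for iv in self.intervals if iv.behavior == behavior])


def read_audio(path: str | Path) -> AudioRecording:
    """Read a PCM WAV file into an :class:`AudioRecording`.

    Integer samples are rescaled by the type maximum so all recordings live
    on a common [-1, 1] amplitude scale; float WAV is passed through.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read {path}: {exc}") from exc
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] > MAX_CHANNELS:
        raise AudioFormatError(
            f"{path}: {data.shape[1]} channels unsupported (max {MAX_CHANNELS})"
        )
    if data.dtype == np.int16:
        bit_depth, scaled = 16, data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        bit_depth, scaled = 32, data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        bit_depth, scaled = 8, (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        bit_depth, scaled = 32, data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported sample dtype {data.dtype}")
    channels = [np.ascontiguousarray(scaled[:, i]) for i in range(scaled.shape[1])]
    return AudioRecording(
        channels=channels, sample_rate_hz=int(rate), bit_depth=bit_depth, id=path.stem
    )


def write_audio(recording: AudioRecording, path: str | Path) -> None:
    """Write a recording as 16-bit PCM WAV (samples clipped to [-1, 1])."""
    data = np.stack(recording.channels, axis=1)
    ints = np.clip(np.round(data * 32768.0), -32768, 32767).astype(np.int16)
    if ints.shape[1] == 1:
        ints = ints[:, 0]
    wavfile.write(Path(path), recording.sample_rate_hz, ints)


LABEL_HEADER = ["onset_s", "offset_s", "behavior"]


def read_labels(path: str | Path) -> LabelTrack:
    """Read an interval-label CSV (``onset_s,offset_s,behavior``).

    Rows are sorted by onset. Validation failures (onset >= offset, overlapping
    scratch intervals) raise :class:`LabelValidationError` with the offending
    line number where applicable.
    """
    path = Path(path)
    intervals: list[LabeledInterval] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [c.strip() for c in header] != LABEL_HEADER:
            raise LabelValidationError(
                f"{path}: expected header {','.join(LABEL_HEADER)!r}, got {header!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 3:
                raise LabelValidationError(f"{path}:{lineno}: expected 3 columns")
            try:
                onset, offset = float(row[0]), float(row[1])
            except ValueError as exc:
                raise LabelValidationError(f"{path}:{lineno}: {exc}") from exc
            try:
                intervals.append(LabeledInterval(onset, offset, row[2].strip()))
            except LabelValidationError as exc:
                raise LabelValidationError(f"{path}:{lineno}: {exc}") from exc
    return LabelTrack(intervals)


def write_labels(track: LabelTrack, path: str | Path) -> None:
    """Write a label track as CSV; inverse of :func:`read_labels`."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(LABEL_HEADER)
        for iv in track:
            writer.writerow([f"{iv.onset_s:.6f}", f"{iv.offset_s:.6f}", iv.behavior])
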