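"""I/O for event streams, EMG recordings, dataset manifests and chunked samples.

On-disk formats
---------------
Event CSV: a line ``width,height``, a line with the two integer values,
a line ``t_us,x,y,p``, then one row per event (timestamp in microseconds,
x column, y row, polarity 0=OFF / 1=ON).

EMG CSV: a line ``rate_hz``, a line with the sampling rate, then one row
per time sample with 8 comma-separated integers (one per channel).

HDF5: one group per recording holding datasets ``emg`` (channels x time,
uint8) and ``events`` (n x 4 int64 columns t_us, x, y, p), with attrs
``rate``, ``width``, ``height``, ``label``, ``subject``, ``session``,
``repetition``.

Coordinates are 0-based, x = column, y = row, origin top-left.  Event
timestamps are non-decreasing microseconds from recording start; the Myo
and DVS streams of one recording are assumed pre-aligned at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import h5py
import numpy as np

GESTURES = ("pinky", "elle", "yo", "index", "thumb")

EMG_RATE_HZ = 200
EMG_CHANNELS = 8
DVS_WIDTH = 128
DVS_HEIGHT = 128

_EVENT_DTYPE = np.int64


class ParseError(ValueError):
    """A file did not conform to the documented schema."""


class ValidationError(ValueError):
    """In-memory data violated a structural invariant."""


@dataclass(frozen=True)
class EventStream:
    """Timestamped polarity events from a DVS-like sensor.

    ``events`` is an (n, 4) int64 array with columns (t_us, x, y, p);
    timestamps non-decreasing, coordinates inside the sensor, p in {0, 1}.
    """

    events: np.ndarray
    width: int
    height: int

    def __post_init__(self) -> None:
        ev = np.asarray(self.events, dtype=_EVENT_DTYPE).reshape(-1, 4)
        object.__setattr__(self, "events", ev)
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("sensor dimensions must be positive")
        if len(ev):
            if np.any(np.diff(ev[:, 0]) < 0):
                raise ValidationError("event timestamps must be non-decreasing")
            if np.any((ev[:, 1] < 0) | (ev[:, 1] >= self.width)):
                raise ValidationError(f"event x out of [0, {self.width})")
            if np.any((ev[:, 2] < 0) | (ev[:, 2] >= self.height)):
                raise ValidationError(f"event y out of [0, {self.height})")
            if np.any((ev[:, 3] < 0) | (ev[:, 3] > 1)):
                raise ValidationError("polarity must be 0 or 1")

    def __len__(self) -> int:
        return len(self.events)

    @property
    def t(self) -> np.ndarray:
        return self.events[:, 0]

    @property
    def x(self) -> np.ndarray:
        return self.events[:, 1]

    @property
    def y(self) -> np.ndarray:
        return self.events[:, 2]

    @property
    def p(self) -> np.ndarray:
        return self.events[:, 3]

    def slice_time(self, start_us: int, end_us: int, rebase: bool = True) -> "EventStream":
        """Events with start_us <= t < end_us, optionally re-based to t=0."""
        m = (self.events[:, 0] >= start_us) & (self.events[:, 0] < end_us)
        ev = self.events[m].copy()
        if rebase:
            ev[:, 0] -= start_us
        return EventStream(ev, self.width, self.height)


@dataclass(frozen=True)
class EMGRecording:
    """Multi-channel sampled biosignal; raw unitless values in 8-bit range."""

    samples: np.ndarray  # channels x time
    rate: float = EMG_RATE_HZ

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.samples))
        object.__setattr__(self, "samples", s)
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")
        if s.size and (s.min() < 0 or s.max() > 255):
            raise ValidationError("EMG values must lie in the 8-bit range [0, 255]")

    @property
    def channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.rate

    def slice_samples(self, start: int, end: int) -> "EMGRecording":
        return EMGRecording(self.samples[:, start:end].copy(), self.rate)


@dataclass(frozen=True)
class Recording:
    """One full gesture recording with both modalities, pre-aligned at t=0."""

    emg: EMGRecording
    dvs: EventStream
    label: str
    subject: int = 0
    session: int = 0
    repetition: int = 0

    def __post_init__(self) -> None:
        if self.label not in GESTURES:
            raise ValidationError(f"unknown gesture label {self.label!r}")


@dataclass(frozen=True)
class GestureSample:
    """A fixed-duration chunk of one recording, both modalities aligned."""

    emg: EMGRecording
    dvs: EventStream
    label: str
    duration_ms: float
    subject: int
    session: int
    repetition: int
    chunk_index: int

    def __post_init__(self) -> None:
        if self.label not in GESTURES:
            raise ValidationError(f"unknown gesture label {self.label!r}")


@dataclass(frozen=True)
class DatasetManifest:
    """Factorial structure of a recording campaign.

    Total sample count is the product of the five factors; chunks must fit
    inside each recording.
    """

    n_subjects: int = 21
    n_sessions: int = 3
    n_repetitions: int = 5
    n_gestures: int = 5
    n_chunks_per_recording: int = 10
    recording_duration_s: float = 2.0
    chunk_duration_ms: float = 200.0

    def __post_init__(self) -> None:
        counts = (self.n_subjects, self.n_sessions, self.n_repetitions,
                  self.n_gestures, self.n_chunks_per_recording)
        if any(c < 1 for c in counts):
            raise ValidationError("all manifest counts must be >= 1")
        if self.chunk_duration_ms * self.n_chunks_per_recording > self.recording_duration_s * 1000.0 + 1e-9:
            raise ValidationError("chunks do not fit inside the recording duration")
        if self.n_gestures > len(GESTURES):
            raise ValidationError(f"at most {len(GESTURES)} gesture classes supported")

    @property
    def n_recordings(self) -> int:
        return self.n_subjects * self.n_sessions * self.n_repetitions * self.n_gestures

    @property
    def total_samples(self) -> int:
        return self.n_recordings * self.n_chunks_per_recording


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def load_events(path) -> EventStream:
    """Read an event CSV file into a validated :class:`EventStream`."""
    with open(path, "r") as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) < 3 or lines[0].replace(" ", "") != "width,height":
        raise ParseError(f"{path}: expected 'width,height' header on line 1")
    try:
        width, height = (int(v) for v in lines[1].split(","))
    except ValueError as exc:
        raise ParseError(f"{path}: line 2: cannot parse sensor dimensions") from exc
    if lines[2].replace(" ", "") != "t_us,x,y,p":
        raise ParseError(f"{path}: expected 't_us,x,y,p' header on line 3")
    rows = []
    for i, ln in enumerate(lines[3:], start=4):
        parts = ln.split(",")
        if len(parts) != 4:
            raise ParseError(f"{path}: line {i}: expected 4 fields, got {len(parts)}")
        try:
            rows.append([int(v) for v in parts])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-integer field") from exc
    ev = np.array(rows, dtype=_EVENT_DTYPE).reshape(-1, 4)
    return EventStream(ev, width, height)


def save_events(stream: EventStream, path) -> None:
    with open(path, "w") as fh:
        fh.write("width,height\n")
        fh.write(f"{stream.width},{stream.height}\n")
        fh.write("t_us,x,y,p\n")
        for t, x, y, p in stream.events:
            fh.write(f"{t},{x},{y},{p}\n")


def load_emg(path) -> EMGRecording:
    """Read an EMG CSV file into a validated :class:`EMGRecording`."""
    with open(path, "r") as fh:
        lines = [ln.strip() for ln in fh]
    lines = [ln for ln in lines if ln]
    if len(lines) < 2 or lines[0].replace(" ", "") != "rate_hz":
        raise ParseError(f"{path}: expected 'rate_hz' header on line 1")
    try:
        rate = float(lines[1])
    except ValueError as exc:
        raise ParseError(f"{path}: line 2: cannot parse sampling rate") from exc
    rows = []
    for i, ln in enumerate(lines[2:], start=3):
        parts = ln.split(",")
        try:
            rows.append([int(v) for v in parts])
        except ValueError as exc:
            raise ParseError(f"{path}: line {i}: non-integer field") from exc
        if len(rows[-1]) != len(rows[0]):
            raise ParseError(f"{path}: line {i}: inconsistent channel count")
    samples = np.array(rows, dtype=np.int64).T if rows else np.zeros((0, 0), dtype=np.int64)
    return EMGRecording(samples, rate)


def save_emg(rec: EMGRecording, path) -> None:
    with open(path, "w") as fh:
        fh.write("rate_hz\n")
        fh.write(f"{rec.rate:g}\n")
        for col in rec.samples.T:
            fh.write(",".join(str(int(v)) for v in col) + "\n")


# ---------------------------------------------------------------------------
# HDF5 I/O
# ---------------------------------------------------------------------------

def save_recordings(recordings: Sequence[Recording], path) -> None:
    """Write recordings to HDF5, one group per recording."""
    with h5py.File(path, "w") as fh:
        for i, rec in enumerate(recordings):
            g = fh.create_group(f"rec{i:05d}")
            g.create_dataset("emg", data=rec.emg.samples.astype(np.uint8))
            g.create_dataset("events", data=rec.dvs.events)
            g.attrs["rate"] = rec.emg.rate
            g.attrs["width"] = rec.dvs.width
            g.attrs["height"] = rec.dvs.height
            g.attrs["label"] = rec.label
            g.attrs["subject"] = rec.subject
            g.attrs["session"] = rec.session
            g.attrs["repetition"] = rec.repetition


def load_recordings(path) -> list[Recording]:
    out = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            emg = EMGRecording(np.asarray(g["emg"], dtype=np.int64), float(g.attrs["rate"]))
            dvs = EventStream(np.asarray(g["events"]), int(g.attrs["width"]), int(g.attrs["height"]))
            out.append(Recording(
                emg=emg, dvs=dvs,
                label=str(g.attrs["label"]),
                subject=int(g.attrs["subject"]),
                session=int(g.attrs["session"]),
                repetition=int(g.attrs["repetition"]),
            ))
    return out


# ---------------------------------------------------------------------------
# Chunking
# ---------------------------------------------------------------------------

def chunk_recording(rec: Recording, manifest: DatasetManifest) -> list[GestureSample]:
    """Cut one recording into contiguous, non-overlapping aligned chunks.

    Chunk k covers [k*D, (k+1)*D) ms in both modalities (half-open); EMG by
    sample index, events by timestamp.  Both are re-based so each chunk
    starts at t = 0.
    """
    dur_ms = manifest.chunk_duration_ms
    n = manifest.n_chunks_per_recording
    spc = dur_ms * rec.emg.rate / 1000.0
    if abs(spc - round(spc)) > 1e-9:
        raise ValidationError("chunk duration is not a whole number of EMG samples")
    spc = int(round(spc))
    needed = n * spc
    who = f"recording subject={rec.subject} session={rec.session} rep={rec.repetition} label={rec.label}"
    if rec.emg.n_samples < needed:
        raise ValidationError(f"{who}: EMG too short ({rec.emg.n_samples} < {needed} samples)")
    # events beyond the chunked span are dropped silently
    out = []
    for k in range(n):
        emg = rec.emg.slice_samples(k * spc, (k + 1) * spc)
        dvs = rec.dvs.slice_time(int(k * dur_ms * 1000), int((k + 1) * dur_ms * 1000))
        out.append(GestureSample(
            emg=emg, dvs=dvs, label=rec.label, duration_ms=dur_ms,
            subject=rec.subject, session=rec.session,
            repetition=rec.repetition, chunk_index=k,
        ))
    return out


def chunk_dataset(recordings: Iterable[Recording], manifest: DatasetManifest) -> list[GestureSample]:
    """Chunk every recording; the result size equals the manifest product."""
    recordings = list(recordings)
    if len(recordings) != manifest.n_recordings:
        raise ValidationError(
            f"expected {manifest.n_recordings} recordings per manifest, got {len(recordings)}")
    samples: list[GestureSample] = []
    for rec in recordings:
        samples.extend(chunk_recording(rec, manifest))
    assert len(samples) == manifest.total_samples
    return samples
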