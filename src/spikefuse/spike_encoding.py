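"""Spike encoders: delta modulation of EMG and event-stream preprocessing.

The delta modulator normalizes raw 8-bit samples to [-1, 1) via
(v - 128) / 128, linearly interpolates each channel by an integer factor,
and emits UP/DOWN pulses whenever the signal departs from a tracking
reference by more than the threshold.  The reference moves in threshold
steps, so the signal is exactly recoverable as
r(t) = x(0) + delta * (N_up(t) - N_down(t)) up to the quantization bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from spikefuse.aer_io import EMGRecording, EventStream, ValidationError

logger = logging.getLogger(__name__)

# relative slack on the threshold comparison; absorbs float accumulation
# error so that a ramp spanning k*delta emits exactly k spikes
_REL_TOL = 1e-9


def normalize_8bit(samples: np.ndarray) -> np.ndarray:
    """Map raw unsigned 8-bit values onto [-1, 1)."""
    return (np.asarray(samples, dtype=np.float64) - 128.0) / 128.0


@dataclass(frozen=True)
class DeltaModConfig:
    """Delta-modulator parameters on the normalized signal scale."""

    threshold: float = 0.05
    interpolation_factor: int = 3500

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if int(self.interpolation_factor) != self.interpolation_factor or self.interpolation_factor < 1:
            raise ValidationError("interpolation factor must be an integer >= 1")


@dataclass(frozen=True)
class SpikeTrainPair:
    """Per-channel UP and DOWN spike times in microseconds."""

    up_times: tuple
    down_times: tuple

    @property
    def channels(self) -> int:
        return len(self.up_times)

    def counts(self) -> tuple[np.ndarray, np.ndarray]:
        up = np.array([len(t) for t in self.up_times])
        down = np.array([len(t) for t in self.down_times])
        return up, down


@dataclass(frozen=True)
class SpikeRaster:
    """Spike counts binned on a regular tick grid; last axis is time.

    EMG layout is 16 x ticks (channel 2c = UP, 2c+1 = DOWN of EMG channel
    c); DVS layout is 2 x H x W x ticks (plane 0 = OFF, plane 1 = ON).
    """

    counts: np.ndarray
    tick_ms: float = 1.0
    channel_layout: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        object.__setattr__(self, "counts", c)
        if c.size and c.min() < 0:
            raise ValidationError("spike counts must be non-negative")

    @property
    def n_ticks(self) -> int:
        return self.counts.shape[-1]

    @property
    def duration_ms(self) -> float:
        return self.n_ticks * self.tick_ms

    def flat(self) -> np.ndarray:
        """channels x ticks view with all leading axes flattened."""
        return self.counts.reshape(-1, self.n_ticks)


def _interpolate(channel: np.ndarray, factor: int) -> np.ndarray:
    """Linear interpolation: n samples -> (n-1)*factor + 1 samples."""
    n = len(channel)
    if n < 2 or factor == 1:
        return channel.astype(np.float64)
    xi = np.arange((n - 1) * factor + 1) / factor
    return np.interp(xi, np.arange(n), channel)


def delta_modulate(rec: EMGRecording, cfg: DeltaModConfig = DeltaModConfig()) -> SpikeTrainPair:
    """Encode each EMG channel independently into UP/DOWN spike trains.

    Spike times are the interpolated-sample times in microseconds; at most
    one spike is emitted per interpolated sample.  A single-sample
    recording yields empty trains.
    """
    delta = cfg.threshold
    factor = int(cfg.interpolation_factor)
    step_us = 1e6 / (rec.rate * factor)
    norm = normalize_8bit(rec.samples)
    up_all, down_all = [], []
    for ch in norm:
        sig = _interpolate(ch, factor)
        ups, downs = _track(sig, delta)
        up_all.append(np.round(ups * step_us).astype(np.int64))
        down_all.append(np.round(downs * step_us).astype(np.int64))
    return SpikeTrainPair(tuple(up_all), tuple(down_all))


def _track_core(sig, tol, delta, ups, downs):  # pragma: no cover - thin loop
    x0 = sig[0]
    k = 0  # reference = x0 + k * delta, kept as a counter for exactness
    nu = 0
    nd = 0
    for i in range(1, len(sig)):
        dev = sig[i] - (x0 + k * delta)
        if dev > tol:
            ups[nu] = i
            nu += 1
            k += 1
        elif dev < -tol:
            downs[nd] = i
            nd += 1
            k -= 1
    return nu, nd


try:  # sequential loop; JIT pays off at interpolation factors in the 1000s
    from numba import njit

    _track_core = njit(cache=True)(_track_core)
except ImportError:  # pragma: no cover
    pass


def _track(sig: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Tracking-reference loop; returns UP/DOWN indices into ``sig``."""
    if len(sig) < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    tol = delta * (1.0 - _REL_TOL)
    ups = np.empty(len(sig), dtype=np.int64)
    downs = np.empty(len(sig), dtype=np.int64)
    nu, nd = _track_core(np.ascontiguousarray(sig, dtype=np.float64), tol, delta, ups, downs)
    return ups[:nu].copy(), downs[:nd].copy()


def reconstruct(trains: SpikeTrainPair, cfg: DeltaModConfig, x0: np.ndarray,
                t_us: np.ndarray) -> np.ndarray:
    """Piecewise-constant decode r(t) = x0 + delta * (N_up(t) - N_down(t)).

    ``t_us`` are query times; returns channels x len(t_us).
    """
    t_us = np.asarray(t_us)
    out = np.empty((trains.channels, len(t_us)))
    for c in range(trains.channels):
        n_up = np.searchsorted(trains.up_times[c], t_us, side="right")
        n_down = np.searchsorted(trains.down_times[c], t_us, side="right")
        out[c] = x0[c] + cfg.threshold * (n_up - n_down)
    return out


# ---------------------------------------------------------------------------
# DVS preprocessing
# ---------------------------------------------------------------------------

def crop_events(ev: EventStream, size: int = 40) -> EventStream:
    """Crop to a size x size window centered on the median event position.

    The window is clamped to lie fully inside the sensor; retained events
    are re-based to [0, size)^2.  An empty stream yields an empty stream
    with the window at the sensor center.
    """
    if len(ev):
        cx = float(np.median(ev.x))
        cy = float(np.median(ev.y))
    else:
        cx, cy = (ev.width - 1) / 2.0, (ev.height - 1) / 2.0
    x0 = int(np.clip(round(cx) - size // 2, 0, ev.width - size))
    y0 = int(np.clip(round(cy) - size // 2, 0, ev.height - size))
    m = (ev.x >= x0) & (ev.x < x0 + size) & (ev.y >= y0) & (ev.y < y0 + size)
    kept = ev.events[m].copy()
    kept[:, 1] -= x0
    kept[:, 2] -= y0
    return EventStream(kept, size, size)


def subsample_quad(ev: EventStream) -> tuple[EventStream, EventStream, EventStream, EventStream]:
    """Partition a 40x40 stream into four half-resolution phase streams.

    Stream k receives events whose pixel phase (x mod 2, y mod 2) equals
    (k mod 2, k // 2), mapped to (x // 2, y // 2).
    """
    if ev.width % 2 or ev.height % 2:
        raise ValidationError("subsample_quad requires even sensor dimensions")
    w2, h2 = ev.width // 2, ev.height // 2
    out = []
    for k in range(4):
        px, py = k % 2, k // 2
        m = ((ev.x % 2) == px) & ((ev.y % 2) == py)
        sub = ev.events[m].copy()
        sub[:, 1] //= 2
        sub[:, 2] //= 2
        out.append(EventStream(sub, w2, h2))
    return tuple(out)


# ---------------------------------------------------------------------------
# Rasterization onto the algorithmic tick grid
# ---------------------------------------------------------------------------

def rasterize_trains(trains: SpikeTrainPair, duration_ms: float,
                     tick_ms: float = 1.0) -> SpikeRaster:
    """Bin UP/DOWN trains into a 2C x ticks count raster.

    Channel 2c holds UP spikes of EMG channel c, channel 2c+1 its DOWN
    spikes.  Spikes at or beyond the duration are dropped (logged).
    """
    n_ticks = int(round(duration_ms / tick_ms))
    counts = np.zeros((2 * trains.channels, n_ticks), dtype=np.int64)
    dropped = 0
    tick_us = tick_ms * 1000.0
    for c in range(trains.channels):
        for row, times in ((2 * c, trains.up_times[c]), (2 * c + 1, trains.down_times[c])):
            idx = np.floor(np.asarray(times) / tick_us).astype(np.int64)
            ok = idx < n_ticks
            dropped += int(np.sum(~ok))
            np.add.at(counts[row], idx[ok], 1)
    if dropped:
        logger.info("rasterize_trains: dropped %d spikes beyond %.1f ms", dropped, duration_ms)
    layout = f"{2 * trains.channels} = {trains.channels} EMG channels x (UP, DOWN)"
    return SpikeRaster(counts, tick_ms, layout)


def rasterize_events(ev: EventStream, duration_ms: float, tick_ms: float = 1.0,
                     merge_polarity: bool = False) -> SpikeRaster:
    """Bin events into a polarity x H x W x ticks count raster.

    With ``merge_polarity`` ON and OFF land in a single plane (H x W x
    ticks), the layout used by the subMLP path.  Events at or beyond the
    duration are dropped (logged).
    """
    n_ticks = int(round(duration_ms / tick_ms))
    tick_us = tick_ms * 1000.0
    idx = np.floor(ev.t / tick_us).astype(np.int64)
    ok = idx < n_ticks
    dropped = int(np.sum(~ok))
    if dropped:
        logger.info("rasterize_events: dropped %d events beyond %.1f ms", dropped, duration_ms)
    if merge_polarity:
        counts = np.zeros((ev.height, ev.width, n_ticks), dtype=np.int64)
        np.add.at(counts, (ev.y[ok], ev.x[ok], idx[ok]), 1)
        layout = f"{ev.height}x{ev.width} merged polarity"
    else:
        counts = np.zeros((2, ev.height, ev.width, n_ticks), dtype=np.int64)
        np.add.at(counts, (ev.p[ok], ev.y[ok], ev.x[ok], idx[ok]), 1)
        layout = f"2x{ev.height}x{ev.width} (plane 0 = OFF, 1 = ON)"
    return SpikeRaster(counts, tick_ms, layout)
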