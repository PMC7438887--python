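"""Seeded synthetic datasets mimicking the recording campaign's structure.

EMG: each gesture has an 8-channel activation envelope; the signal is a
noisy amplitude-modulated burst around the 128 mid-rail, quantized to
8-bit.  DVS: each gesture has a sparse hand-edge template on the 128x128
sensor; a jittering rigid motion path generates ON/OFF events on template
pixels (polarity follows the horizontal motion sign) plus uniform
background noise.  A scalar ``difficulty`` in [0, 1] mixes the per-class
templates/envelopes toward their common mean, degrading separability.

All generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from spikefuse.aer_io import (
    DVS_HEIGHT,
    DVS_WIDTH,
    EMG_CHANNELS,
    EMG_RATE_HZ,
    GESTURES,
    DatasetManifest,
    EMGRecording,
    EventStream,
    Recording,
    ValidationError,
)


@dataclass(frozen=True)
class SynthConfig:
    manifest: DatasetManifest = field(default_factory=DatasetManifest)
    seed: int = 0
    difficulty: float = 0.0
    emg_amplitude: float = 60.0
    emg_noise_sd: float = 6.0
    dvs_event_rate_per_px_ms: float = 0.06  # template-pixel firing probability / ms
    dvs_noise_events_per_ms: float = 0.5
    jitter_px: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValidationError("difficulty must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Per-gesture generative templates
# ---------------------------------------------------------------------------

def _emg_envelopes(rng: np.random.Generator, n_gestures: int, difficulty: float) -> np.ndarray:
    """(n_gestures, 8) channel activation envelopes, mixed by difficulty."""
    base = 0.15 + 0.85 * rng.random((n_gestures, EMG_CHANNELS))
    # deterministic structure: each gesture strongly drives a distinct channel pair
    for g in range(n_gestures):
        base[g, (2 * g) % EMG_CHANNELS] += 1.2
        base[g, (2 * g + 1) % EMG_CHANNELS] += 0.8
    mean = base.mean(axis=0, keepdims=True)
    return (1 - difficulty) * base + difficulty * mean


def _hand_template(g: int, n_gestures: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) edge-pixel coordinates of a stylized hand for gesture ``g``.

    A palm arc plus g+1 raised "fingers" drawn as vertical strokes; classes
    are distinct by construction.
    """
    pts = []
    cx, cy = DVS_WIDTH // 2, DVS_HEIGHT // 2 + 10
    # palm: half-circle of radius 12
    for a in np.linspace(0, np.pi, 40):
        pts.append((cx + 12 * np.cos(a), cy + 12 * np.sin(a)))
    n_fingers = g + 1
    xs = np.linspace(cx - 14, cx + 14, n_fingers) if n_fingers > 1 else [cx]
    for j, fx in enumerate(xs):
        length = 18 + 6 * ((g + j) % 3)
        for d in np.linspace(0, length, int(length)):
            pts.append((fx, cy - 8 - d))
            pts.append((fx + 2, cy - 8 - d))  # two-pixel-wide stroke -> edges
    arr = np.round(np.asarray(pts)).astype(np.int64)
    return np.unique(arr, axis=0)


def _mixed_templates(rng: np.random.Generator, n_gestures: int,
                     difficulty: float) -> list[np.ndarray]:
    temps = [_hand_template(g, n_gestures, rng) for g in range(n_gestures)]
    if difficulty <= 0:
        return temps
    shared = temps[0]
    out = []
    for t in temps:
        k = int(round(difficulty * len(t)))
        idx = rng.choice(len(shared), size=min(k, len(shared)), replace=True)
        repl = shared[idx]
        keep = t[rng.permutation(len(t))[: len(t) - len(repl)]]
        out.append(np.concatenate([keep, repl]) if len(repl) else t)
    return out


# ---------------------------------------------------------------------------
# Single-recording synthesis
# ---------------------------------------------------------------------------

def _synth_emg(rng, envelope: np.ndarray, n_samples: int, cfg: SynthConfig,
               gesture: int) -> np.ndarray:
    t = np.arange(n_samples) / EMG_RATE_HZ
    carrier = np.abs(np.sin(2 * np.pi * (3.0 + 0.7 * gesture) * t))
    sig = 128.0 + cfg.emg_amplitude * envelope[:, None] * carrier[None, :] * \
        rng.choice([-1.0, 1.0], size=(EMG_CHANNELS, n_samples))
    sig += rng.normal(0.0, cfg.emg_noise_sd, sig.shape)
    return np.clip(np.round(sig), 0, 255).astype(np.int64)


def _synth_events(rng, template: np.ndarray, duration_ms: float,
                  cfg: SynthConfig) -> np.ndarray:
    n_steps = int(duration_ms)
    # smooth jitter path: integrated gaussian steps, pulled back to center
    path = np.zeros((n_steps, 2))
    vel = np.zeros(2)
    for i in range(1, n_steps):
        vel = 0.9 * vel + rng.normal(0, 0.35, 2) - 0.02 * path[i - 1]
        path[i] = path[i - 1] + vel
    path = np.clip(path, -cfg.jitter_px, cfg.jitter_px)
    speed = np.abs(np.diff(path[:, 0], prepend=path[0, 0])) + \
        np.abs(np.diff(path[:, 1], prepend=path[0, 1]))
    p_fire = np.clip(cfg.dvs_event_rate_per_px_ms * (0.3 + speed), 0, 1)

    rows = []
    for ms in range(n_steps):
        fire = rng.random(len(template)) < p_fire[ms]
        if np.any(fire):
            xy = template[fire] + np.round(path[ms]).astype(np.int64)
            pol = 1 if (path[ms, 0] - path[ms - 1, 0] if ms else 0) >= 0 else 0
            ts = rng.integers(0, 1000, size=fire.sum()) + ms * 1000
            rows.append(np.column_stack([ts, xy[:, 0], xy[:, 1],
                                         np.full(fire.sum(), pol)]))
        n_noise = rng.poisson(cfg.dvs_noise_events_per_ms)
        if n_noise:
            ts = rng.integers(0, 1000, size=n_noise) + ms * 1000
            nx = rng.integers(0, DVS_WIDTH, size=n_noise)
            ny = rng.integers(0, DVS_HEIGHT, size=n_noise)
            np_pol = rng.integers(0, 2, size=n_noise)
            rows.append(np.column_stack([ts, nx, ny, np_pol]))
    if not rows:
        return np.zeros((0, 4), dtype=np.int64)
    ev = np.concatenate(rows).astype(np.int64)
    ev[:, 1] = np.clip(ev[:, 1], 0, DVS_WIDTH - 1)
    ev[:, 2] = np.clip(ev[:, 2], 0, DVS_HEIGHT - 1)
    return ev[np.argsort(ev[:, 0], kind="stable")]


def generate_dataset(cfg: SynthConfig) -> tuple[list[Recording], DatasetManifest]:
    """Generate the full factorial set of recordings for cfg.manifest."""
    m = cfg.manifest
    rng = np.random.default_rng(cfg.seed)
    envelopes = _emg_envelopes(rng, m.n_gestures, cfg.difficulty)
    templates = _mixed_templates(rng, m.n_gestures, cfg.difficulty)
    n_emg = int(round(m.recording_duration_s * EMG_RATE_HZ))
    dur_ms = m.recording_duration_s * 1000.0
    recordings = []
    for subject in range(m.n_subjects):
        for session in range(m.n_sessions):
            for rep in range(m.n_repetitions):
                for g in range(m.n_gestures):
                    emg = EMGRecording(_synth_emg(rng, envelopes[g], n_emg, cfg, g),
                                       EMG_RATE_HZ)
                    ev = EventStream(_synth_events(rng, templates[g], dur_ms, cfg),
                                     DVS_WIDTH, DVS_HEIGHT)
                    recordings.append(Recording(
                        emg=emg, dvs=ev, label=GESTURES[g],
                        subject=subject, session=session, repetition=rep))
    return recordings, m


# ---------------------------------------------------------------------------
# Separable toy spike dataset
# ---------------------------------------------------------------------------

def generate_separable_toy(n_classes: int = 2, seed: int = 0, n_channels: int = 10,
                           n_ticks: int = 50, n_per_class: int = 100,
                           rate_hi: float = 0.7, rate_lo: float = 0.02
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Rate-coded spike dataset with disjoint active channel sets per class.

    Returns (X, y): X is (n, channels, ticks) of 0/1 spikes; a linear
    readout on spike counts separates the classes by construction.
    """
    if n_channels < n_classes:
        raise ValidationError("need at least one channel per class")
    rng = np.random.default_rng(seed)
    per = n_channels // n_classes
    X = np.zeros((n_classes * n_per_class, n_channels, n_ticks))
    y = np.repeat(np.arange(n_classes), n_per_class)
    for k in range(n_classes):
        rows = slice(k * n_per_class, (k + 1) * n_per_class)
        rates = np.full(n_channels, rate_lo)
        rates[k * per:(k + 1) * per] = rate_hi
        X[rows] = (rng.random((n_per_class, n_channels, n_ticks))
                   < rates[None, :, None]).astype(np.float64)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]
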