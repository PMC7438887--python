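"""Cross-validation, accuracy-vs-duration curves, and run records.

The harness evaluates the crossbar (ODIN + MorphIC style) route: chunks
are reduced to per-channel spike counts (EMG delta-modulator UP/DOWN
counts; DVS cropped, quad-subsampled event counts), the quantized ANNs
are trained on those counts, and late fusion retrains a head on the
concatenated hidden activations.  Folds split by recording session.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from spikefuse.aer_io import GESTURES, GestureSample, ValidationError
from spikefuse.snn_training import QuantizedAnn, TrainConfig, train_quantized_ann
from spikefuse.spike_encoding import (
    DeltaModConfig,
    crop_events,
    delta_modulate,
    subsample_quad,
)

APS_FRAME_PERIOD_MS = 50.0  # 20 fps emulated frame camera

DEFAULT_DURATIONS_MS = (10.0, 25.0, 50.0, 100.0, 150.0, 200.0)


# ---------------------------------------------------------------------------
# Count-feature extraction
# ---------------------------------------------------------------------------

def emg_spike_counts(sample: GestureSample, cfg: DeltaModConfig,
                     duration_ms: Optional[float] = None) -> np.ndarray:
    """16-vector of UP/DOWN spike counts (channel 2c = UP, 2c+1 = DOWN)."""
    trains = delta_modulate(sample.emg, cfg)
    limit = (duration_ms if duration_ms is not None else sample.duration_ms) * 1000.0
    out = np.zeros(2 * trains.channels)
    for c in range(trains.channels):
        out[2 * c] = np.searchsorted(trains.up_times[c], limit, side="left")
        out[2 * c + 1] = np.searchsorted(trains.down_times[c], limit, side="left")
    return out


def dvs_quad_counts(sample: GestureSample, crop: int = 40,
                    duration_ms: Optional[float] = None) -> list[np.ndarray]:
    """Four 400-vectors of per-pixel event counts (polarity merged)."""
    ev = sample.dvs
    if duration_ms is not None:
        ev = ev.slice_time(0, int(duration_ms * 1000), rebase=False)
    cropped = crop_events(ev, crop)
    quads = subsample_quad(cropped)
    out = []
    for q in quads:
        img = np.zeros((q.height, q.width), dtype=np.float64)
        np.add.at(img, (q.y, q.x), 1)
        out.append(img.ravel())
    return out


@dataclass
class CountFeatures:
    """Per-sample count features for a whole dataset slice."""

    emg: np.ndarray              # (n, 16)
    dvs: list                    # 4 arrays (n, 400)
    y: np.ndarray                # (n,) class indices
    sessions: np.ndarray         # (n,)


def extract_count_features(samples: Sequence[GestureSample],
                           dm_cfg: DeltaModConfig = DeltaModConfig(),
                           duration_ms: Optional[float] = None) -> CountFeatures:
    emg = np.stack([emg_spike_counts(s, dm_cfg, duration_ms) for s in samples])
    quads = [dvs_quad_counts(s, duration_ms=duration_ms) for s in samples]
    dvs = [np.stack([q[k] for q in quads]) for k in range(4)]
    y = np.array([GESTURES.index(s.label) for s in samples])
    sessions = np.array([s.session for s in samples])
    return CountFeatures(emg, dvs, y, sessions)


# ---------------------------------------------------------------------------
# Trained model bundle (count route)
# ---------------------------------------------------------------------------

@dataclass
class CountModelBundle:
    """EMG MLP + four DVS subMLPs + fusion head trained on count features."""

    emg_ann: QuantizedAnn
    sub_anns: list
    fusion_head: QuantizedAnn
    emg_scale: np.ndarray
    dvs_scale: float

    def _emg_hidden(self, emg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        logits, acts = self.emg_ann.forward(emg / self.emg_scale)
        return logits, acts[-2]

    def _dvs_parts(self, dvs: list) -> tuple[np.ndarray, list]:
        logits_sum = 0.0
        hiddens = []
        for ann, x in zip(self.sub_anns, dvs):
            logits, acts = ann.forward(x / self.dvs_scale)
            logits_sum = logits_sum + logits
            hiddens.append(acts[-2])
        return logits_sum, hiddens

    def predict(self, feats: CountFeatures, modality: str) -> np.ndarray:
        if modality == "emg":
            return self._emg_hidden(feats.emg)[0].argmax(axis=1)
        if modality == "dvs":
            return self._dvs_parts(feats.dvs)[0].argmax(axis=1)
        if modality == "fusion":
            _, eh = self._emg_hidden(feats.emg)
            _, dh = self._dvs_parts(feats.dvs)
            H = np.concatenate([eh] + dh, axis=1)
            return self.fusion_head.forward(H)[0].argmax(axis=1)
        raise ValidationError(f"unknown modality {modality!r}")

    def accuracy(self, feats: CountFeatures, modality: str) -> float:
        return float(np.mean(self.predict(feats, modality) == feats.y))


def train_count_models(train: CountFeatures, cfg: TrainConfig) -> CountModelBundle:
    emg_scale = np.maximum(train.emg.std(axis=0), 1.0)
    dvs_scale = max(float(np.concatenate(train.dvs).std()), 1e-6)
    emg_ann = train_quantized_ann((16, 230, 5), ("int3", "int3"),
                                  (train.emg / emg_scale, train.y), cfg)
    sub_anns = [
        train_quantized_ann((400, 210, 5), ("binary", "binary"),
                            (x / dvs_scale, train.y),
                            replace(cfg, seed=cfg.seed + 1 + k))
        for k, x in enumerate(train.dvs)
    ]
    bundle = CountModelBundle(emg_ann, sub_anns, None, emg_scale, dvs_scale)
    _, eh = bundle._emg_hidden(train.emg)
    _, dh = bundle._dvs_parts(train.dvs)
    H = np.concatenate([eh] + dh, axis=1)
    bundle.fusion_head = train_quantized_ann(
        (H.shape[1], 5), ("int3",), (H, train.y),
        replace(cfg, seed=cfg.seed + 7))
    return bundle


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    per_fold: dict               # modality -> list of fold accuracies (%)
    mean: dict                   # modality -> mean accuracy (%)
    sd: dict                     # modality -> std over folds (%)
    fold_sessions: list
    bundles: list = field(default_factory=list)


def session_folds(sessions: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Deterministic partition of unique sessions into k held-out groups."""
    uniq = np.unique(sessions)
    if len(uniq) < k:
        raise ValidationError(f"need at least {k} sessions for {k}-fold CV, "
                              f"got {len(uniq)}")
    order = np.random.default_rng(seed).permutation(uniq)
    return [order[i::k] for i in range(k)]


def crossvalidate(samples: Sequence[GestureSample], k: int = 3, seed: int = 0,
                  cfg: Optional[TrainConfig] = None,
                  dm_cfg: DeltaModConfig = DeltaModConfig(),
                  features: Optional[CountFeatures] = None,
                  keep_bundles: bool = False) -> CVResult:
    """k-fold session-split CV of the count-route models.

    Each fold holds out one session group across all subjects; reports
    mean and standard deviation of accuracy (%) per modality.
    """
    cfg = cfg or TrainConfig(epochs=10, lr=0.01, seed=seed)
    feats = features if features is not None else extract_count_features(samples, dm_cfg)
    folds = session_folds(feats.sessions, k, seed)
    per_fold = {m: [] for m in ("emg", "dvs", "fusion")}
    bundles = []
    for held_out in folds:
        test_mask = np.isin(feats.sessions, held_out)
        tr = _subset(feats, ~test_mask)
        te = _subset(feats, test_mask)
        bundle = train_count_models(tr, cfg)
        for m in per_fold:
            per_fold[m].append(100.0 * bundle.accuracy(te, m))
        if keep_bundles:
            bundles.append(bundle)
    mean = {m: float(np.mean(v)) for m, v in per_fold.items()}
    sd = {m: float(np.std(v)) for m, v in per_fold.items()}
    return CVResult(per_fold, mean, sd, [f.tolist() for f in folds], bundles)


def _subset(f: CountFeatures, mask: np.ndarray) -> CountFeatures:
    return CountFeatures(f.emg[mask], [x[mask] for x in f.dvs],
                         f.y[mask], f.sessions[mask])


# ---------------------------------------------------------------------------
# Accuracy vs stimulus duration
# ---------------------------------------------------------------------------

def accuracy_vs_duration(bundle: CountModelBundle, samples: Sequence[GestureSample],
                         modality: str = "fusion",
                         durations_ms: Sequence[float] = DEFAULT_DURATIONS_MS,
                         dm_cfg: DeltaModConfig = DeltaModConfig(),
                         frame_period_ms: Optional[float] = None) -> dict[float, float]:
    """Accuracy (%) after truncating each sample's spikes to a duration.

    With ``frame_period_ms`` set (frame-camera baseline emulation) the
    curve holds NaN ("no prediction") for durations shorter than one frame
    period.
    """
    max_dur = min(s.duration_ms for s in samples)
    curve = {}
    for d in durations_ms:
        if d > max_dur:
            raise ValidationError(f"duration {d} ms exceeds sample length {max_dur} ms")
        if frame_period_ms is not None and d < frame_period_ms:
            curve[float(d)] = float("nan")
            continue
        feats = extract_count_features(samples, dm_cfg, duration_ms=d)
        curve[float(d)] = 100.0 * bundle.accuracy(feats, modality)
    return curve


# ---------------------------------------------------------------------------
# Run records
# ---------------------------------------------------------------------------

def run_record(config: dict, seed: int, metrics: dict, path=None) -> dict:
    """Assemble (and optionally write) a JSON run record with config hash."""
    blob = json.dumps(config, sort_keys=True, default=str)
    rec = {
        "config": config,
        "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16],
        "seed": seed,
        "metrics": metrics,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(rec, fh, indent=2, default=_json_default)
    return rec


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
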