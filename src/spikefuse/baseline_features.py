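"""Traditional-ML baseline path: MAV/RMS features and non-spiking nets.

Features are computed per channel over non-overlapping windows of T
samples (default 40 = 200 ms at 200 Hz) and concatenated MAV-block-first:
E(n) = [MAV_1..MAV_C, RMS_1..RMS_C].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from spikefuse.aer_io import EMGRecording, ValidationError
from spikefuse.spike_encoding import normalize_8bit
from spikefuse.snn_core import (
    ConvLayer,
    DenseLayer,
    FlattenLayer,
    NetworkSpec,
    NeuronConfig,
    PoolLayer,
    QuantSpec,
)

WINDOW_SAMPLES = 40  # 200 ms at 200 Hz


def mav(window: np.ndarray) -> float:
    """Mean absolute value of one channel window."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValidationError("empty feature window")
    return float(np.mean(np.abs(window)))


def rms(window: np.ndarray) -> float:
    """Root mean square of one channel window."""
    window = np.asarray(window, dtype=np.float64)
    if window.size == 0:
        raise ValidationError("empty feature window")
    return float(np.sqrt(np.mean(window ** 2)))


def feature_vector(rec: EMGRecording, window_index: int = 0,
                   window_samples: int = WINDOW_SAMPLES,
                   normalized: bool = False) -> np.ndarray:
    """E(n) for window n: per-channel MAV block then RMS block (length 2C).

    By default features are computed on the raw unitless values; set
    ``normalized`` to use the same (v-128)/128 map as the spike encoder.
    """
    start = window_index * window_samples
    end = start + window_samples
    if end > rec.n_samples:
        raise ValidationError(
            f"window {window_index} needs samples [{start}, {end}) "
            f"but recording has {rec.n_samples}")
    block = rec.samples[:, start:end].astype(np.float64)
    if normalized:
        block = normalize_8bit(block)
    mavs = np.mean(np.abs(block), axis=1)
    rmss = np.sqrt(np.mean(block ** 2, axis=1))
    return np.concatenate([mavs, rmss])


def all_feature_vectors(rec: EMGRecording, window_samples: int = WINDOW_SAMPLES,
                        normalized: bool = False) -> np.ndarray:
    """Stack E(n) for every complete window; shape (n_windows, 2C)."""
    n = rec.n_samples // window_samples
    return np.stack([feature_vector(rec, i, window_samples, normalized) for i in range(n)])


# ---------------------------------------------------------------------------
# Baseline (non-spiking) network topologies
# ---------------------------------------------------------------------------

@dataclass
class AnnSpec:
    """A small ReLU/softmax feedforward net described via snn_core layers.

    The layer containers are reused for their shapes/weights only; neuron
    configs are ignored in the rate-based forward pass.
    """

    spec: NetworkSpec

    def n_params(self) -> int:
        return self.spec.n_params()


def _float_dense(rng, out, inp, name):
    lif = NeuronConfig(threshold=1.0)
    return DenseLayer(rng.normal(0, 0.1, (out, inp)), lif, QuantSpec("float"), name=name)


def baseline_networks(rng: np.random.Generator | None = None) -> dict[str, NetworkSpec]:
    """Non-spiking counterparts of the chip networks.

    Frame inputs replace events: the CNN takes one gray-scale channel
    instead of two polarity channels; the subMLPs take 20x20 sub-sampled
    frames; the EMG nets take 16 MAV/RMS features.
    """
    rng = rng or np.random.default_rng(0)
    lif = NeuronConfig(threshold=1.0)
    q = QuantSpec("float")
    nets = {}
    nets["emg-mlp-230"] = NetworkSpec(
        name="emg-mlp-230",
        layers=[_float_dense(rng, 230, 16, "hidden"), _float_dense(rng, 5, 230, "output")],
        input_shape=(16,))
    nets["emg-mlp-128"] = NetworkSpec(
        name="emg-mlp-128",
        layers=[_float_dense(rng, 128, 16, "hidden1"),
                _float_dense(rng, 128, 128, "hidden2"),
                _float_dense(rng, 5, 128, "output")],
        input_shape=(16,))
    for k in range(4):
        nets[f"frame-submlp-{k}"] = NetworkSpec(
            name=f"frame-submlp-{k}",
            layers=[_float_dense(rng, 210, 400, "hidden"),
                    _float_dense(rng, 5, 210, "output")],
            input_shape=(400,))
    nets["frame-cnn"] = NetworkSpec(
        name="frame-cnn",
        layers=[
            ConvLayer(rng.normal(0, 0.1, (8, 1, 3, 3)), lif, q, name="conv1"),
            PoolLayer(name="pool1"),
            ConvLayer(rng.normal(0, 0.1, (16, 8, 3, 3)), lif, q, name="conv2"),
            PoolLayer(name="pool2"),
            ConvLayer(rng.normal(0, 0.1, (32, 16, 3, 3)), lif, q, name="conv3"),
            FlattenLayer(name="flatten"),
            _float_dense(rng, 512, 3200, "dense1"),
            _float_dense(rng, 5, 512, "output"),
        ],
        input_shape=(1, 40, 40))
    return nets
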