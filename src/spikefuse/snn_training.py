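"""Training paths for the chip networks.

Two routes:

* ``train_surrogate`` — backpropagation-through-time directly in the
  spiking domain for dense CUBA-LIF networks.  The hard spike function is
  replaced in the backward pass by an exponentially decaying escape-rate
  surrogate; forward passes use quantized weights (and rounded integer
  delays) while full-precision shadow variables receive the updates.
* ``train_quantized_ann`` + ``ann_to_snn`` — rate-based ReLU training with
  straight-through quantization (binary or 3-bit weights), then weight
  installation into a leak-free integrate-and-fire network with per-layer
  firing thresholds chosen by grid search.

``retrain_fusion_head`` retrains only the final 5-unit layer of a fusion
network on the concatenated penultimate spike counts; upstream weights are
bit-frozen.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import spearmanr

from spikefuse.aer_io import ValidationError
from spikefuse.snn_core import (
    MAX_DELAY,
    DenseLayer,
    NetworkSpec,
    NeuronConfig,
    QuantSpec,
    run_network,
)
from spikefuse.spike_encoding import SpikeRaster


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    lr: float = 0.01
    batch_size: int = 32
    seed: int = 0
    surrogate_width: float = 0.5    # escape-rate decay length in membrane units
    surrogate_scale: float = 1.0
    logit_scale: float = 0.25       # maps output spike counts to logits
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    train_delays: bool = True

    def __post_init__(self) -> None:
        if self.epochs <= 0:
            raise ValidationError("epochs must be positive")


@dataclass
class ThresholdSearchSpec:
    """Grid search data for ANN-to-SNN threshold balancing.

    ``hidden_grid`` x ``output_grid`` candidate thresholds are evaluated on
    the validation rasters; the candidate with the best accuracy wins, ties
    broken by hidden firing rate closest to ``target_hidden_rate`` (when
    given), enabling rate balancing across modalities.
    """

    hidden_grid: Sequence[float]
    output_grid: Sequence[float]
    rasters: list
    labels: np.ndarray
    target_hidden_rate: Optional[float] = None
    extra_ticks: int = 0

    def __post_init__(self) -> None:
        if not len(self.hidden_grid) or not len(self.output_grid):
            raise ValidationError("threshold grid must be non-empty")


def weights_digest(spec: NetworkSpec) -> str:
    """SHA-256 over every weight/delay array, branches included."""
    h = hashlib.sha256()
    for lyr in spec.iter_layers():
        if hasattr(lyr, "weights"):
            h.update(np.ascontiguousarray(lyr.weights).tobytes())
            if getattr(lyr, "delays", None) is not None:
                h.update(np.ascontiguousarray(lyr.delays).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Surrogate-gradient BPTT in the spiking domain
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, shape, cfg: TrainConfig):
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0
        self.cfg = cfg

    def step(self, grad: np.ndarray) -> np.ndarray:
        c = self.cfg
        self.t += 1
        self.m = c.beta1 * self.m + (1 - c.beta1) * grad
        self.v = c.beta2 * self.v + (1 - c.beta2) * grad ** 2
        mhat = self.m / (1 - c.beta1 ** self.t)
        vhat = self.v / (1 - c.beta2 ** self.t)
        return c.lr * mhat / (np.sqrt(vhat) + c.eps)


class _TrainLayer:
    """Shadow-variable dense spiking layer for BPTT."""

    def __init__(self, lyr: DenseLayer, cfg: TrainConfig):
        self.quant = lyr.quant
        self.neuron = lyr.neuron
        self.w_shadow = lyr.weights.astype(np.float64).copy()
        self.has_delays = lyr.delays is not None
        self.d_shadow = (lyr.delays.astype(np.float64).copy()
                         if self.has_delays else None)
        self.opt_w = _Adam(self.w_shadow.shape, cfg)
        self.opt_d = _Adam(self.w_shadow.shape, cfg) if self.has_delays else None
        self.cfg = cfg

    @property
    def qweights(self) -> np.ndarray:
        return self.quant.quantize(self.w_shadow)

    @property
    def int_delays(self) -> np.ndarray:
        return np.clip(np.round(self.d_shadow), 0, MAX_DELAY).astype(np.int64)

    def delay_groups(self):
        """[(d, mask)] with forward weights split by integer delay."""
        w = self.qweights
        if not self.has_delays:
            return [(0, w)]
        d_int = self.int_delays
        return [(int(d), w * (d_int == d)) for d in np.unique(d_int)]


def _shift(s: np.ndarray, lag: int) -> np.ndarray:
    """s[..., t - lag] with zeros before t=0 (s is (B, C, T))."""
    if lag <= 0:
        return s
    out = np.zeros_like(s)
    out[..., lag:] = s[..., :-lag]
    return out


def _layer_forward(tl: _TrainLayer, s_in: np.ndarray, smooth: bool = False):
    """Run one layer over all ticks; returns (spikes, cache)."""
    B, _, T = s_in.shape
    drive = np.zeros((B, tl.qweights.shape[0], T))
    for d, w in tl.delay_groups():
        drive += np.einsum("oc,bct->bot", w, _shift(s_in, 1 + d))
    cfg = tl.neuron
    a_i, a_v, theta = cfg.alpha_i, cfg.alpha_v, cfg.threshold
    N = drive.shape[1]
    i = np.zeros((B, N))
    v = np.zeros((B, N))
    I = np.zeros_like(drive)
    U = np.zeros_like(drive)
    S = np.zeros_like(drive)
    w_s = tl.cfg.surrogate_width
    for t in range(T):
        i = a_i * i + drive[..., t]
        u = a_v * v + i
        if smooth:
            s = expit((u - theta) / w_s)
        else:
            s = (u >= theta).astype(np.float64)
        v = u * (1.0 - s)
        I[..., t], U[..., t], S[..., t] = i, u, s
    return S, {"drive": drive, "I": I, "U": U, "S": S, "s_in": s_in}


def _surrogate_deriv(u: np.ndarray, cfg_train: TrainConfig, theta: float) -> np.ndarray:
    w = cfg_train.surrogate_width
    return cfg_train.surrogate_scale / (2.0 * w) * np.exp(-np.abs(u - theta) / w)


def _layer_backward(tl: _TrainLayer, cache: dict, dS: np.ndarray, smooth: bool = False):
    """BPTT through the CUBA recurrences; returns (dW, dDelay, dS_in)."""
    U, S, s_in = cache["U"], cache["S"], cache["s_in"]
    cfg = tl.neuron
    a_i, a_v, theta = cfg.alpha_i, cfg.alpha_v, cfg.threshold
    B, N, T = U.shape
    w_s = tl.cfg.surrogate_width
    dDrive = np.zeros((B, N, T))
    di = np.zeros((B, N))
    dv = np.zeros((B, N))
    for t in range(T - 1, -1, -1):
        u = U[..., t]
        s = S[..., t]
        if smooth:
            sg = expit((u - theta) / w_s)
            dsdu = sg * (1 - sg) / w_s
            du = dS[..., t] * dsdu + dv * ((1 - s) - u * dsdu)
        else:
            sg = _surrogate_deriv(u, tl.cfg, theta)
            # reset path treats the spike indicator as constant (detached)
            du = dS[..., t] * sg + dv * (1 - s)
        di = du + a_i * di
        dv = a_v * du
        dDrive[..., t] = di
    dW = np.zeros_like(tl.w_shadow)
    dS_in = np.zeros_like(s_in)
    dDel = np.zeros_like(tl.w_shadow) if tl.has_delays else None
    for d, w in tl.delay_groups():
        mask = (w != 0) if tl.has_delays else slice(None)
        s_lag = _shift(s_in, 1 + d)
        g = np.einsum("bot,bct->oc", dDrive, s_lag)
        if tl.has_delays:
            dW += g * (tl.int_delays == d)
        else:
            dW += g
        # route gradient back to inputs through this delay group
        dS_in += _shift_neg(np.einsum("oc,bot->bct", w, dDrive), 1 + d)
        if tl.has_delays:
            # d(drive)/d(delay) ~ -ds_in/dt at the delayed tick
            diff = _shift(s_in, 2 + d) - s_lag
            dDel += np.einsum("bot,bct->oc", dDrive, diff) * w
    return dW, dDel, dS_in


def _shift_neg(x: np.ndarray, lead: int) -> np.ndarray:
    out = np.zeros_like(x)
    out[..., :-lead] = x[..., lead:]
    return out


def _forward_all(layers, X, smooth=False):
    caches = []
    s = X
    for tl in layers:
        s, cache = _layer_forward(tl, s, smooth)
        caches.append(cache)
    return s, caches


def spike_count_loss(S_out: np.ndarray, y: np.ndarray, logit_scale: float):
    """Softmax cross-entropy on scaled output spike counts."""
    counts = S_out.sum(axis=2)
    logits = counts * logit_scale
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    dcounts = (p - np.eye(p.shape[1])[y]) * logit_scale / n
    dS = np.repeat(dcounts[:, :, None], S_out.shape[2], axis=2)
    return loss, dS, counts


def train_surrogate(spec: NetworkSpec, data, cfg: TrainConfig = TrainConfig()
                    ) -> NetworkSpec:
    """Train a dense spiking network with surrogate-gradient BPTT.

    ``data`` is (X, y) with X of shape (n, channels, ticks) spike counts.
    The forward pass uses quantized weights and integer delays; shadow
    variables carry the Adam updates; delays round to ticks each epoch.
    Returns a quantization-closed, trained copy of the spec.
    """
    if spec.chip_model != "loihi":
        raise ValidationError("surrogate training targets Loihi-model networks")
    if any(not isinstance(l, DenseLayer) for l in spec.layers):
        raise NotImplementedError("surrogate training supports dense layers only")
    X, y = data
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed)
    layers = [_TrainLayer(l, cfg) for l in spec.layers]
    n = len(y)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            S_out, caches = _forward_all(layers, X[idx])
            loss, dS, _ = spike_count_loss(S_out, y[idx], cfg.logit_scale)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: check thresholds/learning rate")
            for tl, cache in zip(reversed(layers), reversed(caches)):
                dW, dDel, dS = _layer_backward(tl, cache, dS)
                tl.w_shadow -= tl.opt_w.step(dW)
                if tl.has_delays and cfg.train_delays:
                    tl.d_shadow -= tl.opt_d.step(dDel)
                    tl.d_shadow = np.clip(tl.d_shadow, 0, MAX_DELAY)
        for tl in layers:  # integer tick constraint, applied every epoch
            if tl.has_delays:
                tl.d_shadow = tl.int_delays.astype(np.float64)
    new_layers = [
        DenseLayer(tl.qweights, l.neuron, l.quant,
                   delays=tl.int_delays if tl.has_delays else None, name=l.name)
        for tl, l in zip(layers, spec.layers)
    ]
    return NetworkSpec(name=spec.name, layers=new_layers, input_shape=spec.input_shape,
                       chip_model=spec.chip_model, trained=True)


def surrogate_accuracy(spec: NetworkSpec, X: np.ndarray, y: np.ndarray) -> float:
    """Batch spike-count argmax accuracy using the training forward pass."""
    cfg = TrainConfig()
    layers = [_TrainLayer(l, cfg) for l in spec.layers]
    S_out, _ = _forward_all(layers, np.asarray(X, dtype=np.float64))
    pred = S_out.sum(axis=2).argmax(axis=1)
    return float(np.mean(pred == np.asarray(y)))


# ---------------------------------------------------------------------------
# Quantization-aware ANN training (ODIN / MorphIC route)
# ---------------------------------------------------------------------------

@dataclass
class QuantizedAnn:
    """ReLU MLP with straight-through-quantized weights, ready for mapping."""

    weights: list            # full-precision shadows
    quants: list             # per-layer QuantSpec
    trained: bool = False

    def qweights(self) -> list:
        return [q.quantize(w) for w, q in zip(self.weights, self.quants)]

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list]:
        acts = [np.asarray(X, dtype=np.float64)]
        for k, w in enumerate(self.qweights()):
            z = acts[-1] @ w.T
            acts.append(np.maximum(z, 0.0) if k < len(self.weights) - 1 else z)
        return acts[-1], acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[0].argmax(axis=1)


def _softmax_ce(logits: np.ndarray, y: np.ndarray):
    logits = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    return loss, (p - np.eye(p.shape[1])[y]) / n


def train_quantized_ann(layer_sizes: Sequence[int], quant_kinds: Sequence[str],
                        data, cfg: TrainConfig = TrainConfig(),
                        scales: Optional[Sequence[float]] = None) -> QuantizedAnn:
    """Train a ReLU MLP with straight-through weight quantization.

    ``layer_sizes`` like (16, 230, 5); ``quant_kinds`` one kind per weight
    matrix.  Inputs are spike-count vectors per chunk.  Per-layer int
    scales are chosen from the initialization spread at training start.
    """
    X, y = data
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    rng = np.random.default_rng(cfg.seed)
    weights, quants, opts = [], [], []
    for k in range(len(layer_sizes) - 1):
        fan_in = layer_sizes[k]
        w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (layer_sizes[k + 1], fan_in))
        kind = quant_kinds[k]
        if kind in ("int3", "int8") and scales is None:
            scale = max(float(np.percentile(np.abs(w), 99)) / 3.0, 1e-6)
        else:
            scale = scales[k] if scales is not None else 1.0
        weights.append(w)
        quants.append(QuantSpec(kind, scale) if kind != "binary" else QuantSpec("binary"))
        opts.append(_Adam(w.shape, cfg))
    ann = QuantizedAnn(weights, quants)
    n = len(y)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits, acts = ann.forward(X[idx])
            loss, dz = _softmax_ce(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite loss in ANN training")
            qws = ann.qweights()
            for k in range(len(weights) - 1, -1, -1):
                a = acts[k]
                dW = dz.T @ a  # straight-through: gradient w.r.t. quantized = shadow
                if k > 0:
                    dz = (dz @ qws[k]) * (acts[k] > 0)
                weights[k] -= opts[k].step(dW)
                if quants[k].kind == "binary":
                    np.clip(weights[k], -1.0, 1.0, out=weights[k])
    ann.trained = True
    return ann


def ann_accuracy(ann: QuantizedAnn, X: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(ann.predict(X) == np.asarray(y)))


def ann_to_snn(ann: QuantizedAnn, search: ThresholdSearchSpec,
               chip_model: str = "none", name: str = "mapped",
               return_info: bool = False):
    """Install quantized ANN weights into a leak-free LIF net.

    Per-layer firing thresholds come from the grid search in ``search``:
    best validation accuracy wins, ties broken by mean hidden firing rate
    closest to ``target_hidden_rate``.  Raises if the network is silent at
    every grid point.
    """
    if not ann.trained:
        raise ValidationError("map a trained ANN only")
    qws = ann.qweights()
    best = None
    any_output = False
    for th_h, th_o in product(search.hidden_grid, search.output_grid):
        spec = _lif_from_weights(qws, ann.quants, th_h, th_o, chip_model, name)
        correct = 0
        hidden_total = 0.0
        out_total = 0.0
        for raster, label in zip(search.rasters, search.labels):
            res = run_network(spec, raster, extra_ticks=search.extra_ticks,
                              capture_penultimate=True)
            correct += int(res.decision == label)
            hidden_total += float(res.penultimate_counts.sum())
            out_total += float(res.counts.sum())
        acc = correct / len(search.labels)
        rate = hidden_total / (len(search.labels) * spec.penultimate_size)
        any_output = any_output or out_total > 0
        key = (acc, -abs(rate - search.target_hidden_rate)
               if search.target_hidden_rate is not None else 0.0)
        if best is None or key > best[0]:
            best = (key, spec, {"threshold_hidden": th_h, "threshold_output": th_o,
                                "accuracy": acc, "mean_hidden_rate": rate})
    if not any_output:
        raise ValidationError(
            "network silent at every grid point; extend the threshold grid downward")
    _, spec, info = best
    spec.trained = True
    return (spec, info) if return_info else spec


def _lif_from_weights(qws, quants, th_hidden, th_out, chip_model, name) -> NetworkSpec:
    layers = []
    for k, (w, q) in enumerate(zip(qws, quants)):
        th = th_out if k == len(qws) - 1 else th_hidden
        cfg = NeuronConfig(current_decay=4096, voltage_decay=0, threshold=th)
        layers.append(DenseLayer(w, cfg, q, name=f"dense{k}"))
    return NetworkSpec(name=name, layers=layers, input_shape=(qws[0].shape[1],),
                       chip_model=chip_model)


def snn_ann_rate_correlation(spec: NetworkSpec, ann: QuantizedAnn,
                             rasters: Sequence[SpikeRaster]) -> float:
    """Spearman correlation between SNN hidden spike counts and ANN hidden
    activations over validation samples (rate-mapping sanity check)."""
    snn_rates, ann_acts = [], []
    for raster in rasters:
        res = run_network(spec, raster, capture_penultimate=True)
        snn_rates.append(res.penultimate_counts)
        x = raster.flat().sum(axis=1)
        _, acts = ann.forward(x[None, :])
        ann_acts.append(acts[-2][0])
    rho = spearmanr(np.concatenate(snn_rates), np.concatenate(ann_acts)).statistic
    return float(rho)


# ---------------------------------------------------------------------------
# Fusion head retraining
# ---------------------------------------------------------------------------

def collect_penultimate_counts(fused: NetworkSpec, raster_inputs: Sequence,
                               extra_ticks: int = 0) -> np.ndarray:
    """Run the frozen upstream branches; stack concatenated hidden counts."""
    rows = [run_network(fused, r, extra_ticks=extra_ticks).penultimate_counts
            for r in raster_inputs]
    return np.stack(rows)


def retrain_fusion_head(fused: NetworkSpec, data, cfg: TrainConfig = TrainConfig()
                        ) -> NetworkSpec:
    """Retrain only the final dense layer of a fusion network.

    ``data`` is (H, y): concatenated penultimate spike counts per sample
    and labels.  Upstream branch weights are reused untouched (verify with
    :func:`weights_digest`).
    """
    H, y = data
    H = np.asarray(H, dtype=np.float64)
    head = fused.layers[-1]
    quant = head.quant
    width = head.in_features
    ann = train_quantized_ann((width, head.units), (quant.kind,), (H, y), cfg,
                              scales=None if quant.kind == "binary" else [quant.scale])
    new_head = DenseLayer(ann.qweights()[0], head.neuron, quant, name=head.name)
    out = NetworkSpec(name=fused.name, layers=[new_head], input_shape=fused.input_shape,
                      chip_model=fused.chip_model, branches=fused.branches,
                      combine=fused.combine)
    out.trained = True
    return out
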