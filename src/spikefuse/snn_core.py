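"""Discrete-time simulator for quantized spiking networks.

Neuron model: current-based leaky integrate-and-fire on a 1 ms tick grid.
Both state variables decay by the factor (4096 - d) / 4096 per tick::

    i[t] = i[t-1] * (4096 - current_decay) / 4096 + drive[t]
    v[t] = v[t-1] * (4096 - voltage_decay) / 4096 + i[t]
    spike iff v[t] >= threshold, then v resets to 0

Timing convention: dense and conv synapses add one tick of transport
latency, plus the per-synapse axonal delay (dense layers only); pooling
and flattening are instantaneous.  A spike leaving layer l at tick t
therefore reaches layer l+1's current at tick t + 1 + delay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import h5py
import numpy as np

from spikefuse.aer_io import ValidationError
from spikefuse.spike_encoding import SpikeRaster

DECAY_SCALE = 4096
MAX_DELAY = 63  # 6-bit axonal delays

GESTURE_CLASSES = 5


class ShapeError(ValidationError):
    """Layer shapes do not compose, or a raster does not match the input."""


# ---------------------------------------------------------------------------
# Neuron model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronConfig:
    """CUBA-LIF parameters; decays are integers in [0, 4096]."""

    current_decay: int = 1024
    voltage_decay: int = 1024
    threshold: float = 1.0
    refractory: int = 0

    def __post_init__(self) -> None:
        for name in ("current_decay", "voltage_decay"):
            d = getattr(self, name)
            if not 0 <= d <= DECAY_SCALE:
                raise ValidationError(f"{name} must be in [0, {DECAY_SCALE}]")
        if self.threshold <= 0:
            raise ValidationError("threshold must be positive")
        if self.refractory < 0:
            raise ValidationError("refractory must be >= 0")

    @property
    def alpha_i(self) -> float:
        return (DECAY_SCALE - self.current_decay) / DECAY_SCALE

    @property
    def alpha_v(self) -> float:
        return (DECAY_SCALE - self.voltage_decay) / DECAY_SCALE


@dataclass
class CubaState:
    """Per-neuron dynamic state (any array shape)."""

    i: np.ndarray
    v: np.ndarray
    refrac: np.ndarray

    @classmethod
    def zeros(cls, shape) -> "CubaState":
        return cls(np.zeros(shape), np.zeros(shape), np.zeros(shape, dtype=np.int64))


def cuba_step(state: CubaState, drive: np.ndarray, cfg: NeuronConfig) -> tuple[CubaState, np.ndarray]:
    """Advance one tick given the already-delayed weighted input ``drive``.

    Returns the new state and the binary spike array.  Neurons in their
    refractory window neither integrate voltage nor spike.
    """
    i = state.i * cfg.alpha_i + drive
    v = state.v * cfg.alpha_v + i
    active = state.refrac <= 0
    v = np.where(active, v, 0.0)
    spikes = (v >= cfg.threshold) & active
    v = np.where(spikes, 0.0, v)
    refrac = np.where(spikes, cfg.refractory, np.maximum(state.refrac - 1, 0))
    return CubaState(i, v, refrac), spikes.astype(np.float64)


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuantSpec:
    """Representable weight set: binary {-1,+1}; intN = signed ints x scale."""

    kind: str = "float"  # binary | int3 | int8 | float
    scale: float = 1.0

    _RANGES = {"int3": (-4, 3), "int8": (-128, 127)}

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "int3", "int8", "float"):
            raise ValidationError(f"unknown quantization kind {self.kind!r}")
        if self.scale <= 0:
            raise ValidationError("scale must be positive")

    def quantize(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=np.float64)
        if self.kind == "float":
            return w
        if self.kind == "binary":
            return np.where(w >= 0, 1.0, -1.0)
        lo, hi = self._RANGES[self.kind]
        return np.clip(np.round(w / self.scale), lo, hi) * self.scale

    def contains(self, w: np.ndarray) -> bool:
        return bool(np.allclose(self.quantize(w), w, rtol=0, atol=1e-12))


CHIP_QUANT = {"odin": "int3", "morphic": "binary", "loihi": "int8", "none": None}


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

@dataclass
class DenseLayer:
    """Fully connected spiking layer; optional per-synapse axonal delays."""

    weights: np.ndarray  # (out, in)
    neuron: NeuronConfig
    quant: QuantSpec = field(default_factory=QuantSpec)
    delays: Optional[np.ndarray] = None  # (out, in) int ticks in [0, 63]
    name: str = "dense"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 2:
            raise ShapeError(f"layer {self.name}: weights must be 2-D")
        if self.delays is not None:
            self.delays = np.asarray(self.delays, dtype=np.int64)
            if self.delays.shape != self.weights.shape:
                raise ShapeError(f"layer {self.name}: delays shape mismatch")
            if self.delays.min() < 0 or self.delays.max() > MAX_DELAY:
                raise ValidationError(f"layer {self.name}: delays outside [0, {MAX_DELAY}]")

    @property
    def units(self) -> int:
        return self.weights.shape[0]

    @property
    def in_features(self) -> int:
        return self.weights.shape[1]

    def out_shape(self, in_shape) -> tuple:
        if int(np.prod(in_shape)) != self.in_features:
            raise ShapeError(
                f"layer {self.name}: expected {self.in_features} inputs, got {np.prod(in_shape)}")
        return (self.units,)

    def n_params(self) -> int:
        return self.weights.size


@dataclass
class ConvLayer:
    """2-D convolution, square kernel, stride 1, zero padding (same)."""

    weights: np.ndarray  # (out_c, in_c, k, k)
    neuron: NeuronConfig
    quant: QuantSpec = field(default_factory=QuantSpec)
    name: str = "conv"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 4 or self.weights.shape[2] != self.weights.shape[3]:
            raise ShapeError(f"layer {self.name}: kernels must be (out, in, k, k) square")

    @property
    def units(self) -> int:
        return self.weights.shape[0]

    def out_shape(self, in_shape) -> tuple:
        if len(in_shape) != 3 or in_shape[0] != self.weights.shape[1]:
            raise ShapeError(f"layer {self.name}: expected {self.weights.shape[1]} input channels")
        return (self.weights.shape[0], in_shape[1], in_shape[2])

    def n_params(self) -> int:
        return self.weights.size


@dataclass
class PoolLayer:
    """2x2 max pool on per-tick spike indicators (logical OR)."""

    size: int = 2
    name: str = "pool"

    def out_shape(self, in_shape) -> tuple:
        if len(in_shape) != 3:
            raise ShapeError(f"layer {self.name}: pooling expects (C, H, W) input")
        return (in_shape[0], in_shape[1] // self.size, in_shape[2] // self.size)

    def n_params(self) -> int:
        return 0


@dataclass
class FlattenLayer:
    name: str = "flatten"

    def out_shape(self, in_shape) -> tuple:
        return (int(np.prod(in_shape)),)

    def n_params(self) -> int:
        return 0


Layer = Union[DenseLayer, ConvLayer, PoolLayer, FlattenLayer]


# ---------------------------------------------------------------------------
# Network specification
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """A quantized layered SNN, possibly an ensemble of parallel branches.

    For branch ensembles ``layers`` holds the (possibly empty) head applied
    after combining branches; ``combine`` is ``sum_outputs`` (class scores
    added) or ``concat_hidden`` (branch penultimate layers concatenated).
    """

    name: str
    layers: list
    input_shape: tuple
    chip_model: str = "none"
    trained: bool = False
    branches: Optional[list] = None
    combine: Optional[str] = None

    def __post_init__(self) -> None:
        if self.chip_model not in CHIP_QUANT:
            raise ValidationError(f"unknown chip model {self.chip_model!r}")
        want = CHIP_QUANT[self.chip_model]
        for lyr in self.iter_layers():
            if want is not None and hasattr(lyr, "quant") and lyr.quant.kind != want:
                raise ValidationError(
                    f"{self.name}: chip {self.chip_model} requires {want} weights "
                    f"but layer {lyr.name} uses {lyr.quant.kind}")
        self.validate_shapes()

    def iter_layers(self):
        if self.branches:
            for b in self.branches:
                yield from b.iter_layers()
        yield from self.layers

    def validate_shapes(self) -> None:
        if self.branches:
            for b in self.branches:
                b.validate_shapes()
            if self.combine not in ("sum_outputs", "concat_hidden", "fusion_concat"):
                raise ValidationError(f"{self.name}: unknown combine rule {self.combine!r}")
            if self.combine == "sum_outputs":
                outs = {b.output_size for b in self.branches}
                if len(outs) != 1:
                    raise ShapeError(f"{self.name}: branch output sizes differ")
            shape: tuple = (self.combined_width(),)
        else:
            shape = tuple(self.input_shape)
        for lyr in self.layers:
            shape = lyr.out_shape(shape)

    def combined_width(self) -> int:
        if self.combine == "sum_outputs":
            return self.branches[0].output_size
        return sum(b.penultimate_size for b in self.branches)

    @property
    def output_size(self) -> int:
        if self.layers:
            last = self.layers[-1]
            return last.units if hasattr(last, "units") else int(np.prod(
                last.out_shape(self._shape_before(len(self.layers) - 1))))
        if self.branches and self.combine == "sum_outputs":
            return self.branches[0].output_size
        raise ValidationError(f"{self.name}: no output layer")

    def _shape_before(self, k: int) -> tuple:
        shape: tuple = ((self.combined_width(),) if self.branches
                        else tuple(self.input_shape))
        for lyr in self.layers[:k]:
            shape = lyr.out_shape(shape)
        return shape

    @property
    def penultimate_size(self) -> int:
        """Width of the layer feeding the final (output) layer."""
        if self.branches and not self.layers:
            # ensemble without a head: fusion taps the branch hidden layers
            return sum(b.penultimate_size for b in self.branches)
        if len(self.layers) >= 2:
            return int(np.prod(self._shape_before(len(self.layers) - 1)))
        if self.branches:
            return self.combined_width()
        return int(np.prod(self.input_shape))

    def hidden_and_output_units(self) -> int:
        """Neuron count of all spiking layers (hidden + output)."""
        return sum(lyr.units for lyr in self.iter_layers() if hasattr(lyr, "units"))

    def n_params(self) -> int:
        return sum(lyr.n_params() for lyr in self.iter_layers())

    def is_quantized(self) -> bool:
        return all(lyr.quant.contains(lyr.weights)
                   for lyr in self.iter_layers() if hasattr(lyr, "quant"))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

class _DenseState:
    def __init__(self, lyr: DenseLayer):
        self.lyr = lyr
        self.state = CubaState.zeros(lyr.units)
        maxd = int(lyr.delays.max()) if lyr.delays is not None else 0
        self.hist = np.zeros((maxd + 2, lyr.in_features))  # ring buffer of inputs
        self.ptr = 0
        self._groups = [(int(d), lyr.weights * (lyr.delays == d))
                        for d in np.unique(lyr.delays)]

    def step(self, in_spikes: np.ndarray) -> np.ndarray:
        # record input, then read back with 1-tick transport + axonal delay
        n = len(self.hist)
        self.hist[self.ptr] = in_spikes.ravel()
        drive = np.zeros(self.lyr.units)
        for d, w in self._groups:
            drive += w @ self.hist[(self.ptr - 1 - d) % n]
        self.ptr = (self.ptr + 1) % n
        self.state, spikes = cuba_step(self.state, drive, self.lyr.neuron)
        return spikes


class _DenseStateNoDelay:
    """Fast path: no axonal delays, only the 1-tick transport latency."""

    def __init__(self, lyr: DenseLayer):
        self.lyr = lyr
        self.state = CubaState.zeros(lyr.units)
        self.prev = np.zeros(lyr.in_features)

    def step(self, in_spikes: np.ndarray) -> np.ndarray:
        drive = self.lyr.weights @ self.prev
        self.prev = in_spikes.ravel().astype(np.float64)
        self.state, spikes = cuba_step(self.state, drive, self.lyr.neuron)
        return spikes


class _ConvState:
    def __init__(self, lyr: ConvLayer, in_shape):
        self.lyr = lyr
        self.out = lyr.out_shape(in_shape)
        self.state = CubaState.zeros(self.out)
        self.prev = np.zeros(in_shape)

    def step(self, in_spikes: np.ndarray) -> np.ndarray:
        drive = conv2d_same(self.prev, self.lyr.weights)
        self.prev = np.asarray(in_spikes, dtype=np.float64)
        self.state, spikes = cuba_step(self.state, drive, self.lyr.neuron)
        return spikes


def conv2d_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Correlate (C, H, W) input with (O, C, k, k) kernels, zero 'same' pad."""
    k = w.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    return np.einsum("chwij,ocij->ohw", win, w)


def pool_spikes(x: np.ndarray, size: int = 2) -> np.ndarray:
    """OR of spike indicators over non-overlapping size x size windows."""
    c, h, w = x.shape
    h2, w2 = h // size, w // size
    xv = x[:, :h2 * size, :w2 * size].reshape(c, h2, size, w2, size)
    return (xv.max(axis=(2, 4)) > 0).astype(np.float64)


def _make_state(lyr, in_shape):
    if isinstance(lyr, DenseLayer):
        if lyr.delays is None or (lyr.delays.size and lyr.delays.max() == 0) or lyr.delays.size == 0:
            return _DenseStateNoDelay(lyr)
        return _DenseState(lyr)
    if isinstance(lyr, ConvLayer):
        return _ConvState(lyr, in_shape)
    return lyr  # stateless


class LayerStack:
    """Stateful tick-by-tick executor for a plain (branchless) layer list."""

    def __init__(self, layers: Sequence[Layer], input_shape: tuple):
        self.layers = list(layers)
        self.states = []
        shape = tuple(input_shape)
        for lyr in self.layers:
            self.states.append(_make_state(lyr, shape))
            shape = lyr.out_shape(shape)
        self.output_shape = shape

    def step(self, in_spikes: np.ndarray, start: int = 0,
             stop: Optional[int] = None) -> np.ndarray:
        x = np.asarray(in_spikes, dtype=np.float64)
        stop = len(self.layers) if stop is None else stop
        for lyr, st in zip(self.layers[start:stop], self.states[start:stop]):
            if isinstance(lyr, PoolLayer):
                x = pool_spikes(x, lyr.size)
            elif isinstance(lyr, FlattenLayer):
                x = x.ravel()
            else:
                x = st.step(x)
        return x

    def final_voltage(self) -> np.ndarray:
        return self.states[-1].state.v


@dataclass
class RunResult:
    """Classification readout of one simulated inference."""

    counts: np.ndarray          # cumulative output spikes per class
    trace: np.ndarray           # classes x ticks output spikes
    decision: int
    final_v: np.ndarray
    penultimate_counts: Optional[np.ndarray] = None


def _decide(counts: np.ndarray, final_v: np.ndarray) -> int:
    best = counts.max()
    cand = np.flatnonzero(counts == best)
    if len(cand) == 1:
        return int(cand[0])
    vbest = final_v[cand].max()
    cand = cand[final_v[cand] == vbest]
    return int(cand[0])


def _input_at(raster_counts: np.ndarray, t: int) -> np.ndarray:
    return raster_counts[..., t] if t < raster_counts.shape[-1] else \
        np.zeros(raster_counts.shape[:-1])


def _flatten_rasters(raster) -> list:
    if isinstance(raster, (list, tuple)):
        out = []
        for r in raster:
            out.extend(_flatten_rasters(r))
        return out
    return [raster]


class _BranchRunner:
    """Tick-by-tick executor of a (possibly nested) branch, tapped at its
    penultimate layer."""

    def __init__(self, spec: NetworkSpec, raster):
        self.spec = spec
        if spec.branches is not None:
            rasters = list(raster) if isinstance(raster, (list, tuple)) else [raster]
            if len(rasters) != len(spec.branches):
                raise ShapeError(f"{spec.name}: expected {len(spec.branches)} input "
                                 f"rasters, got {len(rasters)}")
            self.children = [_BranchRunner(b, r) for b, r in zip(spec.branches, rasters)]
        else:
            _check_input(spec, raster)
            self.children = None
            self.stack = LayerStack(spec.layers, spec.input_shape)
            self.counts_in = raster.counts.reshape(
                tuple(spec.input_shape) + (raster.n_ticks,))

    def penultimate_step(self, t: int) -> np.ndarray:
        if self.children is not None:
            return np.concatenate([c.penultimate_step(t) for c in self.children])
        x = _input_at(self.counts_in, t)
        return np.ravel(self.stack.step(x, stop=len(self.spec.layers) - 1))


def run_network(spec: NetworkSpec, raster, extra_ticks: int = 0,
                capture_penultimate: bool = False) -> RunResult:
    """Simulate one inference; decision = argmax of cumulative output counts.

    ``raster`` is a SpikeRaster for plain networks, or a (possibly nested)
    sequence of SpikeRasters matching the branch structure for ensembles
    and fusion networks.  Ties break on larger final membrane potential,
    then lowest class index.  Deterministic given spec and raster.
    """
    if spec.branches is None:
        return _run_plain(spec, raster, extra_ticks, capture_penultimate)
    rasters = list(raster) if isinstance(raster, (list, tuple)) else [raster]
    if len(rasters) != len(spec.branches):
        raise ShapeError(f"{spec.name}: expected {len(spec.branches)} input rasters, "
                         f"got {len(rasters)}")

    if spec.combine == "sum_outputs":
        results = [run_network(b, r, extra_ticks) for b, r in zip(spec.branches, rasters)]
        counts = np.sum([r.counts for r in results], axis=0)
        trace = np.sum([r.trace for r in results], axis=0)
        final_v = np.sum([r.final_v for r in results], axis=0)
        return RunResult(counts, trace, _decide(counts, final_v), final_v)

    # concat_hidden / fusion_concat: branch penultimate spikes feed the head
    n_ticks = max(r.n_ticks for r in _flatten_rasters(rasters)) + extra_ticks
    runners = [_BranchRunner(b, r) for b, r in zip(spec.branches, rasters)]
    width = spec.combined_width()
    head = LayerStack(spec.layers, (width,)) if spec.layers else None
    out_size = spec.output_size if head is not None else width
    trace = np.zeros((out_size, n_ticks))
    pen_counts = np.zeros(width)
    for t in range(n_ticks):
        h = np.concatenate([r.penultimate_step(t) for r in runners])
        pen_counts += h
        out = head.step(h) if head is not None else h
        trace[:, t] = out
    counts = trace.sum(axis=1)
    final_v = head.final_voltage() if head is not None else np.zeros(out_size)
    return RunResult(counts, trace, _decide(counts, final_v), final_v,
                     penultimate_counts=pen_counts)


def _check_input(spec: NetworkSpec, raster: SpikeRaster) -> None:
    got = int(np.prod(raster.counts.shape[:-1]))
    want = int(np.prod(spec.input_shape))
    if got != want:
        raise ShapeError(f"{spec.name}: raster has {got} channels, input layer expects {want}")


def _run_plain(spec: NetworkSpec, raster: SpikeRaster, extra_ticks: int = 0,
               capture_penultimate: bool = False) -> RunResult:
    _check_input(spec, raster)
    counts_in = raster.counts.reshape(tuple(spec.input_shape) + (raster.n_ticks,))
    n_ticks = raster.n_ticks + extra_ticks
    stack = LayerStack(spec.layers, spec.input_shape)
    out_size = spec.output_size
    trace = np.zeros((out_size, n_ticks))
    pen = np.zeros(spec.penultimate_size) if capture_penultimate else None
    n_layers = len(spec.layers)
    for t in range(n_ticks):
        x = _input_at(counts_in, t)
        if capture_penultimate:
            h = stack.step(x, stop=n_layers - 1)
            pen += np.ravel(h)
            out = stack.step(h, start=n_layers - 1)
        else:
            out = stack.step(x)
        trace[:, t] = np.ravel(out)
    counts = trace.sum(axis=1)
    final_v = stack.final_voltage()
    return RunResult(counts, trace, _decide(counts, final_v), final_v,
                     penultimate_counts=pen)


# ---------------------------------------------------------------------------
# Fusion and ensembles
# ---------------------------------------------------------------------------

def build_fusion(net_a: NetworkSpec, net_b: NetworkSpec,
                 output_quant: QuantSpec, neuron: Optional[NeuronConfig] = None,
                 n_classes: int = GESTURE_CLASSES, chip_model: str = "none",
                 rng: Optional[np.random.Generator] = None,
                 name: str = "fusion") -> NetworkSpec:
    """Concatenate two trained nets' penultimate layers under a fresh head.

    Upstream weights are shared (frozen by convention: only the head is
    retrained).  The head input width is the sum of the two penultimate
    sizes.
    """
    for net in (net_a, net_b):
        if not net.trained:
            raise ValidationError(f"cannot fuse untrained network {net.name!r}")
    width = net_a.penultimate_size + net_b.penultimate_size
    rng = rng or np.random.default_rng(0)
    w = output_quant.quantize(rng.normal(0, output_quant.scale, (n_classes, width)))
    neuron = neuron or NeuronConfig(current_decay=1024, voltage_decay=128, threshold=64.0)
    head = DenseLayer(w, neuron, output_quant, name=f"{name}_head")
    return NetworkSpec(name=name, layers=[head], input_shape=(width,),
                       chip_model=chip_model, branches=[net_a, net_b],
                       combine="fusion_concat")


def submlp_ensemble(streams: Sequence[SpikeRaster], branches: Sequence[NetworkSpec],
                    mode: str = "sum_outputs", extra_ticks: int = 0):
    """Run four subMLP branches on their four phase streams.

    ``sum_outputs`` returns a RunResult with summed class scores;
    ``concat_hidden`` returns the concatenated per-branch hidden spike
    counts (width = sum of branch hidden sizes).
    """
    if len(streams) != 4 or len(branches) != 4:
        raise ValidationError("subMLP ensemble requires exactly 4 streams and 4 branches")
    if mode == "sum_outputs":
        results = [_run_plain(b, r, extra_ticks) for b, r in zip(branches, streams)]
        counts = np.sum([r.counts for r in results], axis=0)
        trace = np.sum([r.trace for r in results], axis=0)
        final_v = np.sum([r.final_v for r in results], axis=0)
        return RunResult(counts, trace, _decide(counts, final_v), final_v)
    if mode == "concat_hidden":
        results = [_run_plain(b, r, extra_ticks, capture_penultimate=True)
                   for b, r in zip(branches, streams)]
        return np.concatenate([r.penultimate_counts for r in results])
    raise ValidationError(f"unknown ensemble mode {mode!r}")


# ---------------------------------------------------------------------------
# Reference architectures
# ---------------------------------------------------------------------------

def _rand_quant(rng, shape, quant: QuantSpec) -> np.ndarray:
    return quant.quantize(rng.normal(0.0, 2.0 * quant.scale, shape))


def emg_odin_spec(rng: Optional[np.random.Generator] = None,
                  thresholds=(8.0, 32.0)) -> NetworkSpec:
    """16-230-5 MLP with 3-bit weights on a single 256-neuron core."""
    rng = rng or np.random.default_rng(0)
    q = QuantSpec("int3", scale=1.0)
    lif = lambda th: NeuronConfig(current_decay=DECAY_SCALE, voltage_decay=0, threshold=th)
    return NetworkSpec(
        name="emg-odin",
        layers=[
            DenseLayer(_rand_quant(rng, (230, 16), q), lif(thresholds[0]), q, name="hidden"),
            DenseLayer(_rand_quant(rng, (5, 230), q), lif(thresholds[1]), q, name="output"),
        ],
        input_shape=(16,), chip_model="odin")


def dvs_morphic_branch(rng: Optional[np.random.Generator] = None,
                       thresholds=(48.0, 96.0), index: int = 0) -> NetworkSpec:
    """One 400-210-5 binary-weight subMLP (a 20x20 phase stream)."""
    rng = rng or np.random.default_rng(0)
    q = QuantSpec("binary")
    lif = lambda th: NeuronConfig(current_decay=DECAY_SCALE, voltage_decay=0, threshold=th)
    return NetworkSpec(
        name=f"dvs-morphic-sub{index}",
        layers=[
            DenseLayer(_rand_quant(rng, (210, 400), q), lif(thresholds[0]), q, name="hidden"),
            DenseLayer(_rand_quant(rng, (5, 210), q), lif(thresholds[1]), q, name="output"),
        ],
        input_shape=(400,), chip_model="morphic")


def dvs_morphic_spec(rng: Optional[np.random.Generator] = None,
                     thresholds=(48.0, 96.0)) -> NetworkSpec:
    """Four 400-210-5 binary subMLPs whose class scores are summed."""
    rng = rng or np.random.default_rng(0)
    branches = [dvs_morphic_branch(rng, thresholds, k) for k in range(4)]
    return NetworkSpec(name="dvs-morphic", layers=[], input_shape=(400,),
                       chip_model="morphic", branches=branches, combine="sum_outputs")


def emg_loihi_spec(rng: Optional[np.random.Generator] = None,
                   decay: int = 1024, threshold: float = 64.0) -> NetworkSpec:
    """16-128d-128d-5 MLP, 8-bit weights and trainable 6-bit axonal delays."""
    rng = rng or np.random.default_rng(0)
    q = QuantSpec("int8", scale=2.0)
    cfg = NeuronConfig(current_decay=decay, voltage_decay=decay, threshold=threshold)
    def dense(out, inp, name):
        return DenseLayer(_rand_quant(rng, (out, inp), q), cfg, q,
                          delays=np.zeros((out, inp), dtype=np.int64), name=name)
    return NetworkSpec(
        name="emg-loihi",
        layers=[dense(128, 16, "hidden1"), dense(128, 128, "hidden2"),
                dense(5, 128, "output")],
        input_shape=(16,), chip_model="loihi")


def dvs_loihi_cnn_spec(rng: Optional[np.random.Generator] = None,
                       current_decay: int = 1024, voltage_decay: int = 128,
                       threshold: float = 64.0) -> NetworkSpec:
    """40x40x2-8c3-2p-16c3-2p-32c3-512-5 CNN with 8-bit weights."""
    rng = rng or np.random.default_rng(0)
    q = QuantSpec("int8", scale=0.5)
    cfg = NeuronConfig(current_decay=current_decay, voltage_decay=voltage_decay,
                       threshold=threshold)
    return NetworkSpec(
        name="dvs-loihi-cnn",
        layers=[
            ConvLayer(_rand_quant(rng, (8, 2, 3, 3), q), cfg, q, name="conv1"),
            PoolLayer(name="pool1"),
            ConvLayer(_rand_quant(rng, (16, 8, 3, 3), q), cfg, q, name="conv2"),
            PoolLayer(name="pool2"),
            ConvLayer(_rand_quant(rng, (32, 16, 3, 3), q), cfg, q, name="conv3"),
            FlattenLayer(name="flatten"),
            DenseLayer(_rand_quant(rng, (512, 3200), q), cfg, q, name="dense1"),
            DenseLayer(_rand_quant(rng, (5, 512), q), cfg, q, name="output"),
        ],
        input_shape=(2, 40, 40), chip_model="loihi")


# ---------------------------------------------------------------------------
# Serialization: structure as JSON/YAML, weights as HDF5
# ---------------------------------------------------------------------------

def _layer_meta(lyr) -> dict:
    meta: dict = {"name": lyr.name, "kind": type(lyr).__name__}
    if hasattr(lyr, "neuron"):
        n = lyr.neuron
        meta["neuron"] = {"current_decay": n.current_decay, "voltage_decay": n.voltage_decay,
                          "threshold": n.threshold, "refractory": n.refractory}
        meta["quant"] = {"kind": lyr.quant.kind, "scale": lyr.quant.scale}
    if isinstance(lyr, PoolLayer):
        meta["size"] = lyr.size
    return meta


def save_network(spec: NetworkSpec, path_prefix: str) -> None:
    """Write ``<prefix>.json`` (structure) and ``<prefix>.h5`` (weights)."""
    def describe(s: NetworkSpec) -> dict:
        return {
            "name": s.name, "input_shape": list(s.input_shape),
            "chip_model": s.chip_model, "trained": s.trained,
            "combine": s.combine,
            "layers": [_layer_meta(l) for l in s.layers],
            "branches": [describe(b) for b in s.branches] if s.branches else None,
        }
    with open(f"{path_prefix}.json", "w") as fh:
        json.dump(describe(spec), fh, indent=2)
    with h5py.File(f"{path_prefix}.h5", "w") as fh:
        def dump(s: NetworkSpec, g) -> None:
            for i, lyr in enumerate(s.layers):
                if hasattr(lyr, "weights"):
                    g.create_dataset(f"layer{i}_weights", data=lyr.weights)
                    if getattr(lyr, "delays", None) is not None:
                        g.create_dataset(f"layer{i}_delays", data=lyr.delays)
            if s.branches:
                for j, b in enumerate(s.branches):
                    dump(b, g.create_group(f"branch{j}"))
        dump(spec, fh)


def load_network(path_prefix: str) -> NetworkSpec:
    with open(f"{path_prefix}.json") as fh:
        meta = json.load(fh)
    with h5py.File(f"{path_prefix}.h5", "r") as fh:
        def build(m: dict, g) -> NetworkSpec:
            layers = []
            for i, lm in enumerate(m["layers"]):
                kind = lm["kind"]
                if kind in ("DenseLayer", "ConvLayer"):
                    n = NeuronConfig(**lm["neuron"])
                    q = QuantSpec(**lm["quant"])
                    w = np.asarray(g[f"layer{i}_weights"])
                    if kind == "DenseLayer":
                        d = (np.asarray(g[f"layer{i}_delays"])
                             if f"layer{i}_delays" in g else None)
                        layers.append(DenseLayer(w, n, q, delays=d, name=lm["name"]))
                    else:
                        layers.append(ConvLayer(w, n, q, name=lm["name"]))
                elif kind == "PoolLayer":
                    layers.append(PoolLayer(size=lm.get("size", 2), name=lm["name"]))
                else:
                    layers.append(FlattenLayer(name=lm["name"]))
            branches = ([build(bm, g[f"branch{j}"]) for j, bm in enumerate(m["branches"])]
                        if m.get("branches") else None)
            return NetworkSpec(name=m["name"], layers=layers,
                               input_shape=tuple(m["input_shape"]),
                               chip_model=m["chip_model"], trained=m["trained"],
                               branches=branches, combine=m.get("combine"))
        return build(meta, fh)
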