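# spikefuse

A tested library and CLI for fully neuromorphic hand-gesture recognition
from two complementary sensors: surface EMG (8 channels, 200 Hz, unsigned
8-bit) and an event camera (AER records: microsecond timestamp, x, y,
polarity). It covers the whole pipeline:

- **`aer_io`** — event-stream / EMG / manifest I/O (CSV and HDF5) and
  cutting 2 s recordings into aligned 200 ms chunks.
- **`spike_encoding`** — delta-modulator encoding of EMG into UP/DOWN
  spike trains (threshold 0.05 on the normalized signal, interpolation
  factor 3500), event cropping to 40×40, quad subsampling to four 20×20
  phase streams, and rasterization onto a 1 ms tick grid.
- **`snn_core`** — a discrete-time simulator for quantized spiking nets:
  CUBA leaky integrate-and-fire neurons with integer decays out of 4096,
  dense/conv/pool layers, 6-bit axonal delays, subMLP ensembles, and
  penultimate-layer fusion graphs. Reference architectures included:
  16-230-5 (3-bit weights), four 400-210-5 binary subMLPs, 16-128d-128d-5
  (8-bit weights, trainable delays), and the
  40x40x2-8c3-2p-16c3-2p-32c3-512-5 CNN.
- **`snn_training`** — surrogate-gradient BPTT in the spiking domain
  (escape-rate surrogate, shadow-variable quantization, delay gradients),
  quantization-aware ReLU training with straight-through binary/3-bit
  weights, ANN-to-SNN mapping with threshold-balancing grid search, and
  fusion-head retraining with bit-frozen upstream weights.
- **`baseline_features`** — MAV/RMS feature extraction over 40-sample
  windows and the non-spiking baseline topologies.
- **`hardware_cost`** — analytic chip cost model: crossbar SOP accounting
  (total vs useful synaptic operations, single-SOP AER remap for fusion),
  dynamic power `E_SOP × r_SOP`, energy, processing time, energy-delay
  product, and chip utilization. Presets: a 256-neuron single-core chip
  (8.4 pJ/SOP, 75 MHz) and a 4×512-neuron quad-core chip (30 pJ/SOP,
  55 MHz), two clock cycles per SOP.
- **`synthetic_data`** — seeded synthetic campaigns mirroring the dataset
  structure (21 subjects × 3 sessions × 5 repetitions × 5 gestures × 10
  chunks = 15,750 samples) with gesture-dependent EMG envelopes and
  moving hand-edge event clouds, plus a linearly separable rate-coded toy
  set for training tests.
- **`evaluation`** — session-split k-fold cross-validation,
  accuracy-vs-stimulus-duration curves (with a 20 fps frame-camera
  baseline emulation that yields no prediction below one frame period),
  and JSON run records.

Everything is NumPy/SciPy; no GPU or deep-learning framework is required.

## CLI

```bash
spikefuse simulate --out data.h5 --seed 7 --subjects 2 --difficulty 0.8
spikefuse encode --emg emg.csv --threshold 0.05 --interp 3500 --out spikes.csv
spikefuse features --emg emg.csv --window 40 --out feats.csv
spikefuse evaluate --data data.h5 --folds 3 --epochs 10 --seed 0 --report run.json
spikefuse cost --chip morphic --in-spikes 1200 --hidden-spikes 300 --report cost.json
```

`evaluate` runs the crossbar-route pipeline: delta-modulator spike counts
and quad event counts feed quantized ANNs (3-bit EMG MLP, four binary
subMLPs), and a retrained 1,070-wide fusion head combines the hidden
layers.

## File formats

- Event CSV: line `width,height`, a line with the two values, line
  `t_us,x,y,p`, then one event per row. Coordinates are 0-based, x =
  column, y = row, origin top-left; polarity 1 = ON, 0 = OFF.
- EMG CSV: line `rate_hz`, a line with the rate, then one row of 8
  integers per sample.
- HDF5: one group per recording with datasets `emg` (8 × T uint8) and
  `events` (N × 4 int64), attrs `rate`, `width`, `height`, `label`,
  `subject`, `session`, `repetition`.
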