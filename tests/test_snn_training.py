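import numpy as np
import pytest

from spikefuse.aer_io import ValidationError
from spikefuse.snn_core import (
    DenseLayer,
    NetworkSpec,
    NeuronConfig,
    QuantSpec,
    build_fusion,
    emg_loihi_spec,
    run_network,
)
from spikefuse.snn_training import (
    QuantizedAnn,
    ThresholdSearchSpec,
    TrainConfig,
    _TrainLayer,
    _forward_all,
    _layer_backward,
    ann_accuracy,
    ann_to_snn,
    collect_penultimate_counts,
    retrain_fusion_head,
    snn_ann_rate_correlation,
    spike_count_loss,
    surrogate_accuracy,
    train_quantized_ann,
    train_surrogate,
    weights_digest,
)
from spikefuse.spike_encoding import SpikeRaster
from spikefuse.synthetic_data import generate_separable_toy


def _toy_loihi_spec(rng, sizes=(10, 20, 2), delays=True, scale=0.05,
                    threshold=1.0):
    q = QuantSpec("int8", scale)
    cfg = NeuronConfig(current_decay=1024, voltage_decay=1024, threshold=threshold)
    layers = []
    for k in range(len(sizes) - 1):
        w = q.quantize(rng.normal(0, 0.3, (sizes[k + 1], sizes[k])))
        d = np.zeros((sizes[k + 1], sizes[k]), dtype=np.int64) if delays else None
        layers.append(DenseLayer(w, cfg, q, delays=d, name=f"d{k}"))
    return NetworkSpec("toy-loihi", layers, (sizes[0],), chip_model="loihi")


class TestTrainSurrogate:
    def test_separable_toy_reaches_95pct(self):
        X, y = generate_separable_toy(2, seed=3, n_channels=10, n_ticks=50,
                                      n_per_class=60)
        spec = _toy_loihi_spec(np.random.default_rng(0))
        trained = train_surrogate(spec, (X, y), TrainConfig(epochs=30, lr=0.02, seed=0))
        assert surrogate_accuracy(trained, X, y) >= 0.95
        assert trained.trained and trained.is_quantized()

    def test_zero_learning_rate_leaves_weights(self):
        X, y = generate_separable_toy(2, seed=1, n_per_class=10, n_ticks=20)
        spec = _toy_loihi_spec(np.random.default_rng(1))
        trained = train_surrogate(spec, (X, y), TrainConfig(epochs=2, lr=0.0, seed=0))
        for a, b in zip(spec.layers, trained.layers):
            np.testing.assert_array_equal(a.weights, b.weights)
            np.testing.assert_array_equal(a.delays, b.delays)

    def test_emg_loihi_topology_with_trainable_delays(self):
        spec = emg_loihi_spec()
        assert [l.units for l in spec.layers] == [128, 128, 5]
        assert all(l.delays is not None for l in spec.layers)
        X, y = generate_separable_toy(2, seed=2, n_channels=16, n_ticks=20,
                                      n_per_class=8)
        trained = train_surrogate(spec, (X, y % 5),
                                  TrainConfig(epochs=1, lr=0.01, seed=0))
        for lyr in trained.layers:
            assert lyr.delays.dtype == np.int64
            assert lyr.delays.min() >= 0 and lyr.delays.max() <= 63

    def test_seed_determinism(self):
        X, y = generate_separable_toy(2, seed=5, n_per_class=20, n_ticks=30)
        runs = []
        for _ in range(2):
            spec = _toy_loihi_spec(np.random.default_rng(7))
            runs.append(train_surrogate(spec, (X, y),
                                        TrainConfig(epochs=3, lr=0.02, seed=42)))
        for a, b in zip(runs[0].layers, runs[1].layers):
            np.testing.assert_array_equal(a.weights, b.weights)
            np.testing.assert_array_equal(a.delays, b.delays)

    def test_rejects_non_loihi(self):
        from spikefuse.snn_core import emg_odin_spec
        with pytest.raises(ValidationError):
            train_surrogate(emg_odin_spec(), (None, None))

    def test_quantization_closure_every_step(self):
        # forward weights are the quantized view of the shadows at all times
        cfg = TrainConfig()
        lyr = _TrainLayer(_toy_loihi_spec(np.random.default_rng(3)).layers[0], cfg)
        lyr.w_shadow += np.random.default_rng(0).normal(0, 0.01, lyr.w_shadow.shape)
        assert lyr.quant.contains(lyr.qweights)


def test_gradient_check_smoothed_3_neuron_net():
    rng = np.random.default_rng(5)
    q = QuantSpec("float")
    ncfg = NeuronConfig(current_decay=1024, voltage_decay=1024, threshold=1.0)
    w1 = rng.normal(0, 0.5, (2, 3))
    w2 = rng.normal(0, 0.5, (1, 2))
    cfg = TrainConfig(surrogate_width=0.5)
    X = (rng.random((4, 3, 20)) < 0.3).astype(float)
    y = np.array([0, 0, 0, 0])

    def run_ce(w1v, w2v):
        layers = [_TrainLayer(DenseLayer(w1v, ncfg, q, name="a"), cfg),
                  _TrainLayer(DenseLayer(w2v, ncfg, q, name="b"), cfg)]
        S, caches = _forward_all(layers, X, smooth=True)
        total = float(S.sum()) / S.shape[0]
        dS = np.full_like(S, 1.0 / S.shape[0])
        return total, layers, caches, dS

    l0, layers, caches, dS = run_ce(w1, w2)
    dW2, _, dS1 = _layer_backward(layers[1], caches[1], dS, smooth=True)
    dW1, _, _ = _layer_backward(layers[0], caches[0], dS1, smooth=True)
    eps = 1e-6
    for W, dW, which in ((w1, dW1, 0), (w2, dW2, 1)):
        for i in range(W.shape[0]):
            for j in range(W.shape[1]):
                Wp = W.copy()
                Wp[i, j] += eps
                lp = run_ce(Wp if which == 0 else w1, Wp if which == 1 else w2)[0]
                assert abs((lp - l0) / eps - dW[i, j]) < 1e-4


@pytest.fixture(scope="module")
def count_data():
    X, y = generate_separable_toy(5, seed=4, n_channels=20, n_ticks=40,
                                  n_per_class=40)
    return X.sum(axis=2), y


class TestQuantizedAnn:
    def test_binary_submlp_above_chance(self):
        rng = np.random.default_rng(1)
        X, y = generate_separable_toy(5, seed=9, n_channels=400, n_ticks=30,
                                      n_per_class=30, rate_hi=0.3)
        counts = X.sum(axis=2)
        ann = train_quantized_ann((400, 210, 5), ("binary", "binary"),
                                  (counts / counts.std(), y),
                                  TrainConfig(epochs=10, seed=0))
        assert ann_accuracy(ann, counts / counts.std(), y) > 0.5  # chance = 0.2

    def test_int3_emg_net_above_chance(self, count_data):
        X, y = count_data
        Xs = X / X.std()
        ann = train_quantized_ann((20, 230, 5), ("int3", "int3"), (Xs, y),
                                  TrainConfig(epochs=10, seed=0))
        assert ann_accuracy(ann, Xs, y) > 0.5

    def test_weight_support_in_representable_set(self, count_data):
        X, y = count_data
        ann = train_quantized_ann((20, 16, 5), ("int3", "binary"),
                                  (X / X.std(), y), TrainConfig(epochs=3, seed=0))
        for w, q in zip(ann.qweights(), ann.quants):
            assert q.contains(w)


class TestAnnToSnn:
    def _toy_raster_data(self, n_channels=12, n=40, seed=0, n_classes=2,
                         rate_hi=0.7):
        X, y = generate_separable_toy(n_classes, seed=seed, n_channels=n_channels,
                                      n_ticks=40, n_per_class=n // n_classes,
                                      rate_hi=rate_hi)
        rasters = [SpikeRaster(x) for x in X]
        return X.sum(axis=2), y, rasters

    def test_trivial_rate_identity(self):
        ann = QuantizedAnn([np.array([[1.0]])], [QuantSpec("float")], trained=True)
        from spikefuse.snn_training import _lif_from_weights
        spec = _lif_from_weights(ann.qweights(), ann.quants, 1.0, 1.0, "none", "id")
        counts = np.ones((1, 10), dtype=int)
        res = run_network(spec, SpikeRaster(counts), extra_ticks=1)
        assert res.counts[0] == 10  # N in -> N out

    def test_silent_network_detected(self):
        counts, y, rasters = self._toy_raster_data()
        ann = train_quantized_ann((12, 8, 2), ("int3", "int3"), (counts / 10, y),
                                  TrainConfig(epochs=5, seed=0))
        search = ThresholdSearchSpec([1e9], [1e9], rasters[:10], y[:10])
        with pytest.raises(ValidationError, match="silent"):
            ann_to_snn(ann, search)

    def test_mapping_accuracy_and_correlation(self):
        counts, y, rasters = self._toy_raster_data(seed=2)
        ann = train_quantized_ann((12, 8, 2), ("int3", "int3"), (counts, y),
                                  TrainConfig(epochs=10, seed=0))
        search = ThresholdSearchSpec([2.0, 5.0, 10.0, 20.0], [1.0, 3.0, 10.0],
                                     rasters[:20], y[:20], extra_ticks=2)
        spec, info = ann_to_snn(ann, search, return_info=True)
        assert spec.trained
        assert info["accuracy"] >= 0.8
        rho = snn_ann_rate_correlation(spec, ann, rasters[:20])
        assert rho > 0

    def test_rate_balancing_within_20pct(self):
        # map modality A, then balance modality B's hidden rate against it
        counts_a, ya, rasters_a = self._toy_raster_data(seed=3)
        counts_b, yb, rasters_b = self._toy_raster_data(n_channels=24, seed=4,
                                                        rate_hi=0.4)
        ann_a = train_quantized_ann((12, 10, 2), ("int3", "int3"), (counts_a, ya),
                                    TrainConfig(epochs=8, seed=0))
        ann_b = train_quantized_ann((24, 10, 2), ("int3", "int3"), (counts_b, yb),
                                    TrainConfig(epochs=8, seed=0))
        grid = list(np.geomspace(0.05, 60.0, 18))
        setpoint = 4.0  # common activity target (spikes/neuron/sample)
        spec_a, info_a = ann_to_snn(
            ann_a, ThresholdSearchSpec(grid, [2.0], rasters_a[:20], ya[:20],
                                       target_hidden_rate=setpoint),
            return_info=True)
        spec_b, info_b = ann_to_snn(
            ann_b, ThresholdSearchSpec(grid, [2.0], rasters_b[:20], yb[:20],
                                       target_hidden_rate=setpoint),
            return_info=True)
        ra, rb = info_a["mean_hidden_rate"], info_b["mean_hidden_rate"]
        assert abs(rb - ra) <= 0.2 * max(ra, rb)


@pytest.fixture(scope="module")
def fused_setup():
    X, y = generate_separable_toy(2, seed=6, n_channels=10, n_ticks=40,
                                  n_per_class=30)
    cfg = TrainConfig(epochs=8, lr=0.02, seed=0)
    net_a = train_surrogate(_toy_loihi_spec(np.random.default_rng(1),
                                            (10, 12, 2)), (X, y), cfg)
    net_b = train_surrogate(_toy_loihi_spec(np.random.default_rng(2),
                                            (10, 8, 2)), (X, y), cfg)
    fused = build_fusion(net_a, net_b, QuantSpec("int8", 0.05),
                         NeuronConfig(current_decay=1024, voltage_decay=1024,
                                      threshold=1.0), n_classes=2,
                         chip_model="loihi")
    rasters = [[SpikeRaster(x), SpikeRaster(x)] for x in X]
    return fused, rasters, y


class TestFusionHeadRetraining:
    def test_upstream_digest_unchanged(self, fused_setup):
        fused, rasters, y = fused_setup
        before = [weights_digest(b) for b in fused.branches]
        H = collect_penultimate_counts(fused, rasters[:20])
        out = retrain_fusion_head(fused, (H, y[:20]), TrainConfig(epochs=3, seed=0))
        after = [weights_digest(b) for b in out.branches]
        assert before == after
        assert out.branches[0] is fused.branches[0]  # shared, not copied

    def test_head_width_and_only_head_changes(self, fused_setup):
        fused, rasters, y = fused_setup
        assert fused.layers[-1].in_features == 12 + 8
        H = collect_penultimate_counts(fused, rasters[:20])
        out = retrain_fusion_head(fused, (H, y[:20]), TrainConfig(epochs=3, seed=0))
        assert out.layers[-1].quant.contains(out.layers[-1].weights)
        assert len(out.layers) == 1
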