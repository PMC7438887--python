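import numpy as np
import pytest

from spikefuse.aer_io import ValidationError
from spikefuse.snn_core import (
    CubaState,
    DenseLayer,
    FlattenLayer,
    NetworkSpec,
    NeuronConfig,
    PoolLayer,
    QuantSpec,
    ShapeError,
    build_fusion,
    conv2d_same,
    cuba_step,
    cuba_step as _cuba_step,
    dvs_loihi_cnn_spec,
    dvs_morphic_spec,
    emg_loihi_spec,
    emg_odin_spec,
    load_network,
    pool_spikes,
    run_network,
    save_network,
    submlp_ensemble,
)
from spikefuse.spike_encoding import SpikeRaster


class TestCubaStep:
    def test_decay_example_1000_to_750(self):
        cfg = NeuronConfig(current_decay=1024, voltage_decay=1024, threshold=2000.0)
        state = CubaState(np.zeros(1), np.array([1000.0]), np.zeros(1, dtype=int))
        state, spikes = cuba_step(state, np.zeros(1), cfg)
        assert state.v[0] == 750.0  # 1000 * (4096 - 1024) / 4096 exactly
        assert spikes[0] == 0

    def test_zero_input_monotone_decay_no_spike(self):
        cfg = NeuronConfig(current_decay=1024, voltage_decay=512, threshold=10.0)
        state = CubaState(np.zeros(1), np.array([9.0]), np.zeros(1, dtype=int))
        prev = 9.0
        for _ in range(50):
            state, spikes = cuba_step(state, np.zeros(1), cfg)
            assert spikes[0] == 0
            assert 0 <= state.v[0] <= prev
            prev = state.v[0]

    def test_full_voltage_decay_boundary(self):
        # voltage_decay = 4096: v depends on i only
        cfg = NeuronConfig(current_decay=4096, voltage_decay=4096, threshold=5.0)
        state = CubaState.zeros(1)
        state, _ = cuba_step(state, np.array([3.0]), cfg)
        assert state.v[0] == 3.0
        state, _ = cuba_step(state, np.array([2.0]), cfg)
        assert state.v[0] == 2.0  # no carry-over from previous v

    def test_spike_resets_to_zero(self):
        cfg = NeuronConfig(current_decay=4096, voltage_decay=0, threshold=1.0)
        state = CubaState.zeros(1)
        state, spikes = cuba_step(state, np.array([1.5]), cfg)
        assert spikes[0] == 1 and state.v[0] == 0.0

    def test_decay_range_validation(self):
        with pytest.raises(ValidationError):
            NeuronConfig(current_decay=5000)


# ---------------------------------------------------------------------------
# Independent event-driven oracle
# ---------------------------------------------------------------------------

def naive_event_driven(spec: NetworkSpec, raster_counts: np.ndarray, n_ticks: int):
    """Per-spike queue simulation, one synapse at a time.

    Every spike of source neuron j at tick t schedules w[o, j] onto target
    o's current at tick t + 1 + delay[o, j].
    """
    layers = spec.layers
    sizes = [layers[0].in_features] + [l.units for l in layers]
    pending = [np.zeros((n_ticks + 70, sizes[k + 1])) for k in range(len(layers))]
    i_state = [np.zeros(s) for s in sizes[1:]]
    v_state = [np.zeros(s) for s in sizes[1:]]
    out_trace = np.zeros((sizes[-1], n_ticks))

    def deliver(layer_idx, src, t, amount=1.0):
        lyr = layers[layer_idx]
        for o in range(lyr.units):
            d = int(lyr.delays[o, src]) if lyr.delays is not None else 0
            when = t + 1 + d
            if when < len(pending[layer_idx]):
                pending[layer_idx][when, o] += amount * lyr.weights[o, src]

    for t in range(n_ticks):
        if t < raster_counts.shape[1]:
            for j in range(raster_counts.shape[0]):
                if raster_counts[j, t]:
                    deliver(0, j, t, float(raster_counts[j, t]))
        for k, lyr in enumerate(layers):
            a_i = (4096 - lyr.neuron.current_decay) / 4096
            a_v = (4096 - lyr.neuron.voltage_decay) / 4096
            for o in range(lyr.units):
                i_state[k][o] = i_state[k][o] * a_i + pending[k][t, o]
                v_state[k][o] = v_state[k][o] * a_v + i_state[k][o]
                if v_state[k][o] >= lyr.neuron.threshold:
                    v_state[k][o] = 0.0
                    if k + 1 < len(layers):
                        deliver(k + 1, o, t)
                    else:
                        out_trace[o, t] += 1
    return out_trace, v_state[-1]


def _random_dense_spec(rng, with_delays=False):
    sizes = [rng.integers(2, 8) for _ in range(3)]
    q = QuantSpec("float")
    layers = []
    for k in range(2):
        cfg = NeuronConfig(current_decay=int(rng.integers(0, 4097)),
                           voltage_decay=int(rng.integers(0, 4097)),
                           threshold=float(rng.uniform(0.5, 3.0)))
        delays = (rng.integers(0, 8, (sizes[k + 1], sizes[k]))
                  if with_delays else None)
        layers.append(DenseLayer(rng.normal(0, 1.0, (sizes[k + 1], sizes[k])),
                                 cfg, q, delays=delays, name=f"d{k}"))
    return NetworkSpec(f"rand", layers, (sizes[0],))


@pytest.mark.parametrize("with_delays", [False, True])
def test_simulator_matches_oracle_50_trials(with_delays):
    rng = np.random.default_rng(2024 + with_delays)
    for trial in range(25):
        spec = _random_dense_spec(rng, with_delays)
        n_ticks = int(rng.integers(10, 50))
        counts = (rng.random((spec.input_shape[0], n_ticks)) < 0.3).astype(np.int64)
        res = run_network(spec, SpikeRaster(counts), extra_ticks=10)
        oracle_trace, oracle_v = naive_event_driven(spec, counts, n_ticks + 10)
        np.testing.assert_array_equal(res.trace, oracle_trace)
        np.testing.assert_allclose(res.final_v, oracle_v, rtol=1e-10, atol=1e-10)


class TestRunNetwork:
    def test_all_zero_raster_ties_to_class_0(self):
        spec = emg_odin_spec()
        res = run_network(spec, SpikeRaster(np.zeros((16, 20), dtype=int)))
        assert res.counts.sum() == 0
        assert res.decision == 0

    def test_identity_passthrough_count(self):
        cfg = NeuronConfig(current_decay=4096, voltage_decay=4096, threshold=1.0)
        lyr = DenseLayer(np.array([[5.0]]), cfg, QuantSpec("float"),
                         delays=np.array([[3]]), name="id")
        spec = NetworkSpec("id", [lyr], (1,))
        counts = np.zeros((1, 20), dtype=int)
        counts[0, [2, 5, 9]] = 1
        res = run_network(spec, SpikeRaster(counts), extra_ticks=5)
        assert res.counts[0] == 3
        # delayed by 1 (transport) + 3 (axonal)
        np.testing.assert_array_equal(np.flatnonzero(res.trace[0]), [6, 9, 13])

    def test_monotonicity_excitatory_single_layer(self):
        rng = np.random.default_rng(5)
        cfg = NeuronConfig(current_decay=2048, voltage_decay=2048, threshold=1.0)
        lyr = DenseLayer(rng.uniform(0.1, 1.0, (4, 6)), cfg, QuantSpec("float"))
        spec = NetworkSpec("exc", [lyr], (6,))
        base = (rng.random((6, 30)) < 0.2).astype(np.int64)
        res1 = run_network(spec, SpikeRaster(base), extra_ticks=5)
        more = base.copy()
        more[rng.integers(0, 6, 10), rng.integers(0, 30, 10)] += 1
        res2 = run_network(spec, SpikeRaster(more), extra_ticks=5)
        assert np.all(res2.counts >= res1.counts)

    def test_determinism(self):
        rng = np.random.default_rng(9)
        spec = _random_dense_spec(rng, with_delays=True)
        counts = (np.random.default_rng(1).random((spec.input_shape[0], 30)) < 0.3)
        r1 = run_network(spec, SpikeRaster(counts.astype(int)))
        r2 = run_network(spec, SpikeRaster(counts.astype(int)))
        np.testing.assert_array_equal(r1.trace, r2.trace)
        assert r1.decision == r2.decision

    def test_shape_mismatch_names_layer(self):
        spec = emg_odin_spec()
        with pytest.raises(ShapeError, match="emg-odin"):
            run_network(spec, SpikeRaster(np.zeros((8, 10), dtype=int)))


class TestFusion:
    def _trained(self, spec):
        spec.trained = True
        if spec.branches:
            for b in spec.branches:
                b.trained = True
        return spec

    def test_odin_morphic_fusion_width_1070(self):
        odin = self._trained(emg_odin_spec())
        morphic = self._trained(dvs_morphic_spec())
        fused = build_fusion(odin, morphic, QuantSpec("int3"))
        assert fused.combined_width() == 1070
        assert fused.layers[-1].in_features == 1070

    def test_loihi_fusion_width_640(self):
        mlp = self._trained(emg_loihi_spec())
        cnn = self._trained(dvs_loihi_cnn_spec())
        fused = build_fusion(mlp, cnn, QuantSpec("int8", 2.0))
        assert fused.combined_width() == 640

    def test_self_fusion_doubles(self):
        net = self._trained(emg_odin_spec())
        fused = build_fusion(net, net, QuantSpec("int3"))
        assert fused.combined_width() == 2 * 230

    def test_untrained_inputs_rejected(self):
        with pytest.raises(ValidationError, match="untrained"):
            build_fusion(emg_odin_spec(), self._trained(dvs_morphic_spec()),
                         QuantSpec("int3"))

    def test_fusion_run_produces_counts(self):
        rng = np.random.default_rng(0)
        odin = self._trained(emg_odin_spec(rng, thresholds=(2.0, 4.0)))
        morphic = self._trained(dvs_morphic_spec(rng, thresholds=(8.0, 16.0)))
        fused = build_fusion(odin, morphic, QuantSpec("int3"),
                             NeuronConfig(current_decay=4096, voltage_decay=0,
                                          threshold=4.0))
        emg = SpikeRaster((rng.random((16, 50)) < 0.3).astype(int))
        quads = [SpikeRaster((rng.random((400, 50)) < 0.05).astype(int))
                 for _ in range(4)]
        res = run_network(fused, [emg, quads])
        assert res.penultimate_counts.shape == (1070,)
        assert res.trace.shape[0] == 5


class TestSubmlpEnsemble:
    def _branches(self, rng, same_weights=False):
        from spikefuse.snn_core import dvs_morphic_branch
        if same_weights:
            b = dvs_morphic_branch(np.random.default_rng(0), (8.0, 4.0))
            return [b] * 4
        return [dvs_morphic_branch(rng, (8.0, 4.0), k) for k in range(4)]

    def test_identical_streams_and_weights_sum_to_4x(self):
        rng = np.random.default_rng(2)
        branches = self._branches(rng, same_weights=True)
        stream = SpikeRaster((rng.random((400, 30)) < 0.1).astype(int))
        single = run_network(branches[0], stream)
        ens = submlp_ensemble([stream] * 4, branches, "sum_outputs")
        np.testing.assert_array_equal(ens.counts, 4 * single.counts)

    def test_one_active_branch_only(self):
        rng = np.random.default_rng(3)
        branches = self._branches(rng)
        active = SpikeRaster((rng.random((400, 30)) < 0.1).astype(int))
        silent = SpikeRaster(np.zeros((400, 30), dtype=int))
        ens = submlp_ensemble([active, silent, silent, silent], branches,
                              "sum_outputs")
        alone = run_network(branches[0], active)
        np.testing.assert_array_equal(ens.counts, alone.counts)

    def test_concat_hidden_width_840(self):
        rng = np.random.default_rng(4)
        branches = self._branches(rng)
        streams = [SpikeRaster((rng.random((400, 20)) < 0.1).astype(int))
                   for _ in range(4)]
        hidden = submlp_ensemble(streams, branches, "concat_hidden")
        assert hidden.shape == (840,)  # 4 x 210

    def test_wrong_stream_count(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValidationError):
            submlp_ensemble([SpikeRaster(np.zeros((400, 5), dtype=int))] * 3,
                            self._branches(rng), "sum_outputs")


class TestQuantSpec:
    def test_representable_sets(self):
        assert QuantSpec("binary").contains(np.array([-1.0, 1.0]))
        assert not QuantSpec("binary").contains(np.array([0.0]))
        q3 = QuantSpec("int3", 0.5)
        assert q3.contains(np.array([-2.0, 1.5, 0.0]))
        assert not q3.contains(np.array([2.5]))  # 5 * 0.5, outside [-4, 3]
        q8 = QuantSpec("int8", 1.0)
        assert q8.contains(np.arange(-128, 128, dtype=float))
        assert not q8.contains(np.array([128.0]))

    def test_chip_constrains_quant(self):
        cfg = NeuronConfig(threshold=1.0)
        lyr = DenseLayer(np.ones((2, 2)), cfg, QuantSpec("float"))
        with pytest.raises(ValidationError, match="odin"):
            NetworkSpec("bad", [lyr], (2,), chip_model="odin")

    def test_reference_specs_are_quantized(self):
        for spec in (emg_odin_spec(), dvs_morphic_spec(), emg_loihi_spec(),
                     dvs_loihi_cnn_spec()):
            assert spec.is_quantized()


class TestConvPool:
    def test_conv2d_same_matches_manual(self):
        rng = np.random.default_rng(0)
        x = rng.random((2, 5, 5))
        w = rng.random((3, 2, 3, 3))
        out = conv2d_same(x, w)
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
        manual = np.zeros((3, 5, 5))
        for o in range(3):
            for r in range(5):
                for c in range(5):
                    manual[o, r, c] = np.sum(xp[:, r:r + 3, c:c + 3] * w[o])
        np.testing.assert_allclose(out, manual)

    def test_pool_is_logical_or(self):
        x = np.zeros((1, 4, 4))
        x[0, 0, 0] = 1
        x[0, 1, 1] = 3  # counts collapse to indicator
        out = pool_spikes(x)
        assert out.shape == (1, 2, 2)
        assert out[0, 0, 0] == 1.0
        assert out[0, 1, 1] == 0.0

    def test_cnn_shapes_compose(self):
        spec = dvs_loihi_cnn_spec()
        # 40x40x2 -> 8@40 -> 8@20 -> 16@20 -> 16@10 -> 32@10 -> 3200 -> 512 -> 5
        assert spec.layers[-2].in_features == 3200
        assert spec.penultimate_size == 512


def test_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    spec = dvs_morphic_spec(rng)
    spec.trained = True
    prefix = str(tmp_path / "net")
    save_network(spec, prefix)
    back = load_network(prefix)
    assert back.is_quantized()
    assert back.combined_width() == spec.combined_width()
    for a, b in zip(spec.iter_layers(), back.iter_layers()):
        if hasattr(a, "weights"):
            np.testing.assert_array_equal(a.weights, b.weights)

    spec2 = emg_loihi_spec(rng)
    prefix2 = str(tmp_path / "net2")
    save_network(spec2, prefix2)
    back2 = load_network(prefix2)
    for a, b in zip(spec2.layers, back2.layers):
        np.testing.assert_array_equal(a.delays, b.delays)
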