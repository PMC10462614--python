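"""IF convolution dynamics, lateral inhibition, STDP algebra and training."""

import numpy as np
import pytest

from spikenc.errors import DataError, DimensionError
from spikenc.frontend import SpikeWave
from spikenc.scnn import (
    IFConvLayer,
    SpikeEvent,
    STDPConfig,
    convergence_measure,
    extract_features,
    if_convolve_spikes,
    lateral_inhibition,
    select_stdp_winners,
    stdp_update,
    train_layer,
)
from spikenc.synthetic import generate_stimuli
from spikenc.frontend import build_dog_bank, encode_image


def brute_force_if_simulator(sw: SpikeWave, layer: IFConvLayer):
    """Independent scalar IF simulator: explicit loops over every neuron,
    time step and synapse; voltage integrates spikes of the previous step,
    fires at threshold, resets, and fires at most once per image."""
    T, C, H, W = sw.shape
    kh, kw = layer.kernel_size
    pad = layer.pad
    padded = np.pad(sw.spikes, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Ho = H + 2 * pad - kh + 1
    Wo = W + 2 * pad - kw + 1
    events = []
    for o in range(layer.n_out):
        for r in range(Ho):
            for c in range(Wo):
                v = 0.0
                for t in range(1, T):
                    inc = 0.0
                    for ci in range(C):
                        for dy in range(kh):
                            for dx in range(kw):
                                if padded[t - 1, ci, r + dy, c + dx]:
                                    inc += layer.weights[o, ci, dy, dx]
                    v += inc
                    if v >= layer.v_th:
                        events.append(SpikeEvent(t, o, r, c, v))
                        break  # fires at most once; reset is irrelevant after
    return sorted(events, key=lambda e: (e.t, e.channel, e.row, e.col))


class TestIFConvolution:
    def test_forced_fire_at_t1_with_unit_weights(self):
        spikes = np.zeros((5, 1, 6, 6), dtype=bool)
        spikes[0, 0, 1:4, 1:4] = True  # 9 spikes in one RF... add one more
        spikes[0, 0, 0, 2] = True
        sw = SpikeWave(spikes)
        layer = IFConvLayer(np.ones((1, 1, 5, 5)), v_th=10.0, pad=2)
        events = if_convolve_spikes(sw, layer)
        at_center = [e for e in events if (e.row, e.col) == (2, 2)]
        assert len(at_center) == 1
        assert at_center[0].t == 1

    def test_empty_wave_no_events(self, small_layer):
        sw = SpikeWave(np.zeros((6, 2, 5, 5), dtype=bool))
        assert if_convolve_spikes(sw, small_layer) == []

    def test_channel_mismatch_raises(self, small_layer):
        sw = SpikeWave(np.zeros((6, 3, 5, 5), dtype=bool))
        with pytest.raises(DimensionError):
            if_convolve_spikes(sw, small_layer)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed, small_layer, spike_wave_factory):
        rng = np.random.default_rng(seed)
        sw = spike_wave_factory(rng, T=10, C=2, H=8, W=8, p=0.25)
        fast = if_convolve_spikes(sw, small_layer)
        slow = brute_force_if_simulator(sw, small_layer)
        assert len(fast) == len(slow)
        for a, b in zip(sorted(fast, key=lambda e: (e.t, e.channel, e.row, e.col)), slow):
            assert (a.t, a.channel, a.row, a.col) == (b.t, b.channel, b.row, b.col)
            assert a.potential == pytest.approx(b.potential, abs=1e-10)


class TestLateralInhibition:
    def test_earliest_survives_per_position(self):
        events = [SpikeEvent(5, 1, 3, 3, 11.0), SpikeEvent(2, 0, 3, 3, 10.5)]
        out = lateral_inhibition(events)
        assert out == [SpikeEvent(2, 0, 3, 3, 10.5)]

    def test_single_event_unchanged(self):
        e = [SpikeEvent(4, 2, 1, 1, 10.0)]
        assert lateral_inhibition(e) == e

    def test_time_tie_goes_to_lowest_channel(self):
        events = [SpikeEvent(2, 7, 0, 0, 12.0), SpikeEvent(2, 3, 0, 0, 10.0)]
        assert lateral_inhibition(events)[0].channel == 3


class TestWinnerSelection:
    def test_single_winner_is_globally_earliest(self):
        cfg = STDPConfig(winners_per_image=1)
        events = [
            SpikeEvent(3, 0, 0, 0, 10.0),
            SpikeEvent(1, 2, 4, 4, 10.2),
            SpikeEvent(2, 1, 2, 2, 15.0),
        ]
        assert select_stdp_winners(events, cfg) == [SpikeEvent(1, 2, 4, 4, 10.2)]

    def test_no_events_no_winners(self):
        assert select_stdp_winners([], STDPConfig()) == []

    def test_two_earliest_on_distinct_channels(self):
        cfg = STDPConfig(winners_per_image=2, inhibition_radius=0)
        events = [
            SpikeEvent(1, 0, 0, 0, 10.0),
            SpikeEvent(1, 0, 5, 5, 12.0),  # same channel as a better event
            SpikeEvent(2, 1, 1, 1, 10.0),
            SpikeEvent(3, 2, 2, 2, 20.0),
            SpikeEvent(4, 3, 3, 3, 30.0),
        ]
        winners = select_stdp_winners(events, cfg)
        # brute-force expectation: rank by (t, -potential), one per channel
        assert [w.channel for w in winners] == [0, 1]
        assert winners[0].potential == 12.0  # higher potential wins the t=1 tie


class TestSTDPAlgebra:
    def _one_synapse_setup(self, w0, presyn_spikes_at=None):
        weights = np.full((1, 1, 1, 1), w0)
        layer = IFConvLayer(weights, v_th=10.0, pad=0)
        spikes = np.zeros((6, 1, 1, 1), dtype=bool)
        if presyn_spikes_at is not None:
            spikes[presyn_spikes_at, 0, 0, 0] = True
        sw = SpikeWave(spikes)
        winner = SpikeEvent(3, 0, 0, 0, 10.0)
        return layer, sw, winner

    def test_potentiation_at_half(self):
        layer, sw, winner = self._one_synapse_setup(0.5, presyn_spikes_at=1)
        stdp_update(layer, winner, sw, STDPConfig())
        assert layer.weights[0, 0, 0, 0] == pytest.approx(0.5 + 0.001, abs=1e-15)

    def test_silent_presynapse_depressed(self):
        layer, sw, winner = self._one_synapse_setup(0.5, presyn_spikes_at=None)
        stdp_update(layer, winner, sw, STDPConfig())
        assert layer.weights[0, 0, 0, 0] == pytest.approx(0.5 - 0.00075, abs=1e-15)

    def test_late_presynapse_depressed(self):
        layer, sw, winner = self._one_synapse_setup(0.5, presyn_spikes_at=5)
        stdp_update(layer, winner, sw, STDPConfig())
        assert layer.weights[0, 0, 0, 0] == pytest.approx(0.5 - 0.00075, abs=1e-15)

    @pytest.mark.parametrize("w0", [0.0, 1.0])
    def test_zero_and_one_are_fixed_points(self, w0):
        layer, sw, winner = self._one_synapse_setup(w0, presyn_spikes_at=1)
        stdp_update(layer, winner, sw, STDPConfig())
        assert layer.weights[0, 0, 0, 0] == w0

    def test_weights_stay_in_unit_interval_under_random_updates(
        self, spike_wave_factory
    ):
        rng = np.random.default_rng(7)
        layer = IFConvLayer(rng.random((4, 2, 3, 3)), v_th=3.0, pad=1)
        cfg = STDPConfig()
        for _ in range(300):  # 300 updates x 18 synapses = 5400 modifications
            sw = spike_wave_factory(rng, T=6, C=2, H=5, W=5, p=0.3)
            winner = SpikeEvent(
                int(rng.integers(1, 6)), int(rng.integers(4)),
                int(rng.integers(5)), int(rng.integers(5)), 3.0,
            )
            stdp_update(layer, winner, sw, cfg)
            assert layer.weights.min() >= 0.0 and layer.weights.max() <= 1.0


class TestConvergenceMeasure:
    def test_saturated_weights_give_zero(self):
        w = np.array([0.0, 1.0, 1.0, 0.0]).reshape(1, 1, 2, 2)
        assert convergence_measure(IFConvLayer(w)) == 0.0

    def test_half_weights_give_quarter(self):
        w = np.full((2, 1, 2, 2), 0.5)
        assert convergence_measure(IFConvLayer(w)) == 0.25

    def test_mixed_weights_direct_value(self):
        w = np.array([0.2, 0.8]).reshape(1, 1, 1, 2)
        assert convergence_measure(IFConvLayer(w)) == pytest.approx(0.16)


class TestTraining:
    def _tiny_waves(self, n=12, seed=0):
        bank = build_dog_bank("digit")
        imgs = generate_stimuli("bars", n, (20, 20), seed=seed)
        return bank, [encode_image(im, bank) for im in imgs]

    def test_stops_once_threshold_crossed(self):
        # stopping contract: a threshold the very first presentation satisfies
        # halts training immediately with converged status
        bank, waves = self._tiny_waves()
        layer = IFConvLayer.initialize(n_out=4, n_in=2, seed=0, v_th=3.0)
        c0 = convergence_measure(layer)
        cfg = STDPConfig(convergence_stop=min(c0 * 1.05, 0.249), max_epochs=50)
        result = train_layer(waves, layer, cfg)
        assert result.converged
        assert result.epochs_run == 1
        assert len(result.trace) == 1
        assert result.trace[-1] < cfg.convergence_stop

    def test_same_seed_reproduces_weights(self):
        bank, waves = self._tiny_waves()
        runs = []
        for _ in range(2):
            layer = IFConvLayer.initialize(n_out=4, n_in=2, seed=1, v_th=3.0)
            cfg = STDPConfig(seed=5, max_epochs=3)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                runs.append(train_layer(waves, layer, cfg).layer.weights.copy())
        np.testing.assert_array_equal(runs[0], runs[1])

    def test_structured_stimuli_drive_weights_to_saturation(self):
        # oriented bars give consistent winners, so STDP saturates the
        # weights toward {0, 1} and C falls below the stopping threshold
        bank, waves = self._tiny_waves(n=30, seed=3)
        layer = IFConvLayer.initialize(n_out=8, n_in=2, seed=2, v_th=3.0)
        c0 = convergence_measure(layer)
        cfg = STDPConfig(max_epochs=200, convergence_stop=0.01, rate_boost_every=100)
        result = train_layer(waves, layer, cfg)
        assert result.converged
        assert result.trace[-1] < 0.01 < c0

    def test_no_images_raises(self):
        layer = IFConvLayer.initialize(n_out=2, n_in=2, seed=0)
        with pytest.raises(DataError):
            train_layer([], layer, STDPConfig())


class TestExtractFeatures:
    def test_silent_input_gives_zero_features(self, small_layer):
        sw = SpikeWave(np.zeros((6, 2, 5, 5), dtype=bool))
        np.testing.assert_array_equal(extract_features(sw, small_layer), 0.0)

    def test_matches_no_reset_time_stepped_oracle(
        self, small_layer, spike_wave_factory
    ):
        rng = np.random.default_rng(9)
        sw = spike_wave_factory(rng, T=8, C=2, H=7, W=7, p=0.3)
        feats = extract_features(sw, small_layer)
        # independent oracle: infinite-threshold scalar integration to T
        T, C, H, W = sw.shape
        kh, kw = small_layer.kernel_size
        pad = small_layer.pad
        padded = np.pad(sw.spikes, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        expected = np.zeros_like(feats)
        for o in range(small_layer.n_out):
            for r in range(feats.shape[1]):
                for c in range(feats.shape[2]):
                    v = 0.0
                    for t in range(T):  # all spikes contribute to the readout
                        for ci in range(C):
                            for dy in range(kh):
                                for dx in range(kw):
                                    if padded[t, ci, r + dy, c + dx]:
                                        v += small_layer.weights[o, ci, dy, dx]
                    expected[o, r, c] = v
        np.testing.assert_allclose(feats, expected, atol=1e-10)

    def test_additive_in_the_spike_count_map(self, small_layer, spike_wave_factory):
        rng = np.random.default_rng(10)
        a = spike_wave_factory(rng, T=6, C=2, H=6, W=6, p=0.2)
        # disjoint support: b spikes only where a is silent
        free = ~a.spikes.any(axis=0)
        b_spikes = np.zeros_like(a.spikes)
        c, h, w = np.nonzero(free & (rng.random(free.shape) < 0.3))
        b_spikes[rng.integers(0, 6, c.size), c, h, w] = True
        b = SpikeWave(b_spikes)
        union = SpikeWave(a.spikes | b.spikes)
        np.testing.assert_allclose(
            extract_features(union, small_layer),
            extract_features(a, small_layer) + extract_features(b, small_layer),
            atol=1e-10,
        )
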