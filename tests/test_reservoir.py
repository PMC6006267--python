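"""Small-world wiring, retinotopic input mapping, LIF dynamics and STDP."""

import numpy as np
import pytest

from retinosnn.reservoir import (
    NeuronCoordinates,
    Reservoir,
    ReservoirConfig,
    STDPConfig,
    connectivity_snapshot,
    init_reservoir,
    map_inputs_retinotopic,
    propagate_and_record,
    run_unsupervised,
)
from retinosnn.retina import SpikeRaster
from retinosnn.synthetic import generate_v1_cloud


def grid_coords(n=130, spacing=1.0):
    """Deterministic 3D grid cloud with unit spacing (no randomness)."""
    side = int(np.ceil(n ** (1 / 3))) + 1
    pts = np.array(
        [(i, j, k) for i in range(side) for j in range(side) for k in range(side)],
        dtype=float,
    )[:n]
    return NeuronCoordinates(pts * spacing, anterior_axis=1)


def forced_reservoir(n=130, **cfg_kwargs):
    """Reservoir with no initial synapses, all-excitatory signs, and
    channels 0..127 assigned one-to-one to neurons 0..127."""
    cfg = ReservoirConfig(p_connect=0.0, seed=0, **cfg_kwargs)
    res = init_reservoir(grid_coords(n), cfg)
    res.excitatory[:] = True
    res.sign[:, :] = 1
    res.input_assignment = np.arange(128)
    return res


def raster_from_spikes(spikes: dict[int, list[int]], T: int) -> SpikeRaster:
    mat = np.zeros((128, T), dtype=bool)
    for ch, bins in spikes.items():
        mat[ch, bins] = True
    return SpikeRaster(mat)


class TestInit:
    def test_pairs_beyond_dmax_never_connect(self):
        coords = NeuronCoordinates(np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]]))
        res = init_reservoir(coords, ReservoirConfig(p_connect=1.0, seed=0))
        assert res.w_mag.sum() == 0.0

    def test_in_range_pairs_connect_at_p_one(self):
        coords = NeuronCoordinates(np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]]))
        res = init_reservoir(coords, ReservoirConfig(p_connect=1.0, seed=0))
        assert res.w_mag[0, 1] > 0 and res.w_mag[1, 0] > 0

    def test_edges_respect_structure(self, small_cloud):
        res = init_reservoir(small_cloud, ReservoirConfig(seed=4))
        i, j = np.nonzero(res.w_mag)
        assert len(i) > 0
        assert np.all(i != j)
        assert np.all(res.distances[i, j] <= res.config.d_max)

    def test_excitatory_fraction_near_80_percent(self, small_cloud):
        fractions = [
            init_reservoir(small_cloud, ReservoirConfig(seed=s)).excitatory.mean()
            for s in range(10)
        ]
        p, n = 0.8, 10 * small_cloud.n
        assert abs(np.mean(fractions) - p) < 2.58 * np.sqrt(p * (1 - p) / n) + 1e-9

    def test_same_seed_reproduces_edge_list(self, small_cloud):
        a = init_reservoir(small_cloud, ReservoirConfig(seed=11))
        b = init_reservoir(small_cloud, ReservoirConfig(seed=11))
        assert np.array_equal(a.w_mag, b.w_mag)
        assert np.array_equal(a.sign, b.sign)

    def test_outgoing_signs_are_dale_consistent(self, small_cloud):
        res = init_reservoir(small_cloud, ReservoirConfig(seed=4))
        i, j = np.nonzero(res.w_mag)
        expected = np.where(res.excitatory[i], 1, -1)
        assert np.array_equal(res.sign[i, j], expected)

    def test_per_connection_signs_break_dale(self, small_cloud):
        res = init_reservoir(
            small_cloud, ReservoirConfig(seed=4, per_connection_signs=True)
        )
        i, j = np.nonzero(res.w_mag)
        signs = res.sign[i, j]
        # some presynaptic neuron has outgoing edges of both signs
        mixed = any(
            len(np.unique(signs[i == pre])) == 2 for pre in np.unique(i)
        )
        assert mixed

    def test_single_neuron_rejected(self):
        with pytest.raises(ValueError):
            init_reservoir(
                NeuronCoordinates(np.zeros((1, 3))), ReservoirConfig()
            )


class TestRetinotopicMapping:
    def test_assignment_injective_and_deterministic(self, default_map):
        coords = generate_v1_cloud(732, seed=7)
        a = map_inputs_retinotopic(coords, default_map)
        b = map_inputs_retinotopic(coords, default_map)
        assert np.array_equal(a, b)
        assert len(np.unique(a)) == 128

    def test_fovea_channels_land_in_posterior_half(self, default_map):
        coords = generate_v1_cloud(732, seed=7)
        assignment = map_inputs_retinotopic(coords, default_map)
        ant = coords.positions[:, coords.anterior_axis]
        median = np.sort(ant)[coords.n // 2]
        assert np.all(ant[assignment[64:]] < median)  # fovea posterior
        assert np.all(ant[assignment[:64]] >= median)  # groups anterior

    def test_mirrored_channels_map_to_opposite_lateral_sides(self, default_map):
        coords = generate_v1_cloud(732, seed=7)
        assignment = map_inputs_retinotopic(coords, default_map)
        lateral = coords.positions[:, 0]
        # g1 row-major 4x4 tiling: cells 0 and 3 are horizontal mirror images
        for left, right in [(0, 3), (4, 7), (16, 19)]:
            assert lateral[assignment[left]] * lateral[assignment[right]] < 0

    def test_too_few_neurons_rejected(self, default_map):
        with pytest.raises(ValueError):
            map_inputs_retinotopic(grid_coords(100), default_map)


class TestLIFDynamics:
    def test_silent_network_stays_silent(self):
        res = forced_reservoir()
        raster = raster_from_spikes({}, 20)
        record = propagate_and_record(res, raster)
        assert not record.any()
        assert np.all(res.potential == 0.0)

    def test_hand_computed_update_crosses_threshold(self):
        res = forced_reservoir()
        res.potential[5] = 0.4
        res.prev_spikes[7] = True
        res.w_mag[7, 5] = 0.2
        res.sign[7, 5] = 1
        spikes = res.step(np.zeros(128, dtype=bool))
        # 0.4 * (1 - 0.002) + 0.2 = 0.5992 >= 0.5
        assert spikes[5]
        assert res.potential[5] == 0.0
        assert res.refractory[5] == 6

    def test_subthreshold_update_value(self):
        res = forced_reservoir()
        res.potential[5] = 0.2
        res.prev_spikes[7] = True
        res.w_mag[7, 5] = 0.1
        res.sign[7, 5] = 1
        res.step(np.zeros(128, dtype=bool))
        assert res.potential[5] == pytest.approx(0.2 * 0.998 + 0.1)

    def test_refractory_neuron_ignores_input(self):
        res = forced_reservoir()
        res.refractory[3] = 2
        res.potential[3] = 0.25
        inp = np.zeros(128, dtype=bool)
        inp[3] = True  # would otherwise force a spike
        spikes = res.step(inp)
        assert not spikes[3]
        assert res.potential[3] == 0.25
        assert res.refractory[3] == 1

    def test_input_spike_forces_assigned_neuron(self):
        res = forced_reservoir()
        record = propagate_and_record(res, raster_from_spikes({42: [5]}, 10))
        assert record[42, 5]
        assert record.sum() == 1

    def test_refractory_period_enforced(self):
        res = forced_reservoir()
        raster = raster_from_spikes({10: list(range(20))}, 20)
        record = propagate_and_record(res, raster)
        times = np.flatnonzero(record[10])
        assert np.all(np.diff(times) > res.config.refractory_bins)

    def test_zero_leak_accumulates_exact_running_sum(self):
        res = forced_reservoir(leak_rate=0.0, fire_threshold=100.0)
        res.w_mag[0, 1] = 0.3
        res.sign[0, 1] = 1
        for t in range(7):
            res.prev_spikes = np.zeros(130, dtype=bool)
            res.prev_spikes[0] = True
            res.step(np.zeros(128, dtype=bool))
            assert res.potential[1] == pytest.approx(0.3 * (t + 1))

    def test_frozen_propagation_is_deterministic(self, small_cloud, default_map):
        res = init_reservoir(small_cloud, ReservoirConfig(seed=2))
        res.input_assignment = map_inputs_retinotopic(small_cloud, default_map)
        rng = np.random.default_rng(0)
        raster = SpikeRaster(rng.random((128, 40)) < 0.1)
        a = propagate_and_record(res, raster)
        b = propagate_and_record(res, raster)
        assert np.array_equal(a, b)

    def test_more_input_never_fewer_injections(self, small_cloud, default_map):
        res = init_reservoir(small_cloud, ReservoirConfig(seed=2))
        res.input_assignment = map_inputs_retinotopic(small_cloud, default_map)
        rng = np.random.default_rng(1)
        big = rng.random((128, 40)) < 0.15
        small = big & (rng.random((128, 40)) < 0.5)
        n_big = propagate_and_record(res, SpikeRaster(big)).sum()
        n_small = propagate_and_record(res, SpikeRaster(small)).sum()
        assert n_big >= n_small


class TestSTDP:
    def test_zero_rate_is_noop(self):
        res = forced_reservoir()
        res.w_mag[5, 7] = 0.3
        before = res.w_mag.copy()
        raster = raster_from_spikes({5: [3], 7: [4]}, 10)
        run_unsupervised(res, [raster], STDPConfig(rate=0.0))
        assert np.array_equal(res.w_mag, before)

    def test_causal_pair_closed_form_potentiation(self):
        res = forced_reservoir()
        res.w_mag[5, 7] = 0.3
        res.w_mag[7, 5] = 0.5
        raster = raster_from_spikes({5: [3], 7: [4]}, 6)
        run_unsupervised(res, [raster], STDPConfig(rate=0.01, tau_bins=2.0))
        # pre 5 at bin 3, post 7 at bin 4: dt=1, additive LTP
        assert res.w_mag[5, 7] == pytest.approx(0.3 + 0.01 * np.exp(-0.5))
        # synapse 7->5 sees the anti-causal pair: multiplicative LTD
        assert res.w_mag[7, 5] == pytest.approx(0.5 - 0.01 * 0.5 * np.exp(-0.5))

    def test_pairs_outside_window_do_not_update(self):
        res = forced_reservoir()
        res.w_mag[5, 7] = 0.3
        raster = raster_from_spikes({5: [0], 7: [10]}, 12)  # dt=10 > window 6
        run_unsupervised(res, [raster], STDPConfig())
        assert res.w_mag[5, 7] == 0.3

    def test_new_connection_grows_on_first_causal_pairing(self):
        res = forced_reservoir()
        # neurons 5 and 6 are adjacent grid points, within 2 * d_max
        assert res.w_mag[5, 6] == 0.0
        assert res.growth_mask[5, 6]
        raster = raster_from_spikes({5: [3], 6: [4]}, 6)
        run_unsupervised(res, [raster], STDPConfig(rate=0.01))
        assert res.w_mag[5, 6] == pytest.approx(0.01)
        assert res.sign[5, 6] == (1 if res.excitatory[5] else -1)

    def test_no_growth_beyond_twice_wiring_radius(self):
        res = forced_reservoir()
        assert not res.growth_mask[5, 7]  # grid distance > 2 * d_max
        raster = raster_from_spikes({5: [3], 7: [4]}, 6)
        run_unsupervised(res, [raster], STDPConfig(rate=0.01))
        assert res.w_mag[5, 7] == 0.0

    def test_inhibitory_synapse_keeps_sign(self):
        res = forced_reservoir()
        res.excitatory[5] = False
        res.sign[5, :] = -1
        res.w_mag[5, 7] = 0.3
        # anti-causal pair on the inhibitory synapse: post 7 first, pre 5 later
        raster = raster_from_spikes({7: [3], 5: [4]}, 8)
        run_unsupervised(res, [raster], STDPConfig())
        assert res.w_mag[5, 7] == pytest.approx(0.3 * (1 - 0.01 * np.exp(-0.5)))
        assert res.sign[5, 7] == -1

    def test_weights_stay_bounded(self, small_cloud, default_map):
        res = init_reservoir(small_cloud, ReservoirConfig(seed=5))
        res.input_assignment = map_inputs_retinotopic(small_cloud, default_map)
        rng = np.random.default_rng(2)
        rasters = [SpikeRaster(rng.random((128, 50)) < 0.2) for _ in range(4)]
        stdp = STDPConfig(rate=0.2, w_max=1.0)
        run_unsupervised(res, rasters, stdp)
        assert res.w_mag.min() >= 0.0
        assert res.w_mag.max() <= stdp.w_max

    def test_empty_training_list_rejected(self):
        with pytest.raises(ValueError):
            run_unsupervised(forced_reservoir(), [], STDPConfig())


class TestSnapshot:
    def test_untrained_snapshot_structure(self, small_cloud):
        res = init_reservoir(small_cloud, ReservoirConfig(seed=6))
        snap = connectivity_snapshot(res)
        assert set(snap.columns) == {"i", "j", "weight", "sign", "distance"}
        assert (snap["distance"] <= res.config.d_max).all()
        assert (np.sign(snap["weight"]) == snap["sign"]).all()
        expected = np.where(res.excitatory[snap["i"]], 1, -1)
        assert np.array_equal(snap["sign"].to_numpy(), expected)
        assert snap.attrs["n_positive"] + snap.attrs["n_negative"] == len(snap)

    def test_training_changes_snapshot_and_bridges_gaps(self, small_cloud, default_map):
        res = init_reservoir(small_cloud, ReservoirConfig(seed=6))
        res.input_assignment = map_inputs_retinotopic(small_cloud, default_map)
        before = connectivity_snapshot(res)
        rng = np.random.default_rng(3)
        rasters = [SpikeRaster(rng.random((128, 60)) < 0.2) for _ in range(3)]
        run_unsupervised(res, rasters, STDPConfig())
        after = connectivity_snapshot(res)
        assert not before.equals(after)
        assert (after["distance"] > res.config.d_max).any()  # grown long edges

    def test_snapshot_serializes_csv_and_graphml(self, small_cloud, tmp_path):
        from retinosnn.reservoir import save_snapshot
        import networkx as nx

        res = init_reservoir(small_cloud, ReservoirConfig(seed=6))
        snap = connectivity_snapshot(res)
        save_snapshot(snap, tmp_path / "e.csv", tmp_path / "e.graphml")
        assert (tmp_path / "e.csv").exists()
        g = nx.read_graphml(tmp_path / "e.graphml")
        assert g.number_of_edges() == len(snap)
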