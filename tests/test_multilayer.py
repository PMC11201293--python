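import numpy as np
import pytest

import restdyn as rd
from restdyn.multilayer import DEFAULT_GAMMAS, DEFAULT_OMEGAS

from conftest import brute_force_q, set_partitions


def random_layers(rng, n_nodes, n_layers):
    layers = np.zeros((n_layers, n_nodes, n_nodes))
    for s in range(n_layers):
        a = (rng.random((n_nodes, n_nodes)) < 0.5) * rng.random((n_nodes, n_nodes))
        a = np.triu(a, 1)
        layers[s] = a + a.T
    return layers


class TestSlidingWindows:
    def test_stated_parameters_give_191_layers(self, rng):
        lay = rd.sliding_windows(rng.standard_normal((230, 6)), window=40, overlap=0.975)
        assert lay.shape == (191, 6, 6)

    def test_no_overlap_gives_disjoint_layers(self, rng):
        lay = rd.sliding_windows(rng.standard_normal((230, 4)), window=40, overlap=0.0)
        assert lay.shape[0] == 5

    def test_anticorrelated_pair_truncated_to_zero(self, rng):
        base = rng.standard_normal(100)
        x = np.column_stack([base, -base])
        lay = rd.sliding_windows(x, window=40, overlap=0.5)
        assert lay.max() == 0.0

    def test_layers_are_valid_adjacency(self, rng):
        lay = rd.sliding_windows(rng.standard_normal((120, 5)), window=40, overlap=0.9)
        assert lay.min() >= 0
        assert np.abs(np.diagonal(lay, axis1=1, axis2=2)).max() == 0
        np.testing.assert_allclose(lay, np.swapaxes(lay, 1, 2), atol=1e-12)

    def test_short_series_rejected(self, rng):
        with pytest.raises(ValueError, match="shorter"):
            rd.sliding_windows(rng.standard_normal((30, 4)), window=40)


class TestModularity:
    def test_attains_brute_force_optimum(self):
        rng = np.random.default_rng(5)
        layers = random_layers(rng, 4, 2)
        best = max(
            brute_force_q(layers, 1.0, 0.5, np.array(p)) for p in set_partitions(8)
        )
        cs = rd.multilayer_modularity(layers, gamma=1.0, omega=0.5, seed=0)
        assert brute_force_q(layers, 1.0, 0.5, cs.labels.ravel()) == pytest.approx(
            best, abs=1e-9
        )

    def test_strong_coupling_freezes_communities(self, rng):
        layers = random_layers(rng, 8, 6)
        cs = rd.multilayer_modularity(layers, gamma=1.0, omega=100.0, seed=1)
        assert rd.node_flexibility(cs).max() == 0.0

    def test_single_layer_cliques_hand_computed_q(self):
        a = np.zeros((6, 6))
        a[:3, :3] = 1.0
        a[3:, 3:] = 1.0
        np.fill_diagonal(a, 0.0)
        cs = rd.multilayer_modularity(a[None], gamma=1.0, omega=0.0, seed=0)
        lab = cs.labels[0]
        assert len(np.unique(lab)) == 2
        assert np.all(lab[:3] == lab[0]) and np.all(lab[3:] == lab[3])
        # two 3-cliques: Q = 1 - 2 * (6/12)^2 = 0.5 with the diagonal null term
        assert cs.quality == pytest.approx(0.5, abs=1e-12)

    def test_seeded_determinism(self, rng):
        layers = random_layers(rng, 10, 4)
        a = rd.multilayer_modularity(layers, seed=7)
        b = rd.multilayer_modularity(layers, seed=7)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.quality == b.quality

    def test_zero_weight_layer_flagged(self):
        layers = np.zeros((2, 4, 4))
        layers[0, 0, 1] = layers[0, 1, 0] = 1.0
        with pytest.warns(UserWarning, match="zero total weight"):
            rd.multilayer_modularity(layers, seed=0)


class TestNodeFlexibility:
    def test_limits(self):
        assert rd.node_flexibility(np.ones((5, 3), int)).max() == 0.0
        alternating = np.tile([[1], [2]], (3, 4))[:6]
        np.testing.assert_array_equal(rd.node_flexibility(alternating), 1.0)

    def test_single_change_over_191_layers(self):
        labels = np.ones((191, 2), dtype=int)
        labels[100:, 0] = 2
        nf = rd.node_flexibility(labels)
        assert nf[0] == pytest.approx(1 / 190)
        assert nf[1] == 0.0

    def test_relabeling_invariance(self, rng):
        labels = rng.integers(1, 4, size=(10, 5))
        perm = {1: 7, 2: 5, 3: 9}
        relabeled = np.vectorize(perm.get)(labels)
        np.testing.assert_array_equal(
            rd.node_flexibility(labels), rd.node_flexibility(relabeled)
        )

    def test_single_layer_rejected(self):
        with pytest.raises(ValueError):
            rd.node_flexibility(np.ones((1, 4), int))


class TestFlexibilityGrid:
    def test_shape_and_names(self, rng):
        nf = rd.flexibility_grid(
            rng.standard_normal((120, 6)), window=40, overlap=0.9, seed=0
        )
        assert nf.shape == (6, 9)
        assert list(nf.columns)[0] == "NF_g1_o1"
        assert list(nf.columns)[-1] == "NF_g3_o3"
        assert float(nf.min().min()) >= 0 and float(nf.max().max()) <= 1

    def test_single_cell_equals_direct_call(self, rng):
        x = rng.standard_normal((120, 5))
        nf = rd.flexibility_grid(
            x, gammas=(1.0,), omegas=(0.75,), window=40, overlap=0.9, seed=42
        )
        child = np.random.SeedSequence(42).spawn(1)[0]
        cs = rd.multilayer_modularity(
            rd.sliding_windows(x, window=40, overlap=0.9),
            gamma=1.0, omega=0.75, seed=child,
        )
        np.testing.assert_allclose(nf["NF_g1_o1"], rd.node_flexibility(cs))

    def test_deterministic_given_seed(self, rng):
        x = rng.standard_normal((100, 5))
        a = rd.flexibility_grid(x, window=40, overlap=0.9, seed=3)
        b = rd.flexibility_grid(x, window=40, overlap=0.9, seed=3)
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            rd.flexibility_grid(rng.standard_normal((100, 4)), gammas=())


def test_flexibility_decreases_with_coupling_on_average():
    # stronger interlayer coupling suppresses community switching
    rng = np.random.default_rng(0)
    cfg = rd.SimulationConfig(
        n_patients=0, n_controls=10, n_parcels=10, n_volumes=120, seed=6
    )
    co = rd.generate_cohort(cfg)
    means = []
    for omega in (0.5, 1.0):
        nf = []
        for i, sub in enumerate(co.subjects()):
            cs = rd.multilayer_modularity(
                rd.sliding_windows(co.node_series[sub], window=40, overlap=0.9),
                gamma=1.0, omega=omega, seed=i,
            )
            nf.append(rd.node_flexibility(cs).mean())
        means.append(np.mean(nf))
    assert means[1] <= means[0] + 1e-9
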