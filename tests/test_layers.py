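import numpy as np
import pytest
from scipy.stats import pearsonr

from multiplexcore import (
    SolverError,
    ValidationError,
    binarize_to_density,
    fc_from_timeseries,
    mc_via_sice,
    population_average,
    proportional_scaling,
    sc_from_streamlines,
)
from multiplexcore.layers import SICEDensityMatcher, build_population_connectome
from multiplexcore.synthetic import PlantedModel, make_observations, sample_uptake_subjects

from conftest import make_parcellation


class TestFunctionalConnectivity:
    def test_identical_columns_correlate_perfectly(self):
        parc = make_parcellation(2)
        t = np.arange(50.0)
        ts = np.column_stack([t, t])
        net = fc_from_timeseries(ts, parc)
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 0] == 0.0

    def test_negated_column_anticorrelates(self):
        parc = make_parcellation(2)
        t = np.sin(np.arange(50.0))
        net = fc_from_timeseries(np.column_stack([t, -t]), parc)
        assert net.weights[0, 1] == pytest.approx(-1.0)

    def test_quadrature_sinusoids_are_uncorrelated(self):
        parc = make_parcellation(2)
        t = np.arange(100)
        ts = np.column_stack([np.sin(2 * np.pi * t / 100), np.cos(2 * np.pi * t / 100)])
        net = fc_from_timeseries(ts, parc)
        assert abs(net.weights[0, 1]) < 1e-10

    def test_matches_pairwise_pearson_oracle(self, rng):
        n = 6
        parc = make_parcellation(n)
        ts = rng.standard_normal((40, n))
        net = fc_from_timeseries(ts, parc)
        for i in range(n):
            for j in range(i + 1, n):
                r = pearsonr(ts[:, i], ts[:, j]).statistic
                assert net.weights[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_column_names_node(self):
        parc = make_parcellation(3)
        ts = np.column_stack([np.arange(10.0), np.full(10, 2.0), np.arange(10.0) ** 2])
        with pytest.raises(ValidationError, match="node 1"):
            fc_from_timeseries(ts, parc)


class TestStructuralConnectivity:
    def test_volume_sum_normalization(self):
        parc = make_parcellation(2, volumes=[2.0, 3.0])
        counts = np.array([[0.0, 10.0], [10.0, 0.0]])
        net = sc_from_streamlines(counts, parc)
        assert net.weights[0, 1] == pytest.approx(2.0)

    def test_zero_counts_give_zero_weights(self, parc4):
        net = sc_from_streamlines(np.zeros((4, 4)), parc4)
        assert not net.weights.any()

    def test_doubling_volumes_halves_weights(self, rng):
        counts = rng.poisson(5, (5, 5)).astype(float)
        counts = np.triu(counts, 1) + np.triu(counts, 1).T
        vols = rng.uniform(500, 1500, 5)
        w1 = sc_from_streamlines(counts, make_parcellation(5, volumes=vols)).weights
        w2 = sc_from_streamlines(counts, make_parcellation(5, volumes=2 * vols)).weights
        assert np.allclose(w2, w1 / 2)

    def test_negative_count_rejected(self, parc4):
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = -1
        with pytest.raises(ValidationError):
            sc_from_streamlines(counts, parc4)


class TestPopulationAverage:
    def test_single_network_is_identity(self, rng, parc4):
        w = rng.random((4, 4))
        w = np.triu(w, 1) + np.triu(w, 1).T
        net = sc_from_streamlines(w, parc4)
        assert np.allclose(population_average([net]).weights, net.weights)

    def test_mean_of_zero_and_one(self, parc4):
        ones = np.ones((4, 4)) - np.eye(4)
        a = sc_from_streamlines(np.zeros((4, 4)), parc4)
        b = sc_from_streamlines(ones * 1000, parc4)  # vols 1000+1000 -> weight 0.5
        avg = population_average([a, b])
        off = avg.weights[np.triu_indices(4, 1)]
        assert np.allclose(off, 0.25)

    def test_mean_of_copies_is_input(self, rng, parc4):
        w = rng.random((4, 4))
        w = np.triu(w, 1) + np.triu(w, 1).T
        net = sc_from_streamlines(w, parc4)
        assert np.allclose(population_average([net] * 5).weights, net.weights)

    def test_mixed_modalities_rejected(self, parc4):
        a = sc_from_streamlines(np.zeros((4, 4)), parc4)
        b = fc_from_timeseries(np.random.default_rng(0).standard_normal((10, 4)), parc4)
        with pytest.raises(ValidationError):
            population_average([a, b])


class TestProportionalScaling:
    @pytest.mark.parametrize(
        "raw, expected",
        [((2.0, 2.0, 2.0, 2.0), (0.25, 0.25, 0.25, 0.25)), ((1.0, 3.0), (0.25, 0.75))],
    )
    def test_examples(self, raw, expected):
        assert np.allclose(proportional_scaling(np.array(raw)), expected)

    def test_scale_invariance(self, rng):
        v = rng.uniform(0.5, 5.0, 20)
        assert np.allclose(proportional_scaling(v), proportional_scaling(7.3 * v))

    def test_rows_sum_to_one(self, rng):
        table = rng.uniform(0.5, 5.0, (6, 10))
        out = proportional_scaling(table)
        assert np.allclose(out.sum(axis=1), 1.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            proportional_scaling(np.array([1.0, 0.0]))


class TestBinarizeToDensity:
    def test_keeps_largest_weight_edges(self, rng):
        parc = make_parcellation(5)
        w = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        w[iu] = rng.permutation(np.arange(1, 11, dtype=float))
        w = w + w.T
        net = sc_from_streamlines(w * 2000, parc)  # volume-normalized back to w
        binary = binarize_to_density(net, 0.2)
        kept = set(zip(*np.nonzero(np.triu(binary.weights, 1))))
        top2 = {tuple(sorted((iu[0][k], iu[1][k]))) for k in np.argsort(w[iu])[-2:]}
        assert kept == top2
        assert binary.edge_count == 2

    def test_near_full_density_drops_weakest_edge(self, rng):
        parc = make_parcellation(5)
        w = np.zeros((5, 5))
        iu = np.triu_indices(5, 1)
        w[iu] = rng.permutation(np.arange(1, 11, dtype=float))
        w = w + w.T
        net = sc_from_streamlines(w * 2000, parc)
        binary = binarize_to_density(net, 0.9)
        assert binary.edge_count == 9  # complete graph minus one
        weakest = np.argmin(w[iu])
        i, j = iu[0][weakest], iu[1][weakest]
        assert binary.weights[i, j] == 0

    def test_hundred_nodes_twenty_percent_gives_990_edges(self, rng):
        parc = make_parcellation(100)
        w = rng.random((100, 100))
        w = np.triu(w, 1) + np.triu(w, 1).T
        net = sc_from_streamlines(w * 2000, parc)
        assert binarize_to_density(net, 0.20).edge_count == 990

    def test_full_tie_warns_and_is_deterministic(self, parc4):
        ones = (np.ones((4, 4)) - np.eye(4)) * 2000
        net = sc_from_streamlines(ones, parc4)
        with pytest.warns(UserWarning, match="edge index"):
            a = binarize_to_density(net, 0.5)
        with pytest.warns(UserWarning):
            b = binarize_to_density(net, 0.5)
        assert np.array_equal(a.weights, b.weights)
        assert a.edge_count == 3


def _chain_adjacency(n: int) -> np.ndarray:
    adj = np.zeros((n, n))
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = 1
    return adj + adj.T


class TestSICE:
    def test_independent_data_sparse_end_is_empty(self, rng):
        parc = make_parcellation(10)
        x = rng.standard_normal((1000, 10)) * rng.uniform(0.5, 2.0, 10) + 5.0
        matcher = SICEDensityMatcher(np.abs(x) + 1.0, parc)
        matcher.support_at_density(0.1)
        assert matcher._fit(1.0) == 0  # full penalty kills every edge

    def test_chain_precision_recovered(self):
        n = 10
        parc = make_parcellation(n)
        chain = _chain_adjacency(n)
        model = PlantedModel(n_nodes=n, hub_set=(0, 1), subjects=1000, seed=0)
        up = sample_uptake_subjects(model, np.random.default_rng(11), chain, n_subjects=1000)
        net = mc_via_sice(up, parc, 9 / 45)
        iu = np.triu_indices(n, 1)
        pred, true = net.weights[iu] > 0, chain[iu] > 0
        tp = (pred & true).sum()
        f1 = 2 * tp / (pred.sum() + true.sum())
        assert f1 >= 0.9

    def test_density_nonincreasing_in_penalty(self, rng):
        parc = make_parcellation(12)
        model = PlantedModel(n_nodes=12, hub_set=(0, 1, 2), subjects=200, seed=2)
        up = sample_uptake_subjects(
            model, rng, _chain_adjacency(12), n_subjects=200
        )
        matcher = SICEDensityMatcher(up, parc)
        for d in (0.1, 0.3, 0.5):
            matcher.support_at_density(d)
        probed = sorted(matcher._cache.items())
        counts = [m for _, m in probed]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_support_symmetric_and_subject_order_invariant(self, rng):
        parc = make_parcellation(10)
        model = PlantedModel(n_nodes=10, hub_set=(0, 1), subjects=100, seed=3)
        up = sample_uptake_subjects(model, rng, _chain_adjacency(10), n_subjects=100)
        a = mc_via_sice(up, parc, 0.2).weights
        b = mc_via_sice(up[::-1], parc, 0.2).weights
        assert np.array_equal(a, a.T)
        assert np.array_equal(a, b)

    def test_too_few_subjects_rejected(self, rng):
        parc = make_parcellation(5)
        with pytest.raises(ValidationError):
            SICEDensityMatcher(rng.random((2, 5)) + 1, parc)


class TestEqualDensityLayers:
    def test_all_layers_share_exact_edge_count(self):
        model = PlantedModel(n_nodes=30, hub_set=tuple(range(5)), subjects=200,
                             n_timepoints=60, seed=7)
        parc, obs, _ = make_observations(model)
        connectome = build_population_connectome(obs)
        for density in (0.1, 0.2, 0.4):
            target = int(np.floor(density * 435 + 0.5))
            counts = [lay.edge_count for lay in connectome.binary_layers(density)]
            assert counts == [target] * 3
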