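"""Self-organizing map: initialization, BMU search, training, partitions."""

import dataclasses
import warnings

import numpy as np
import pytest

from irae_som import SomConfig, category_ratio_matrix, preset_profiles, simulate
from irae_som.som import (find_bmu, init_weights, modal_partition, partition_of,
                          train, unit_distance_summary)
from irae_som.synthetic import SEPARABLE4_PARTITION
from irae_som.tables import RatioMatrix


def matrix(rows, drugs=None, features=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    drugs = drugs or [f"d{i}" for i in range(rows.shape[0])]
    features = features or [f"f{j}" for j in range(rows.shape[1])]
    return RatioMatrix(drugs, features, rows)


class TestInitWeights:
    def test_sample_init_from_single_row_forces_all_units(self):
        data = matrix([[3.0, 7.0]])
        w = init_weights(SomConfig(grid_rows=2, grid_cols=2, seed=0), data)
        assert w.shape == (4, 2)
        assert np.allclose(w, [3.0, 7.0])

    def test_same_seed_identical_weights(self):
        data = matrix(np.arange(12).reshape(4, 3))
        cfg = SomConfig(grid_rows=3, grid_cols=2, seed=42)
        assert np.array_equal(init_weights(cfg, data), init_weights(cfg, data))

    def test_uniform_random_init_stays_in_observed_range(self):
        rng = np.random.default_rng(3)
        data = matrix(rng.uniform(-5, 30, size=(6, 4)))
        cfg = SomConfig(grid_rows=5, grid_cols=5, init="uniform-random", seed=7)
        w = init_weights(cfg, data)
        lo, hi = data.values.min(axis=0), data.values.max(axis=0)
        assert np.all(w >= lo) and np.all(w <= hi)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            init_weights(SomConfig(seed=0), matrix(np.empty((0, 2)), drugs=[]))


class TestFindBmu:
    def test_exact_match_wins(self):
        w = np.arange(12.0).reshape(4, 3)
        assert find_bmu(w, w[3]) == 3

    def test_all_equidistant_ties_break_to_unit_zero(self):
        w = np.ones((5, 2))
        assert find_bmu(w, np.array([9.0, 9.0])) == 0

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            find_bmu(np.ones((3, 2)), np.ones(3))

    def test_matches_exhaustive_scan_on_200_random_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(200):
            n_units = int(rng.integers(2, 30))
            dim = int(rng.integers(1, 8))
            w = rng.normal(size=(n_units, dim))
            x = rng.normal(size=dim)
            dists = [float(np.linalg.norm(w[u] - x)) for u in range(n_units)]
            best = min(range(n_units), key=lambda u: (dists[u], u))
            assert find_bmu(w, x) == best


class TestTrain:
    def test_no_training_assigns_against_initial_weights(self):
        data = matrix([[0.0, 0.0], [10.0, 10.0], [20.0, 0.0]])
        cfg = SomConfig(grid_rows=3, grid_cols=1, n_iter=0, seed=5)
        model = train(cfg, data)
        w0 = init_weights(cfg, data, rng=np.random.default_rng(5))
        assert np.array_equal(model.weights, w0)
        for i, d in enumerate(data.drugs):
            u = model.assignments[d]
            if np.allclose(model.weights[u], data.values[i]):
                assert np.linalg.norm(model.weights[u] - data.values[i]) == 0.0

    def test_vanishing_learning_rate_leaves_weights_unchanged(self):
        data = matrix(np.random.default_rng(0).uniform(0, 50, size=(5, 4)))
        cfg = SomConfig(grid_rows=2, grid_cols=3, alpha0=1e-300, n_iter=50, seed=9)
        model = train(cfg, data)
        w0 = init_weights(cfg, data, rng=np.random.default_rng(9))
        assert np.allclose(model.weights, w0)

    def test_single_row_training_converges_to_it(self):
        data = matrix([[5.0, -2.0, 8.0]])
        cfg = SomConfig(grid_rows=2, grid_cols=1, radius0=0.0, n_iter=400,
                        alpha0=0.5, seed=2)
        model = train(cfg, data)
        assert model.quantization_error < 1e-3
        # quantization error shrinks as training proceeds
        qes = [train(dataclasses.replace(cfg, n_iter=n), data).quantization_error
               for n in (0, 50, 400)]
        assert qes[2] <= qes[1] <= qes[0]

    def test_determinism_same_config_same_model(self, published_matrix):
        cfg = SomConfig(seed=31)
        m1, m2 = train(cfg, published_matrix), train(cfg, published_matrix)
        assert np.array_equal(m1.weights, m2.weights)
        assert m1.assignments == m2.assignments
        assert m1.quantization_error == m2.quantization_error

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValueError):
            train(SomConfig(seed=0), matrix([[np.nan, 1.0]]))


class TestPartition:
    def test_all_drugs_one_unit_is_a_single_group(self):
        part = partition_of({f"d{i}": 3 for i in range(8)})
        assert part == frozenset({frozenset(f"d{i}" for i in range(8))})

    def test_label_permutation_invariance(self):
        a = {"x": 0, "y": 0, "z": 4}
        b = {"x": 9, "y": 9, "z": 1}
        assert partition_of(a) == partition_of(b)

    def test_published_unit_column_partition(self, published_units, published_partition):
        assert partition_of(published_units) == published_partition
        assert {frozenset(g) for g in published_partition} == {
            frozenset({"Atezolizumab"}), frozenset({"Nivolumab"}),
            frozenset({"Ipilimumab", "Pembrolizumab"}),
            frozenset({"Avelumab", "Cemiplimab", "Durvalumab", "Tremelimumab"}),
        }


class TestUnitDistances:
    def test_two_by_one_grid_has_exactly_one_pair(self):
        data = matrix([[0.0, 0.0], [4.0, 3.0]])
        model = train(SomConfig(grid_rows=2, grid_cols=1, n_iter=0, seed=0), data)
        df = unit_distance_summary(model)
        assert len(df) == 1

    def test_identical_weights_give_zero_distances(self):
        data = matrix([[1.0, 2.0]])
        model = train(SomConfig(grid_rows=3, grid_cols=3, n_iter=0, seed=0), data)
        assert (unit_distance_summary(model)["distance"] == 0).all()

    def test_distances_match_direct_recomputation(self, published_matrix):
        model = train(SomConfig(grid_rows=3, grid_cols=4, seed=17), published_matrix)
        df = unit_distance_summary(model)
        # 3x4 grid: 3*3 horizontal + 2*4 vertical adjacent pairs
        assert len(df) == 17
        for _, row in df.iterrows():
            expect = np.linalg.norm(model.weights[int(row.unit_a)]
                                    - model.weights[int(row.unit_b)])
            assert row.distance == pytest.approx(expect)


def test_large_map_on_pt_level_shares(catalog):
    """The 5x5 map accepts the 125-feature PT-share input."""
    from irae_som.tables import pt_ratio_matrix

    cfg = preset_profiles("separable4", catalog)
    _, gt = simulate(cfg, catalog)
    mx = pt_ratio_matrix(gt, drugs=cfg.drug_names, catalog=catalog)
    assert (len(mx.drugs), len(mx.features)) == (8, 125)
    model = train(SomConfig(grid_rows=5, grid_cols=5, seed=8), mx)
    assert model.weights.shape == (25, 125)
    assert all(0 <= u < 25 for u in model.assignments.values())
    assert model.quantization_error >= 0


def test_cluster_recovery_on_separable_profiles(catalog):
    """A 6x1 map recovers the generating 1/2/1/4 partition as the mode."""
    cfg = preset_profiles("separable4", catalog)
    tables, gt = simulate(cfg, catalog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mx = category_ratio_matrix(gt, drugs=cfg.drug_names, catalog=catalog)
    part, freq = modal_partition(SomConfig(), mx, n_seeds=50)
    expected = frozenset(frozenset(g) for g in SEPARABLE4_PARTITION)
    assert part == expected
    assert freq >= 0.5
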