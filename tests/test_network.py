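"""Network construction, TOM, dendrogram cutting, eigengenes and hubs."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from holocorr import (
    ModuleAssignment,
    ModuleNetwork,
    NetworkParams,
    OmicsLayer,
    adjacency_from_correlation,
    detect_modules,
    intramodular_connectivity,
    module_eigengene,
    simulate_bundle,
    tom_similarity,
)
from holocorr.network import (
    PowerFitRow,
    choose_power,
    connectivity,
    correlation_matrix,
    cut_dendrogram_to_modules,
    merge_close_modules,
    soft_threshold_scan,
    top_hub_per_module,
)

from conftest import make_layer


def random_correlation(rng, n):
    """Random positive-definite correlation matrix."""
    X = rng.standard_normal((n + 5, n))
    R = np.corrcoef(X, rowvar=False)
    return np.clip(R, -1, 1)


class TestAdjacency:
    def test_perfect_correlation_gives_unit_edge(self):
        R = np.array([[1.0, 1.0], [1.0, 1.0]])
        for beta in (1, 2, 6):
            A = adjacency_from_correlation(R, beta)
            assert A[0, 1] == 1.0

    def test_unsigned_squares_magnitude(self):
        R = np.array([[1.0, -0.5], [-0.5, 1.0]])
        A = adjacency_from_correlation(R, 2, "unsigned")
        assert A[0, 1] == pytest.approx(0.25)

    def test_signed_kills_anticorrelation(self):
        R = np.array([[1.0, -1.0], [-1.0, 1.0]])
        for beta in (1, 3, 7):
            A = adjacency_from_correlation(R, beta, "signed")
            assert A[0, 1] == 0.0

    def test_asymmetric_input_refused(self):
        R = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            adjacency_from_correlation(R, 2)

    def test_range_and_diagonal_property(self, rng):
        for n in (3, 8, 15):
            A = adjacency_from_correlation(random_correlation(rng, n), 4)
            assert np.allclose(A, A.T)
            assert A.min() >= 0 and A.max() <= 1
            assert np.allclose(np.diag(A), 1.0)


def tom_oracle(A):
    """Naive O(n^3) topological overlap, straight from the definition."""
    n = A.shape[0]
    k = [sum(A[i, u] for u in range(n) if u != i) for i in range(n)]
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(
                A[i, u] * A[u, j] for u in range(n) if u != i and u != j
            )
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


class TestTom:
    def test_disconnected_pair_without_shared_neighbors(self):
        A = np.eye(4)
        tom = tom_similarity(A)
        assert tom[0, 1] == 0.0

    def test_three_node_fixture(self):
        # A12 = A13 = 0.5, A23 = 0 -> TOM_23 = 0.25 / 1.5
        A = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.0], [0.5, 0.0, 1.0]])
        tom = tom_similarity(A)
        assert tom[1, 2] == pytest.approx(0.25 / 1.5, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 12, 20, 30])
    def test_matches_triple_loop_oracle(self, rng, n):
        A = adjacency_from_correlation(random_correlation(rng, n), 3)
        np.testing.assert_allclose(tom_similarity(A), tom_oracle(A), atol=1e-12)

    def test_symmetry_range_diagonal(self, rng):
        for n in (4, 10, 25):
            A = adjacency_from_correlation(random_correlation(rng, n), 5)
            tom = tom_similarity(A)
            assert np.allclose(tom, tom.T)
            assert tom.min() >= 0 and tom.max() <= 1
            assert np.allclose(np.diag(tom), 1.0)

    def test_invalid_adjacency_refused(self):
        with pytest.raises(ValueError, match="adjacency"):
            tom_similarity(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestSoftThreshold:
    def test_first_crossing_rule(self):
        rows = [
            PowerFitRow(p, r, 1.0)
            for p, r in zip((1, 2, 3, 4, 5), (0.2, 0.5, 0.81, 0.9, 0.95))
        ]
        assert choose_power(rows, 0.8) == 3

    def test_fallback_to_best_fit(self):
        rows = [PowerFitRow(p, r, 1.0) for p, r in [(1, 0.1), (2, 0.6), (3, 0.4)]]
        assert choose_power(rows, 0.8) == 2

    def test_mean_connectivity_decreases_with_power(self, rng):
        layer = make_layer(rng.standard_normal((30, 25)))
        params = NetworkParams(power_grid=(1, 2, 4, 8), rsq_target=0.99)
        rows, _ = soft_threshold_scan(layer, params)
        ks = [r.mean_connectivity for r in rows]
        assert all(a > b for a, b in zip(ks, ks[1:]))
        # oracle: direct degree computation on the same correlation matrix
        R = correlation_matrix(layer)
        k1 = connectivity(adjacency_from_correlation(R, 1))
        assert rows[0].mean_connectivity == pytest.approx(k1.mean(), abs=1e-12)

    def test_constant_feature_named_in_error(self, rng):
        vals = rng.standard_normal((12, 3))
        vals[:, 1] = 7.0
        layer = make_layer(vals)
        with pytest.raises(ValueError, match="f2"):
            soft_threshold_scan(layer, NetworkParams())

    def test_few_samples_warns(self, rng):
        layer = make_layer(rng.standard_normal((5, 6)))
        with pytest.warns(UserWarning, match="unreliable"):
            soft_threshold_scan(layer, NetworkParams(power_grid=(1, 2)))


def block_tom(sizes, within=1.0, between=0.0):
    n = sum(sizes)
    tom = np.full((n, n), between)
    start = 0
    for s in sizes:
        tom[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(tom, 1.0)
    return tom


class TestCutDendrogram:
    def test_two_perfect_blocks(self):
        tom = block_tom([4, 3])
        fids = [f"f{i}" for i in range(7)]
        a = cut_dendrogram_to_modules(tom, fids, NetworkParams(min_module_size=2))
        assert a.labels == ["M1"] * 4 + ["M2"] * 3

    def test_small_block_left_unassigned(self):
        tom = block_tom([5, 2])
        fids = [f"f{i}" for i in range(7)]
        a = cut_dendrogram_to_modules(tom, fids, NetworkParams(min_module_size=3))
        assert a.labels == ["M1"] * 5 + ["unassigned"] * 2

    def test_hand_traced_six_feature_tree(self):
        # blocks {f1,f2,f3} at TOM .9, {f4,f5} at .8, f6 isolated;
        # average linkage merges at d=.1, .1, .2 then everything at 1.0;
        # cut at .99 of max height separates the three branches.
        tom = np.zeros((6, 6))
        tom[:3, :3] = 0.9
        tom[3:5, 3:5] = 0.8
        np.fill_diagonal(tom, 1.0)
        fids = [f"f{i + 1}" for i in range(6)]
        a = cut_dendrogram_to_modules(tom, fids, NetworkParams(min_module_size=2))
        assert a.labels == ["M1", "M1", "M1", "M2", "M2", "unassigned"]

    def test_everything_unassigned_below_min_size(self):
        tom = block_tom([3])
        with pytest.warns(UserWarning, match="unassigned"):
            a = cut_dendrogram_to_modules(
                tom, ["f1", "f2", "f3"], NetworkParams(min_module_size=5)
            )
        assert set(a.labels) == {"unassigned"}


class TestEigengene:
    def test_rank_one_module_recovers_profile(self, rng):
        z = rng.standard_normal(15)
        layer = make_layer(np.column_stack([z, z, z]))
        eig = module_eigengene(layer, ["f1", "f2", "f3"])
        assert np.linalg.norm(eig) == pytest.approx(1.0)
        assert np.corrcoef(eig, z)[0, 1] == pytest.approx(1.0)

    def test_sign_orientation_is_deterministic(self, rng):
        z = rng.standard_normal(12)
        layer = make_layer(np.column_stack([z, -z]))
        eig1 = module_eigengene(layer, ["f1", "f2"])
        eig2 = module_eigengene(layer, ["f1", "f2"])
        np.testing.assert_array_equal(eig1, eig2)
        assert abs(np.corrcoef(eig1, z)[0, 1]) == pytest.approx(1.0)
        # orientation rule falls back to the first member when the mean
        # profile vanishes
        assert np.corrcoef(eig1, z)[0, 1] > 0

    def test_matches_independent_pca_oracle(self, rng):
        layer = make_layer(rng.standard_normal((20, 5)))
        eig = module_eigengene(layer, layer.feature_ids)
        Z = (layer.values - layer.values.mean(0)) / layer.values.std(0)
        # oracle: eigendecomposition of the sample Gram matrix
        w, V = np.linalg.eigh(Z @ Z.T)
        pc1 = V[:, np.argmax(w)]
        assert abs(np.corrcoef(eig, pc1)[0, 1]) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_member_named(self, rng):
        vals = rng.standard_normal((10, 2))
        vals[:, 1] = 3.0
        layer = make_layer(vals)
        with pytest.raises(ValueError, match="f2"):
            module_eigengene(layer, ["f1", "f2"])


class TestMergeModules:
    def _two_block_layer(self, rng, shared_factor):
        f1 = rng.standard_normal(30)
        f2 = f1 if shared_factor else rng.standard_normal(30)
        a = 0.95
        blocks = [
            a * f[:, None] + np.sqrt(1 - a * a) * rng.standard_normal((30, 10))
            for f in (f1, f2)
        ]
        layer = make_layer(np.column_stack(blocks))
        assignment = ModuleAssignment(
            layer.feature_ids, ["M1"] * 10 + ["M2"] * 10
        )
        return layer, assignment

    def test_zero_height_never_merges(self, rng):
        layer, assignment = self._two_block_layer(rng, shared_factor=True)
        out = merge_close_modules(layer, assignment, 0.0)
        assert out.labels == assignment.labels

    def test_same_factor_modules_merge(self, rng):
        layer, assignment = self._two_block_layer(rng, shared_factor=True)
        out = merge_close_modules(layer, assignment, 0.25)
        assert len(out.module_ids) == 1
        assert set(out.labels) == {"M1"}

    def test_independent_modules_stay_separate(self, rng):
        layer, assignment = self._two_block_layer(rng, shared_factor=False)
        out = merge_close_modules(layer, assignment, 0.25)
        assert len(out.module_ids) == 2


class TestConnectivityAndHubs:
    def test_pair_module(self):
        A = np.array([[1.0, 0.7], [0.7, 1.0]])
        a = ModuleAssignment(["f1", "f2"], ["M1", "M1"])
        np.testing.assert_allclose(intramodular_connectivity(A, a), [0.7, 0.7])

    def test_hand_summed_triplet(self):
        # |cor| pattern 0.9 (f1,f2), 0.8 (f1,f3), 0.5 (f2,f3)
        R = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.5], [0.8, 0.5, 1.0]])
        a = ModuleAssignment(["f1", "f2", "f3"], ["M1"] * 3)
        k1 = intramodular_connectivity(adjacency_from_correlation(R, 1), a)
        np.testing.assert_allclose(k1, [1.7, 1.4, 1.3], atol=1e-12)
        k2 = intramodular_connectivity(adjacency_from_correlation(R, 2), a)
        np.testing.assert_allclose(k2, [1.45, 1.06, 0.89], atol=1e-12)

    def test_unassigned_features_score_zero(self):
        A = np.eye(3)
        a = ModuleAssignment(["f1", "f2", "f3"], ["M1", "M1", "unassigned"])
        assert intramodular_connectivity(A, a)[2] == 0.0

    def test_hub_is_argmax_of_k_within(self, rng):
        R = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.5], [0.8, 0.5, 1.0]])
        layer = make_layer(rng.standard_normal((10, 3)))
        a = ModuleAssignment(["f1", "f2", "f3"], ["M1"] * 3)
        k = intramodular_connectivity(adjacency_from_correlation(R, 1), a)
        hubs, hub_layer = top_hub_per_module(layer, a, k)
        assert hubs == {"M1": "f1"}
        assert hub_layer.feature_ids == ["f1"]
        np.testing.assert_array_equal(hub_layer.values[:, 0], layer.values[:, 0])
        assert hub_layer.provenance == "hubs"

    def test_exact_tie_breaks_lexicographically(self, rng):
        layer = make_layer(rng.standard_normal((8, 2)), prefix_f="g")
        a = ModuleAssignment(["g1", "g2"], ["M1", "M1"])
        k = np.array([0.5, 0.5])
        hubs, _ = top_hub_per_module(layer, a, k)
        assert hubs == {"M1": "g1"}

    def test_one_hub_column_per_module(self, planted_layer_spec, fitted_params):
        bundle, _ = simulate_bundle(planted_layer_spec, seed=3)
        res = detect_modules(bundle.layer("host"), fitted_params)
        assert res.hub_layer.n_features == len(res.module_ids)
        for mod, hub in res.hubs.items():
            members = res.assignment.members(mod)
            assert hub in members
            kmap = dict(zip(res.assignment.feature_ids, res.k_within))
            assert kmap[hub] == max(kmap[f] for f in members)


class TestDetectModules:
    def test_noiseless_two_module_recovery(self, rng):
        f1, f2 = rng.standard_normal((2, 20))
        cols = [f1 * c for c in rng.uniform(0.5, 2.0, 8)] + [
            f2 * c for c in rng.uniform(0.5, 2.0, 8)
        ]
        layer = make_layer(np.column_stack(cols))
        res = detect_modules(layer, NetworkParams(power=6, min_module_size=4))
        truth = ["A"] * 8 + ["B"] * 8
        assert adjusted_rand_score(truth, res.assignment.labels) == 1.0

    def test_determinism(self, planted_layer_spec, fitted_params):
        bundle, _ = simulate_bundle(planted_layer_spec, seed=5)
        r1 = detect_modules(bundle.layer("host"), fitted_params)
        r2 = detect_modules(bundle.layer("host"), fitted_params)
        assert r1.assignment.labels == r2.assignment.labels
        assert r1.hubs == r2.hubs
        np.testing.assert_array_equal(r1.k_within, r2.k_within)

    def test_feature_permutation_invariance(self, planted_layer_spec, fitted_params, rng):
        bundle, _ = simulate_bundle(planted_layer_spec, seed=6)
        layer = bundle.layer("host")
        perm = rng.permutation(layer.n_features)
        permuted = OmicsLayer(
            layer.layer_id,
            layer.sample_ids,
            [layer.feature_ids[i] for i in perm],
            layer.values[:, perm],
        )
        r1 = detect_modules(layer, fitted_params)
        r2 = detect_modules(permuted, fitted_params)
        m1 = r1.assignment.as_dict()
        m2 = r2.assignment.as_dict()
        labels1 = [m1[f] for f in layer.feature_ids]
        labels2 = [m2[f] for f in layer.feature_ids]
        assert adjusted_rand_score(labels1, labels2) == 1.0

    def test_missing_values_refused(self, rng):
        vals = rng.standard_normal((10, 5))
        vals[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            detect_modules(make_layer(vals), NetworkParams(min_module_size=2))

    def test_feature_cap_enforced(self, rng):
        layer = make_layer(rng.standard_normal((5, 30)))
        with pytest.raises(ValueError, match="cap"):
            ModuleNetwork(layer, NetworkParams(max_features=10))

    def test_eigengene_tracks_planted_factor(self, fitted_params):
        from holocorr import LayerSpec, ModuleSpec, SimulationSpec, evaluate_recovery

        spec = SimulationSpec(
            n_samples=40,
            layers=[LayerSpec("L", [ModuleSpec("A", 25, 0.85)], 10)],
            seed=0,
        )
        hits = 0
        for seed in range(10):
            bundle, truth = simulate_bundle(spec, seed=seed)
            res = detect_modules(bundle.layer("L"), fitted_params)
            rep = evaluate_recovery(truth, res, "L")
            if rep.eigengene_factor_corr and min(rep.eigengene_factor_corr.values()) >= 0.9:
                hits += 1
        assert hits >= 9
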