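import numpy as np
import pytest

from fcgnn import (
    BaseGNN,
    BaseModelConfig,
    EnsembleConfig,
    OptimizerConfig,
    base_forward,
    ensemble_fit,
    ensemble_predict,
    gat_layer,
    gcn_layer,
    load_model,
    make_batch,
    prepare_graphs,
    sage_layer,
    save_model,
    train_base,
)
from fcgnn.gnn_models import PreppedGraph

ARCHS = ("gcn", "gat", "sage")


def random_graph(rng, n, p=0.4):
    """Random undirected edge set on n nodes."""
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return edges


def dense_gcn_oracle(x, a, w=None):
    n = a.shape[0]
    a_sl = a + np.eye(n)
    d = np.diag(1.0 / np.sqrt(a_sl.sum(axis=1)))
    h = x if w is None else x @ w
    return d @ a_sl @ d @ h


def sage_loop_oracle(x, edges, w_self, w_neigh):
    n = x.shape[0]
    nbrs = {i: [] for i in range(n)}
    for i, j in edges:
        nbrs[i].append(j)
        nbrs[j].append(i)
    out = np.zeros((n, w_self.shape[1]))
    for i in range(n):
        mean = (np.mean([x[j] for j in nbrs[i]], axis=0)
                if nbrs[i] else np.zeros(x.shape[1]))
        out[i] = x[i] @ w_self + mean @ w_neigh
    return out


class TestGCNLayer:
    def test_matches_dense_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(3, 10))
            edges = random_graph(rng, n)
            a = np.zeros((n, n))
            for i, j in edges:
                a[i, j] = a[j, i] = rng.uniform(0.1, 1.0)
            x = rng.normal(size=(n, 4))
            w = rng.normal(size=(4, 3))
            assert np.allclose(gcn_layer(x, a, w),
                               dense_gcn_oracle(x, a, w), atol=1e-6)

    def test_no_edges_identity_propagation(self, rng):
        x = rng.normal(size=(5, 3))
        out = gcn_layer(x, np.zeros((5, 5)))
        assert np.allclose(out, x, atol=1e-12)

    def test_path_graph_unit_weights(self, rng):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1.0
        x = rng.normal(size=(3, 2))
        assert np.allclose(gcn_layer(x, a), dense_gcn_oracle(x, a),
                           atol=1e-6)

    def test_permutation_equivariance(self, rng):
        n = 7
        a = np.zeros((n, n))
        for i, j in random_graph(rng, n):
            a[i, j] = a[j, i] = rng.uniform(0.1, 1.0)
        x = rng.normal(size=(n, 4))
        perm = rng.permutation(n)
        out = gcn_layer(x, a)
        out_p = gcn_layer(x[perm], a[np.ix_(perm, perm)])
        assert np.allclose(out_p, out[perm], atol=1e-6)

    def test_rejects_bad_adjacency(self, rng):
        x = rng.normal(size=(4, 2))
        asym = np.triu(np.ones((4, 4)), 1)
        with pytest.raises(ValueError):
            gcn_layer(x, asym)
        neg = -np.ones((4, 4)) + np.eye(4)
        with pytest.raises(ValueError):
            gcn_layer(x, neg)


class TestGATLayer:
    def test_attention_rows_sum_to_one(self, rng):
        for _ in range(10):
            n = int(rng.integers(2, 9))
            edges = random_graph(rng, n)
            x = rng.normal(size=(n, 3))
            _, (pairs, alpha) = gat_layer(x, edges, heads=4, out_dim=5,
                                          seed=0, return_attention=True)
            dst = pairs[:, 1]
            for d in range(n):
                rows = alpha[dst == d]
                assert np.allclose(rows.sum(axis=0), 1.0, atol=1e-6)

    def test_single_node_self_attention(self, rng):
        x = rng.normal(size=(1, 4))
        w = rng.normal(size=(4, 6))  # 2 heads x 3
        out, (pairs, alpha) = gat_layer(x, [], heads=2, out_dim=3, weight=w,
                                        return_attention=True)
        assert np.allclose(alpha, 1.0)
        assert np.allclose(out, (x @ w), atol=1e-6)

    def test_identical_features_uniform_attention(self, rng):
        x = np.tile(rng.normal(size=(1, 3)), (2, 1))
        _, (pairs, alpha) = gat_layer(x, [(0, 1)], heads=2, out_dim=4,
                                      seed=3, return_attention=True)
        assert np.allclose(alpha, 0.5, atol=1e-6)

    def test_head_averaging_dimensions(self, rng):
        x = rng.normal(size=(5, 3))
        edges = [(0, 1), (1, 2), (3, 4)]
        out_c = gat_layer(x, edges, heads=4, out_dim=5, concat=True, seed=1)
        out_a = gat_layer(x, edges, heads=4, out_dim=5, concat=False, seed=1)
        assert out_c.shape == (5, 20)
        assert out_a.shape == (5, 5)
        assert np.allclose(out_a,
                           out_c.reshape(5, 4, 5).mean(axis=1), atol=1e-6)


class TestSAGELayer:
    def test_matches_loop_oracle(self, rng):
        for _ in range(10):
            n = 6
            edges = random_graph(rng, n)
            x = rng.normal(size=(n, 3))
            w_self = rng.normal(size=(3, 4))
            w_neigh = rng.normal(size=(3, 4))
            assert np.allclose(
                sage_layer(x, edges, w_self, w_neigh),
                sage_loop_oracle(x, edges, w_self, w_neigh), atol=1e-6)

    def test_isolated_node_uses_only_self(self, rng):
        x = rng.normal(size=(3, 2))
        w_self = rng.normal(size=(2, 2))
        w_neigh = rng.normal(size=(2, 2))
        out = sage_layer(x, [(0, 1)], w_self, w_neigh)
        assert np.allclose(out[2], x[2] @ w_self, atol=1e-12)

    def test_star_center_aggregates_leaf_feature(self, rng):
        f = rng.normal(size=3)
        x = np.vstack([rng.normal(size=3), np.tile(f, (4, 1))])
        edges = [(0, j) for j in range(1, 5)]
        w_self = np.zeros((3, 3))
        out = sage_layer(x, edges, w_self, np.eye(3))
        assert np.allclose(out[0], f, atol=1e-12)


class TestBaseForward:
    @pytest.mark.parametrize("arch", ARCHS)
    def test_eval_mode_deterministic(self, arch, small_prepped):
        prepped, _ = small_prepped
        model = BaseGNN(BaseModelConfig.for_arch(arch),
                        in_dim=prepped[0].x.shape[1], seed=0)
        batch = make_batch(prepped[:8])
        z1, p1 = base_forward(batch, model)
        z2, p2 = base_forward(batch, model)
        assert np.array_equal(z1, z2)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("arch", ARCHS)
    def test_duplicated_graph_same_logits(self, arch, small_prepped):
        prepped, _ = small_prepped
        model = BaseGNN(BaseModelConfig.for_arch(arch),
                        in_dim=prepped[0].x.shape[1], seed=0)
        batch = make_batch([prepped[0], prepped[0], prepped[1]])
        z, _ = base_forward(batch, model)
        assert np.allclose(z[0], z[1], atol=1e-6)

    @pytest.mark.parametrize("arch", ARCHS)
    def test_pooled_output_permutation_invariant(self, arch, rng,
                                                 small_cohort):
        # relabelling the nodes (adjacency conjugated by P, feature ROWS
        # permuted, each node keeping its own feature vector) must leave
        # the pooled graph-level logits unchanged
        import copy

        cohort, _ = small_cohort
        g = cohort.graphs[0]
        n = g.n_nodes
        perm = rng.permutation(n)
        inv = np.argsort(perm)  # new index of original node i is inv[i]
        gp = copy.deepcopy(g)
        gp.adjacency = g.adjacency[np.ix_(perm, perm)]
        gp.node_features = g.node_features[perm]
        gp.edges = {(min(inv[i], inv[j]), max(inv[i], inv[j]))
                    for i, j in g.edges}
        model = BaseGNN(BaseModelConfig.for_arch(arch), in_dim=n, seed=0)
        zb, _ = base_forward(make_batch([PreppedGraph(g)]), model)
        zp, _ = base_forward(make_batch([PreppedGraph(gp)]), model)
        assert np.allclose(zb, zp, atol=1e-4)

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError):
            make_batch([])


class TestTrainBase:
    def test_first_epoch_loss_near_chance(self, small_prepped):
        prepped, _ = small_prepped
        model = train_base(prepped, BaseModelConfig.for_arch("gcn"),
                           OptimizerConfig(epochs=1, seed=0))
        assert model.history[0] == pytest.approx(np.log(2.0), abs=0.3)

    def test_separable_cohort_learns(self, small_prepped):
        prepped, labels = small_prepped
        model = train_base(prepped, BaseModelConfig.for_arch("gcn"),
                           OptimizerConfig(epochs=40, seed=0))
        preds = np.argmax(model.predict_proba(prepped), axis=1)
        assert np.mean(preds == labels) >= 0.95

    def test_same_seed_identical_trajectory(self, small_prepped):
        prepped, _ = small_prepped
        cfg = BaseModelConfig.for_arch("sage")
        m1 = train_base(prepped, cfg, OptimizerConfig(epochs=3, seed=7))
        m2 = train_base(prepped, cfg, OptimizerConfig(epochs=3, seed=7))
        assert m1.history == m2.history
        for p1, p2 in zip(m1.params, m2.params):
            assert np.array_equal(p1.data, p2.data)

    def test_different_seed_different_weights(self, small_prepped):
        prepped, _ = small_prepped
        cfg = BaseModelConfig.for_arch("sage")
        m1 = train_base(prepped, cfg, OptimizerConfig(epochs=2, seed=7))
        m2 = train_base(prepped, cfg, OptimizerConfig(epochs=2, seed=8))
        assert any(not np.array_equal(p1.data, p2.data)
                   for p1, p2 in zip(m1.params, m2.params))

    def test_single_class_errors(self, small_prepped):
        prepped, labels = small_prepped
        only0 = [g for g, y in zip(prepped, labels) if y == 0]
        with pytest.raises(ValueError, match="both classes"):
            train_base(only0, BaseModelConfig.for_arch("gcn"),
                       OptimizerConfig(epochs=1, seed=0))


@pytest.fixture(scope="module")
def trained_bases_and_prepped():
    from fcgnn import GraphConfig
    from fcgnn.synthetic_data import SyntheticCohortSpec, generate_cohort

    spec = SyntheticCohortSpec(n_per_group=(30, 30), n_regions=24,
                               effect_size=1.5, noise_sd=0.2,
                               n_effect_edges=30, seed=42)
    cohort, _ = generate_cohort(spec, GraphConfig(k=5))
    prepped = prepare_graphs(cohort.graphs)
    opt = OptimizerConfig(epochs=15, seed=0)
    bases = [train_base(prepped, BaseModelConfig.for_arch(a), opt)
             for a in ARCHS]
    return bases, prepped, cohort.labels


class TestEnsemble:
    def test_frozen_bases_unchanged(self, trained_bases_and_prepped):
        bases, prepped, _ = trained_bases_and_prepped
        before = [b.predict_logits(prepped[:10]) for b in bases]
        ensemble_fit(bases, prepped, EnsembleConfig(),
                     OptimizerConfig(epochs=5, seed=1))
        after = [b.predict_logits(prepped[:10]) for b in bases]
        for zb, za in zip(before, after):
            assert np.array_equal(zb, za)

    def test_meta_input_width(self, trained_bases_and_prepped):
        bases, prepped, _ = trained_bases_and_prepped
        ens = ensemble_fit(bases, prepped, EnsembleConfig(),
                           OptimizerConfig(epochs=2, seed=1))
        assert ens.base_features(prepped[:4]).shape == (4, 6)

    def test_prediction_normalised_and_deterministic(
            self, trained_bases_and_prepped):
        bases, prepped, _ = trained_bases_and_prepped
        ens = ensemble_fit(bases, prepped, EnsembleConfig(),
                           OptimizerConfig(epochs=5, seed=1))
        p1, y1 = ensemble_predict(ens, prepped[:12])
        p2, y2 = ensemble_predict(ens, prepped[:12])
        assert np.array_equal(p1, p2)
        assert np.array_equal(y1, y2)
        assert np.allclose(p1.sum(axis=1), 1.0, atol=1e-6)

    def test_ensemble_not_much_worse_than_best_base(
            self, trained_bases_and_prepped):
        bases, prepped, labels = trained_bases_and_prepped
        ens = ensemble_fit(bases, prepped, EnsembleConfig(),
                           OptimizerConfig(epochs=10, seed=1))
        _, preds = ensemble_predict(ens, prepped)
        acc_ens = np.mean(preds == labels)
        accs = [np.mean(np.argmax(b.predict_proba(prepped), axis=1)
                        == labels) for b in bases]
        assert acc_ens >= max(accs) - 0.05

    def test_checkpoint_round_trip(self, trained_bases_and_prepped,
                                   tmp_path):
        bases, prepped, _ = trained_bases_and_prepped
        ens = ensemble_fit(bases, prepped, EnsembleConfig(),
                           OptimizerConfig(epochs=2, seed=1))
        path = tmp_path / "ens.json"
        save_model(ens, path)
        loaded = load_model(path)
        p1, _ = ensemble_predict(ens, prepped[:6])
        p2, _ = ensemble_predict(loaded, prepped[:6])
        assert np.allclose(p1, p2, atol=1e-7)
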