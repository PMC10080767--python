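import numpy as np
import pytest

from mhamfd._autodiff import Tensor
from mhamfd.attention import (
    compute_class_weights,
    forward,
    hierar_aggregate,
    init_params,
    inter_aggregate,
    intra_aggregate,
    loss_fn,
)
from mhamfd.hetero import build_hetero_graph
from mhamfd.relations import (
    build_all_relation_graphs,
    build_relation_adjacency,
    enumerate_relation_paths,
    group_by_level,
    RelationPath,
)

from _oracles import dense_forward, dense_intra, dense_semantic
from conftest import random_claims

RELATIONS = enumerate_relation_paths(3)


def small_graph(seed=0, n_patients=5):
    rng = np.random.default_rng(seed)
    claims = random_claims(rng, n_patients=n_patients)
    g = build_hetero_graph(claims)
    X = np.random.default_rng(seed + 100).standard_normal((g.n_patients, 6))
    return g, X


class TestInitParams:
    def test_shapes_follow_heads_and_dims(self):
        p = init_params(10, RELATIONS, d=64, heads=8)
        assert p.d_head == 8
        assert p.rel_W["PDP"].shape == (8, 10, 8)
        assert p.rel_a_self["PDTMP"].shape == (8, 8, 1)
        assert len(p.rel_W) == 7

    def test_same_seed_bitwise_identical(self):
        a = init_params(5, RELATIONS, seed=3)
        b = init_params(5, RELATIONS, seed=3)
        for (ta, _), (tb, _) in zip(a.trainable(), b.trainable()):
            np.testing.assert_array_equal(ta.data, tb.data)

    def test_dim_not_divisible_by_heads_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            init_params(5, RELATIONS, d=30, heads=8)


class TestIntra:
    def test_isolated_patient_attends_only_itself(self):
        g, X = small_graph(1, n_patients=1)
        params = init_params(X.shape[1], RELATIONS, d=8, heads=2, classifier_hidden=0, seed=0)
        adj = build_relation_adjacency(g, RelationPath.from_name("PDTMP"))
        emb, alpha, _ = intra_aggregate(X, adj, params)
        assert alpha[0, 0] == pytest.approx(1.0)
        oracle, _ = dense_intra(
            X, adj.neighbors, params.rel_W["PDTMP"].data,
            params.rel_a_self["PDTMP"].data, params.rel_a_neigh["PDTMP"].data,
        )
        np.testing.assert_allclose(emb.data, oracle, atol=1e-10)

    def test_identical_features_give_uniform_attention(self):
        g, X = small_graph(2, n_patients=6)
        X = np.ones((g.n_patients, 4))
        params = init_params(4, RELATIONS, d=8, heads=2, seed=1)
        for name in ("PDP", "PTP"):
            adj = build_relation_adjacency(g, RelationPath.from_name(name))
            _, alpha, _ = intra_aggregate(X, adj, params)
            for i in range(adj.n):
                att = sorted(adj.neighbors[i] | {i})
                np.testing.assert_allclose(alpha[i, att], 1.0 / len(att), atol=1e-12)

    @pytest.mark.parametrize("heads", [1, 4])
    def test_matches_dense_oracle(self, heads):
        g, X = small_graph(3, n_patients=5)
        params = init_params(6, RELATIONS, d=8, heads=heads, seed=2)
        for path in RELATIONS:
            adj = build_relation_adjacency(g, path)
            emb, alpha, _ = intra_aggregate(X, adj, params)
            oracle_emb, oracle_alpha = dense_intra(
                X, adj.neighbors, params.rel_W[path.name].data,
                params.rel_a_self[path.name].data, params.rel_a_neigh[path.name].data,
            )
            np.testing.assert_allclose(emb.data, oracle_emb, atol=1e-6)
            np.testing.assert_allclose(alpha, oracle_alpha.mean(axis=0), atol=1e-6)

    def test_non_finite_features_rejected(self):
        g, X = small_graph(4)
        X[0, 0] = np.nan
        params = init_params(6, RELATIONS, d=8, heads=2)
        adj = build_relation_adjacency(g, RELATIONS[0])
        with pytest.raises(ValueError, match="finite"):
            intra_aggregate(X, adj, params)


class TestSemanticAttention:
    def setup_method(self):
        self.params = init_params(4, RELATIONS, d=8, heads=2, d_att=16, seed=5)

    def test_single_relation_level_gets_weight_one(self):
        e = Tensor(np.random.default_rng(0).standard_normal((5, 8)))
        combined, beta, _ = inter_aggregate([e], self.params)
        assert beta == pytest.approx([1.0])
        np.testing.assert_array_equal(combined.data, e.data)

    def test_identical_embeddings_share_weight_equally(self):
        e = np.random.default_rng(1).standard_normal((5, 8))
        _, beta, _ = inter_aggregate([Tensor(e), Tensor(e.copy())], self.params)
        np.testing.assert_allclose(beta, [0.5, 0.5], atol=1e-12)
        _, gamma, _ = hierar_aggregate([Tensor(e)] * 3, self.params)
        np.testing.assert_allclose(gamma, np.ones(3) / 3, atol=1e-12)

    @pytest.mark.parametrize("m", [2, 3])
    def test_matches_dense_oracle(self, m):
        rng = np.random.default_rng(m)
        embeds = [rng.standard_normal((6, 8)) for _ in range(m)]
        got, beta, _ = inter_aggregate([Tensor(e) for e in embeds], self.params)
        want, want_beta = dense_semantic(
            embeds, self.params.W0.data, self.params.b0.data, self.params.q0.data
        )
        np.testing.assert_allclose(beta, want_beta, atol=1e-6)
        np.testing.assert_allclose(got.data, want, atol=1e-6)
        assert beta.sum() == pytest.approx(1.0)

    def test_shape_mismatch_rejected(self):
        a, b = Tensor(np.zeros((3, 8))), Tensor(np.zeros((4, 8)))
        with pytest.raises(ValueError, match="shape"):
            inter_aggregate([a, b], self.params)
        with pytest.raises(ValueError, match="shape"):
            hierar_aggregate([a, b], self.params)


class TestForward:
    def test_report_layout_three_levels(self):
        g, X = small_graph(6)
        params = init_params(6, RELATIONS, d=8, heads=2, seed=0)
        levels = group_by_level(build_all_relation_graphs(g))
        res = forward(X, levels, params)
        assert [len(res.report.beta[lvl]) for lvl in (1, 2, 3)] == [3, 3, 1]
        assert res.report.gamma.shape == (3,)
        assert res.report.beta[3] == pytest.approx([1.0])
        d = res.report.as_dict()
        assert set(d["level_attention"]) == {"single", "dual", "triple"}
        assert set(d["relation_attention"]) == {p.name for p in RELATIONS}

    def test_attention_weights_normalised(self):
        g, X = small_graph(7, n_patients=8)
        params = init_params(6, RELATIONS, d=16, heads=4, seed=1)
        levels = group_by_level(build_all_relation_graphs(g))
        res = forward(X, levels, params)
        for name, alpha in res.report.alpha.items():
            np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-6, err_msg=name)
        for lvl, beta in res.report.beta.items():
            assert beta.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.report.gamma.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_features_zero_classifier_give_even_odds(self):
        g, X = small_graph(8)
        params = init_params(6, RELATIONS, d=8, heads=2, classifier_hidden=0, seed=0)
        params.Wc.data[:] = 0.0
        levels = group_by_level(build_all_relation_graphs(g))
        res = forward(np.zeros_like(X), levels, params)
        np.testing.assert_array_equal(res.logits.data, 0.0)

    @pytest.mark.parametrize("classifier_hidden", [0, 16])
    def test_full_forward_matches_chained_dense_oracle(self, classifier_hidden):
        g, X = small_graph(9, n_patients=5)
        params = init_params(
            6, RELATIONS, d=8, heads=2, d_att=16, seed=3, classifier_hidden=classifier_hidden
        )
        levels = group_by_level(build_all_relation_graphs(g))
        res = forward(X, levels, params)
        H, logits = dense_forward(X, levels, params)
        np.testing.assert_allclose(res.H.data, H, atol=1e-5)
        np.testing.assert_allclose(res.logits.data, logits, atol=1e-5)

    def test_permutation_equivariance(self):
        g, X = small_graph(10, n_patients=7)
        params = init_params(6, RELATIONS, d=8, heads=2, seed=4)
        adjs = build_all_relation_graphs(g)
        levels = group_by_level(adjs)
        res = forward(X, levels, params)

        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_patients)  # new_index -> old_index
        inv = np.argsort(perm)
        permuted = {}
        for name, adj in adjs.items():
            neigh = [set(int(inv[j]) for j in adj.neighbors[perm[i]]) for i in range(adj.n)]
            permuted[name] = type(adj)(path=adj.path, n=adj.n, neighbors=neigh)
        res_p = forward(X[perm], group_by_level(permuted), params)
        np.testing.assert_allclose(res_p.H.data, res.H.data[perm], atol=1e-5)
        np.testing.assert_allclose(res_p.logits.data, res.logits.data[perm], atol=1e-5)

        labels = np.array([1, 0, 1, 0, 0, 1, -1])
        mask = labels >= 0
        loss = loss_fn(res.logits, labels, mask)
        loss_p = loss_fn(res_p.logits, labels[perm], mask[perm])
        assert loss_p.data == pytest.approx(loss.data, abs=1e-5)


class TestLoss:
    def test_perfect_predictions_give_zero_loss(self):
        logits = Tensor(np.array([[50.0, -50.0], [-50.0, 50.0]]))
        loss = loss_fn(logits, np.array([0, 1]), np.array([0, 1]))
        assert loss.data == pytest.approx(0.0, abs=1e-10)

    def test_even_odds_give_ln2(self):
        logits = Tensor(np.zeros((4, 2)))
        loss = loss_fn(logits, np.array([0, 1, 0, 1]), np.arange(4))
        assert loss.data == pytest.approx(np.log(2), abs=1e-12)

    def test_class_weighted_mean_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal((6, 2))
        y = np.array([0, 0, 0, 0, 0, 1])
        w = np.array([1.0, 70.0])
        loss = loss_fn(Tensor(z), y, np.arange(6), w)
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        nll = -np.log(p[np.arange(6), y])
        expected = (w[y] * nll).sum() / w[y].sum()
        assert loss.data == pytest.approx(expected, rel=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            loss_fn(Tensor(np.zeros((2, 2))), np.array([0, 1]), np.array([], dtype=int))

    def test_inverse_class_weights_normalised_to_mean_one(self):
        labels = np.array([1, 0, 0, 0, 0, 0, 0, 0])
        w = compute_class_weights(labels, np.arange(8))
        assert w.mean() == pytest.approx(1.0)
        assert w[1] / w[0] == pytest.approx(7.0)


class TestGradients:
    def test_autodiff_matches_finite_differences(self):
        g, X = small_graph(12, n_patients=5)
        params = init_params(6, RELATIONS, d=8, heads=2, d_att=16, seed=7)
        levels = group_by_level(build_all_relation_graphs(g))
        labels = (np.arange(g.n_patients) % 2).astype(np.int64)
        mask = np.arange(g.n_patients)

        def compute_loss():
            res = forward(X, levels, params)
            return loss_fn(res.logits, labels, mask)

        loss = compute_loss()
        loss.backward()
        rng = np.random.default_rng(0)
        eps = 1e-6
        checked = 0
        for t, _ in params.trainable():
            grad = t.grad
            assert grad is not None and np.all(np.isfinite(grad))
            flat = t.data.reshape(-1)
            for idx in rng.choice(flat.size, size=min(3, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = compute_loss().data
                flat[idx] = orig - eps
                down = compute_loss().data
                flat[idx] = orig
                fd = (up - down) / (2 * eps)
                ad = grad.reshape(-1)[idx]
                # floor the scale at FD noise level so near-zero gradients
                # are compared absolutely rather than relatively
                denom = max(abs(fd), abs(ad), 1e-6)
                assert abs(fd - ad) / denom < 1e-4, (t.shape, idx, fd, ad)
                checked += 1
        assert checked >= 30
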