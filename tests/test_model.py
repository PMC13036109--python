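"""Network components: encoder, KL, attention, pooling, head, loss, training."""

import numpy as np
import pytest

from cytomod import (ModelConfig, ModulePartition, SimulationConfig, build_graph,
                     classify, encode, evaluate_metrics, gat_propagate,
                     generate_cohort, kl_term, load_model, module_pool,
                     predict_proba, save_model, stratified_split, total_loss,
                     train_model, zscore_normalize)
from cytomod.graph import CoexpressionGraph
from cytomod.model import GeneModuleNet, LossBreakdown, welch_t_scores


@pytest.fixture(scope="module")
def small_net(toy_graph, toy_partition):
    config = ModelConfig(seed=3, init_scheme="random")
    return GeneModuleNet(toy_graph.n_nodes, toy_partition, toy_graph, config)


class TestKL:
    def test_prior_matches_posterior(self):
        assert kl_term(np.zeros(4), np.ones(4)) == pytest.approx(0.0, abs=1e-12)

    def test_unit_mean_closed_form(self):
        assert kl_term(np.array([1.0]), np.array([1.0])) == pytest.approx(0.5)

    def test_wide_posterior_closed_form(self):
        # 0.5 * (4 - 1 - ln 4) ~ 0.8069
        assert kl_term(np.array([0.0]), np.array([2.0])) == pytest.approx(
            0.5 * (4 - 1 - np.log(4)), abs=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            kl_term(np.zeros(2), np.array([1.0, 0.0]))


class TestEncoder:
    def test_eval_mode_z_equals_mu(self, small_net):
        x = np.random.default_rng(0).normal(size=(3, small_net.n_genes))
        state = encode(small_net, x, sample=False)
        assert np.array_equal(state.z, state.mu)
        assert np.all(state.sigma > 0)

    def test_identical_samples_identical_latents(self, small_net):
        x = np.random.default_rng(1).normal(size=(1, small_net.n_genes))
        two = np.vstack([x, x])
        state = encode(small_net, two)
        assert np.array_equal(state.mu[0], state.mu[1])
        assert np.array_equal(state.node_embeddings[0], state.node_embeddings[1])

    def test_mu_gradient_wrt_input_nonzero(self, small_net):
        """Finite-difference sensitivity of mu to a single gene's expression."""
        rng = np.random.default_rng(2)
        x = rng.normal(size=(1, small_net.n_genes))
        eps = 1e-3
        xp, xm = x.copy(), x.copy()
        xp[0, 5] += eps
        xm[0, 5] -= eps
        d = (encode(small_net, xp).mu - encode(small_net, xm).mu) / (2 * eps)
        assert np.all(np.isfinite(d))
        assert np.abs(d).max() > 1e-8

    def test_dimension_mismatch_rejected(self, small_net):
        with pytest.raises(ValueError):
            encode(small_net, np.zeros((2, small_net.n_genes + 1)))


class TestGAT:
    def test_edgeless_graph_is_per_node_transform(self, toy_partition):
        """Only self-loops -> each node's output independent of the others."""
        n = toy_partition.n_genes
        empty = np.array([], dtype=np.int64)
        graph = CoexpressionGraph(n_nodes=n, edge_a=empty, edge_b=empty,
                                  r=np.array([]), weight=np.array([]))
        net = GeneModuleNet(n, toy_partition, graph, ModelConfig(seed=0,
                            init_scheme="random"))
        rng = np.random.default_rng(3)
        emb = rng.normal(size=(1, n, 32))
        base = gat_propagate(net, emb)
        emb2 = emb.copy()
        emb2[0, 7] += 10.0  # perturb one node
        out2 = gat_propagate(net, emb2)
        changed = np.abs(out2 - base).max(axis=2)[0] > 1e-8
        assert changed[7]
        assert not changed[np.arange(n) != 7].any()

    def test_attention_normalised_per_neighbourhood(self, small_net):
        """Attention coefficients over each in-neighbourhood sum to 1."""
        rng = np.random.default_rng(4)
        from cytomod.autodiff import Tensor, gather, segment_sum
        h = Tensor(rng.normal(size=(2, small_net.n_genes, 32)).astype(np.float32))
        B, N = 2, small_net.n_genes
        H = small_net.config.gat_heads
        Dh = 32 // H
        wh = (h @ small_net.params["gat_w"]).reshape(B, N, H, Dh)
        s_src = (wh * small_net.params["gat_asrc"]).sum(axis=3)
        s_dst = (wh * small_net.params["gat_adst"]).sum(axis=3)
        kappa = small_net.params["gat_kappa"].softplus()
        logits = (gather(s_src, small_net.src_plan)
                  + gather(s_dst, small_net.dst_plan)).leaky_relu(0.2) \
            + kappa * Tensor(small_net._lnw)
        shift = small_net.dst_plan.segment_reduce(logits.data, np.maximum)
        num = (logits - Tensor(shift[:, small_net.dst_plan.idx])).exp()
        denom = segment_sum(num, small_net.dst_plan)
        att = (num / gather(denom, small_net.dst_plan)).data
        sums = small_net.dst_plan.segment_reduce(att)
        assert np.allclose(sums, 1.0, atol=1e-5)

    def test_permutation_equivariance(self, toy_graph, toy_partition):
        """Permuting genes (and the graph consistently) permutes outputs."""
        n = toy_graph.n_nodes
        rng = np.random.default_rng(5)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        config = ModelConfig(seed=1, init_scheme="random")
        net = GeneModuleNet(n, toy_partition, toy_graph, config)

        # permuted copy: same parameters, permuted gene-wise state and graph
        part_p = ModulePartition(toy_partition.module_of_gene[perm])
        graph_p = CoexpressionGraph(
            n_nodes=n, edge_a=inv[toy_graph.edge_a], edge_b=inv[toy_graph.edge_b],
            r=toy_graph.r, weight=toy_graph.weight, gamma=toy_graph.gamma)
        net_p = GeneModuleNet(n, part_p, graph_p, config)
        for k, v in net.params.items():
            net_p.params[k].data = v.data.copy()
        net_p.params["gene_emb"].data = net.params["gene_emb"].data[perm]

        emb = rng.normal(size=(2, n, 32)).astype(np.float32)
        out = gat_propagate(net, emb)
        out_p = gat_propagate(net_p, emb[:, perm])
        assert np.allclose(out_p, out[:, perm], atol=1e-4)


class TestPoolingAndHead:
    def test_single_module_mean(self):
        part = ModulePartition(np.zeros(3, dtype=int))
        emb = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        pooled = module_pool(emb, part)
        assert np.allclose(pooled[0], [2 / 3, 2 / 3])

    def test_permutation_within_module_invariant(self):
        part = ModulePartition(np.array([0, 0, 1, 1]))
        rng = np.random.default_rng(6)
        emb = rng.normal(size=(4, 5))
        pooled = module_pool(emb, part)
        pooled_swapped = module_pool(emb[[1, 0, 3, 2]], part)
        assert np.allclose(pooled, pooled_swapped)

    def test_identical_embeddings_single_module(self):
        part = ModulePartition(np.zeros(5, dtype=int))
        v = np.array([0.3, -0.2, 1.0])
        pooled = module_pool(np.tile(v, (5, 1)), part)
        assert np.allclose(pooled[0], v)

    def test_classify_range_and_determinism(self, small_net):
        rng = np.random.default_rng(7)
        emb = rng.normal(size=(4, small_net.n_modules, 32))
        a = classify(small_net, emb)
        b = classify(small_net, emb)
        assert np.all((a.p > 0) & (a.p < 1))
        assert np.array_equal(a.p, b.p)
        assert np.allclose(a.p, 1 / (1 + np.exp(-a.logit)))

    def test_classify_module_count_mismatch(self, small_net):
        with pytest.raises(ValueError):
            classify(small_net, np.zeros((1, small_net.n_modules + 2, 32)))

    def test_logit_bias_shifts_probability_up(self, small_net):
        rng = np.random.default_rng(8)
        emb = rng.normal(size=(3, small_net.n_modules, 32))
        base = classify(small_net, emb).p
        small_net.params["clf_b2_bias"].data = small_net.params[
            "clf_b2_bias"].data + 2.0
        shifted = classify(small_net, emb).p
        small_net.params["clf_b2_bias"].data = small_net.params[
            "clf_b2_bias"].data - 2.0
        assert np.all(shifted > base)


class TestLoss:
    def test_alpha_beta_zero_reduces_to_bce(self, small_net):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(4, small_net.n_genes))
        y = np.array([1, 0, 1, 0])
        _, parts = total_loss(small_net, x, y, alpha=0.0, beta=0.0)
        assert parts.total == pytest.approx(parts.bce, abs=1e-7)

    def test_decomposition_identity(self, small_net):
        """total = bce + alpha*mse + beta*kl, with each term recomputed."""
        rng = np.random.default_rng(10)
        x = rng.normal(size=(5, small_net.n_genes))
        y = np.array([1, 1, 0, 0, 1])
        alpha, beta = 0.7, 0.2
        _, parts = total_loss(small_net, x, y, alpha=alpha, beta=beta)
        assert parts.total == pytest.approx(
            parts.bce + alpha * parts.mse + beta * parts.kl, abs=1e-6)
        assert parts.kl >= 0

        # independent recomputation of each term
        out = small_net.forward(x)
        p = out["p"].data.astype(np.float64)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        mse = np.mean((out["xhat"].data.astype(np.float64) - x) ** 2)
        sigma = np.exp(0.5 * out["logvar"].data.astype(np.float64))
        kl = kl_term(out["mu"].data.astype(np.float64), sigma)
        assert parts.bce == pytest.approx(bce, rel=1e-4)
        assert parts.mse == pytest.approx(mse, rel=1e-4)
        assert parts.kl == pytest.approx(kl, rel=1e-4, abs=1e-6)

    def test_nonbinary_labels_rejected(self, small_net):
        with pytest.raises(ValueError):
            total_loss(small_net, np.zeros((2, small_net.n_genes)),
                       np.array([0.5, 1.0]))


class TestTraining:
    def test_history_finite_and_deterministic(self, toy_normalized, toy_graph,
                                              toy_partition):
        train_z, _ = toy_normalized
        config = ModelConfig(seed=5, max_epochs=4, early_stop_patience=4)
        a = train_model(train_z, toy_graph, toy_partition, config)
        b = train_model(train_z, toy_graph, toy_partition, config)
        assert all(np.isfinite(h["loss"]) for h in a.history)
        pa = predict_proba(a, train_z)
        pb = predict_proba(b, train_z)
        assert np.array_equal(pa, pb)

    def test_strong_signal_toy_matches_linear_oracle(self):
        """Strong-DEG toy: net within 0.05 of a logistic-regression oracle."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.metrics import roc_auc_score

        from cytomod import louvain_partition
        cfg = SimulationConfig(n_genes=200, n_modules=2, n_deg_up=5, n_deg_down=5,
                               mu_up_range=(1.5, 2.5), mu_down_range=(-2.5, -1.5),
                               deg_allocation="uniform", seed=3)
        cohort = generate_cohort(cfg)
        split = stratified_split(cohort, seed=3)
        tz = zscore_normalize(split.train)
        ez = zscore_normalize(split.test, reference=split.train)
        oracle = LogisticRegression(max_iter=2000).fit(tz.expression, tz.labels)
        oracle_auc = roc_auc_score(split.test.labels,
                                   oracle.predict_proba(ez.expression)[:, 1])
        graph = build_graph(tz, fraction=0.02)
        part = louvain_partition(graph, seed=3)
        trained = train_model(tz, graph, part, ModelConfig(seed=3, max_epochs=50))
        net_auc = evaluate_metrics(predict_proba(trained, ez), split.test.labels)["auc"]
        assert net_auc >= 0.95
        assert net_auc >= oracle_auc - 0.05

    def test_predict_proba_composes_pipeline_stages(self, toy_trained,
                                                    toy_normalized):
        """predict_proba == classify(module_pool(gat(encode(x)))) manually."""
        _, test_z = toy_normalized
        x = test_z.expression[:3]
        p = predict_proba(toy_trained, test_z.subset(np.arange(3)))
        net = toy_trained.net
        state = encode(net, x)
        propagated = gat_propagate(net, state.node_embeddings)
        pooled = module_pool(propagated, toy_trained.partition)
        manual = classify(net, pooled).p
        assert np.allclose(p, manual, atol=1e-5)

    def test_full_network_permutation_invariance(self, toy_trained, toy_normalized):
        """Consistently permuting gene columns + graph leaves p unchanged."""
        _, test_z = toy_normalized
        x = test_z.expression[:2]
        n = x.shape[1]
        rng = np.random.default_rng(11)
        perm = rng.permutation(n)
        inv = np.argsort(perm)

        net = toy_trained.net
        part_p = ModulePartition(toy_trained.partition.module_of_gene[perm])
        g = net.graph
        graph_p = CoexpressionGraph(n_nodes=n, edge_a=inv[g.edge_a],
                                    edge_b=inv[g.edge_b], r=g.r, weight=g.weight,
                                    gamma=g.gamma)
        net_p = GeneModuleNet(n, part_p, graph_p, net.config)
        for k, v in net.params.items():
            net_p.params[k].data = v.data.copy()
        net_p.params["gene_emb"].data = net.params["gene_emb"].data[perm]
        # decoder and gene-wise params are per-gene: permute them too
        net_p.params["dec_w"].data = net.params["dec_w"].data[:, perm]
        net_p.params["dec_bias"].data = net.params["dec_bias"].data[perm]

        p = net.forward(x)["p"].data
        p_perm = net_p.forward(x[:, perm])["p"].data
        assert np.allclose(p, p_perm, atol=1e-5)

    def test_predictions_in_unit_interval(self, toy_trained, toy_normalized):
        _, test_z = toy_normalized
        p = predict_proba(toy_trained, test_z)
        assert p.shape == (test_z.n_samples,)
        assert np.all((p > 0) & (p < 1))

    def test_save_load_round_trip(self, toy_trained, toy_normalized, tmp_path):
        _, test_z = toy_normalized
        path = tmp_path / "model.npz"
        save_model(toy_trained, str(path))
        loaded = load_model(str(path))
        assert np.allclose(predict_proba(loaded, test_z),
                           predict_proba(toy_trained, test_z))
        assert np.allclose(loaded.module_sigma, toy_trained.module_sigma)


class TestMetrics:
    def test_perfect_separation(self):
        m = evaluate_metrics(np.array([0.9, 0.8, 0.1, 0.2]), np.array([1, 1, 0, 0]))
        assert all(m[k] == 1.0 for k in ("auc", "accuracy", "precision", "recall", "f1"))

    def test_brute_force_pair_counting(self):
        """AUC 0.75 = 3 concordant of 4 positive-negative pairs."""
        m = evaluate_metrics(np.array([0.9, 0.4, 0.6, 0.1]), np.array([1, 1, 0, 0]))
        assert m["auc"] == pytest.approx(0.75)

    def test_all_ties_half_credit(self):
        m = evaluate_metrics(np.array([0.5, 0.5, 0.5, 0.5]), np.array([1, 0, 1, 0]))
        assert m["auc"] == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_metrics(np.array([0.2, 0.8]), np.array([1, 1]))

    def test_welch_t_identifies_shifted_genes(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(100, 20))
        y = np.r_[np.ones(50, int), np.zeros(50, int)]
        x[y == 1, 3] += 2.0
        t = welch_t_scores(x, y)
        assert np.argmax(np.abs(t)) == 3
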