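import numpy as np
import pytest

from atlaskit.netcore import IntegrityError, NetworkNode, NodeSeed, RegulatoryNetwork
from atlaskit.propagation import (
    PropagationConfig,
    build_transition,
    combine_min,
    compute_marker_scores,
    extract_subnetworks,
    permutation_zscores,
    propagate,
)
from atlaskit.isspatch import CellMatrix
from .conftest import make_path_network, make_random_network
from .test_netcore import bfs_components


class TestBuildTransition:
    def test_path_graph_degree_normalization(self, path_net):
        T = build_transition(path_net)
        M = T.matrix.toarray()
        j = T.index["chr1:100-200"]
        col = M[:, j]
        assert col[T.index["TF1"]] == pytest.approx(0.5)
        assert col[T.index["G1"]] == pytest.approx(0.5)
        assert col[j] == 0.0

    def test_isolated_node_gets_uniform_column(self):
        nodes = [
            NetworkNode("TF1", "TF"),
            NetworkNode("G1", "gene"),
            NetworkNode("G2", "gene"),
            NetworkNode("G3", "gene"),
        ]
        edges = [("TF1", "G1", 1.0, "tf-gene"), ("TF1", "G2", 1.0, "tf-gene")]
        T = build_transition(RegulatoryNetwork(nodes, edges))
        col = T.matrix.toarray()[:, T.index["G3"]]
        assert np.allclose(col, 0.25)

    @pytest.mark.parametrize("seed", range(3))
    def test_columns_sum_to_one(self, seed):
        net, _ = make_random_network(seed=seed)
        T = build_transition(net)
        sums = np.asarray(T.matrix.sum(axis=0)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-12)


class TestPropagate:
    def test_pure_restart_returns_seed(self, path_net):
        T = build_transition(path_net)
        cfg = PropagationConfig(restart_prob=1.0)
        q = propagate(T, NodeSeed({"TF1": 3.0, "G1": 1.0}), cfg)
        assert q[T.index["TF1"]] == pytest.approx(0.75)
        assert q[T.index["G1"]] == pytest.approx(0.25)
        assert q[T.index["chr1:100-200"]] == 0.0

    def test_regular_graph_uniform_seed_fixed_point(self):
        # 4-cycle TF1-R1-TF2-R2: every node degree 2, so uniform is invariant
        nodes = [
            NetworkNode("TF1", "TF"),
            NetworkNode("TF2", "TF"),
            NetworkNode("G1", "gene"),
            NetworkNode("G2", "gene"),
        ]
        edges = [
            ("TF1", "G1", 1.0, "tf-gene"),
            ("TF2", "G1", 1.0, "tf-gene"),
            ("TF2", "G2", 1.0, "tf-gene"),
            ("TF1", "G2", 1.0, "tf-gene"),
        ]
        T = build_transition(RegulatoryNetwork(nodes, edges))
        q = propagate(T, NodeSeed({n.id: 1.0 for n in nodes}))
        assert np.allclose(q, 0.25, atol=1e-7)

    def test_no_positive_seed_raises(self, path_net):
        T = build_transition(path_net)
        with pytest.raises(ValueError, match="positive"):
            propagate(T, NodeSeed({"TF1": 0.0}))

    def test_nonconvergence_reports_residual(self, path_net):
        T = build_transition(path_net)
        cfg = PropagationConfig(max_iter=1, tol=1e-15)
        with pytest.raises(RuntimeError, match="residual"):
            propagate(T, NodeSeed({"TF1": 1.0}), cfg)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_linear_solve(self, seed):
        """Power iteration equals the closed-form solve of
        (I - (1-r)T) q = r s on small random graphs."""
        net, _ = make_random_network(seed=seed, n_tf=2, n_region=8, n_gene=12, module=4)
        T = build_transition(net)
        rng = np.random.default_rng(seed)
        s = rng.uniform(0, 1, T.n)
        seed_vec = NodeSeed(dict(zip(T.nodes, s)))
        cfg = PropagationConfig(tol=1e-14)
        q = propagate(T, seed_vec, cfg)
        r = cfg.restart_prob
        q_exact = np.linalg.solve(np.eye(T.n) - (1 - r) * T.matrix.toarray(), r * s / s.sum())
        assert np.max(np.abs(q - q_exact)) < 1e-10

    def test_mass_conservation(self):
        net, _ = make_random_network(seed=7)
        T = build_transition(net)
        rng = np.random.default_rng(7)
        for _ in range(5):
            s = dict(zip(T.nodes, rng.uniform(0, 1, T.n)))
            q = propagate(T, NodeSeed(s))
            assert q.sum() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_seed(self):
        """Raising one node's raw seed never lowers its propagated score."""
        net, _ = make_random_network(seed=3)
        T = build_transition(net)
        rng = np.random.default_rng(3)
        s = rng.uniform(0.1, 1, T.n)
        base = propagate(T, NodeSeed(dict(zip(T.nodes, s))))
        i = int(rng.integers(T.n))
        s2 = s.copy()
        s2[i] *= 5
        bumped = propagate(T, NodeSeed(dict(zip(T.nodes, s2))))
        assert bumped[i] >= base[i] - 1e-12


class TestPermutationZscores:
    def test_constant_seed_gives_zero_z(self, path_net):
        T = build_transition(path_net)
        cfg = PropagationConfig(n_perm=20, rng_seed=0)
        res = permutation_zscores(T, NodeSeed({n: 2.0 for n in T.nodes}), cfg)
        assert np.allclose(res.sd_perm, 0.0, atol=1e-12)
        assert np.allclose(res.z, 0.0)
        assert np.allclose(res.p_emp, 1.0)

    def test_single_permutation_boundary(self, path_net):
        T = build_transition(path_net)
        cfg = PropagationConfig(n_perm=1, rng_seed=0)
        res = permutation_zscores(T, NodeSeed({"TF1": 1.0}), cfg)
        assert np.isfinite(res.z).all()
        assert ((res.p_emp > 0) & (res.p_emp <= 1)).all()

    def test_reproducible_under_same_seed(self):
        net, _ = make_random_network(seed=11, n_tf=3, n_region=10, n_gene=17, module=4)
        T = build_transition(net)
        rng = np.random.default_rng(4)
        seed = NodeSeed(dict(zip(T.nodes, rng.uniform(0, 1, T.n))))
        cfg = PropagationConfig(n_perm=200, rng_seed=42)
        a = permutation_zscores(T, seed, cfg)
        b = permutation_zscores(T, seed, cfg)
        assert np.array_equal(a.mu_perm, b.mu_perm)
        assert np.array_equal(a.sd_perm, b.sd_perm)
        assert np.array_equal(a.z, b.z)
        c = permutation_zscores(T, seed, PropagationConfig(n_perm=200, rng_seed=43))
        assert not np.array_equal(a.mu_perm, c.mu_perm)

    def test_degree_binned_mode_runs(self):
        net, _ = make_random_network(seed=5)
        T = build_transition(net)
        cfg = PropagationConfig(n_perm=50, rng_seed=1, perm_mode="degree_binned")
        rng = np.random.default_rng(5)
        res = permutation_zscores(T, NodeSeed(dict(zip(T.nodes, rng.uniform(0, 1, T.n)))), cfg)
        assert np.isfinite(res.z).all()


def nb_counts(rng, shape, mean=4.0, theta=10.0):
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p, size=shape)


class TestMarkerScores:
    def make_cells(self, X, labels):
        genes = [f"G{i}" for i in range(X.shape[1])]
        cells = [f"c{i}" for i in range(X.shape[0])]
        return CellMatrix(X, genes, cells, labels=labels)

    def test_exclusive_gene_scores_high_in_its_cluster(self):
        rng = np.random.default_rng(0)
        X = nb_counts(rng, (100, 10))
        X[:50, 0] += 30  # gene G0 high only in cluster A
        labels = ["A"] * 50 + ["B"] * 50
        seeds = compute_marker_scores(self.make_cells(X, labels))
        assert seeds["A"].scores.get("G0", 0) > 10
        assert seeds["B"].scores.get("G0", 0) == 0

    def test_identical_gene_scores_zero(self):
        rng = np.random.default_rng(1)
        X = np.tile(nb_counts(rng, (1, 6)), (40, 1)) + 1  # every cell identical
        labels = ["A"] * 20 + ["B"] * 20
        seeds = compute_marker_scores(self.make_cells(X, labels))
        for s in seeds.values():
            assert len(s) == 0

    def test_permuted_labels_yield_no_markers(self):
        """Under a random label assignment BH keeps nearly every gene null."""
        rng = np.random.default_rng(2)
        X = nb_counts(rng, (120, 200))
        labels = list(rng.permutation(["A"] * 60 + ["B"] * 60))
        seeds = compute_marker_scores(self.make_cells(X, labels))
        # score > -log10(0.05) means p_adj < 0.05
        frac = np.mean([
            np.mean([v > -np.log10(0.05) for v in s.scores.values()]) if s.scores else 0.0
            for s in seeds.values()
        ])
        assert frac < 0.02

    def test_small_cluster_excluded(self):
        rng = np.random.default_rng(3)
        X = nb_counts(rng, (43, 5)) + 1
        labels = ["A"] * 20 + ["B"] * 21 + ["C"] * 2
        seeds = compute_marker_scores(self.make_cells(X, labels))
        assert set(seeds) == {"A", "B"}


class TestCombineAndExtract:
    def make_result(self, nodes, z):
        from atlaskit.propagation import PropagationResult

        n = len(nodes)
        zeros = np.zeros(n)
        return PropagationResult(list(nodes), zeros, zeros, zeros, np.asarray(z, float), np.ones(n), "t")

    def test_idempotent_on_equal_inputs(self):
        r = self.make_result(["a", "b"], [1.0, 2.0])
        combined = combine_min(r, r)
        assert combined.scores == {"a": 1.0, "b": 2.0}

    def test_elementwise_min(self):
        a = self.make_result(["a", "b"], [3.0, 0.0])
        b = self.make_result(["a", "b"], [1.0, 5.0])
        assert combine_min(a, b).scores == {"a": 1.0, "b": 0.0}

    def test_mismatched_universe_rejected(self):
        a = self.make_result(["a"], [1.0])
        b = self.make_result(["b"], [1.0])
        with pytest.raises(IntegrityError):
            combine_min(a, b)

    def test_combined_bounded_by_both(self):
        rng = np.random.default_rng(0)
        nodes = [f"n{i}" for i in range(30)]
        za, zb = rng.normal(size=30), rng.normal(size=30)
        combined = combine_min(self.make_result(nodes, za), self.make_result(nodes, zb))
        vals = np.array([combined[n] for n in nodes])
        assert (vals <= za + 1e-12).all() and (vals <= zb + 1e-12).all()

    def test_threshold_above_max_gives_empty(self, path_net):
        combined = NodeSeed({n: 1.0 for n in path_net.nodes}, allow_negative=True)
        assert extract_subnetworks(path_net, combined, PropagationConfig(z_thresh=5)) == []

    def test_two_high_cliques_joined_by_low_node(self):
        # two TF-region-gene triangles joined through one low-scoring gene
        from atlaskit.netcore import GenomicInterval

        def region(i):
            return NetworkNode(f"chr1:{i}00-{i}50", "region", GenomicInterval("chr1", i * 100, i * 100 + 50))

        nodes = [
            NetworkNode("TF1", "TF"), region(1), NetworkNode("GA", "gene"),
            NetworkNode("TF2", "TF"), region(2), NetworkNode("GB", "gene"),
            NetworkNode("GLOW", "gene"),
        ]
        edges = [
            ("TF1", nodes[1].id, 1, "tf-region"), (nodes[1].id, "GA", 1, "region-gene"),
            ("TF2", nodes[4].id, 1, "tf-region"), (nodes[4].id, "GB", 1, "region-gene"),
            (nodes[1].id, "GLOW", 1, "region-gene"), (nodes[4].id, "GLOW", 1, "region-gene"),
        ]
        net = RegulatoryNetwork(nodes, edges)
        scores = {n.id: 5.0 for n in nodes}
        scores["GLOW"] = 0.0
        subs = extract_subnetworks(net, NodeSeed(scores, allow_negative=True), PropagationConfig(z_thresh=2))
        assert len(subs) == 2
        assert all(len(s.nodes) == 3 for s in subs)

    @pytest.mark.parametrize("seed", range(3))
    def test_components_match_bfs_oracle(self, seed):
        net, _ = make_random_network(seed=seed)
        rng = np.random.default_rng(seed)
        scores = NodeSeed(dict(zip(net.node_ids, rng.normal(size=net.n_nodes))), allow_negative=True)
        cfg = PropagationConfig(z_thresh=0.5)
        subs = extract_subnetworks(net, scores, cfg)
        keep = {n for n, v in scores.items() if v > 0.5}
        adj: dict = {}
        for r in net.edges.itertuples(index=False):
            adj.setdefault(r.source, set()).add(r.target)
            adj.setdefault(r.target, set()).add(r.source)
        assert sorted([sorted(s.nodes) for s in subs]) == sorted(
            [sorted(c) for c in bfs_components(adj, keep)]
        )
        # ranked by mean score descending
        means = [s.mean_score for s in subs]
        assert means == sorted(means, reverse=True)
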