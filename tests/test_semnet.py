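"""Unit tests for the semantic-network pipeline (incidence -> cosine ->
TMFG -> topological quantifiers -> LONO/LOSO)."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cogflex import semnet
from cogflex.synthetic import SyntheticConfig, gen_aut

from conftest import random_weighted_network


def raw_table(rows):
    return pd.DataFrame(rows, columns=["participant_id", "condition",
                                       "prompt", "response"])


class TestPreprocess:
    def test_normalization_map_and_dedup(self):
        raw = raw_table([
            ("p1", "A", "q", "Newspapers"),
            ("p1", "A", "q", "newspaper"),
            ("p2", "A", "q", "brick"),
        ])
        out = semnet.preprocess_aut(raw, {"newspapers": "newspaper"})
        m = out["A"]
        assert m.response_labels == ["brick", "newspaper"]
        # duplicate token from p1 collapses to a single incidence
        assert m.matrix.sum() == 2

    def test_identity_map_keeps_tokens(self):
        raw = raw_table([("p1", "A", "q", "Rope")])
        out = semnet.preprocess_aut(raw)
        assert out["A"].response_labels == ["rope"]

    def test_empty_table_errors(self):
        with pytest.raises(ValueError, match="empty"):
            semnet.preprocess_aut(raw_table([]))


class TestOverlapCounts:
    def test_identical_sets(self):
        c = semnet.overlap_counts({"a", "b"}, {"a", "b"})
        assert c.discordant_a_only == c.discordant_b_only == 0
        assert c.n_total == 2

    def test_disjoint_sets(self):
        c = semnet.overlap_counts({"a"}, {"b", "c"})
        assert c.concordant_both == 0
        assert c.n_total == 3


class TestMatchedSelection:
    def test_threshold_and_matching(self):
        rows = []
        # "shared" given by 2 participants in both conditions; "rare" by 1
        for cond in ("A", "B"):
            for p in ("p1", "p2"):
                for tok in ("shared", "t1", "t2", "t3"):
                    rows.append((p, cond, "q", tok))
            rows.append(("p1", cond, "q", "rare"))
        out = semnet.preprocess_aut(raw_table(rows))
        ma, mb = semnet.select_matched_responses(out["A"], out["B"])
        assert "rare" not in ma.response_labels
        assert ma.response_labels == mb.response_labels
        assert set(ma.response_labels) == {"shared", "t1", "t2", "t3"}

    def test_too_few_nodes_errors(self):
        rows = [(p, c, "q", "only") for p in ("p1", "p2") for c in ("A", "B")]
        out = semnet.preprocess_aut(raw_table(rows))
        with pytest.raises(ValueError, match="at least 4"):
            semnet.select_matched_responses(out["A"], out["B"])


class TestCosineNetwork:
    def test_hand_values(self):
        m = semnet.ResponseMatrix(
            np.array([[1, 1, 1], [1, 0, 1], [0, 0, 1], [0, 1, 0]]),
            ["u", "v", "w"], ["p1", "p2", "p3", "p4"], "A")
        net = semnet.cosine_network(m)
        uv = 1 / (np.sqrt(2) * np.sqrt(2))  # u=(1,1,0,0), v=(1,0,0,1)
        assert net.weights[0, 1] == pytest.approx(uv)
        assert np.all(np.diag(net.weights) == 0)

    def test_identical_and_orthogonal_columns(self):
        m = semnet.ResponseMatrix(
            np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]]),
            ["a", "b", "c"], ["p1", "p2", "p3"], "A")
        net = semnet.cosine_network(m)
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 2] == pytest.approx(0.0)

    def test_zero_column_errors(self):
        m = semnet.ResponseMatrix(np.array([[1, 0], [1, 0]]),
                                  ["a", "b"], ["p1", "p2"], "A")
        with pytest.raises(ValueError, match="all-zero"):
            semnet.cosine_network(m)

    def test_symmetry_and_range(self, rng):
        mat = (rng.random((20, 12)) < 0.4).astype(int)
        mat[:, mat.sum(0) == 0] = 1
        net = semnet.cosine_network(
            semnet.ResponseMatrix(mat, [f"t{j}" for j in range(12)],
                                  list(range(20)), "A"))
        assert np.allclose(net.weights, net.weights.T)
        assert net.weights.min() >= 0 and net.weights.max() <= 1


class TestTMFG:
    def test_k4_passthrough(self, rng):
        net = random_weighted_network(4, rng)
        out = semnet.tmfg(net)
        assert len(out.edges()) == 6

    def test_edge_count_formula(self, rng):
        for n in (5, 10, 23):
            out = semnet.tmfg(random_weighted_network(n, rng))
            assert len(out.edges()) == 3 * (n - 2)

    def test_planar_and_connected(self, rng):
        for _ in range(5):
            out = semnet.tmfg(random_weighted_network(15, rng))
            g = out.to_networkx(binarize=True)
            assert nx.check_planarity(g)[0]
            assert nx.is_connected(g)

    def test_too_small_errors(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            semnet.tmfg(random_weighted_network(3, rng))

    def test_beats_random_planar_subgraph(self, rng):
        """The greedy filter retains more weight than a random connected
        planar subgraph with the same edge budget."""
        for _ in range(5):
            net = random_weighted_network(12, rng)
            filtered = semnet.tmfg(net)
            kept = sum(w for _, _, w in filtered.edges())
            # random maximal planar graph via random greedy edge insertion
            edges = [(i, j) for i in range(12) for j in range(i + 1, 12)]
            rng.shuffle(edges)
            g = nx.Graph()
            g.add_nodes_from(range(12))
            total = 0.0
            for i, j in edges:
                g.add_edge(i, j)
                if nx.check_planarity(g)[0]:
                    total += net.weights[i, j]
                else:
                    g.remove_edge(i, j)
            assert kept >= total


class TestMetrics:
    def test_triangle(self):
        w = np.ones((3, 3)) - np.eye(3)
        m = semnet.compute_metrics(semnet.WeightedNetwork(list("abc"), w))
        assert m.cc == pytest.approx(1.0)
        assert m.aspl == pytest.approx(1.0)

    def test_three_node_path(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
        m = semnet.compute_metrics(semnet.WeightedNetwork(list("abc"), w))
        assert m.cc == pytest.approx(0.0)
        assert m.aspl == pytest.approx(4 / 3)

    def test_two_triangle_modularity(self):
        """Louvain recovers the brute-force optimal two-community split of
        two triangles joined by a bridge (Q = 5/14)."""
        w = np.zeros((6, 6))
        for i, j in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]:
            w[i, j] = w[j, i] = 1.0
        m = semnet.compute_metrics(
            semnet.WeightedNetwork([str(i) for i in range(6)], w))
        assert m.q == pytest.approx(5 / 14, abs=1e-9)

    def test_disconnected_errors(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            semnet.compute_metrics(semnet.WeightedNetwork(list("abcd"), w))

    def test_aspl_cc_against_bruteforce(self, rng):
        """ASPL and CC agree with direct all-pairs BFS / triangle counting
        on small random connected graphs."""
        for _ in range(10):
            g = nx.gnp_random_graph(10, 0.45, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g) or g.number_of_edges() < 2:
                continue
            w = nx.to_numpy_array(g)
            m = semnet.compute_metrics(
                semnet.WeightedNetwork([str(i) for i in range(10)], w))
            # brute-force ASPL via BFS from every node
            dists = dict(nx.all_pairs_shortest_path_length(g))
            pairs = [(i, j) for i in g for j in g if i < j]
            aspl = np.mean([dists[i][j] for i, j in pairs])
            # brute-force local clustering by triangle counting
            ccs = []
            for v in g:
                nbrs = list(g[v])
                k = len(nbrs)
                if k < 2:
                    ccs.append(0.0)
                    continue
                links = sum(g.has_edge(u, x) for a, u in enumerate(nbrs)
                            for x in nbrs[a + 1:])
                ccs.append(2 * links / (k * (k - 1)))
            assert m.aspl == pytest.approx(aspl)
            assert m.cc == pytest.approx(np.mean(ccs))

    def test_sampled_baseline_runs(self, rng):
        net = semnet.tmfg(random_weighted_network(12, rng))
        m = semnet.compute_metrics(
            net, semnet.RandomBaseline(kind="sampled", n_samples=5, seed=0))
        assert np.isfinite(m.s)


class TestLONO:
    def test_iteration_count(self, rng):
        net = semnet.tmfg(random_weighted_network(12, rng))
        dist = semnet.lono(net)
        assert len(dist.unit_ids) + len(dist.skipped) == 12

    def test_vertex_transitive_symmetry(self):
        """All LONO iterations coincide on a vertex-transitive graph."""
        g = nx.circulant_graph(8, [1, 2])
        w = nx.to_numpy_array(g).astype(float)
        dist = semnet.lono(semnet.WeightedNetwork([str(i) for i in range(8)], w))
        for name in ("aspl", "cc", "q", "s"):
            vals = dist.values(name)
            assert np.ptp(vals) == pytest.approx(0.0, abs=1e-12)

    def test_hub_removal_skipped_with_warning(self):
        w = np.zeros((6, 6))
        w[0, 1:] = w[1:, 0] = 1.0  # star: removing the hub disconnects
        with pytest.warns(UserWarning, match="skipped"):
            dist = semnet.lono(semnet.WeightedNetwork(
                [str(i) for i in range(6)], w))
        assert "0" in dist.skipped


class TestLOSO:
    @pytest.fixture(scope="class")
    def small_aut(self):
        cfg = SyntheticConfig(seed=11, n_participants=12, vocab_size=40)
        return gen_aut(cfg)

    def test_iteration_count_and_pairing(self, small_aut):
        dists = semnet.loso(small_aut, ("OR", "DD"))
        n = small_aut["participant_id"].nunique()
        for c in ("OR", "DD"):
            assert len(dists[c].unit_ids) + len(dists[c].skipped) == n
        # pairing key is the removed participant id
        assert dists["OR"].unit_ids == dists["DD"].unit_ids

    def test_duplicated_participant_exchangeable(self, small_aut):
        """Removing either copy of a duplicated participant gives identical
        metrics."""
        dup = small_aut[small_aut["participant_id"] == "p000"].copy()
        dup["participant_id"] = "p999"
        raw = pd.concat([small_aut, dup], ignore_index=True)
        dists = semnet.loso(raw, ("OR", "DD"))
        for c in ("OR", "DD"):
            vals = {u: m for u, m in zip(dists[c].unit_ids, dists[c].metrics)}
            assert vals["p000"].as_dict() == pytest.approx(
                vals["p999"].as_dict())


class TestEndToEndDirection:
    def test_presets_order_aspl(self):
        """The homogeneous-co-occurrence arm forms a shorter-path network
        than the fragmented arm on the default generator."""
        cfg = SyntheticConfig(seed=2)
        nets = semnet.run_semnet_pipeline(gen_aut(cfg), ("OR", "DD"))
        m = {c: semnet.compute_metrics(nets[c]) for c in nets}
        assert m["DD"].aspl < m["OR"].aspl
        assert m["DD"].s > m["OR"].s
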