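"""Community detection, nodal role metrics, global statistics, class ANOVA."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy.stats import f_oneway

import hubgenes as hg
from hubgenes.connectivity import BinaryGraph
from hubgenes.netmetrics import ModularPartition, _rewired_null, class_anova, modularity
from tests_helpers import modularity_bruteforce, nodal_metrics_bruteforce, random_connectivity


def _graph_from_adjacency(A, coords=None):
    A = np.asarray(A, bool)
    n = A.shape[0]
    coords = np.random.default_rng(0).uniform(-50, 50, (n, 3)) if coords is None else coords
    ei, ej = np.nonzero(np.triu(A, 1))
    edges = pd.DataFrame({"region_i": ei, "region_j": ej})
    return BinaryGraph(A, list(range(n)), coords, density=A.sum() / (n * (n - 1)), edges=edges)


def two_cliques():
    A = np.zeros((10, 10))
    A[:5, :5] = 1
    A[5:, 5:] = 1
    np.fill_diagonal(A, 0)
    return A


class TestModularityAndLouvain:
    def test_two_disconnected_cliques_q_half(self):
        """Two equal cliques at gamma=1: the clique partition has Q = 0.5
        and Louvain finds it."""
        A = two_cliques()
        part = hg.louvain(_graph_from_adjacency(A), gamma=1.0, seed=0)
        assert part.n_modules == 2
        assert np.array_equal(part.labels[:5], np.full(5, part.labels[0]))
        assert part.modularity == pytest.approx(0.5)

    def test_one_module_partition_has_zero_q(self):
        A = two_cliques()
        assert modularity(A, np.ones(10), gamma=1.0) == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_double_sum_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(8, 25))
            A = (rng.random((n, n)) < 0.3).astype(float)
            A = np.triu(A, 1)
            A = A + A.T
            if A.sum() == 0:
                continue
            labels = rng.integers(1, 4, n)
            gamma = float(rng.uniform(0.5, 2.5))
            assert modularity(A, labels, gamma) == pytest.approx(
                modularity_bruteforce(A, labels, gamma), abs=1e-12
            )

    def test_louvain_beats_trivial_partition(self, rng):
        g = None
        mat, coords = random_connectivity(rng, 40)
        g = hg.build_graph(mat, 0.15, coords)
        part = hg.louvain(g, gamma=1.0, seed=1)
        assert part.modularity >= 0.0


@pytest.fixture(scope="module")
def planted():
    G = nx.planted_partition_graph(8, 25, 0.8, 0.02, seed=42)
    labels = np.repeat(np.arange(8), 25)
    return G, labels


class TestConsensus:
    def test_recovers_planted_partition(self, planted):
        from sklearn.metrics import adjusted_rand_score

        G, truth = planted
        part = hg.consensus_partition(G, gamma=1.0, n_runs=50, seed=0)
        assert adjusted_rand_score(truth, part.labels) > 0.9

    def test_single_run_reduces_to_louvain(self, planted):
        G, _ = planted
        single = hg.consensus_partition(G, gamma=1.0, n_runs=1, seed=7)
        direct = hg.louvain(G, gamma=1.0, seed=7)
        assert np.array_equal(single.labels, direct.labels)

    def test_higher_resolution_gives_at_least_as_many_modules(self, planted):
        G, _ = planted
        m1 = hg.consensus_partition(G, gamma=1.0, n_runs=20, seed=1).n_modules
        m2 = hg.consensus_partition(G, gamma=2.0, n_runs=20, seed=1).n_modules
        assert m2 >= m1

    def test_relabelling_invariance(self, planted):
        """Permuting node order permutes consensus labels consistently."""
        from sklearn.metrics import adjusted_rand_score

        G, _ = planted
        n = G.number_of_nodes()
        rng = np.random.default_rng(3)
        perm = rng.permutation(n)
        A = nx.to_numpy_array(G)
        part = hg.consensus_partition(A, gamma=1.0, n_runs=30, seed=2)
        part_p = hg.consensus_partition(A[np.ix_(perm, perm)], gamma=1.0, n_runs=30, seed=2)
        # map permuted labels back to original node order and compare partitions
        back = np.empty(n, dtype=int)
        back[perm] = part_p.labels
        assert adjusted_rand_score(part.labels, back) == pytest.approx(1.0)


class TestNodalMetrics:
    def test_all_intra_node_has_zero_pc(self):
        A = two_cliques()
        g = _graph_from_adjacency(A)
        part = ModularPartition(labels=np.array([1] * 5 + [2] * 5), gamma=1.0, region_ids=g.region_ids)
        m = hg.nodal_metrics(g, part)
        assert np.allclose(m["PC"], 0.0)
        assert np.array_equal(m["k"], m["k_intra"])

    def test_four_way_even_node_pc(self):
        # star node 0 with one edge into each of 4 modules
        A = np.zeros((9, 9))
        for j in (1, 3, 5, 7):
            A[0, j] = A[j, 0] = 1
        # pair up remaining nodes so every node has an edge
        for a, b in [(1, 2), (3, 4), (5, 6), (7, 8)]:
            A[a, b] = A[b, a] = 1
        labels = np.array([1, 1, 1, 2, 2, 3, 3, 4, 4])
        g = _graph_from_adjacency(A)
        part = ModularPartition(labels=labels, gamma=1.0, region_ids=g.region_ids)
        m = hg.nodal_metrics(g, part)
        assert m["PC"].iloc[0] == pytest.approx(1 - 4 * (1 / 4) ** 2)
        assert m["PC"].iloc[0] == pytest.approx(0.75)

    def test_matches_per_edge_loop_oracle(self, rng):
        for _ in range(5):
            mat, coords = random_connectivity(rng, 30)
            g = hg.build_graph(mat, 0.2, coords)
            labels = rng.integers(1, 5, 30)
            part = ModularPartition(labels=labels, gamma=1.0, region_ids=g.region_ids)
            m = hg.nodal_metrics(g, part)
            oracle = nodal_metrics_bruteforce(g.adjacency, labels, coords)
            for col in ("k", "k_intra", "k_inter", "PC", "d"):
                assert np.allclose(m[col], oracle[col], atol=1e-10, equal_nan=True)
            assert np.array_equal(m["k"], m["k_intra"] + m["k_inter"])
            assert m["k"].sum() == 2 * g.n_edges

    def test_isolated_node_pc_missing(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1  # node 3 isolated
        g = _graph_from_adjacency(A)
        part = ModularPartition(labels=np.array([1, 1, 2, 2]), gamma=1.0, region_ids=g.region_ids)
        m = hg.nodal_metrics(g, part)
        assert np.isnan(m["PC"].iloc[3]) and np.isnan(m["d"].iloc[3])

    def test_subject_aggregation_mean_and_median(self, rng):
        tables = []
        for s in range(3):
            df = pd.DataFrame(
                {"k": rng.integers(1, 10, 4)}, index=[f"R{i}" for i in range(4)]
            )
            tables.append(df)
        mean = hg.average_metrics(tables, how="mean")
        med = hg.average_metrics(tables, how="median")
        stacked = np.stack([t["k"].to_numpy() for t in tables])
        assert np.allclose(mean["k"], stacked.mean(axis=0))
        assert np.allclose(med["k"], np.median(stacked, axis=0))


class TestGlobalMetrics:
    def test_complete_graph_closed_forms(self):
        A = np.ones((10, 10)) - np.eye(10)
        g = _graph_from_adjacency(A)
        gm = hg.global_metrics(g, n_null=3, seed=0)
        assert gm.C == pytest.approx(1.0)
        assert gm.L == pytest.approx(1.0)

    def test_rewiring_preserves_degree_sequence(self, rng):
        mat, coords = random_connectivity(rng, 40)
        g = hg.build_graph(mat, 0.15, coords)
        G = nx.from_numpy_array(g.adjacency.astype(int))
        H = _rewired_null(G, seed=5)
        assert sorted(d for _, d in G.degree()) == sorted(d for _, d in H.degree())
        assert nx.is_connected(H)

    def test_normalized_rich_club_near_one_for_er_graphs(self):
        """phi_norm(k) ~ 1 on Erdos-Renyi graphs (no rich club by construction)."""
        vals = {}
        for seed in range(50):
            G = nx.gnp_random_graph(80, 0.15, seed=seed)
            if not nx.is_connected(G):
                continue
            A = nx.to_numpy_array(G)
            g = _graph_from_adjacency(A)
            degs = g.degrees()
            gm = hg.global_metrics(g, n_null=5, seed=seed)
            for k, phi in gm.rich_club.items():
                if (degs > k).sum() >= 10:
                    vals.setdefault(k, []).append(phi)
        means = {k: np.mean(v) for k, v in vals.items() if len(v) >= 25}
        assert means, "no degree level with enough samples"
        for k, m in means.items():
            assert abs(m - 1.0) < 0.1


class TestClassAnova:
    def test_identical_class_multisets_give_zero_f(self):
        v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        c = np.array(["a"] * 3 + ["b"] * 3)
        F, d1, d2, p = class_anova(v, c)
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_study_scale_degrees_of_freedom(self, rng):
        """285 regions in 7 classes give the (6, 278) design."""
        v = rng.normal(size=285)
        c = np.repeat(np.arange(7), [41, 41, 41, 41, 41, 40, 40])
        F, d1, d2, p = class_anova(v, c)
        assert (d1, d2) == (6, 278)

    def test_matches_scipy_oracle(self, rng):
        for _ in range(10):
            v = rng.normal(size=60)
            c = rng.integers(0, 4, 60)
            if min(np.bincount(c)) < 2:
                continue
            F, _, _, p = class_anova(v, c)
            F2, p2 = f_oneway(*[v[c == i] for i in np.unique(c)])
            assert F == pytest.approx(F2, abs=1e-10)
            assert p == pytest.approx(p2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            class_anova(np.arange(4.0), np.zeros(4))
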