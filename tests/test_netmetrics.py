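"""Graph metrics against hand computations, brute-force oracles and networkx."""

import itertools

import networkx as nx
import numpy as np
import pytest

from nirsmoco.netmetrics import (
    compute_metrics,
    global_efficiency,
    global_metrics,
    local_metrics,
    node_efficiency,
    node_local_efficiency,
    region_aggregate,
    small_world_sigma,
)


def _adj(n, edges):
    a = np.zeros((n, n), dtype=bool)
    for u, v in edges:
        a[u, v] = a[v, u] = True
    return a


# ---------------------------------------------------------------- oracles --

def _bfs_dist(adj, src):
    n = adj.shape[0]
    dist = [np.inf] * n
    dist[src] = 0
    queue = [src]
    while queue:
        u = queue.pop(0)
        for v in range(n):
            if adj[u, v] and dist[v] == np.inf:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _oracle_metrics(adj):
    """Brute-force BFS / triangle-enumeration metrics."""
    n = adj.shape[0]
    dists = [_bfs_dist(adj, u) for u in range(n)]
    node_eff = np.array([
        np.mean([1.0 / dists[u][v] for v in range(n) if v != u]) for u in range(n)])
    glob_eff = node_eff.mean()
    clust = np.zeros(n)
    for u in range(n):
        nbrs = [v for v in range(n) if adj[u, v]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b])
        clust[u] = 2.0 * links / (k * (k - 1))
    loc_eff = np.zeros(n)
    for u in range(n):
        nbrs = [v for v in range(n) if adj[u, v]]
        m = len(nbrs)
        if m < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        sd = [_bfs_dist(sub, i) for i in range(m)]
        vals = [1.0 / sd[i][j] for i in range(m) for j in range(m)
                if i != j and np.isfinite(sd[i][j])]
        loc_eff[u] = sum(vals) / (m * (m - 1))
    deg = adj.sum(axis=1)
    return glob_eff, clust, node_eff, loc_eff, deg


def _connected(adj):
    return all(np.isfinite(_bfs_dist(adj, 0)))


# ------------------------------------------------------------------ tests --

class TestHandComputedExamples:
    def test_complete_graph_k4(self):
        a = _adj(4, itertools.combinations(range(4), 2))
        ge, cc = global_metrics(a)
        assert ge == 1.0 and cc == 1.0

    def test_path_p3(self):
        a = _adj(3, [(0, 1), (1, 2)])
        ge, cc = global_metrics(a)
        assert ge == pytest.approx(5 / 6, abs=1e-12)
        assert cc == 0.0
        # leaf: neighbors at distance 1 and 2
        assert node_efficiency(a)[0] == pytest.approx(0.75, abs=1e-12)

    def test_star_center_has_zero_local_efficiency(self):
        a = _adj(5, [(0, i) for i in range(1, 5)])
        deg, _, nle = local_metrics(a)
        assert deg[0] == 4
        assert nle[0] == 0.0

    def test_triangle_node_local_efficiency_one(self):
        a = _adj(3, [(0, 1), (1, 2), (0, 2)])
        assert np.allclose(node_local_efficiency(a), 1.0)


class TestOracleEquivalence:
    def test_all_connected_graphs_up_to_five_nodes(self):
        for n in range(2, 6):
            pairs = list(itertools.combinations(range(n), 2))
            for bits in range(1 << len(pairs)):
                a = _adj(n, [p for i, p in enumerate(pairs) if bits >> i & 1])
                if not _connected(a):
                    continue
                ge_o, cl_o, ne_o, le_o, dg_o = _oracle_metrics(a)
                ge, cc = global_metrics(a)
                dg, ne, le = local_metrics(a)
                assert abs(ge - ge_o) < 1e-12
                assert abs(cc - cl_o.mean()) < 1e-12
                assert np.abs(ne - ne_o).max() < 1e-12
                assert np.abs(le - le_o).max() < 1e-12
                assert np.array_equal(dg, dg_o)

    def test_random_graphs_match_networkx(self, rng):
        done = 0
        seed = 0
        while done < 30:
            G = nx.gnp_random_graph(8, 0.4, seed=seed)
            seed += 1
            if not nx.is_connected(G):
                continue
            done += 1
            a = nx.to_numpy_array(G, dtype=bool)
            ge, cc = global_metrics(a)
            assert ge == pytest.approx(nx.global_efficiency(G), abs=1e-12)
            assert cc == pytest.approx(nx.average_clustering(G), abs=1e-12)
            assert node_local_efficiency(a).mean() == pytest.approx(
                nx.local_efficiency(G), abs=1e-12)


class TestIdentitiesAndMonotonicity:
    def test_global_efficiency_is_mean_node_efficiency(self, rng):
        for _ in range(20):
            G = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(G):
                continue
            a = nx.to_numpy_array(G, dtype=bool)
            assert global_efficiency(a) == pytest.approx(node_efficiency(a).mean(),
                                                         abs=1e-12)

    def test_adding_edge_never_decreases_efficiency(self, rng):
        for _ in range(20):
            G = nx.gnp_random_graph(9, 0.3, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(G):
                continue
            a = nx.to_numpy_array(G, dtype=bool)
            missing = np.argwhere(~a & ~np.eye(9, dtype=bool))
            if len(missing) == 0:
                continue
            u, v = missing[rng.integers(len(missing))]
            b = a.copy()
            b[u, v] = b[v, u] = True
            assert global_efficiency(b) >= global_efficiency(a) - 1e-12
            assert np.all(node_efficiency(b) >= node_efficiency(a) - 1e-12)

    def test_isomorphism_invariance(self, rng):
        for _ in range(10):
            G = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(1 << 30)))
            if not nx.is_connected(G):
                continue
            a = nx.to_numpy_array(G, dtype=bool)
            perm = rng.permutation(8)
            b = a[np.ix_(perm, perm)]
            assert global_efficiency(b) == pytest.approx(global_efficiency(a), abs=1e-12)
            assert np.allclose(np.sort(node_efficiency(b)), np.sort(node_efficiency(a)),
                               atol=1e-12)
            assert np.allclose(np.sort(node_local_efficiency(b)),
                               np.sort(node_local_efficiency(a)), atol=1e-12)

    def test_disconnected_graph_rejected(self):
        a = _adj(4, [(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="disconnected"):
            node_efficiency(a)


class TestSmallWorldSigma:
    def test_complete_graph_sigma_exactly_one(self):
        a = ~np.eye(5, dtype=bool)
        assert small_world_sigma(a, n_null=5, seed=0) == pytest.approx(1.0)

    def test_watts_strogatz_is_small_world(self):
        hits = 0
        for seed in range(10):
            G = nx.connected_watts_strogatz_graph(30, 4, 0.1, seed=seed)
            a = nx.to_numpy_array(G, dtype=bool)
            if small_world_sigma(a, n_null=20, seed=seed) > 1.0:
                hits += 1
        assert hits >= 9

    def test_random_graph_sigma_near_one(self):
        vals = []
        seed = 0
        while len(vals) < 10:
            G = nx.gnp_random_graph(16, 0.3, seed=seed)
            seed += 1
            if not nx.is_connected(G):
                continue
            a = nx.to_numpy_array(G, dtype=bool)
            vals.append(small_world_sigma(a, n_null=20, seed=seed))
        assert 0.8 <= np.mean(vals) <= 1.2


class TestRegionAggregate:
    REGIONS6 = ["LPFC", "RPFC", "LMC", "RMC", "LOL", "ROL"]

    def test_identical_values_everywhere(self):
        df = region_aggregate({"m": np.full(6, 2.5)}, self.REGIONS6)
        assert np.allclose(df["m"], 2.5)

    def test_single_region_indicator(self):
        vals = np.array([0, 0, 0, 1.0, 0, 0])
        df = region_aggregate({"m": vals}, self.REGIONS6)
        assert df.loc["RMC", "m"] == 1.0
        assert df.drop("RMC")["m"].sum() == 0.0

    def test_matches_groupby_oracle(self, rng):
        regions = [self.REGIONS6[i % 6] for i in range(30)]
        vals = rng.normal(0, 1, 30)
        df = region_aggregate({"m": vals}, regions)
        for reg in self.REGIONS6:
            expect = np.mean([v for v, r in zip(vals, regions) if r == reg])
            assert df.loc[reg, "m"] == pytest.approx(expect, abs=1e-12)

    def test_compute_metrics_bundle(self, rng):
        G = nx.connected_watts_strogatz_graph(12, 4, 0.2, seed=3)
        a = nx.to_numpy_array(G, dtype=bool)
        regions = [self.REGIONS6[i % 6] for i in range(12)]
        ms = compute_metrics(a, channel_regions=regions, sigma_nulls=5)
        assert 0 <= ms.global_efficiency <= 1
        assert 0 <= ms.clustering_coefficient <= 1
        assert ms.small_world_sigma > 0
        df = ms.to_frame()
        assert set(df["scope"]) == {"global", "node", "region"}
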