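"""Graph metrics of thresholded brain networks.

Operates on simple undirected binary adjacency matrices (channels = nodes).
Global metrics: global efficiency, mean clustering coefficient, small-world
index sigma.  Local metrics: node degree, node efficiency and node-local
efficiency (the global efficiency of the subgraph induced by a node's
neighbors).  Local metrics are aggregated to brain regions by unweighted
means over the member channels.

Shortest paths are computed with scipy's csgraph BFS; sigma uses
degree-preserving (Maslov-Sneppen) double-edge-swap null networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "NetworkMetricSet",
    "global_metrics",
    "local_metrics",
    "small_world_sigma",
    "region_aggregate",
    "compute_metrics",
]

logger = logging.getLogger(__name__)


def _check_adjacency(adj: np.ndarray) -> np.ndarray:
    a = np.asarray(adj)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be a square matrix")
    a = a.astype(bool)
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    if a.diagonal().any():
        raise ValueError("adjacency must have an empty diagonal (simple graph)")
    return a


def _distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest paths (inf where unreachable).

    Small graphs use a dense boolean-matmul BFS (much lower overhead than a
    csgraph call per graph); larger ones go through scipy.
    """
    n = adj.shape[0]
    if n > 64:
        return shortest_path(adj.astype(float), method="D", unweighted=True)
    a = adj.astype(np.uint8)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    dist[adj] = 1.0
    reach = adj | np.eye(n, dtype=bool)
    k = 1
    while True:
        new = (reach.astype(np.uint8) @ a) > 0
        newly = new & ~reach
        if not newly.any():
            return dist
        k += 1
        dist[newly] = k
        reach |= new


def is_connected(adj: np.ndarray) -> bool:
    a = _check_adjacency(adj)
    if a.shape[0] == 1:
        return True
    return bool(np.isfinite(_distances(a)).all())


def _require_connected(d: np.ndarray):
    if not np.isfinite(d).all():
        raise ValueError("graph is disconnected; threshold stage should guarantee connectivity")


def degree(adj: np.ndarray) -> np.ndarray:
    return _check_adjacency(adj).sum(axis=1).astype(int)


def clustering_per_node(adj: np.ndarray) -> np.ndarray:
    """Fraction of each node's neighbor pairs that are connected (0 for
    degree < 2)."""
    a = _check_adjacency(adj).astype(float)
    k = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(k >= 2, 2.0 * triangles / (k * (k - 1.0)), 0.0)
    return c


def node_efficiency(adj: np.ndarray) -> np.ndarray:
    """Mean inverse shortest-path length from each node to every other."""
    a = _check_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = _distances(a)
    _require_connected(d)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def global_efficiency(adj: np.ndarray) -> float:
    """Mean of 1/d(u,v) over ordered pairs; equals the mean node efficiency."""
    return float(node_efficiency(adj).mean())


def node_local_efficiency(adj: np.ndarray) -> np.ndarray:
    """Global efficiency of each node's neighbor-induced subgraph (0 when a
    node has fewer than 2 neighbors or its neighbors are fully disconnected)."""
    a = _check_adjacency(adj)
    n = a.shape[0]
    out = np.zeros(n)
    for u in range(n):
        nbrs = np.flatnonzero(a[u])
        if nbrs.size < 2:
            continue
        sub = a[np.ix_(nbrs, nbrs)]
        d = _distances(sub)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        np.fill_diagonal(inv, 0.0)
        inv[~np.isfinite(d)] = 0.0
        m = nbrs.size
        out[u] = inv.sum() / (m * (m - 1))
    return out


def global_metrics(adj: np.ndarray) -> tuple[float, float]:
    """(global efficiency, mean clustering coefficient) of a connected graph."""
    return global_efficiency(adj), float(clustering_per_node(adj).mean())


def local_metrics(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(degree, node efficiency, node-local efficiency) per node."""
    return degree(adj), node_efficiency(adj), node_local_efficiency(adj)


def characteristic_path_length(adj: np.ndarray) -> float:
    a = _check_adjacency(adj)
    d = _distances(a)
    _require_connected(d)
    n = a.shape[0]
    mask = ~np.eye(n, dtype=bool)
    return float(d[mask].mean())


def _rewired_null(G: nx.Graph, rng: np.random.Generator, max_attempts: int = 10) -> nx.Graph | None:
    """One connected degree-preserving rewiring of G, or None on failure."""
    n_edges = G.number_of_edges()
    for _ in range(max_attempts):
        H = G.copy()
        try:
            nx.double_edge_swap(H, nswap=4 * n_edges, max_tries=100 * n_edges,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXError:
            return None  # graph admits no swap (e.g. complete): null = original
        except nx.NetworkXAlgorithmError:
            pass  # ran out of tries; use whatever swaps landed
        if nx.is_connected(H):
            return H
    return None


def small_world_sigma(adj: np.ndarray, n_null: int = 100, seed: int = 0) -> float:
    """Small-world index sigma = (C/C_rand) / (L/L_rand).

    C_rand and L_rand are means over ``n_null`` connected degree-preserving
    rewired null graphs (Maslov-Sneppen double edge swaps).  Graphs that
    cannot be rewired (e.g. complete graphs) use the original graph as its
    own null, giving sigma = 1.  If fewer than ``n_null`` connected nulls are
    achieved, sigma is computed from those obtained, with a warning.
    """
    a = _check_adjacency(adj)
    if a.shape[0] < 4:
        raise ValueError("sigma needs at least 4 nodes")
    d = _distances(a)
    _require_connected(d)
    C = float(clustering_per_node(a).mean())
    L = characteristic_path_length(a)
    G = nx.from_numpy_array(a)
    rng = np.random.default_rng(seed)
    c_null, l_null = [], []
    for _ in range(n_null):
        H = _rewired_null(G, rng)
        if H is None:
            H = G
        h_adj = nx.to_numpy_array(H, dtype=bool)
        c_null.append(float(clustering_per_node(h_adj).mean()))
        l_null.append(characteristic_path_length(h_adj))
    if len(c_null) < n_null:
        logger.warning("only %d/%d connected null graphs achieved", len(c_null), n_null)
    C_rand = float(np.mean(c_null))
    L_rand = float(np.mean(l_null))
    if C_rand == 0 or L == 0:
        return float("nan")
    return (C / C_rand) / (L / L_rand)


@dataclass
class NetworkMetricSet:
    global_efficiency: float
    clustering_coefficient: float
    small_world_sigma: float | None
    node_degree: np.ndarray
    node_efficiency: np.ndarray
    node_local_efficiency: np.ndarray
    node_clustering: np.ndarray
    region_means: pd.DataFrame | None = None   # region x metric

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(scope="global", name="global_efficiency", node=None, region=None,
                 value=self.global_efficiency),
            dict(scope="global", name="clustering_coefficient", node=None, region=None,
                 value=self.clustering_coefficient),
        ]
        if self.small_world_sigma is not None:
            rows.append(dict(scope="global", name="small_world_sigma", node=None,
                             region=None, value=self.small_world_sigma))
        for name, vals in (
            ("node_degree", self.node_degree),
            ("node_efficiency", self.node_efficiency),
            ("node_local_efficiency", self.node_local_efficiency),
            ("clustering_coefficient", self.node_clustering),
        ):
            for k, v in enumerate(vals):
                rows.append(dict(scope="node", name=name, node=k, region=None, value=float(v)))
        if self.region_means is not None:
            for region, vals in self.region_means.iterrows():
                for name, v in vals.items():
                    rows.append(dict(scope="region", name=name, node=None,
                                     region=region, value=float(v)))
        return pd.DataFrame(rows)


def region_aggregate(values_by_metric: dict[str, np.ndarray], channel_regions: list[str]) -> pd.DataFrame:
    """Unweighted mean of each local metric over each region's channels.

    Empty regions are omitted (there are none with the default montage).
    """
    n = len(channel_regions)
    for name, v in values_by_metric.items():
        if len(v) != n:
            raise ValueError(f"{name}: {len(v)} values for {n} channels")
    df = pd.DataFrame(dict(region=channel_regions, **{k: np.asarray(v, dtype=float)
                                                      for k, v in values_by_metric.items()}))
    return df.groupby("region", sort=True).mean()


def compute_metrics(
    adj: np.ndarray,
    channel_regions: list[str] | None = None,
    sigma_nulls: int = 0,
    seed: int = 0,
) -> NetworkMetricSet:
    """All global and local metrics of one thresholded network.

    ``sigma_nulls`` > 0 additionally estimates the small-world index with
    that many rewired nulls (it is the expensive part and off by default).
    """
    ge, cc = global_metrics(adj)
    deg, ne, nle = local_metrics(adj)
    ncl = clustering_per_node(adj)
    sigma = small_world_sigma(adj, n_null=sigma_nulls, seed=seed) if sigma_nulls > 0 else None
    region_means = None
    if channel_regions is not None:
        region_means = region_aggregate(
            {
                "node_degree": deg.astype(float),
                "node_efficiency": ne,
                "node_local_efficiency": nle,
                "clustering_coefficient": ncl,
            },
            channel_regions,
        )
    return NetworkMetricSet(
        global_efficiency=ge,
        clustering_coefficient=cc,
        small_world_sigma=sigma,
        node_degree=deg,
        node_efficiency=ne,
        node_local_efficiency=nle,
        node_clustering=ncl,
        region_means=region_means,
    )
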