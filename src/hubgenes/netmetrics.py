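"""Modular decomposition, nodal role metrics and global network statistics.

Community structure is found by consensus clustering over repeated runs
of the Louvain algorithm at resolution gamma; nodal metrics (total,
intra- and inter-modular degree, participation coefficient, mean
connection distance) are scored against that prototypical partition.
Global statistics (modularity Q, clustering C, path length L,
small-worldness sigma, normalized rich club) are referenced to
degree-preserving rewired null networks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities
from scipy import stats

from .connectivity import BinaryGraph

logger = logging.getLogger(__name__)


@dataclass
class ModularPartition:
    labels: np.ndarray  # module id per region, 1..M
    gamma: float
    region_ids: list
    co_classification: np.ndarray | None = None
    modularity: float | None = None

    @property
    def n_modules(self) -> int:
        return int(len(np.unique(self.labels)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"region_id": self.region_ids, "module": self.labels})


@dataclass
class GlobalMetrics:
    Q: float
    C: float
    L: float
    C_rand: float
    L_rand: float
    sigma: float
    rich_club: dict = field(default_factory=dict)  # degree k -> normalized phi


class ConsensusError(RuntimeError):
    """Consensus clustering failed to converge; carries the last
    co-classification matrix for inspection."""

    def __init__(self, message, co_classification):
        super().__init__(message)
        self.co_classification = co_classification


def _as_adjacency(graph) -> tuple[np.ndarray, list]:
    if isinstance(graph, BinaryGraph):
        return graph.adjacency.astype(float), list(graph.region_ids)
    if isinstance(graph, nx.Graph):
        ids = list(graph.nodes)
        return nx.to_numpy_array(graph), ids
    A = np.asarray(graph, float)
    return A, list(range(A.shape[0]))


def modularity(graph, labels: np.ndarray, gamma: float = 1.0) -> float:
    """Newman modularity at resolution gamma.

    Q(gamma) = (1/2m) sum_ij [A_ij - gamma k_i k_j / 2m] delta(c_i, c_j).
    Works for weighted matrices (used internally by the consensus step).
    """
    A, _ = _as_adjacency(graph)
    labels = np.asarray(labels)
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("graph has no edges")
    same = labels[:, None] == labels[None, :]
    return float(((A - gamma * np.outer(k, k) / two_m) * same).sum() / two_m)


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..M in order of first appearance (for run comparison)."""
    out = np.empty(len(labels), dtype=int)
    mapping: dict = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _louvain_labels(G: nx.Graph, node_order: list, gamma: float, seed: int) -> np.ndarray:
    comms = louvain_communities(G, weight="weight", resolution=gamma, seed=int(seed))
    index = {n: i for i, n in enumerate(node_order)}
    labels = np.empty(len(node_order), dtype=int)
    for m, comm in enumerate(comms, start=1):
        for node in comm:
            labels[index[node]] = m
    return _canonical(labels)


def louvain(graph, gamma: float = 1.0, seed: int = 0) -> ModularPartition:
    """Single Louvain run at resolution gamma (node sweep order is
    randomized from the seed, as the consensus procedure requires)."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    A, ids = _as_adjacency(graph)
    G = nx.from_numpy_array(A)
    labels = _louvain_labels(G, list(range(len(ids))), gamma, seed)
    q = modularity(A, labels, gamma=1.0)
    co = (labels[:, None] == labels[None, :]).astype(float)
    return ModularPartition(labels=labels, gamma=gamma, region_ids=ids, co_classification=co, modularity=q)


def consensus_partition(
    graph,
    gamma: float = 2.0,
    n_runs: int = 100,
    seed: int = 0,
    tau: float = 0.5,
    max_iter: int = 20,
) -> ModularPartition:
    """Consensus clustering over repeated Louvain runs.

    Runs Louvain ``n_runs`` times with distinct sub-seeds, forms the
    co-classification matrix (fraction of runs in which two regions
    share a module), thresholds it at ``tau`` and re-clusters the
    thresholded matrix, iterating until all runs agree. The returned
    partition carries the first-level co-classification matrix.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if n_runs == 1:
        return louvain(graph, gamma=gamma, seed=seed)
    A, ids = _as_adjacency(graph)
    n = len(ids)
    rng = np.random.default_rng(seed)
    current = A
    co_first = None
    for _ in range(max_iter):
        G = nx.from_numpy_array(current)
        subseeds = rng.integers(0, 2**31 - 1, size=n_runs)
        runs = [_louvain_labels(G, list(range(n)), gamma, s) for s in subseeds]
        co = np.zeros((n, n))
        for labels in runs:
            co += labels[:, None] == labels[None, :]
        co /= n_runs
        if co_first is None:
            co_first = co.copy()
        if all(np.array_equal(runs[0], lab) for lab in runs[1:]):
            labels = runs[0]
            q = modularity(A, labels, gamma=1.0)
            return ModularPartition(
                labels=labels, gamma=gamma, region_ids=ids, co_classification=co_first, modularity=q
            )
        current = np.where(co >= tau, co, 0.0)
        np.fill_diagonal(current, 0.0)
    raise ConsensusError(f"consensus did not converge in {max_iter} iterations", co)


def nodal_metrics(graph: BinaryGraph, partition: ModularPartition, coords: np.ndarray | None = None) -> pd.DataFrame:
    """Per-node k, k_intra, k_inter, participation coefficient and mean
    connection distance, scored against the given (prototypical) partition.

    PC(i) = 1 - sum_m (k_i(m) / k_i)^2 over the partition's modules.
    Isolated nodes get NaN PC and d and are logged.
    """
    A = graph.adjacency.astype(float)
    ids = list(graph.region_ids)
    if list(partition.region_ids) != ids:
        raise ValueError("partition region ids do not match graph")
    labels = np.asarray(partition.labels)
    coords = graph.coords if coords is None else np.asarray(coords, float)

    modules = np.unique(labels)
    member = (labels[:, None] == modules[None, :]).astype(float)  # n x M
    counts = A @ member  # k_i(m)
    k = counts.sum(axis=1)
    k_intra = counts[np.arange(len(ids)), np.searchsorted(modules, labels)]
    k_inter = k - k_intra

    with np.errstate(divide="ignore", invalid="ignore"):
        pc = 1.0 - ((counts / k[:, None]) ** 2).sum(axis=1)
        D = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
        d = (A * D).sum(axis=1) / k
    isolated = k == 0
    if isolated.any():
        logger.warning("isolated nodes (PC undefined): %s", [ids[i] for i in np.flatnonzero(isolated)])
        pc[isolated] = np.nan
        d[isolated] = np.nan

    return pd.DataFrame(
        {
            "region_id": ids,
            "k": k.astype(int),
            "k_intra": k_intra.astype(int),
            "k_inter": k_inter.astype(int),
            "PC": pc,
            "d": d,
        }
    ).set_index("region_id")


def average_metrics(metric_tables: list[pd.DataFrame], how: str = "mean") -> pd.DataFrame:
    """Aggregate per-subject nodal metric tables into one table.

    The sample-level response matrix is the subject mean by default;
    ``how='median'`` is exposed as an alternative.
    """
    if not metric_tables:
        raise ValueError("no metric tables to aggregate")
    stacked = pd.concat(metric_tables)
    grouped = stacked.groupby(level=0, sort=False)
    if how == "mean":
        return grouped.mean().loc[metric_tables[0].index]
    if how == "median":
        return grouped.median().loc[metric_tables[0].index]
    raise ValueError("how must be 'mean' or 'median'")


def response_matrix(metrics: pd.DataFrame, columns=("k_intra", "k_inter", "d")) -> pd.DataFrame:
    """The response block for PLS: nodal intra-modular degree,
    inter-modular degree and mean connection distance."""
    return metrics.loc[:, list(columns)].copy()


def _rich_club_phi(G: nx.Graph) -> dict[int, float]:
    degrees = dict(G.degree())
    max_k = max(degrees.values())
    phi = {}
    for k in range(max_k):
        nodes = [n for n, deg in degrees.items() if deg > k]
        nk = len(nodes)
        if nk < 2:
            break
        ek = G.subgraph(nodes).number_of_edges()
        phi[k] = 2.0 * ek / (nk * (nk - 1))
    return phi


def _rewired_null(G: nx.Graph, seed: int, swaps_per_edge: int = 10, max_retry: int = 20) -> nx.Graph:
    """Degree-preserving double-edge-swap null, retried until connected."""
    E = G.number_of_edges()
    for attempt in range(max_retry):
        H = G.copy()
        try:
            nx.double_edge_swap(H, nswap=swaps_per_edge * E, max_tries=100 * swaps_per_edge * E, seed=seed + attempt)
        except nx.NetworkXException:
            # dense/complete graphs admit few or no swaps; the partially
            # rewired graph is still a valid degree-preserving null
            pass
        if nx.is_connected(H):
            return H
    H = G.copy()
    nx.connected_double_edge_swap(H, nswap=swaps_per_edge * E, seed=seed + max_retry)
    return H


def global_metrics(
    graph: BinaryGraph,
    partition: ModularPartition | None = None,
    n_null: int = 100,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> GlobalMetrics:
    """Global topology referenced to degree-preserving nulls.

    sigma = (C / C_rand) / (L / L_rand) with the null means over
    ``n_null`` rewired graphs; the normalized rich club is
    phi(k) / mean phi_rand(k) for each degree k at which at least two
    nodes qualify in the observed graph and every null.
    """
    G = nx.from_numpy_array(graph.adjacency.astype(int))
    if not nx.is_connected(G):
        raise ValueError("global metrics require a connected graph")
    C = nx.average_clustering(G)
    L = nx.average_shortest_path_length(G)
    q = modularity(graph, partition.labels) if partition is not None else np.nan
    phi = _rich_club_phi(G)

    rng = np.random.default_rng(seed)
    c_rand, l_rand = [], []
    phi_rand: dict[int, list] = {k: [] for k in phi}
    for _ in range(n_null):
        H = _rewired_null(G, seed=int(rng.integers(0, 2**31 - 1)), swaps_per_edge=swaps_per_edge)
        c_rand.append(nx.average_clustering(H))
        l_rand.append(nx.average_shortest_path_length(H))
        ph = _rich_club_phi(H)
        for k in phi_rand:
            if k in ph:
                phi_rand[k].append(ph[k])
    C_rand, L_rand = float(np.mean(c_rand)), float(np.mean(l_rand))
    sigma = (C / C_rand) / (L / L_rand)
    rich_norm = {
        k: phi[k] / np.mean(vals) for k, vals in phi_rand.items() if len(vals) == n_null and np.mean(vals) > 0
    }
    return GlobalMetrics(Q=q, C=C, L=L, C_rand=C_rand, L_rand=L_rand, sigma=float(sigma), rich_club=rich_norm)


def class_anova(values, classes) -> tuple[float, int, int, float]:
    """One-way ANOVA of a nodal metric across (cytoarchitectonic) classes.

    F is computed from explicit between/within sums of squares with
    (n_classes - 1, n - n_classes) degrees of freedom.
    Returns (F, df1, df2, p).
    """
    values = np.asarray(values, float)
    classes = np.asarray(classes)
    if values.shape != classes.shape:
        raise ValueError("values and classes must align")
    uniq = np.unique(classes)
    if len(uniq) < 2:
        raise ValueError("need at least two classes")
    groups = [values[classes == c] for c in uniq]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every class needs at least two regions")
    n = len(values)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = len(uniq) - 1, n - len(uniq)
    if ss_within == 0:
        return np.inf if ss_between > 0 else 0.0, df1, df2, 0.0 if ss_between > 0 else 1.0
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return float(F), df1, df2, p
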