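"""Global topology, Louvain modules, Zi-Pi node roles, and the
Erdos-Renyi null-model modularity Z-score.

Module detection runs Louvain (best of several seeded restarts by Newman
modularity) on the unweighted, unsigned edge skeleton. Node roles follow
the within-module degree z-score (Zi) / participation coefficient (Pi)
taxonomy with the standard thresholds Zi = 2.5 and Pi = 0.62: peripherals
(Zi <= 2.5, Pi <= 0.62), connectors (Zi <= 2.5, Pi > 0.62), module hubs
(Zi > 2.5, Pi <= 0.62), network hubs (Zi > 2.5, Pi > 0.62). Topological
determinism is quantified as Z = (Q_obs - mean Q_rand) / sd Q_rand against
an ensemble of G(N, M) random graphs with the same node and edge counts,
each re-partitioned with identical Louvain settings.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_comm

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

PERIPHERAL, CONNECTOR, MODULE_HUB, NETWORK_HUB = (
    "Peripheral", "Connector", "ModuleHub", "NetworkHub")
KEYSTONE_ROLES = (CONNECTOR, MODULE_HUB, NETWORK_HUB)


@dataclass
class ModulePartition:
    membership: dict            # node -> module id (int)
    modularity: float           # Newman Q of this partition
    n_modules: int
    avg_module_size: float

    def communities(self) -> list[set]:
        out: dict[int, set] = {}
        for node, m in self.membership.items():
            out.setdefault(m, set()).add(node)
        return [out[m] for m in sorted(out)]


@dataclass
class NullModelResult:
    q_obs: float
    q_rand_mean: float
    q_rand_sd: float
    z: float
    n_random: int
    seed: int
    ensemble: np.ndarray = field(default_factory=lambda: np.array([]))


def louvain_partition(
    net: nx.Graph, seed: int = 0, resolution: float = 1.0, restarts: int = 10,
) -> ModulePartition:
    """Louvain modules on the unweighted skeleton, best-of-restarts by Q.

    An edgeless graph degenerates to one singleton module per node with
    Q = 0.
    """
    if net.number_of_edges() == 0:
        membership = {node: i for i, node in enumerate(net.nodes)}
        n = max(len(membership), 1)
        return ModulePartition(membership, 0.0, len(membership),
                               1.0 if membership else float("nan"))
    best_comms, best_q = None, -np.inf
    for r in range(restarts):
        comms = nx_comm.louvain_communities(
            net, weight=None, resolution=resolution, seed=seed + r)
        q = nx_comm.modularity(net, comms, weight=None, resolution=resolution)
        if q > best_q:
            best_comms, best_q = comms, q
    membership = {}
    for i, c in enumerate(sorted(best_comms, key=lambda c: sorted(map(str, c))[0])):
        for node in c:
            membership[node] = i
    n_modules = len(best_comms)
    return ModulePartition(
        membership=membership,
        modularity=float(best_q),
        n_modules=n_modules,
        avg_module_size=net.number_of_nodes() / n_modules,
    )


def module_size_stats(partition: "ModulePartition | int", n_modules: int | None = None) -> tuple[int, float]:
    """(number of modules, average module size rounded to 2 decimals).

    Accepts either a :class:`ModulePartition` or raw ``(n_nodes,
    n_modules)`` counts (the worked-example route from printed tables).
    """
    if isinstance(partition, ModulePartition):
        n_nodes, n_modules = len(partition.membership), partition.n_modules
    else:
        n_nodes = int(partition)
        if n_modules is None:
            raise ValueError("n_modules required when passing raw node count")
    if n_modules <= 0:
        raise ValueError("n_modules must be positive")
    return n_modules, round(n_nodes / n_modules, 2)


@dataclass
class GlobalMetrics:
    n_nodes: int
    n_edges: int
    avg_degree: float
    avg_clustering: float
    avg_path_length: float
    n_connected_pairs: int
    modularity: float
    n_modules: int
    avg_module_size: float


def global_metrics(net: nx.Graph, partition: ModulePartition) -> GlobalMetrics:
    """Size, connectivity, clustering, path length, and modular summary.

    Average path length is taken over connected node pairs only (the pair
    count is reported so fragmented graphs are comparable); nodes of
    degree < 2 contribute 0 to the mean clustering coefficient.
    """
    n, m = net.number_of_nodes(), net.number_of_edges()
    if n == 0:
        warnings.warn("empty graph: all metrics NaN")
        nan = float("nan")
        return GlobalMetrics(0, 0, nan, nan, nan, 0, nan, 0, nan)
    total_len, n_pairs = 0.0, 0
    for comp in nx.connected_components(net):
        sub = net.subgraph(comp)
        k = len(comp)
        if k > 1:
            total_len += sum(
                d for _, targets in nx.all_pairs_shortest_path_length(sub)
                for d in targets.values()) / 2.0
            n_pairs += k * (k - 1) // 2
    if n_pairs == 0:
        logger.warning("no connected pairs; average path length undefined")
    return GlobalMetrics(
        n_nodes=n,
        n_edges=m,
        avg_degree=2.0 * m / n,
        avg_clustering=nx.average_clustering(net),
        avg_path_length=total_len / n_pairs if n_pairs else float("nan"),
        n_connected_pairs=n_pairs,
        modularity=partition.modularity,
        n_modules=partition.n_modules,
        avg_module_size=partition.avg_module_size,
    )


def zipi_roles(net: nx.Graph, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score and participation coefficient per node.

    Zi standardizes a node's within-module edge count against its module's
    mean and sd (Zi = 0 when the module's within-degree sd is 0). Pi =
    1 - sum_s (k_is / k_i)^2 over modules s; isolated nodes get Pi = 0.
    Roles follow the four (Zi, Pi) boxes.
    """
    membership = partition.membership
    missing = [v for v in net.nodes if v not in membership]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    nodes = list(net.nodes)
    within = {}
    per_module_counts = {}
    for v in nodes:
        counts: dict[int, int] = {}
        for u in net.neighbors(v):
            counts[membership[u]] = counts.get(membership[u], 0) + 1
        per_module_counts[v] = counts
        within[v] = counts.get(membership[v], 0)

    zi = {}
    for mod in set(membership.values()):
        members = [v for v in nodes if membership[v] == mod]
        kappa = np.array([within[v] for v in members], dtype=float)
        sd = kappa.std()
        mean = kappa.mean()
        for v, k in zip(members, kappa):
            zi[v] = (k - mean) / sd if sd > 0 else 0.0

    rows = []
    for v in nodes:
        k = net.degree(v)
        if k == 0:
            pi = 0.0
        else:
            pi = 1.0 - sum((c / k) ** 2 for c in per_module_counts[v].values())
        role = classify_role(zi[v], pi)
        rows.append((v, k, zi[v], pi, role, net.nodes[v].get("phylum", "Unclassified")))
    df = pd.DataFrame(rows, columns=["otu", "degree", "zi", "pi", "role", "phylum"])
    return df.set_index("otu")


def classify_role(zi: float, pi: float) -> str:
    """Assign the (Zi, Pi) plane box; boundaries are <= / > exactly."""
    if zi <= ZI_THRESHOLD:
        return PERIPHERAL if pi <= PI_THRESHOLD else CONNECTOR
    return MODULE_HUB if pi <= PI_THRESHOLD else NETWORK_HUB


def modularity_zscore(
    net: nx.Graph,
    n_random: int = 100,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 10,
    partition: ModulePartition | None = None,
) -> NullModelResult:
    """Modularity Z-score against a G(N, M) Erdos-Renyi ensemble.

    Each of the ``n_random`` null graphs has exactly the observed node and
    edge counts and is re-partitioned with the same Louvain settings
    (fresh seeds derived from the master seed). Z > 2 is the conventional
    bar for non-random modular structure; sd = 0 yields an infinite
    sentinel with a warning.
    """
    n, m = net.number_of_nodes(), net.number_of_edges()
    if n < 2 or m < 1:
        raise ValueError("need at least 2 nodes and 1 edge for the null model")
    if partition is None:
        partition = louvain_partition(net, seed=seed, resolution=resolution,
                                      restarts=restarts)
    q_obs = partition.modularity
    rng = np.random.default_rng(seed)
    qs = np.empty(n_random)
    for i in range(n_random):
        g_seed = int(rng.integers(0, 2 ** 31 - 1))
        g = nx.gnm_random_graph(n, m, seed=g_seed)
        qs[i] = louvain_partition(g, seed=g_seed, resolution=resolution,
                                  restarts=restarts).modularity
    mean, sd = float(qs.mean()), float(qs.std(ddof=1))
    if sd == 0:
        warnings.warn("null ensemble modularity has zero variance; Z set to inf")
        z = float("inf") if q_obs > mean else (float("-inf") if q_obs < mean else 0.0)
    else:
        z = (q_obs - mean) / sd
    return NullModelResult(q_obs=q_obs, q_rand_mean=mean, q_rand_sd=sd,
                           z=float(z), n_random=n_random, seed=seed, ensemble=qs)


def keystone_taxonomy_profile(roles: pd.DataFrame) -> pd.DataFrame:
    """Phylum composition of each keystone role (connectors, module hubs,
    network hubs); fractions sum to 1 per role; empty roles are omitted."""
    rows = {}
    for role in KEYSTONE_ROLES:
        members = roles[roles["role"] == role]
        if members.empty:
            logger.info("no nodes classified as %s; omitted from profile", role)
            continue
        frac = members["phylum"].value_counts(normalize=True)
        rows[role] = frac
    if not rows:
        logger.info("no keystone taxa identified in this network")
        return pd.DataFrame()
    return pd.DataFrame(rows).T.fillna(0.0)


def two_clique_bridge(k: int = 4) -> nx.Graph:
    """Two k-cliques joined by a single bridge edge (a standard modular
    test graph; for k=4 the two-module partition has Q = 12/13 - 1/2)."""
    g = nx.Graph()
    left = [f"a{i}" for i in range(k)]
    right = [f"b{i}" for i in range(k)]
    for part in (left, right):
        g.add_edges_from(itertools.combinations(part, 2))
    g.add_edge(left[0], right[0])
    return g
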