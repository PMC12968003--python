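"""Stage-wise co-occurrence network construction.

Pairwise Spearman rank correlations among core OTUs, two-sided p-values
(t approximation; exact rank-permutation enumeration for n <= 9 samples),
Benjamini-Hochberg adjustment across all pairs of one network jointly, and
a dual threshold: an edge requires |rho| > 0.7 AND FDR q < 0.01. Edges are
signed by the correlation sign; the negative-edge proportion is the
summary that tracks the shift from cooperative to competitive interaction
structure along succession.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .otu import OtuTable, relative_abundance

logger = logging.getLogger(__name__)


def _spearman_p_t(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation with n-2 df."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.where(np.abs(rho) >= 1.0, 0.0, p)


def _spearman_p_exact(x_ranks: np.ndarray, y_ranks: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p by full enumeration (n <= 9 only)."""
    n = len(x_ranks)
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return 1.0
    count = total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = float(xc[list(perm)] @ yc) / denom
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def correlation_edges(
    core: OtuTable,
    use_relative: bool = True,
    exact_max_n: int = 9,
) -> pd.DataFrame:
    """All-pairs Spearman (rho, p, q) table over the core OTUs.

    Ranks use average tie handling. Constant OTU vectors have undefined
    correlation; their pairs are skipped with a log entry. BH adjustment
    spans all retained pairs of this table jointly (the test family is one
    stage-kingdom network).
    """
    n = core.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples for rank correlations")
    data = relative_abundance(core).values.to_numpy() if use_relative \
        else core.counts.astype(float)
    m = core.n_otus
    constant = data.std(axis=0) == 0
    if constant.any():
        skipped = [core.otu_ids[i] for i in np.flatnonzero(constant)]
        logger.info("skipping %d constant OTUs: %s", len(skipped), skipped[:5])

    ranks = np.apply_along_axis(stats.rankdata, 0, data)
    rc = ranks - ranks.mean(axis=0)
    norm = np.sqrt((rc ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rc.T @ rc) / np.outer(norm, norm)

    ia, ib = np.triu_indices(m, 1)
    keep = ~(constant[ia] | constant[ib])
    ia, ib = ia[keep], ib[keep]
    r = rho[ia, ib]

    if n <= exact_max_n:
        p = np.array([
            _spearman_p_exact(ranks[:, a], ranks[:, b], rv)
            for a, b, rv in zip(ia, ib, r)
        ])
    else:
        p = _spearman_p_t(r, n)
    q = stats.false_discovery_control(p, method="bh")
    otus = np.asarray(core.otu_ids)
    return pd.DataFrame({
        "otu_a": otus[ia], "otu_b": otus[ib],
        "rho": r, "p": p, "q": q,
    })


def build_network(
    pairs: pd.DataFrame,
    core: OtuTable | None = None,
    rho_min: float = 0.7,
    q_max: float = 0.01,
    include_isolated: bool = False,
) -> nx.Graph:
    """Assemble the signed undirected graph from the pair table.

    Edges are pairs with |rho| strictly greater than ``rho_min`` AND q
    strictly below ``q_max``. Nodes are edge-incident OTUs; pass
    ``include_isolated=True`` (with the core table) to also keep isolated
    core OTUs as nodes. Node ``phylum`` attributes are attached when the
    core table is supplied.
    """
    g = nx.Graph(rho_min=rho_min, q_max=q_max)
    hits = pairs[(pairs["rho"].abs() > rho_min) & (pairs["q"] < q_max)]
    for row in hits.itertuples():
        g.add_edge(row.otu_a, row.otu_b, rho=float(row.rho), q=float(row.q),
                   sign=1 if row.rho > 0 else -1)
    if include_isolated and core is not None:
        g.add_nodes_from(core.otu_ids)
    if core is not None:
        for node in g.nodes:
            if node in core.taxonomy:
                g.nodes[node]["phylum"] = core.phylum(node)
    return g


@dataclass
class EdgeSummary:
    positive_edges: int
    negative_edges: int
    total_edges: int
    negative_proportion: float          # fraction in [0, 1]
    negative_percent: float             # percentage rounded to 1 decimal

    def __post_init__(self) -> None:
        assert self.total_edges == self.positive_edges + self.negative_edges


def edge_sign_summary(net: nx.Graph) -> EdgeSummary:
    """Count positive and negative edges; report the negative proportion
    (as a percentage rounded to one decimal, the convention of stage
    comparison tables)."""
    signs = [d.get("sign", 1) for _, _, d in net.edges(data=True)]
    pos = sum(1 for s in signs if s > 0)
    neg = len(signs) - pos
    total = len(signs)
    if total == 0:
        logger.warning("empty network: negative proportion undefined")
        return EdgeSummary(0, 0, 0, float("nan"), float("nan"))
    frac = neg / total
    return EdgeSummary(pos, neg, total, frac, round(100.0 * frac, 1))


def summarize_from_counts(positive: int, negative: int) -> EdgeSummary:
    """Edge-sign summary straight from printed counts (worked examples)."""
    g = nx.Graph()
    for i in range(positive):
        g.add_edge(f"p{i}a", f"p{i}b", sign=1, rho=0.9, q=0.0)
    for i in range(negative):
        g.add_edge(f"n{i}a", f"n{i}b", sign=-1, rho=-0.9, q=0.0)
    return edge_sign_summary(g)
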