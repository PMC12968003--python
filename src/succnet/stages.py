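"""Consensus identification of discrete ecological stages.

Two independent clustering routes — Ward-linkage agglomeration on the
Bray-Curtis matrix and K-means on PCoA coordinates — are scanned over k
with the silhouette score. At the chosen k, samples consistently placed by
both routes (after maximum-agreement label alignment) form Core stages;
conflicting samples are Ambiguous and excluded from stage-conditioned
analyses. Stage identity (Chaos vs Recovery) is assigned either by
convergence to the non-degraded reference (default, cheap) or by comparing
modularity Z-scores of per-cluster networks (the topology-faithful rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .diversity import OrdinationResult

logger = logging.getLogger(__name__)

CHAOS, RECOVERY, AMBIGUOUS = "Chaos", "Recovery", "Ambiguous"


@dataclass
class SilhouetteScan:
    scores: pd.DataFrame     # index k, columns ["hierarchical", "kmeans"]
    best_k: dict[str, int]   # route -> argmax k


@dataclass
class ConsensusAssignment:
    assignment: pd.DataFrame  # sample_id index; hier_label, kmeans_label, core_stage
    k: int

    @property
    def core_samples(self) -> list[str]:
        mask = self.assignment["core_stage"] != AMBIGUOUS
        return list(self.assignment.index[mask])


def _ward_labels(dist: pd.DataFrame, k: int, sqrt_transform: bool = False) -> np.ndarray:
    d = np.asarray(dist, dtype=float)
    if sqrt_transform:
        d = np.sqrt(d)
    z = linkage(squareform(d, checks=False), method="ward")
    return fcluster(z, t=k, criterion="maxclust")


def _kmeans_labels(ordination: OrdinationResult, k: int, seed: int,
                   n_axes: int | None = None, n_init: int = 10) -> np.ndarray:
    coords = ordination.coordinates.to_numpy()
    if n_axes is not None:
        coords = coords[:, :n_axes]
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(coords)
    if len(np.unique(labels)) < k:
        logger.warning("K-means produced an empty cluster; re-running with a new restart")
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed + 1)
        labels = km.fit_predict(coords)
    return labels


def silhouette_scan(
    dist: pd.DataFrame,
    ordination: OrdinationResult,
    k_min: int = 2,
    k_max: int = 6,
    seed: int = 0,
    n_axes: int | None = None,
) -> SilhouetteScan:
    """Mean silhouette for each k on both clustering routes.

    The hierarchical route is scored on the supplied distance matrix
    (precomputed metric); the K-means route is scored in Euclidean
    ordination space.
    """
    n = dist.shape[0]
    if k_max >= n:
        raise ValueError(f"k_max={k_max} must be smaller than n={n}")
    d = np.asarray(dist, dtype=float)
    coords = ordination.coordinates.to_numpy()
    if n_axes is not None:
        coords = coords[:, :n_axes]
    rows = {}
    for k in range(k_min, k_max + 1):
        hier = _ward_labels(dist, k)
        km = _kmeans_labels(ordination, k, seed=seed, n_axes=n_axes)
        rows[k] = {
            "hierarchical": silhouette_score(d, hier, metric="precomputed"),
            "kmeans": silhouette_score(coords, km),
        }
    scores = pd.DataFrame(rows).T
    scores.index.name = "k"
    best = {route: int(scores[route].idxmax()) for route in scores.columns}
    return SilhouetteScan(scores=scores, best_k=best)


def _align_labels(reference: np.ndarray, other: np.ndarray) -> np.ndarray:
    """Relabel ``other`` to maximize agreement with ``reference`` via the
    assignment problem on the contingency table."""
    ref_ids = np.unique(reference)
    oth_ids = np.unique(other)
    cont = np.zeros((len(oth_ids), len(ref_ids)))
    for i, o in enumerate(oth_ids):
        for j, r in enumerate(ref_ids):
            cont[i, j] = np.sum((other == o) & (reference == r))
    rows, cols = linear_sum_assignment(-cont)
    mapping = {oth_ids[i]: ref_ids[j] for i, j in zip(rows, cols)}
    # unmatched labels (more clusters in `other`) keep themselves
    return np.array([mapping.get(o, o) for o in other])


def consensus_cluster(
    dist: pd.DataFrame,
    ordination: OrdinationResult,
    k: int = 2,
    seed: int = 0,
    n_axes: int | None = None,
) -> ConsensusAssignment:
    """Core/Ambiguous assignment from the agreement of the two routes."""
    if k < 2:
        raise ValueError("k must be >= 2")
    hier = _ward_labels(dist, k)
    km = _align_labels(hier, _kmeans_labels(ordination, k, seed=seed, n_axes=n_axes))
    core = np.where(hier == km, hier.astype(str), AMBIGUOUS)
    df = pd.DataFrame(
        {"hier_label": hier, "kmeans_label": km, "core_stage": core},
        index=pd.Index(dist.index, name="sample_id"),
    )
    return ConsensusAssignment(assignment=df, k=k)


def label_stages(
    assignment: ConsensusAssignment,
    convergence: pd.Series | None = None,
    zscores: dict | None = None,
) -> ConsensusAssignment:
    """Attach Chaos/Recovery identities to the two core clusters.

    Default rule: the cluster with the smaller mean Aitchison distance to
    the non-degraded reference is Recovery. Topology rule (pass
    ``zscores``, a mapping cluster label -> modularity Z-score of that
    cluster's co-occurrence network): the cluster with the higher Z-score
    is Recovery. Ties raise, demanding the other rule.
    """
    df = assignment.assignment.copy()
    core = df[df["core_stage"] != AMBIGUOUS]
    clusters = sorted(core["core_stage"].unique())
    if len(clusters) != 2:
        raise ValueError(f"expected exactly 2 core clusters, found {clusters}")
    if zscores is not None:
        crit = {c: float(zscores[c]) for c in clusters}
        recovery_is_max = True
    elif convergence is not None:
        crit = {c: float(convergence[core.index[core["core_stage"] == c]].mean())
                for c in clusters}
        recovery_is_max = False  # closer to reference = Recovery
    else:
        raise ValueError("provide convergence distances or per-cluster z-scores")
    a, b = clusters
    if np.isclose(crit[a], crit[b]):
        raise ValueError("stage-identity criterion tied; use the alternative rule")
    winner = max(crit, key=crit.get) if recovery_is_max else min(crit, key=crit.get)
    rename = {c: (RECOVERY if c == winner else CHAOS) for c in clusters}
    df["core_stage"] = df["core_stage"].map(lambda s: rename.get(s, s))
    return ConsensusAssignment(assignment=df, k=assignment.k)


def stage_composition(assignment: ConsensusAssignment, groups: pd.Series) -> pd.DataFrame:
    """Per-group proportions of Chaos / Recovery / Ambiguous samples."""
    df = assignment.assignment
    stages = df["core_stage"]
    cats = [CHAOS, RECOVERY, AMBIGUOUS]
    out = {}
    for g in pd.unique(groups):
        members = groups.index[groups == g]
        sub = stages.loc[[m for m in members if m in stages.index]]
        n = len(sub)
        out[g] = {c: float((sub == c).sum()) / n if n else np.nan for c in cats}
    comp = pd.DataFrame(out).T[cats]
    comp.index.name = "group"
    return comp
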