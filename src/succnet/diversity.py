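"""Alpha and beta diversity, group tests, and compositional convergence.

Alpha metrics (observed richness, bias-corrected Chao1, Shannon, Gini-
Simpson) and the beta-diversity machinery (Bray-Curtis, classical-scaling
PCoA, PERMANOVA, ANOSIM) are implemented from their definitions; group
comparisons use Kruskal-Wallis followed by Dunn's post-hoc test with
Benjamini-Hochberg correction and a compact letter display.

Convergence along the chronosequence is measured as the Aitchison distance
(Euclidean distance in CLR space) of each sample to the centroid of the
non-degraded reference group.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .otu import CompositionMatrix, OtuTable


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_metrics(table: OtuTable, chao1_bias_corrected: bool = True) -> pd.DataFrame:
    """Per-sample observed OTUs, Chao1, Shannon (natural log), Gini-Simpson.

    Chao1 defaults to the bias-corrected form
    ``S_obs + F1 (F1 - 1) / (2 (F2 + 1))`` (robust when doubletons are
    absent); the classic ``S_obs + F1^2 / (2 F2)`` is available by flag.
    """
    counts = table.counts
    totals = counts.sum(axis=1).astype(float)
    if np.any(totals <= 0):
        bad = table.sample_ids[int(np.argmax(totals <= 0))]
        raise ValueError(f"sample with zero total count: {bad!r}")

    observed = (counts > 0).sum(axis=1)
    f1 = (counts == 1).sum(axis=1).astype(float)
    f2 = (counts == 2).sum(axis=1).astype(float)
    if chao1_bias_corrected:
        chao1 = observed + f1 * (f1 - 1.0) / (2.0 * (f2 + 1.0))
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            chao1 = np.where(f2 > 0, observed + f1 ** 2 / (2.0 * f2), observed + f1 * (f1 - 1.0) / 2.0)

    p = counts / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    shannon = -plogp.sum(axis=1)
    simpson = 1.0 - (p ** 2).sum(axis=1)

    return pd.DataFrame(
        {"observed_otus": observed, "chao1": chao1,
         "shannon_ln": shannon, "gini_simpson": simpson},
        index=pd.Index(table.sample_ids, name="sample_id"),
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn + compact letters
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame      # group_a, group_b, z, p, q
    letters: dict[str, str]     # group -> compact letter display


def _dunn_pairwise(values: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Dunn's post-hoc z-tests on pooled ranks with tie correction."""
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12.0 * (n - 1))
    groups = pd.unique(labels)
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    size = {g: int((labels == g).sum()) for g in groups}
    rows = []
    for a, b in itertools.combinations(groups, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / size[a] + 1.0 / size[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, z, p))
    df = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    df["q"] = stats.false_discovery_control(df["p"], method="bh")
    return df


def _compact_letters(groups: list, pairwise: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Greedy insert-and-absorb compact letter display.

    Groups sharing a letter are not separated at q < alpha.
    """
    sep = {frozenset((r.group_a, r.group_b)) for r in pairwise.itertuples()
           if r.q < alpha}
    letter_sets: list[set] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all(frozenset((g, h)) not in sep for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb subsets
    letter_sets = [s for i, s in enumerate(letter_sets)
                   if not any(s < t for j, t in enumerate(letter_sets) if i != j)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict = {g: "" for g in groups}
    for letter, s in zip(alphabet, letter_sets):
        for g in groups:
            if g in s:
                out[g] += letter
    return out


def compare_groups(values, groups) -> GroupTestResult:
    """Kruskal-Wallis across groups, Dunn's pairwise z-tests with BH
    correction, and a compact letter display at q < 0.05."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("compare_groups needs at least 2 groups")
    samples = [values[labels == g] for g in uniq]
    if np.ptp(values) == 0:
        h, p = 0.0, 1.0  # all observations tied
    else:
        h, p = stats.kruskal(*samples)
    pairwise = _dunn_pairwise(values, labels)
    letters = _compact_letters(list(uniq), pairwise)
    return GroupTestResult(kw_statistic=float(h), kw_p=float(p),
                           pairwise=pairwise, letters=letters)


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis_matrix(comp: CompositionMatrix) -> pd.DataFrame:
    """Bray-Curtis dissimilarity BC(x, y) = sum|x-y| / sum(x+y) between
    relative-abundance profiles."""
    if comp.kind != "relative":
        raise ValueError("bray_curtis_matrix expects a relative composition")
    d = squareform(pdist(comp.values.to_numpy(), metric="braycurtis"))
    return pd.DataFrame(d, index=comp.values.index, columns=comp.values.index)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame        # samples x positive axes
    eigenvalues: np.ndarray          # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(dist: pd.DataFrame) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers the squared distances (Gower matrix), eigendecomposes,
    keeps positive-eigenvalue axes for coordinates; negative eigenvalues
    are reported but contribute no axes and no explained proportion.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ (d ** 2) @ j
    vals, vecs = np.linalg.eigh(g)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(vals.max(), 0) * 1e-12 if vals.max() > 0 else vals > 0
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    index = dist.index if isinstance(dist, pd.DataFrame) else pd.RangeIndex(n)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=vals,
        proportion_explained=prop,
    )


def _group_onehot(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    uniq, inv = np.unique(labels, return_inverse=True)
    onehot = np.eye(len(uniq))[inv]
    return uniq, onehot


def _pseudo_f_batch(d2: np.ndarray, label_idx: np.ndarray, n_groups: int) -> np.ndarray:
    """Pseudo-F for a batch of label assignments.

    ``label_idx`` is (batch, n) of integer group indices. SS_total and
    per-group within sums come from the squared-distance matrix:
    SS_W = sum_g (sum_{i<j in g} d2_ij) / n_g.
    """
    batch, n = label_idx.shape
    onehot = np.zeros((batch, n, n_groups))
    b_idx = np.repeat(np.arange(batch), n)
    s_idx = np.tile(np.arange(n), batch)
    onehot[b_idx, s_idx, label_idx.ravel()] = 1.0
    # within-group pair sums: u_g' D2 u_g counts each pair twice
    quad = np.einsum("bia,ij,bja->ba", onehot, d2, onehot)
    sizes = onehot.sum(axis=1)
    ss_w = (quad / (2.0 * np.where(sizes > 0, sizes, 1))).sum(axis=1)
    ss_t = d2.sum() / (2.0 * n)
    ss_a = ss_t - ss_w
    a = n_groups
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_a / (a - 1)) / (ss_w / (n - a))
    return f


def permanova(dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    Pseudo-F partitions the sum of squared distances by group; the p-value
    uses the (1 + exceedances) / (1 + n_perm) convention, so the minimal
    achievable p with 999 permutations is 0.001.
    """
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("permanova needs at least 2 groups")
    if (np.bincount(inv) < 2).any():
        warnings.warn("a group has a single sample; pseudo-F may be unstable")
    d2 = d ** 2
    f_obs = float(_pseudo_f_batch(d2, inv[None, :], len(uniq))[0])
    if not np.isfinite(f_obs):
        warnings.warn("all within-group distances are zero; F undefined")
        return float("nan"), float("nan")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(inv) for _ in range(n_perm)])
    f_perm = _pseudo_f_batch(d2, perms, len(uniq))
    p = (1.0 + np.sum(f_perm >= f_obs)) / (1.0 + n_perm)
    return f_obs, float(p)


def _anosim_r(rank_d: np.ndarray, same_group: np.ndarray, n: int) -> float:
    between = rank_d[~same_group].mean()
    within = rank_d[same_group].mean()
    return (between - within) / (n * (n - 1) / 4.0)


def anosim(dist: pd.DataFrame, groups, n_perm: int = 999, seed: int = 0) -> tuple[float, float]:
    """Analysis of similarities: rank-based R statistic in [-1, 1] with a
    permutation p-value."""
    d = np.asarray(dist, dtype=float)
    labels = np.asarray(groups)
    uniq, inv = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("anosim needs at least 2 groups")
    n = d.shape[0]
    iu = np.triu_indices(n, 1)
    rank_d = stats.rankdata(d[iu])
    same = inv[iu[0]] == inv[iu[1]]
    if not same.any() or same.all():
        raise ValueError("anosim needs both within- and between-group pairs")
    r_obs = _anosim_r(rank_d, same, n)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(inv)
        same_p = perm[iu[0]] == perm[iu[1]]
        if _anosim_r(rank_d, same_p, n) >= r_obs:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return float(r_obs), float(p)


# ---------------------------------------------------------------------------
# Compositional convergence
# ---------------------------------------------------------------------------

def convergence_to_reference(
    clr: CompositionMatrix, metadata: dict[str, dict], reference_group: str = "ND",
) -> pd.Series:
    """Aitchison distance of every sample to the centroid of the reference
    group, in CLR space."""
    if clr.kind != "clr":
        raise ValueError("convergence_to_reference expects CLR coordinates")
    samples = clr.values.index
    ref = [s for s in samples if metadata[s].get("group") == reference_group]
    if not ref:
        raise ValueError(f"reference group {reference_group!r} has no samples")
    centroid = clr.values.loc[ref].to_numpy().mean(axis=0)
    dist = np.linalg.norm(clr.values.to_numpy() - centroid, axis=1)
    return pd.Series(dist, index=samples, name="aitchison_to_reference")
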