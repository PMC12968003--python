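"""Synthetic chronosequence generator with planted ground truth.

Emulates a restoration chronosequence study design: 11 groups (a severely
degraded control, nine restoration ages, and a non-degraded reference) x 5
replicates = 55 samples, with two latent community regimes. The "chaos"
regime is sparse and weakly modular with almost no negative associations;
the "recovery" regime is dense, strongly modular, carries planted keystone
hubs and a substantial negative-edge fraction.

Mechanism: a Gaussian copula. Per regime, a block-structured latent
correlation matrix (blocks = planted modules, hub rows given cross-block
loadings, a computed fraction of member variables sign-flipped to plant
negative associations) generates multivariate-normal latent vectors; group
means are shifted along a regime axis; latent values map monotonically
(exponentially) to expected relative abundances; counts are multinomial at
fixed depth. The monotone map preserves rank (Spearman) correlation
structure, which is exactly what the downstream network build consumes.

All generator parameters are inventions of this package (the study design
they emulate analyzed real field data); defaults are chosen to produce the
qualitative chaos/recovery contrast at desk scale and are documented in
docs/methods.md.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .otu import OtuTable

logger = logging.getLogger(__name__)

#: Chronosequence group labels in restoration order.
DEFAULT_GROUPS = ("SD", "1y", "4y", "6y", "8y", "9y", "12y", "14y", "16y", "18y", "ND")

#: Groups assigned to the chaos regime by default (early succession).
DEFAULT_CHAOS_GROUPS = ("SD", "1y", "4y", "6y")


@dataclass
class RegimeSpec:
    """Parameters of one latent community regime.

    ``intra_module_corr`` is the latent (Gaussian) correlation between
    members of the same planted module; ``negative_edge_fraction`` is the
    target fraction of negative associations among planted within-module
    pairs, realized by sign-flipping member variables; ``noise_sd`` is
    independent latent noise added on top of the correlated component
    (unit variance), so the effective pairwise latent correlation is
    ``intra_module_corr / (1 + noise_sd**2)``.
    """

    n_modules: int = 6
    module_size_mean: int = 10
    intra_module_corr: float = 0.94
    negative_edge_fraction: float = 0.30
    n_network_hubs: int = 2
    n_module_hubs: int = 4
    n_connectors: int = 6
    noise_sd: float = 0.20
    regime_centroid_shift: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 < self.intra_module_corr < 1.0:
            raise ValueError("intra_module_corr must be in (0, 1)")
        if not 0.0 <= self.negative_edge_fraction <= 0.5:
            raise ValueError("negative_edge_fraction must be in [0, 0.5] "
                             "(sign-flip construction cannot exceed 1/2)")
        if self.noise_sd <= 0 or self.regime_centroid_shift <= 0:
            raise ValueError("noise_sd and regime_centroid_shift must be positive")
        n_planted = self.n_modules * self.module_size_mean
        n_hubs = self.n_network_hubs + self.n_module_hubs + self.n_connectors
        if n_hubs > n_planted:
            raise ValueError("hub counts exceed planted nodes")

    @property
    def n_planted(self) -> int:
        return self.n_modules * self.module_size_mean


#: Default regime presets: sparse/fragmented vs dense/modular/keystone-rich.
CHAOS_DEFAULT = RegimeSpec(
    n_modules=10, module_size_mean=4, intra_module_corr=0.90,
    negative_edge_fraction=0.05, n_network_hubs=0, n_module_hubs=1,
    n_connectors=1, noise_sd=0.35, regime_centroid_shift=2.0,
)
RECOVERY_DEFAULT = RegimeSpec(
    n_modules=6, module_size_mean=10, intra_module_corr=0.94,
    negative_edge_fraction=0.30, n_network_hubs=2, n_module_hubs=4,
    n_connectors=6, noise_sd=0.20, regime_centroid_shift=2.0,
)


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a generated table."""

    stage_labels: dict[str, str]          # sample_id -> "chaos" | "recovery"
    modules: dict[str, str]               # otu_id -> module id (regime-prefixed)
    roles: dict[str, str]                 # otu_id -> planted role
    latent_corr: dict[str, np.ndarray]    # regime -> full latent correlation
    sign: dict[str, np.ndarray] = field(default_factory=dict)  # regime -> +-1 per OTU

    def planted_pairs(self, regime: str, otu_ids: list[str]) -> list[tuple[int, int, float]]:
        """Within-module planted pairs of the given regime as
        (index_a, index_b, latent_corr) triples."""
        prefix = f"{regime}_m"
        idx_of = {o: i for i, o in enumerate(otu_ids)}
        by_module: dict[str, list[str]] = {}
        for o, m in self.modules.items():
            if m.startswith(prefix):
                by_module.setdefault(m, []).append(o)
        corr = self.latent_corr[regime]
        pairs = []
        for members in by_module.values():
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    ia, ib = idx_of[a], idx_of[b]
                    pairs.append((ia, ib, float(corr[ia, ib])))
        return pairs


def _nearest_positive_definite(corr: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Eigenvalue-clipped projection onto the correlation-matrix cone."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() > floor:
        return corr
    logger.info("repairing non-PD latent correlation (min eig %.3g)", vals.min())
    vals = np.clip(vals, floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _flip_fraction(negative_edge_fraction: float) -> float:
    """Fraction f of members to sign-flip so that the fraction of
    opposite-sign within-module pairs 2f(1-f) hits the target."""
    return 0.5 * (1.0 - math.sqrt(1.0 - 2.0 * negative_edge_fraction))


def _build_regime_correlation(
    spec: RegimeSpec, n_otus: int, offset: int, regime: str, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[int, str], dict[int, str]]:
    """Assemble the full latent correlation for one regime.

    Planted blocks occupy columns [offset, offset + n_planted); all other
    OTUs stay independent. Returns (corr, sign vector, module-of-index,
    role-of-index).
    """
    corr = np.eye(n_otus)
    size = spec.module_size_mean
    blocks = [list(range(offset + m * size, offset + (m + 1) * size))
              for m in range(spec.n_modules)]
    module_of: dict[int, str] = {}
    for m, block in enumerate(blocks):
        name = f"{regime}_m{m}"
        for i in block:
            module_of[i] = name
        for i in block:
            for j in block:
                if i != j:
                    corr[i, j] = spec.intra_module_corr

    # Hub placement: network hubs and module hubs take the first slot of
    # successive modules; connectors take second slots round-robin.
    role_of: dict[int, str] = {}
    mod_cycle = list(range(spec.n_modules))
    slot = 0
    for k in range(spec.n_network_hubs):
        role_of[blocks[mod_cycle[slot % spec.n_modules]][0]] = "network_hub"
        slot += 1
    for k in range(spec.n_module_hubs):
        role_of[blocks[mod_cycle[slot % spec.n_modules]][0]] = "module_hub"
        slot += 1
    for k in range(spec.n_connectors):
        role_of[blocks[k % spec.n_modules][1]] = "connector"

    # Cross-module loadings mark hub/connector truth. They are kept mild:
    # a variable cannot be strongly correlated with several mutually
    # independent blocks (sum of squared correlations <= 1), and pushing
    # past that bound only degrades the whole matrix through PD repair.
    cross = 0.5
    for i, role in role_of.items():
        own = module_of[i]
        foreign = [b for b in blocks if module_of[b[0]] != own]
        if role == "connector":
            targets = foreign[:2]
            per_block = 2
        elif role == "network_hub":
            targets = foreign[:3]
            per_block = 2
        else:  # module_hub: strengthen within-module ties only
            for j in blocks[[module_of[b[0]] for b in blocks].index(own)]:
                if j != i:
                    corr[i, j] = corr[j, i] = min(0.98, spec.intra_module_corr + 0.04)
            continue
        for block in targets:
            for j in block[-per_block:]:
                corr[i, j] = corr[j, i] = cross

    # Plant negative associations: flip a computed fraction of members
    # per block (diag(s) @ corr @ diag(s) stays positive definite).
    sign = np.ones(n_otus)
    f = _flip_fraction(spec.negative_edge_fraction)
    for block in blocks:
        n_flip = int(round(f * len(block)))
        if n_flip:
            flip = rng.choice(
                [i for i in block if i not in role_of], size=n_flip, replace=False,
            )
            sign[flip] = -1.0
    corr = sign[:, None] * corr * sign[None, :]
    np.fill_diagonal(corr, 1.0)
    corr = _nearest_positive_definite(corr)
    return corr, sign, module_of, role_of


def generate_chronosequence(
    chaos: RegimeSpec | None = None,
    recovery: RegimeSpec | None = None,
    n_groups: int = 11,
    reps_per_group: int = 5,
    n_otus: int = 300,
    depth: int = 20000,
    seed: int = 0,
    kingdom: str = "bacteria",
    chaos_groups: tuple[str, ...] | None = None,
) -> tuple[OtuTable, SyntheticTruth]:
    """Generate one chronosequence OTU table with full planted truth.

    Defaults give 11 groups x 5 replicates = 55 samples, with the severely
    degraded control and the first three restoration ages in the chaos
    regime (20 samples) and the remaining ages plus the non-degraded
    reference in the recovery regime (35 samples).
    """
    chaos = chaos if chaos is not None else CHAOS_DEFAULT
    recovery = recovery if recovery is not None else RECOVERY_DEFAULT
    if depth <= 0:
        raise ValueError("depth must be positive")
    n_planted = chaos.n_planted + recovery.n_planted
    if n_otus < n_planted:
        raise ValueError(f"n_otus={n_otus} < planted nodes {n_planted}")

    groups = list(DEFAULT_GROUPS[:n_groups]) if n_groups <= len(DEFAULT_GROUPS) \
        else list(DEFAULT_GROUPS) + [f"x{i}y" for i in range(n_groups - len(DEFAULT_GROUPS))]
    if chaos_groups is None:
        chaos_groups = tuple(g for g in DEFAULT_CHAOS_GROUPS if g in groups)
    chaos_set = set(chaos_groups)

    rng = np.random.default_rng(seed)
    otu_ids = [f"OTU_{i + 1}" for i in range(n_otus)]

    corr_c, sign_c, mod_c, role_c = _build_regime_correlation(
        chaos, n_otus, 0, "chaos", rng)
    corr_r, sign_r, mod_r, role_r = _build_regime_correlation(
        recovery, n_otus, chaos.n_planted, "recovery", rng)
    chol = {"chaos": np.linalg.cholesky(corr_c), "recovery": np.linalg.cholesky(corr_r)}
    specs = {"chaos": chaos, "recovery": recovery}

    # Base log-abundance: planted OTUs moderately abundant so their ranks
    # survive multinomial resampling; the rest a broad lognormal background.
    mu0 = rng.normal(0.0, 1.2, size=n_otus)
    mu0[:n_planted] = rng.normal(1.0, 0.4, size=n_planted)
    # Regime axis: per-OTU shift separating the two community states.
    axis = rng.normal(0.0, 1.0, size=n_otus)

    sample_ids, counts, metadata, stage_labels = [], [], {}, {}
    for g in groups:
        regime = "chaos" if g in chaos_set else "recovery"
        spec = specs[regime]
        direction = -0.5 if regime == "chaos" else 0.5
        mean = mu0 + direction * spec.regime_centroid_shift * axis
        for rep in range(1, reps_per_group + 1):
            sid = f"{g}_r{rep}"
            z = chol[regime] @ rng.standard_normal(n_otus)
            latent = mean + z + spec.noise_sd * rng.standard_normal(n_otus)
            p = np.exp(latent - latent.max())
            p /= p.sum()
            counts.append(rng.multinomial(depth, p))
            sample_ids.append(sid)
            metadata[sid] = {"group": g, "replicate": rep, "kingdom": kingdom}
            stage_labels[sid] = regime

    modules = {otu_ids[i]: m for i, m in {**mod_c, **mod_r}.items()}
    roles = {otu_ids[i]: r for i, r in {**role_c, **role_r}.items()}
    for o in modules:
        roles.setdefault(o, "member")

    # Simple two-phylum taxonomy: planted modules alternate phyla so the
    # keystone taxonomy profile has structure to summarize.
    phyla = (["Proteobacteria", "Actinobacteria", "Acidobacteria"]
             if kingdom == "bacteria" else
             ["Ascomycota", "Basidiomycota", "Zygomycota"])
    taxonomy = {}
    for i, o in enumerate(otu_ids):
        if o in modules:
            m_idx = int(modules[o].rsplit("m", 1)[1])
            taxonomy[o] = {"kingdom": kingdom, "phylum": phyla[m_idx % len(phyla)]}
        else:
            taxonomy[o] = {"kingdom": kingdom,
                           "phylum": phyla[i % len(phyla)] if i % 4 else "Unclassified"}

    table = OtuTable(
        counts=np.asarray(counts, dtype=np.int64),
        sample_ids=sample_ids, otu_ids=otu_ids,
        taxonomy=taxonomy, metadata=metadata,
    )
    truth = SyntheticTruth(
        stage_labels=stage_labels, modules=modules, roles=roles,
        latent_corr={"chaos": corr_c, "recovery": corr_r},
        sign={"chaos": sign_c, "recovery": sign_r},
    )
    return table, truth


def planted_hub_network(
    n_modules: int = 6,
    module_size: int = 10,
    p_intra: float = 0.8,
    n_connectors: int = 4,
    n_network_hubs: int = 1,
    seed: int = 0,
):
    """Modular graph with planted keystone wiring, for topology tests.

    Modules are dense Erdos-Renyi blocks. Connector nodes attach to a few
    members of several modules (high participation, low within-module
    degree); a network hub attaches broadly to most modules. Returns
    ``(graph, membership, roles)`` where membership covers module members
    and roles mark the planted keystones. This plants the *graph* layer
    directly — correlation geometry caps how strongly one variable can
    couple to many independent modules, so realized abundance networks
    cannot carry arbitrarily dense hub wiring, but a graph can.
    """
    import networkx as nx

    rng = np.random.default_rng(seed)
    g = nx.Graph()
    membership: dict[str, int] = {}
    modules: list[list[str]] = []
    for m in range(n_modules):
        members = [f"m{m}n{i}" for i in range(module_size)]
        modules.append(members)
        for v in members:
            membership[v] = m
            g.add_node(v)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if rng.random() < p_intra:
                    g.add_edge(a, b)
    roles: dict[str, str] = {}
    for c in range(n_connectors):
        v = f"conn{c}"
        roles[v] = "connector"
        picked = rng.choice(n_modules, size=min(3, n_modules), replace=False)
        for m in picked:
            for u in rng.choice(modules[m], size=2, replace=False):
                g.add_edge(v, u)
    for h in range(n_network_hubs):
        v = f"hub{h}"
        roles[v] = "network_hub"
        for m in range(n_modules):
            for u in rng.choice(modules[m], size=3, replace=False):
                g.add_edge(v, u)
    for _, _, d in g.edges(data=True):
        d.setdefault("sign", 1)
    return g, membership, roles


def truth_report(truth: SyntheticTruth) -> pd.DataFrame:
    """Summarize planted stage sizes, module count, and hub counts."""
    stages = pd.Series(truth.stage_labels)
    module_sizes = pd.Series(truth.modules).value_counts()
    roles = pd.Series(truth.roles)
    rows = [
        ("samples_chaos", int((stages == "chaos").sum())),
        ("samples_recovery", int((stages == "recovery").sum())),
        ("n_modules", int(len(module_sizes))),
        ("mean_module_size", float(module_sizes.mean()) if len(module_sizes) else 0.0),
        ("n_network_hubs", int((roles == "network_hub").sum())),
        ("n_module_hubs", int((roles == "module_hub").sum())),
        ("n_connectors", int((roles == "connector").sum())),
    ]
    return pd.DataFrame(rows, columns=["metric", "value"])
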