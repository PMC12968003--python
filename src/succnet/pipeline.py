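"""End-to-end orchestration: table -> diversity -> stages -> RF validation
-> per-stage networks -> topology / null models -> robustness -> report.

Bacteria and fungi are processed independently end-to-end. Samples left
Ambiguous by the consensus step are excluded from every stage-conditioned
analysis. A single JSON manifest records the configuration hash, every
seed, and every output file, so a run is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, network, rf, robustness, stages, synth, topology
from .otu import OtuTable, clr_transform, filter_core_otus, relative_abundance

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, validated before any stage runs."""

    pseudocount: float = 1.0
    prevalence_min: float = 0.5
    mean_relabund_min: float = 1e-4
    rho_min: float = 0.7
    q_max: float = 0.01
    k_min: int = 2
    k_max: int = 6
    k: int | None = None              # None: modal best_k from the scan
    n_trees: int = 100
    n_folds: int = 5
    n_random: int = 100               # null-model ensemble size
    n_reps: int = 50                  # random-failure repetitions
    collapse_level: float = 0.5
    louvain_restarts: int = 10
    n_perm: int = 999
    reference_group: str = "ND"
    stage_rule: str = "topology"      # "topology" | "convergence"
    seed: int = 0

    def validate(self) -> None:
        checks = [
            (self.pseudocount > 0, "pseudocount must be positive"),
            (0 <= self.prevalence_min <= 1, "prevalence_min must be in [0,1]"),
            (0 <= self.mean_relabund_min <= 1, "mean_relabund_min must be in [0,1]"),
            (0 <= self.rho_min <= 1, "rho_min must be in [0,1]"),
            (0 < self.q_max <= 1, "q_max must be in (0,1]"),
            (2 <= self.k_min <= self.k_max, "need 2 <= k_min <= k_max"),
            (self.n_trees > 0 and self.n_folds >= 2, "n_trees/n_folds invalid"),
            (self.n_random > 1 and self.n_reps > 0, "n_random/n_reps invalid"),
            (0 < self.collapse_level < 1, "collapse_level must be in (0,1)"),
            (self.stage_rule in ("topology", "convergence"), "unknown stage_rule"),
            (self.n_perm >= 1, "n_perm must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid config: {msg}")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str) -> None:
        super().__init__(f"pipeline stage {stage!r} failed: {detail}")
        self.stage = stage


def _write_tsv(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t")
    return path.name


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _stage_network_bundle(
    table: OtuTable, sample_ids: list[str], cfg: PipelineConfig, tag: str, out: Path,
) -> dict:
    """Core filter -> correlations -> network -> topology -> robustness for
    one stage's samples. Returns the manifest fragment."""
    sub = table.select_samples(sample_ids)
    core = filter_core_otus(sub, cfg.prevalence_min, cfg.mean_relabund_min)
    result: dict = {"n_samples": len(sample_ids), "n_core_otus": core.n_otus}
    if core.n_otus < 2 or len(sample_ids) < 4:
        result["note"] = "too few core OTUs or samples; network skipped"
        return result
    pairs = network.correlation_edges(core)
    net = network.build_network(pairs, core=core, rho_min=cfg.rho_min, q_max=cfg.q_max)
    summary = network.edge_sign_summary(net)
    edges = pairs[(pairs["rho"].abs() > cfg.rho_min) & (pairs["q"] < cfg.q_max)].copy()
    edges["sign"] = np.where(edges["rho"] > 0, "+", "-")
    result["edges_tsv"] = _write_tsv(edges.reset_index(drop=True), out / f"{tag}_edges.tsv")
    result["edge_summary"] = dataclasses.asdict(summary)
    if net.number_of_edges() == 0:
        result["note"] = "no significant edges; topology skipped"
        return result

    part = topology.louvain_partition(net, seed=cfg.seed, restarts=cfg.louvain_restarts)
    metrics = topology.global_metrics(net, part)
    roles = topology.zipi_roles(net, part)
    null = topology.modularity_zscore(
        net, n_random=cfg.n_random, seed=cfg.seed,
        restarts=cfg.louvain_restarts, partition=part)
    profile = topology.keystone_taxonomy_profile(roles)
    result["global_metrics"] = dataclasses.asdict(metrics)
    result["null_model"] = {
        "q_obs": null.q_obs, "q_rand_mean": null.q_rand_mean,
        "q_rand_sd": null.q_rand_sd, "z": null.z,
        "n_random": null.n_random, "ensemble": null.ensemble.tolist(),
    }
    result["roles_tsv"] = _write_tsv(roles, out / f"{tag}_roles.tsv")
    if not profile.empty:
        result["keystone_profile_tsv"] = _write_tsv(profile, out / f"{tag}_keystone_profile.tsv")
    else:
        result["keystone_profile_note"] = "no keystone taxa identified"

    curves, thresholds = [], {}
    for strategy in robustness.STRATEGIES:
        curve = robustness.simulate_attack(
            net, strategy, roles=roles, n_reps=cfg.n_reps, seed=cfg.seed)
        curves.append(curve.to_frame())
        th = robustness.collapse_threshold(curve, cfg.collapse_level)
        thresholds[strategy] = {
            "fraction_removed_at_level": th.fraction_removed_at_level,
            "never_crossed": th.never_crossed,
        }
    result["robustness_tsv"] = _write_tsv(
        pd.concat(curves, ignore_index=True), out / f"{tag}_robustness.tsv")
    result["collapse_thresholds"] = {"level": cfg.collapse_level, **thresholds}
    return result


def run_pipeline(
    table: OtuTable,
    out_dir: str | Path,
    config: PipelineConfig | None = None,
) -> dict:
    """Run the full analysis per kingdom; returns the manifest dict."""
    cfg = config or PipelineConfig()
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    kingdoms = sorted({m.get("kingdom") or "all" for m in table.metadata.values()})
    manifest: dict = {"config": dataclasses.asdict(cfg), "config_hash": cfg.hash(),
                      "kingdoms": {}}

    for kingdom in kingdoms:
        samples = [s for s in table.sample_ids
                   if (table.metadata[s].get("kingdom") or "all") == kingdom]
        sub = table.select_samples(samples)
        km: dict = {}
        tag = kingdom

        try:
            alpha = diversity.alpha_metrics(sub)
            km["alpha_tsv"] = _write_tsv(alpha, out / f"{tag}_alpha.tsv")
            groups = sub.groups()
            kw = {}
            for metric in alpha.columns:
                res = diversity.compare_groups(alpha[metric].to_numpy(), groups.to_numpy())
                kw[metric] = {"kw_h": res.kw_statistic, "kw_p": res.kw_p,
                              "letters": res.letters}
            km["alpha_tests"] = kw
        except Exception as exc:
            raise StageError("alpha_diversity", str(exc)) from exc

        try:
            rel = relative_abundance(sub)
            bc = diversity.bray_curtis_matrix(rel)
            km["bray_curtis_tsv"] = _write_tsv(bc, out / f"{tag}_braycurtis.tsv")
            ord_res = diversity.pcoa(bc)
            km["pcoa_tsv"] = _write_tsv(ord_res.coordinates, out / f"{tag}_pcoa.tsv")
            f, p_f = diversity.permanova(bc, groups.to_numpy(), n_perm=cfg.n_perm, seed=cfg.seed)
            r, p_r = diversity.anosim(bc, groups.to_numpy(), n_perm=cfg.n_perm, seed=cfg.seed)
            km["beta_tests"] = {"permanova_f": f, "permanova_p": p_f,
                                "anosim_r": r, "anosim_p": p_r}
        except Exception as exc:
            raise StageError("beta_diversity", str(exc)) from exc

        try:
            clr = clr_transform(sub, cfg.pseudocount)
            conv = diversity.convergence_to_reference(clr, sub.metadata, cfg.reference_group)
            km["convergence_tsv"] = _write_tsv(conv.to_frame(), out / f"{tag}_convergence.tsv")
        except Exception as exc:
            raise StageError("convergence", str(exc)) from exc

        try:
            scan = stages.silhouette_scan(bc, ord_res, cfg.k_min, cfg.k_max, seed=cfg.seed)
            km["silhouette_tsv"] = _write_tsv(scan.scores, out / f"{tag}_silhouette.tsv")
            km["best_k"] = scan.best_k
            if cfg.k is not None:
                k = cfg.k
            else:
                picks = sorted(scan.best_k.values())
                k = picks[0] if picks[0] == picks[-1] else int(pd.Series(picks).mode()[0])
            assignment = stages.consensus_cluster(bc, ord_res, k=k, seed=cfg.seed)
            km["k"] = k
        except Exception as exc:
            raise StageError("stage_clustering", str(exc)) from exc

        try:
            if cfg.stage_rule == "topology":
                zscores = {}
                core_df = assignment.assignment
                for cluster in sorted(core_df.loc[
                        core_df["core_stage"] != stages.AMBIGUOUS, "core_stage"].unique()):
                    ids = list(core_df.index[core_df["core_stage"] == cluster])
                    csub = sub.select_samples(ids)
                    ccore = filter_core_otus(csub, cfg.prevalence_min, cfg.mean_relabund_min)
                    z = -np.inf
                    if ccore.n_otus >= 2 and len(ids) >= 4:
                        cnet = network.build_network(
                            network.correlation_edges(ccore), core=ccore,
                            rho_min=cfg.rho_min, q_max=cfg.q_max)
                        if cnet.number_of_edges() >= 1:
                            z = topology.modularity_zscore(
                                cnet, n_random=cfg.n_random, seed=cfg.seed,
                                restarts=cfg.louvain_restarts).z
                    zscores[cluster] = z
                if len(set(zscores.values())) < 2:
                    labeled = stages.label_stages(assignment, convergence=conv)
                else:
                    labeled = stages.label_stages(assignment, zscores=zscores)
            else:
                labeled = stages.label_stages(assignment, convergence=conv)
            km["assignment_tsv"] = _write_tsv(labeled.assignment, out / f"{tag}_stages.tsv")
            comp = stages.stage_composition(labeled, groups)
            km["stage_composition_tsv"] = _write_tsv(comp, out / f"{tag}_stage_composition.tsv")
        except Exception as exc:
            raise StageError("stage_labeling", str(exc)) from exc

        try:
            core_ids = labeled.core_samples
            core_table = sub.select_samples(core_ids)
            stage_labels = labeled.assignment.loc[core_ids, "core_stage"].to_numpy()
            report = rf.crossval_classify(core_table, stage_labels,
                                          n_trees=cfg.n_trees, n_folds=cfg.n_folds,
                                          seed=cfg.seed)
            ranking = rf.rank_biomarkers(core_table, stage_labels,
                                         n_trees=cfg.n_trees, seed=cfg.seed)
            km["rf"] = {"mean_auc": report.mean_auc, "sd_auc": report.sd_auc,
                        "fold_aucs": report.fold_aucs, "n_core": report.n_core,
                        "confusion": report.confusion.to_dict()}
            km["biomarkers_tsv"] = _write_tsv(
                ranking.top.to_frame(), out / f"{tag}_biomarkers.tsv")
        except Exception as exc:
            raise StageError("rf_validation", str(exc)) from exc

        try:
            km["networks"] = {}
            for stage_name in (stages.CHAOS, stages.RECOVERY):
                ids = list(labeled.assignment.index[
                    labeled.assignment["core_stage"] == stage_name])
                km["networks"][stage_name] = _stage_network_bundle(
                    sub, ids, cfg, f"{tag}_{stage_name.lower()}", out)
        except Exception as exc:
            raise StageError("networks", str(exc)) from exc

        manifest["kingdoms"][kingdom] = km

    manifest = _jsonify(manifest)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def run_synth_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    config: PipelineConfig | None = None,
    **synth_kwargs,
) -> dict:
    """Generate a chronosequence table and run the full pipeline on it."""
    cfg = config or PipelineConfig(seed=seed)
    table, truth = synth.generate_chronosequence(seed=seed, **synth_kwargs)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "truth.json", "w") as fh:
        json.dump(_jsonify({
            "stage_labels": truth.stage_labels,
            "modules": truth.modules,
            "roles": truth.roles,
        }), fh, indent=2, sort_keys=True)
    return run_pipeline(table, out, cfg)
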