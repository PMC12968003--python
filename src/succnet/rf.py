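"""Supervised validation of the ecological stages.

A Random Forest (100 trees) under stratified 5-fold cross-validation
quantifies how predictable the consensus stages are (per-fold ROC/AUC and
a cumulative confusion matrix over all folds), and Gini impurity-based
feature importances rank the OTUs that discriminate the stages
(biomarkers). Features default to relative abundances; a CLR flag exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .otu import OtuTable, clr_transform, relative_abundance


@dataclass
class CrossValReport:
    fold_aucs: list[float]
    mean_auc: float
    sd_auc: float
    confusion: pd.DataFrame            # cumulative 2x2 over all folds
    n_core: int
    roc_points: pd.DataFrame = field(default_factory=pd.DataFrame)
    fold_assignment: pd.Series = field(default_factory=pd.Series)


@dataclass
class BiomarkerRanking:
    importances: pd.Series  # otu_id -> importance, descending, sums to 1
    top: pd.Series          # head(top_n)


def _features(table: OtuTable, transform: str) -> np.ndarray:
    if transform == "relative":
        return relative_abundance(table).values.to_numpy()
    if transform == "clr":
        return clr_transform(table).values.to_numpy()
    raise ValueError(f"unknown feature transform: {transform!r}")


def crossval_classify(
    table: OtuTable,
    stages,
    n_trees: int = 100,
    n_folds: int = 5,
    seed: int = 0,
    transform: str = "relative",
) -> CrossValReport:
    """Stratified k-fold Random-Forest cross-validation of stage labels.

    Per-fold AUC comes from out-of-fold predicted probabilities; the
    confusion matrix thresholds those probabilities at 0.5 and accumulates
    over folds, so its total equals the number of core samples.
    """
    y = np.asarray(stages)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {list(classes)}")
    smallest = np.bincount(y_idx).min()
    if smallest < n_folds:
        raise ValueError(
            f"smallest class has {smallest} samples < {n_folds} folds; use fewer folds")
    x = _features(table, transform)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    aucs, roc_rows = [], []
    cum = np.zeros((2, 2), dtype=int)
    fold_of = np.full(len(y), -1)
    seen: set[int] = set()
    for fold, (train, test) in enumerate(skf.split(x, y_idx)):
        assert not seen.intersection(test), "cross-validation folds must be disjoint"
        seen.update(test)
        fold_of[test] = fold
        model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        model.fit(x[train], y_idx[train])
        proba = model.predict_proba(x[test])[:, 1]
        aucs.append(float(roc_auc_score(y_idx[test], proba)))
        fpr, tpr, _ = roc_curve(y_idx[test], proba)
        roc_rows.extend((fold, f, t) for f, t in zip(fpr, tpr))
        cum += confusion_matrix(y_idx[test], (proba >= 0.5).astype(int), labels=[0, 1])

    confusion = pd.DataFrame(cum, index=[f"true_{c}" for c in classes],
                             columns=[f"pred_{c}" for c in classes])
    return CrossValReport(
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        sd_auc=float(np.std(aucs)),
        confusion=confusion,
        n_core=len(y),
        roc_points=pd.DataFrame(roc_rows, columns=["fold", "fpr", "tpr"]),
        fold_assignment=pd.Series(fold_of, index=table.sample_ids, name="fold"),
    )


def rank_biomarkers(
    table: OtuTable,
    stages,
    n_trees: int = 100,
    seed: int = 0,
    top_n: int = 20,
    transform: str = "relative",
) -> BiomarkerRanking:
    """Gini-importance ranking from one forest fit on all core samples."""
    y = np.asarray(stages)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to rank biomarkers")
    x = _features(table, transform)
    model = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    model.fit(x, y)
    imp = pd.Series(model.feature_importances_, index=table.otu_ids,
                    name="gini_importance")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    imp = imp.sort_values(ascending=False, kind="stable")
    return BiomarkerRanking(importances=imp, top=imp.head(top_n))
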