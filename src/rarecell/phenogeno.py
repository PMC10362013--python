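"""Single-cell alteration classification from phenotypic features.

Predicts each rare cell's binary clonally-altered status from its channel
intensities and morphometric features: correlated features (|Pearson r|
above 0.9) are grouped and represented by their highest-variance member,
a random forest is evaluated by stratified cross-validation with pooled
out-of-fold predictions (AUC), and feature importances are attributed to
their channel by name prefix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureSelectConfig",
    "ModelEval",
    "select_features",
    "train_eval",
    "rank_importance",
]


@dataclass
class FeatureSelectConfig:
    """Correlation-based feature selection.

    Features are grouped by connected components of the |r| > threshold
    graph (Pearson correlation on z-scored features); each group is
    represented by its highest-variance member, ties broken by name.
    """

    corr_threshold: float = 0.9
    grouping: str = "components"  # or "greedy"

    def __post_init__(self) -> None:
        if not (0 < self.corr_threshold < 1):
            raise ValueError("corr_threshold must be in (0, 1)")
        if self.grouping not in ("components", "greedy"):
            raise ValueError("grouping must be 'components' or 'greedy'")


@dataclass
class ModelEval:
    cv_auc: float
    fold_aucs: list[float]
    roc: pd.DataFrame  # fpr, tpr, threshold
    importances: pd.DataFrame  # feature, channel, importance (sorted desc)
    oof_scores: np.ndarray
    model: RandomForestClassifier


def select_features(
    features: pd.DataFrame, config: FeatureSelectConfig | None = None
) -> list[str]:
    """Select one representative per correlated feature group.

    Every discarded feature is correlated above the threshold with some
    feature of its group; the selection is invariant to row and column
    order. Constant features are dropped with a warning before grouping.
    """
    config = config or FeatureSelectConfig()
    if len(features) < 2:
        raise ValueError("need at least 2 cells to estimate correlations")
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    var = X.var(axis=0, ddof=1)
    keep = var > 0
    if not keep.all():
        warnings.warn(f"dropping constant features: {[n for n, k in zip(names, keep) if not k]}")
        names = [n for n, k in zip(names, keep) if k]
        X = X[:, keep]
        var = var[keep]
    corr = np.corrcoef(X, rowvar=False)
    adj = np.abs(corr) > config.corr_threshold
    np.fill_diagonal(adj, False)
    if config.grouping == "components":
        _, labels = connected_components(csr_matrix(adj), directed=False)
    else:  # greedy: scan by descending variance, absorb correlated leftovers
        labels = np.full(len(names), -1)
        order = sorted(range(len(names)), key=lambda i: (-var[i], names[i]))
        comp = 0
        for i in order:
            if labels[i] >= 0:
                continue
            labels[i] = comp
            for j in order:
                if labels[j] < 0 and adj[i, j]:
                    labels[j] = comp
            comp += 1
    selected = []
    for comp in np.unique(labels):
        members = [i for i in range(len(names)) if labels[i] == comp]
        best = min(members, key=lambda i: (-var[i], names[i]))
        selected.append(names[best])
    return [n for n in names if n in set(selected)]


def train_eval(
    features: pd.DataFrame,
    labels: np.ndarray,
    n_folds: int = 5,
    n_trees: int = 1000,
    seed: int = 0,
) -> ModelEval:
    """Stratified cross-validated random forest with pooled-prediction AUC.

    Out-of-fold class-1 probabilities are pooled into a single ROC/AUC;
    a final forest fitted on all cells provides the importance ranking.
    Deterministic given ``seed``.
    """
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    X = features.to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    oof = np.zeros(len(y))
    fold_aucs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + fold, n_jobs=1)
        clf.fit(X[tr], y[tr])
        p = clf.predict_proba(X[te])[:, list(clf.classes_).index(1)]
        oof[te] = p
        if len(np.unique(y[te])) == 2:
            fold_aucs.append(float(roc_auc_score(y[te], p)))
    cv_auc = float(roc_auc_score(y, oof))
    fpr, tpr, thr = roc_curve(y, oof)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    full = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    full.fit(X, y)
    importances = rank_importance(full, list(features.columns))
    return ModelEval(
        cv_auc=cv_auc,
        fold_aucs=fold_aucs,
        roc=roc,
        importances=importances,
        oof_scores=oof,
        model=full,
    )


def rank_importance(
    model: RandomForestClassifier, feature_names: list[str]
) -> pd.DataFrame:
    """Impurity importances sorted descending, channel-tagged by the
    feature-name prefix before the first dot."""
    imp = model.feature_importances_
    df = pd.DataFrame(
        {
            "feature": feature_names,
            "channel": [n.split(".")[0] for n in feature_names],
            "importance": imp,
        }
    )
    return df.sort_values(
        ["importance", "feature"], ascending=[False, True]
    ).reset_index(drop=True)


def top_channel_counts(importances: pd.DataFrame, top_k: int = 20) -> dict:
    """Channel breakdown of the top-k most important features."""
    top = importances.head(top_k)
    return top["channel"].value_counts().to_dict()
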