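"""Patient-level stratification from rare-cell morphology.

The procedure: build a morphological hierarchy (Ward linkage over
z-scored morphometric vectors of all rare events), cut it at every
cluster count k in a scan range, form the sample × cluster count matrix
(cells per mL or per million), fit a seeded random forest at each k and
pick the k with the minimum out-of-bag (OOB) error, then prune by
importance ranking: refit on the top-m clusters for every m and keep the
smallest m attaining the lowest OOB error. Per-sample predictions are the
OOB votes of the final forest, so every sample is predicted out of its
own bag — the small-cohort substitute for a held-out test set.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix

from .assays import ND, SCLC, SampleMeta

__all__ = [
    "Hierarchy",
    "StratifierConfig",
    "StratifierResult",
    "morphometric_columns",
    "build_hierarchy",
    "cut_hierarchy",
    "counts_at_k",
    "scan_k",
    "prune_and_finalize",
    "run_stratifier",
]

_FEATURE_RE = re.compile(r"^(CK|Vim|CD45CD31|DAPI|EpCAM|CD45|Noise)\.")


def morphometric_columns(events: pd.DataFrame) -> list[str]:
    """Channel-prefixed morphometric feature columns of an event table."""
    return [c for c in events.columns if _FEATURE_RE.match(c)]


@dataclass
class Hierarchy:
    """Ward linkage tree over the z-scored morphometrics of all events."""

    linkage_matrix: np.ndarray
    cell_ids: np.ndarray
    sample_ids: np.ndarray
    feature_names: list[str]

    @property
    def n_events(self) -> int:
        return len(self.cell_ids)


@dataclass
class StratifierConfig:
    k_min: int = 2
    k_max: int = 100
    n_trees: int = 1000
    normalization: str = "per_ml"  # or "per_million"
    seed: int = 0
    pruning: bool = True

    def __post_init__(self) -> None:
        if not (2 <= self.k_min <= self.k_max):
            raise ValueError("need 2 <= k_min <= k_max")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.normalization not in ("per_ml", "per_million"):
            raise ValueError("normalization must be 'per_ml' or 'per_million'")


@dataclass
class StratifierResult:
    oob_error_by_k: dict
    chosen_k: int
    importances: np.ndarray  # per cluster of the chosen-k model
    pruned_cluster_set: list
    oob_error_by_m: dict
    predictions: pd.Series  # per-sample OOB predictions
    confusion: pd.DataFrame
    oob_accuracy: float


def build_hierarchy(events: pd.DataFrame, feature_cols: list[str] | None = None) -> Hierarchy:
    """Agglomerative Ward tree (Euclidean metric) over z-scored features.

    Constant features carry no morphology and are dropped with a warning;
    fewer than two events cannot form a tree.
    """
    if feature_cols is None:
        feature_cols = morphometric_columns(events)
    if len(events) < 2:
        raise ValueError("need at least 2 events to build a hierarchy")
    X = events[feature_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        dropped = [c for c, k in zip(feature_cols, keep) if not k]
        warnings.warn(f"dropping constant features: {dropped}")
        feature_cols = [c for c, k in zip(feature_cols, keep) if k]
        X = X[:, keep]
        sd = sd[keep]
    if X.shape[1] == 0:
        raise ValueError("no non-constant features")
    Z = (X - X.mean(axis=0)) / sd
    lm = linkage(Z, method="ward")
    return Hierarchy(
        linkage_matrix=lm,
        cell_ids=events["cell_id"].to_numpy(),
        sample_ids=events["sample_id"].to_numpy(),
        feature_names=feature_cols,
    )


def cut_hierarchy(hierarchy: Hierarchy, k: int) -> np.ndarray:
    """Cluster labels (1..k) from cutting the tree into k clusters."""
    if not (2 <= k <= hierarchy.n_events):
        raise ValueError("k must be in [2, n_events]")
    return fcluster(hierarchy.linkage_matrix, t=k, criterion="maxclust")


def counts_at_k(
    hierarchy: Hierarchy,
    k: int,
    meta: list[SampleMeta],
    normalization: str = "per_ml",
) -> pd.DataFrame:
    """Sample × cluster matrix of normalized event counts at cluster count k.

    Rows cover every sample in ``meta`` (zero-filled); entry (s, c) is the
    count of sample s's events in cluster c divided by the sample's volume
    (per_ml) or scaled to events per million nucleated cells imaged.
    """
    labels = cut_hierarchy(hierarchy, k)
    df = pd.DataFrame({"sample_id": hierarchy.sample_ids, "cluster": labels})
    mat = pd.crosstab(df["sample_id"], df["cluster"])
    mat = mat.reindex(
        index=[m.sample_id for m in meta],
        columns=range(1, int(labels.max()) + 1),
        fill_value=0,
    ).astype(float)
    for m in meta:
        if normalization == "per_ml":
            mat.loc[m.sample_id] /= m.volume_ml
        else:
            if m.nucleated_cells <= 0:
                raise ValueError(f"sample {m.sample_id} has no nucleated-cell total")
            mat.loc[m.sample_id] *= 1e6 / m.nucleated_cells
    return mat


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, seed: int) -> RandomForestClassifier:
    clf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, random_state=seed, n_jobs=1
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rare: a sample with no OOB trees
        clf.fit(X, y)
    return clf


def scan_k(
    hierarchy: Hierarchy,
    meta: list[SampleMeta],
    labels: pd.Series,
    config: StratifierConfig,
) -> tuple[dict, int]:
    """OOB error of a seeded forest at every cluster count in the scan.

    Returns (oob_error_by_k, chosen_k) where chosen_k attains the minimum
    OOB error, ties resolved toward the smallest k.
    """
    y = labels.reindex([m.sample_id for m in meta]).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    k_hi = min(config.k_max, hierarchy.n_events)
    errors: dict[int, float] = {}
    for k in range(config.k_min, k_hi + 1):
        mat = counts_at_k(hierarchy, k, meta, config.normalization)
        clf = _fit_forest(mat.to_numpy(), y, config.n_trees, config.seed)
        errors[k] = 1.0 - float(clf.oob_score_)
    chosen_k = min(errors, key=lambda k: (errors[k], k))
    return errors, chosen_k


def prune_and_finalize(
    matrix: pd.DataFrame,
    labels: pd.Series,
    importances: np.ndarray,
    config: StratifierConfig,
) -> tuple[list, dict, RandomForestClassifier]:
    """Importance-ranked incremental pruning of the chosen-k count matrix.

    For m = 2..k, refit a forest on the m most important clusters and
    record its OOB error; keep the smallest m with the lowest error (the
    full model when pruning is disabled). Returns (pruned cluster set,
    oob_error_by_m, final fitted forest).
    """
    y = labels.reindex(matrix.index).to_numpy()
    order = np.lexsort((np.arange(len(importances)), -importances))
    cols = list(matrix.columns)
    errors_m: dict[int, float] = {}
    if not config.pruning:
        clf = _fit_forest(matrix.to_numpy(), y, config.n_trees, config.seed)
        errors_m[len(cols)] = 1.0 - float(clf.oob_score_)
        return cols, errors_m, clf
    best_m, best_err, best_clf = None, np.inf, None
    for m in range(2, len(cols) + 1):
        top = [cols[i] for i in order[:m]]
        clf = _fit_forest(matrix[top].to_numpy(), y, config.n_trees, config.seed)
        err = 1.0 - float(clf.oob_score_)
        errors_m[m] = err
        if err < best_err - 1e-12:
            best_m, best_err, best_clf = m, err, clf
    pruned = [cols[i] for i in order[:best_m]]
    return pruned, errors_m, best_clf


def run_stratifier(
    events: pd.DataFrame,
    meta: list[SampleMeta],
    config: StratifierConfig | None = None,
    labels: pd.Series | None = None,
) -> StratifierResult:
    """Full patient-level stratification pipeline.

    ``labels`` defaults to each sample's cohort from ``meta``. The result
    carries the OOB error curves of both selection stages, the chosen
    cluster count, the pruned cluster set and per-sample OOB predictions
    with their confusion matrix (rows = true class, columns = predicted).
    """
    config = config or StratifierConfig()
    if labels is None:
        labels = pd.Series({m.sample_id: m.cohort for m in meta})
    hierarchy = build_hierarchy(events)
    errors_k, chosen_k = scan_k(hierarchy, meta, labels, config)
    matrix = counts_at_k(hierarchy, chosen_k, meta, config.normalization)
    y = labels.reindex(matrix.index).to_numpy()
    chosen_clf = _fit_forest(matrix.to_numpy(), y, config.n_trees, config.seed)
    importances = chosen_clf.feature_importances_
    pruned, errors_m, final_clf = prune_and_finalize(matrix, labels, importances, config)
    oob_votes = final_clf.oob_decision_function_
    classes = final_clf.classes_
    pred = classes[np.nanargmax(oob_votes, axis=1)]
    predictions = pd.Series(pred, index=matrix.index, name="oob_prediction")
    class_order = [c for c in (ND, SCLC) if c in set(y)] or sorted(set(y))
    cm = confusion_matrix(y, pred, labels=class_order)
    confusion = pd.DataFrame(cm, index=class_order, columns=class_order)
    accuracy = float((pred == y).mean())
    return StratifierResult(
        oob_error_by_k=errors_k,
        chosen_k=chosen_k,
        importances=importances,
        pruned_cluster_set=pruned,
        oob_error_by_m=errors_m,
        predictions=predictions,
        confusion=confusion,
        oob_accuracy=accuracy,
    )
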