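"""Channel-based gating, group enumeration and cohort comparison.

Each DAPI-positive rare cell is assigned to one of eight channel-based
groups by thresholding its marker intensities; group counts are reported
per mL of blood-equivalent volume, per million nucleated cells imaged,
and as within-sample proportions; cohorts are compared per group with the
two-sided Mann-Whitney U test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .assays import ASSAY_MARKERS, ND, SCLC, SampleMeta, assay_groups, group_name

__all__ = [
    "GateConfig",
    "DEFAULT_STATIC_GATES",
    "fit_gates",
    "classify_events",
    "enumerate_groups",
    "mann_whitney",
    "compare_cohorts",
    "significance_stars",
]

#: default static positivity thresholds (fluorescence units); sits five
#: scaled-MADs above the nominal background of the synthetic generator
DEFAULT_STATIC_GATES = {
    "dapi": 100.0,
    "ck": 100.0,
    "vim": 100.0,
    "cd45cd31": 100.0,
    "epcam": 100.0,
    "cd45": 100.0,
}

_MAD_SCALE = 1.4826  # consistency factor to the normal SD


@dataclass
class GateConfig:
    """Per-channel positivity thresholds.

    ``thresholds`` are global (static) thresholds; ``per_slide`` optionally
    overrides them per slide, as fitted from each slide's background
    population.
    """

    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_STATIC_GATES))
    per_slide: dict | None = None
    method: str = "static"
    k: float = 5.0

    def threshold(self, marker: str, slide_id: str | None = None) -> float:
        if self.per_slide and slide_id in self.per_slide:
            t = self.per_slide[slide_id].get(marker)
            if t is not None:
                return t
        return self.thresholds[marker]


def fit_gates(
    events: pd.DataFrame | None = None,
    method: str = "static",
    k: float = 5.0,
    static: dict | None = None,
    markers: list[str] | None = None,
) -> GateConfig:
    """Build a gate configuration.

    ``static`` passes user thresholds through unchanged. ``k_sigma`` sets,
    per slide and per marker, threshold = median + k * scaled-MAD of the
    intensity of a background (common-cell) population.
    """
    if method == "static":
        thresholds = dict(DEFAULT_STATIC_GATES)
        if static:
            thresholds.update(static)
        return GateConfig(thresholds=thresholds, method="static", k=k)
    if method != "k_sigma":
        raise ValueError("method must be 'static' or 'k_sigma'")
    if not (k > 0):
        raise ValueError("k must be > 0")
    if events is None or len(events) == 0:
        raise ValueError("k_sigma gating needs a non-empty background table")
    if markers is None:
        markers = [c for c in DEFAULT_STATIC_GATES if c in events.columns]
    per_slide: dict = {}
    for slide_id, sub in events.groupby("slide_id"):
        per_slide[slide_id] = {}
        for m in markers:
            x = sub[m].to_numpy(dtype=float)
            med = float(np.median(x))
            mad = float(np.median(np.abs(x - med)))
            per_slide[slide_id][m] = med + k * _MAD_SCALE * mad
    # fallback thresholds: pooled over slides
    pooled = {
        m: float(
            np.median(events[m]) + k * _MAD_SCALE * np.median(np.abs(events[m] - np.median(events[m])))
        )
        for m in markers
    }
    thresholds = dict(DEFAULT_STATIC_GATES)
    thresholds.update(pooled)
    return GateConfig(thresholds=thresholds, per_slide=per_slide, method="k_sigma", k=k)


def classify_events(
    events: pd.DataFrame, gates: GateConfig | None = None, assay: str = "landscape"
) -> pd.DataFrame:
    """Assign each event to a channel group.

    A marker is positive iff its intensity is strictly above its gate.
    Events whose DAPI intensity is not above the DAPI gate are not
    nucleated cells: they are flagged ``rejected`` and carry no group.

    Returns a DataFrame (cell_id, sample_id, slide_id, group, rejected).
    """
    gates = gates or fit_gates(method="static")
    markers = ASSAY_MARKERS[assay]
    required = ["dapi"] + [c for c, _ in markers]
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise ValueError(f"events table lacks channel columns: {missing}")
    slide = events["slide_id"] if "slide_id" in events.columns else pd.Series([None] * len(events))

    def thr(marker):
        return np.array([gates.threshold(marker, s) for s in slide])

    dapi_pos = events["dapi"].to_numpy(dtype=float) > thr("dapi")
    pos = {c: events[c].to_numpy(dtype=float) > thr(c) for c, _ in markers}
    names = []
    for i in range(len(events)):
        combo = tuple(pos[c][i] for c, _ in markers)
        names.append(group_name(assay, combo) if dapi_pos[i] else None)
    out = pd.DataFrame(
        {
            "cell_id": events["cell_id"].to_numpy(),
            "sample_id": events["sample_id"].to_numpy(),
            "slide_id": slide.to_numpy(),
            "group": names,
            "rejected": ~dapi_pos,
        }
    )
    return out


def enumerate_groups(
    calls: pd.DataFrame, meta: list[SampleMeta], assay: str = "landscape"
) -> pd.DataFrame:
    """Per-(sample, group) enumeration table.

    Columns: count, cells_per_ml (count / volume), cells_per_million
    (relative to nucleated cells imaged) and the within-sample proportion
    of classified rare events. Every sample × group combination appears,
    zero-filled. Rejected events are excluded.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    missing = set(calls["sample_id"]) - set(meta_by_id)
    if missing:
        raise ValueError(f"calls reference unknown samples: {sorted(missing)}")
    for m in meta:
        if not (m.volume_ml and m.volume_ml > 0):
            raise ValueError(f"sample {m.sample_id} has no valid volume")
    groups = assay_groups(assay)
    ok = calls[~calls["rejected"]]
    counts = (
        ok.groupby(["sample_id", "group"], sort=False).size().rename("count").reset_index()
    )
    full = pd.MultiIndex.from_product(
        [[m.sample_id for m in meta], groups], names=["sample_id", "group"]
    )
    table = (
        counts.set_index(["sample_id", "group"]).reindex(full, fill_value=0).reset_index()
    )
    vol = table["sample_id"].map(lambda s: meta_by_id[s].volume_ml)
    nuc = table["sample_id"].map(lambda s: meta_by_id[s].nucleated_cells)
    totals = table.groupby("sample_id")["count"].transform("sum")
    table["cells_per_ml"] = table["count"] / vol
    with np.errstate(divide="ignore", invalid="ignore"):
        table["cells_per_million"] = np.where(
            nuc > 0, table["count"] / nuc * 1e6, np.nan
        )
        table["proportion"] = np.where(totals > 0, table["count"] / totals, 0.0)
    table["cohort"] = table["sample_id"].map(lambda s: meta_by_id[s].cohort)
    return table


# ---------------------------------------------------------------------------
# cohort comparison


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Uses exact null enumeration when there are no ties and n1*n2 <= 10,000;
    otherwise the tie-corrected normal approximation with continuity
    correction. Returns (U of the first sample, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return x.size * y.size / 2.0, 1.0
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (not ties and x.size * y.size <= 10_000) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def significance_stars(p: float) -> str:
    if p <= 0.0001:
        return "****"
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_cohorts(
    enumeration: pd.DataFrame,
    value: str = "cells_per_ml",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Per-group two-sided Mann-Whitney U between the SCLC and ND cohorts.

    ``adjust='bh'`` adds Benjamini-Hochberg adjusted p-values (off by
    default; significance is reported on raw p at the usual star levels).
    """
    for cohort in (SCLC, ND):
        if not (enumeration["cohort"] == cohort).any():
            raise ValueError(f"cohort {cohort} is empty")
    rows = []
    for group, sub in enumeration.groupby("group", sort=False):
        x = sub.loc[sub["cohort"] == SCLC, value].to_numpy()
        y = sub.loc[sub["cohort"] == ND, value].to_numpy()
        u, p = mann_whitney(x, y)
        rows.append(
            {
                "group": group,
                "n_sclc": x.size,
                "n_nd": y.size,
                "mean_sclc": float(x.mean()),
                "mean_nd": float(y.mean()),
                "U": u,
                "p": p,
                "stars": significance_stars(p),
            }
        )
    out = pd.DataFrame(rows)
    if adjust == "bh":
        out["p_adj"] = stats.false_discovery_control(out["p"], method="bh")
    return out
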