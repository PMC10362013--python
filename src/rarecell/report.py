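"""Cohort-level summary reporting.

Aggregates the enumeration table, clonality calls and stratifier result
into one machine-readable summary: per-cohort group means and ranges, the
fraction of patients whose CK-only CTCs exceed half of their rare cells,
clonal fractions per channel group, and the stratifier confusion matrix.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .assays import ND, SCLC

__all__ = ["round_half_up", "ck_majority_fraction", "clonal_fractions", "summarize_cohort"]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal half-up rounding (printed-precision convention)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def ck_majority_fraction(enumeration: pd.DataFrame, cohort: str = SCLC) -> dict:
    """Fraction of a cohort's patients whose CK-only group exceeds 50% of
    their rare events; percentage rounded half-up to a whole percent."""
    sub = enumeration[(enumeration["cohort"] == cohort) & (enumeration["group"] == "CK")]
    n = len(sub)
    if n == 0:
        return {"n_patients": 0, "n_majority": 0, "pct": None}
    n_major = int((sub["proportion"] > 0.5).sum())
    return {
        "n_patients": n,
        "n_majority": n_major,
        "pct": round_half_up(100.0 * n_major / n),
    }


def clonal_fractions(truth_or_calls: pd.DataFrame) -> dict:
    """Per channel group: clonal cells / sequenced cells, as a
    whole-percent fraction. Accepts any table with 'group' and 'clonal'
    columns (truth labels or merged clonality calls)."""
    out = {}
    for group, sub in truth_or_calls.groupby("group", sort=False):
        n = len(sub)
        k = int(sub["clonal"].sum())
        out[group] = {
            "n_cells": n,
            "n_clonal": k,
            "pct": round_half_up(100.0 * k / n) if n else None,
        }
    return out


def summarize_cohort(
    enumeration: pd.DataFrame | None = None,
    clonality: pd.DataFrame | None = None,
    stratifier_result=None,
) -> dict:
    """Assemble the cohort report from whichever stages ran."""
    report: dict = {}
    if enumeration is not None and len(enumeration):
        per_cohort = {}
        for cohort in (SCLC, ND):
            sub = enumeration[enumeration["cohort"] == cohort]
            if not len(sub):
                continue
            stats = (
                sub.groupby("group", sort=False)["cells_per_ml"]
                .agg(["mean", "min", "max"])
                .round(2)
            )
            per_cohort[cohort] = {
                g: {"mean": r["mean"], "min": r["min"], "max": r["max"]}
                for g, r in stats.iterrows()
            }
        report["groups_cells_per_ml"] = per_cohort
        report["ck_majority"] = ck_majority_fraction(enumeration)
        totals = enumeration.groupby(["cohort", "sample_id"])["cells_per_ml"].sum()
        report["total_rare_cells_per_ml_mean"] = {
            cohort: round(float(totals[cohort].mean()), 2)
            for cohort in totals.index.get_level_values(0).unique()
        }
    if clonality is not None and len(clonality):
        report["clonal_fractions"] = clonal_fractions(clonality)
    if stratifier_result is not None:
        report["stratifier"] = {
            "chosen_k": stratifier_result.chosen_k,
            "n_pruned_clusters": len(stratifier_result.pruned_cluster_set),
            "oob_accuracy": stratifier_result.oob_accuracy,
            "confusion": {
                str(i): row.to_dict()
                for i, row in stratifier_result.confusion.iterrows()
            },
        }
    return report
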