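"""File formats: event tables, bin counts, SEG, BED, YAML config, JSON report.

Events travel as CSV or Parquet (by extension); genomic bin counts as TSV
with 0-based half-open coordinates; copy-number segments as SEG (1-based
inclusive, log2 mean); alterations as BED. All writers round-trip through
their readers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assays import SampleMeta

__all__ = [
    "ParseError",
    "RunConfig",
    "read_events",
    "write_events",
    "read_bin_counts",
    "write_bin_counts",
    "write_seg",
    "read_seg",
    "write_alterations_bed",
    "read_meta",
    "write_meta",
    "load_config",
    "write_report",
]


class ParseError(ValueError):
    """A file violated its declared schema; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


# ---------------------------------------------------------------------------
# events and metadata


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".parquet":
        events.to_parquet(path, index=False)
    else:
        events.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    required = {"cell_id", "sample_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"events table missing columns {sorted(missing)}")
    return df


def write_meta(meta: list[SampleMeta], path: str | Path) -> None:
    rows = []
    for m in meta:
        rows.append(
            {
                "sample_id": m.sample_id,
                "cohort": m.cohort,
                "volume_ml": m.volume_ml,
                "slide_ids": ";".join(m.slide_ids),
                "nucleated_cells": m.nucleated_cells,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_meta(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    metas = []
    for _, r in df.iterrows():
        metas.append(
            SampleMeta(
                sample_id=str(r["sample_id"]),
                cohort=str(r["cohort"]),
                volume_ml=float(r["volume_ml"]),
                slide_ids=tuple(str(r.get("slide_ids", "")).split(";")) if r.get("slide_ids") else (),
                nucleated_cells=int(r.get("nucleated_cells", 0)),
            )
        )
    return metas


# ---------------------------------------------------------------------------
# bin counts (TSV, 0-based half-open)

_BIN_COLS = ["cell_id", "chrom", "start", "end", "count"]


def write_bin_counts(bin_counts: pd.DataFrame, path: str | Path) -> None:
    bin_counts[_BIN_COLS].to_csv(path, sep="\t", index=False)


def read_bin_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(_BIN_COLS) - set(df.columns)
    if missing:
        raise ParseError(f"bin-count table missing columns {sorted(missing)}")
    bad = df.index[(df["end"] <= df["start"]) | (df["count"] < 0)]
    if len(bad):
        # +2: one for the header, one for 1-based line numbering
        raise ParseError("invalid bin (end <= start or negative count)", line=int(bad[0]) + 2)
    return df


# ---------------------------------------------------------------------------
# SEG (1-based inclusive, log2 segment mean)

_SEG_FLOOR = 2.0**-10  # ratio floor so homozygous losses stay finite in log2


def write_seg(
    segments: pd.DataFrame, cell_id: str, grid: pd.DataFrame, path: str | Path
) -> None:
    """Write one cell's segments as SEG.

    ``segments`` uses within-chromosome inclusive bin indices;
    ``grid`` (chrom, start, end) supplies the bin → bp mapping.
    """
    rows = []
    for _, s in segments.iterrows():
        sub = grid[grid["chrom"] == s["chrom"]].reset_index(drop=True)
        rows.append(
            {
                "ID": cell_id,
                "chrom": s["chrom"],
                "loc.start": int(sub.loc[int(s["start_bin"]), "start"]) + 1,
                "loc.end": int(sub.loc[int(s["end_bin"]), "end"]),
                "num.mark": int(s["n_bins"]),
                "seg.mean": float(np.log2(max(s["mean_ratio"], _SEG_FLOOR))),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_seg(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"SEG file missing columns {sorted(missing)}")
    df["mean_ratio"] = 2.0 ** df["seg.mean"]
    return df


def write_alterations_bed(
    alterations: list, grid: pd.DataFrame, path: str | Path
) -> None:
    """Alterations as BED: name = direction, score = integer copy number."""
    lines = []
    for a in alterations:
        sub = grid[grid["chrom"] == a.chrom].reset_index(drop=True)
        start = int(sub.loc[a.start_bin, "start"])
        end = int(sub.loc[a.end_bin, "end"])
        lines.append(f"{a.chrom}\t{start}\t{end}\t{a.direction}\t{a.cn}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# configuration and reports

_CONFIG_KEYS = {
    "seed": int,
    "paths": dict,
    "cohort": dict,
    "gates": dict,
    "stratifier": dict,
    "cna": dict,
    "model": dict,
}


@dataclass
class RunConfig:
    seed: int = 0
    paths: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    gates: dict = field(default_factory=dict)
    stratifier: dict = field(default_factory=dict)
    cna: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)

    @property
    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_CONFIG_KEYS)
    if unknown:
        raise ParseError(f"unknown config keys: {sorted(unknown)}")
    for key, typ in _CONFIG_KEYS.items():
        if key in raw and not isinstance(raw[key], typ):
            raise ParseError(f"config key {key!r} must be a {typ.__name__}")
    return RunConfig(**raw)


def write_report(report: dict, config: RunConfig | None, path: str | Path) -> None:
    """JSON report stamped with the seed and config hash."""
    out = dict(report)
    if config is not None:
        out["_config_hash"] = config.digest
        out["_seed"] = config.seed
    Path(path).write_text(json.dumps(out, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")
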