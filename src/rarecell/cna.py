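"""Single-cell copy-number analysis from genomic bin read counts.

A cell's profile is reconstructed from the frequency of unique reads per
genomic bin: counts are mean-normalized to ratios, segmented chromosome by
chromosome with a CBS-style recursive binary-splitting procedure, scaled to
integer copy numbers by a ploidy grid search, and reduced to a list of
gain/loss alterations. Per-cell quality control uses total reads, alignment
rate, a 1/MAPD quality score and genome-wide bin coverage. Clonality within
a sample is called when more than two cells share at least three concordant
alterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "Alteration",
    "CNProfile",
    "QCThresholds",
    "QCResult",
    "ClonalityRule",
    "ClonalCall",
    "normalize",
    "quality_score",
    "segment",
    "call_integers",
    "qc",
    "extract_alterations",
    "call_clonality",
]

#: quality score reported for a profile with zero adjacent-bin noise
QS_SENTINEL = 1e9


@dataclass(frozen=True)
class Alteration:
    """A maximal run of bins at a non-diploid integer copy number."""

    chrom: str
    start_bin: int  # within-chromosome bin index, inclusive
    end_bin: int  # inclusive
    cn: int

    def __post_init__(self) -> None:
        if self.end_bin < self.start_bin:
            raise ValueError("end_bin < start_bin")
        if not (0 <= self.cn <= 20):
            raise ValueError("cn out of range")

    @property
    def direction(self) -> str:
        if self.cn > 2:
            return "gain"
        if self.cn < 2:
            return "loss"
        return "neutral"

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin + 1


@dataclass
class QCThresholds:
    """Cell-level inclusion thresholds.

    Defaults: total reads above 50,000, alignment rate above 50%, quality
    score at least 2.5 (inclusive) and nonzero counts in at least 95% of
    bins (a proxy for reads across the whole genome, i.e. no
    apoptosis-induced dropout).
    """

    min_reads: int = 50_000
    min_alignment: float = 0.5
    min_qs: float = 2.5
    min_nonzero_bin_fraction: float = 0.95


@dataclass
class QCResult:
    cell_id: str
    total_reads: int
    alignment_rate: float
    quality_score: float
    nonzero_bin_fraction: float
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)


@dataclass
class CNProfile:
    """Per-cell copy-number profile.

    ``segments`` is a DataFrame with columns (chrom, start_bin, end_bin,
    n_bins, mean_ratio, cn); bin indices are within-chromosome and
    inclusive, and the segments partition each chromosome's bin range.
    """

    cell_id: str
    chroms: np.ndarray  # per-bin chromosome label
    ratios: np.ndarray  # per-bin mean-normalized ratio
    segments: pd.DataFrame
    ploidy: float | None = None
    qc: QCResult | None = None


@dataclass
class ClonalityRule:
    """Clonality: a group of more than two cells from one sample, each pair
    sharing at least three alterations in concordance (same direction,
    reciprocal overlap of at least ``reciprocal_overlap``)."""

    min_group_size: int = 3
    min_shared_alterations: int = 3
    reciprocal_overlap: float = 0.5
    #: "pairwise": concordance edges + connected components (default).
    #: "intersection": additionally require >= min_shared alterations
    #: matched in *every* member of the group.
    semantics: str = "pairwise"

    def __post_init__(self) -> None:
        if self.min_group_size < 3:
            raise ValueError("min_group_size must be >= 3 (more than two cells)")
        if self.min_shared_alterations < 1:
            raise ValueError("min_shared_alterations must be >= 1")
        if not (0 < self.reciprocal_overlap <= 1):
            raise ValueError("reciprocal_overlap must be in (0, 1]")
        if self.semantics not in ("pairwise", "intersection"):
            raise ValueError("semantics must be 'pairwise' or 'intersection'")


@dataclass
class ClonalCall:
    """Per-sample clonality result: per-cell flags and the clonal groups."""

    sample_id: str
    cells: pd.DataFrame  # columns: cell_id, clonal, group_id
    groups: list[list[str]]

    @property
    def clonal_cell_ids(self) -> set[str]:
        return set(self.cells.loc[self.cells["clonal"], "cell_id"])


# ---------------------------------------------------------------------------
# normalization and per-cell noise


def normalize(counts: np.ndarray) -> np.ndarray:
    """Mean-normalize bin counts to copy-number ratios (mean ratio = 1)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-D array")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and non-negative")
    mean = counts.mean()
    if mean == 0:
        raise ValueError("all bin counts are zero")
    return counts / mean


def quality_score(ratios: np.ndarray, chroms: np.ndarray | None = None) -> float:
    """Quality score QS = 1 / MAPD.

    MAPD is the median absolute difference between adjacent bin ratios,
    taken within chromosomes only. A score of 2.5 corresponds to
    MAPD = 0.4; noiseless profiles return a large sentinel.
    """
    ratios = np.asarray(ratios, dtype=float)
    if chroms is None:
        chroms = np.zeros(ratios.size)
    chroms = np.asarray(chroms)
    diffs = np.abs(np.diff(ratios))
    same = chroms[1:] == chroms[:-1]
    diffs = diffs[same]
    if diffs.size == 0:
        raise ValueError("need at least 2 bins on some chromosome")
    mapd = float(np.median(diffs))
    if mapd == 0:
        return QS_SENTINEL
    return 1.0 / mapd


# ---------------------------------------------------------------------------
# segmentation


def _tstat_profile(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best binary split of ``x``: returns (split index, |t| statistic).

    The split at index i separates x[:i] from x[i:]; both sides must have
    at least ``min_bins`` bins. Welch-free pooled-variance t statistic;
    zero pooled variance with differing means yields +inf.
    """
    n = x.size
    if n < 2 * min_bins:
        return -1, 0.0
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    total, total_sq = csum[-1], csq[-1]
    idx = np.arange(min_bins, n - min_bins + 1)
    n1 = idx.astype(float)
    n2 = n - n1
    s1 = csum[idx - 1]
    m1 = s1 / n1
    m2 = (total - s1) / n2
    ss1 = csq[idx - 1] - n1 * m1**2
    ss2 = (total_sq - csq[idx - 1]) - n2 * m2**2
    pooled = (ss1 + ss2) / np.maximum(n - 2, 1)
    se = np.sqrt(np.maximum(pooled, 0.0) * (1.0 / n1 + 1.0 / n2))
    diff = np.abs(m1 - m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(diff == 0, 0.0, np.where(se == 0, np.inf, diff / se))
    best = int(np.argmax(t))
    return int(idx[best]), float(t[best])


#: splits with a mean gap below this are floating-point jitter, not CNAs
_MIN_SPLIT_GAP = 1e-6


def _segment_one_chrom(
    x: np.ndarray,
    alpha: float,
    min_seg_bins: int,
    n_perm: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Recursive binary segmentation of one chromosome; returns
    (start, end) inclusive bin-index pairs."""
    segments: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:  # hi exclusive
        seg = x[lo:hi]
        split, tmax = _tstat_profile(seg, min_seg_bins)
        gap = abs(seg[:split].mean() - seg[split:].mean()) if split > 0 else 0.0
        if split < 0 or tmax == 0.0 or gap < _MIN_SPLIT_GAP:
            segments.append((lo, hi - 1))
            return
        if np.isinf(tmax):
            p = 0.0
        else:
            perm = seg.copy()
            exceed = 0
            for _ in range(n_perm):
                rng.shuffle(perm)
                _, tp = _tstat_profile(perm, min_seg_bins)
                if tp >= tmax:
                    exceed += 1
            p = exceed / n_perm
        if p < alpha:
            recurse(lo, lo + split)
            recurse(lo + split, hi)
        else:
            segments.append((lo, hi - 1))

    recurse(0, x.size)
    return segments


def segment(
    ratios: np.ndarray,
    chroms: np.ndarray,
    alpha: float = 0.01,
    min_seg_bins: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Segment per-bin ratios chromosome by chromosome.

    Recursively splits at the index maximizing the two-sample t statistic
    whenever its permutation p-value is below ``alpha`` and both sides
    retain at least ``min_seg_bins`` bins. Deterministic given ``seed``.

    Returns a DataFrame (chrom, start_bin, end_bin, n_bins, mean_ratio)
    with within-chromosome inclusive bin indices.
    """
    ratios = np.asarray(ratios, dtype=float)
    chroms = np.asarray(chroms)
    if ratios.size != chroms.size:
        raise ValueError("ratios and chroms must have equal length")
    rng = np.random.default_rng(seed)
    rows = []
    # preserve input chromosome order
    seen: list = []
    for c in chroms:
        if c not in seen:
            seen.append(c)
    for c in seen:
        x = ratios[chroms == c]
        for lo, hi in _segment_one_chrom(x, alpha, min_seg_bins, n_perm, rng):
            rows.append(
                {
                    "chrom": c,
                    "start_bin": lo,
                    "end_bin": hi,
                    "n_bins": hi - lo + 1,
                    "mean_ratio": float(x[lo : hi + 1].mean()),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# integer copy-number calling


def call_integers(
    segments: pd.DataFrame,
    ploidy_min: float = 1.5,
    ploidy_max: float = 5.0,
    ploidy_step: float = 0.05,
) -> tuple[pd.DataFrame, float]:
    """Scale segment ratios to integer copy numbers by a ploidy grid search.

    The ploidy P minimizes the length-weighted squared distance of
    ratio*P from the nearest integers; ties go to the P closest to 2
    (diploid). Returns (segments with a ``cn`` column, chosen ploidy).
    """
    if len(segments) == 0:
        raise ValueError("segments must be non-empty")
    ratios = segments["mean_ratio"].to_numpy(dtype=float)
    lengths = segments["n_bins"].to_numpy(dtype=float)
    grid = np.arange(ploidy_min, ploidy_max + 1e-9, ploidy_step)
    scaled = ratios[:, None] * grid[None, :]
    err = (lengths[:, None] * (scaled - np.round(scaled)) ** 2).sum(axis=0)
    best = err.min()
    candidates = grid[np.isclose(err, best, atol=1e-9)]
    ploidy = float(candidates[np.argmin(np.abs(candidates - 2.0))])
    out = segments.copy()
    out["cn"] = np.round(ratios * ploidy).astype(int)
    out.loc[out["cn"] < 0, "cn"] = 0
    return out, ploidy


def profile_from_counts(
    cell_id: str,
    counts: np.ndarray,
    chroms: np.ndarray,
    alpha: float = 0.01,
    min_seg_bins: int = 5,
    n_perm: int = 1000,
    seed: int = 0,
) -> CNProfile:
    """Convenience: normalize → segment → integer-call one cell."""
    ratios = normalize(counts)
    segs = segment(ratios, chroms, alpha, min_seg_bins, n_perm, seed)
    segs, ploidy = call_integers(segs)
    return CNProfile(
        cell_id=cell_id,
        chroms=np.asarray(chroms),
        ratios=ratios,
        segments=segs,
        ploidy=ploidy,
    )


# ---------------------------------------------------------------------------
# quality control


def qc(
    profile: CNProfile,
    total_reads: int,
    alignment_rate: float,
    counts: np.ndarray | None = None,
    thresholds: QCThresholds | None = None,
) -> QCResult:
    """Apply cell-level inclusion criteria; returns the result and attaches
    it to the profile. The quality-score criterion is inclusive (>= 2.5)."""
    thresholds = thresholds or QCThresholds()
    if total_reads is None or alignment_rate is None:
        raise ValueError("total_reads and alignment_rate metadata required")
    qs = quality_score(profile.ratios, profile.chroms)
    if counts is not None:
        counts = np.asarray(counts, dtype=float)
        nonzero = float((counts > 0).mean())
    else:
        nonzero = float((profile.ratios > 0).mean())
    failed = []
    if not total_reads > thresholds.min_reads:
        failed.append("total_reads")
    if not alignment_rate > thresholds.min_alignment:
        failed.append("alignment_rate")
    if not qs >= thresholds.min_qs:
        failed.append("quality_score")
    if not nonzero >= thresholds.min_nonzero_bin_fraction:
        failed.append("nonzero_bin_fraction")
    result = QCResult(
        cell_id=profile.cell_id,
        total_reads=int(total_reads),
        alignment_rate=float(alignment_rate),
        quality_score=qs,
        nonzero_bin_fraction=nonzero,
        passed=not failed,
        failed_criteria=failed,
    )
    profile.qc = result
    return result


# ---------------------------------------------------------------------------
# alterations and clonality


def extract_alterations(profile: CNProfile, min_bins: int = 5) -> list[Alteration]:
    """Maximal runs of constant non-diploid copy number spanning at least
    ``min_bins`` bins. Runs separated by even a single diploid bin are
    reported separately (no bridging)."""
    alts: list[Alteration] = []
    segs = profile.segments
    for chrom, sub in segs.groupby("chrom", sort=False):
        sub = sub.sort_values("start_bin")
        run_start = run_end = None
        run_cn = None
        for _, row in sub.iterrows():
            cn = int(row["cn"])
            if cn == run_cn and run_end is not None and row["start_bin"] == run_end + 1:
                run_end = int(row["end_bin"])
                continue
            if run_cn is not None and run_cn != 2:
                if run_end - run_start + 1 >= min_bins:
                    alts.append(Alteration(str(chrom), run_start, run_end, run_cn))
            run_start, run_end, run_cn = int(row["start_bin"]), int(row["end_bin"]), cn
        if run_cn is not None and run_cn != 2:
            if run_end - run_start + 1 >= min_bins:
                alts.append(Alteration(str(chrom), run_start, run_end, run_cn))
    return alts


def _alterations_match(a: Alteration, b: Alteration, reciprocal_overlap: float) -> bool:
    if a.chrom != b.chrom or a.direction != b.direction:
        return False
    ov = min(a.end_bin, b.end_bin) - max(a.start_bin, b.start_bin) + 1
    if ov <= 0:
        return False
    return ov >= reciprocal_overlap * a.n_bins and ov >= reciprocal_overlap * b.n_bins


def _n_shared(
    alts_a: list[Alteration], alts_b: list[Alteration], reciprocal_overlap: float
) -> int:
    """Greedy one-to-one matching count between two alteration lists."""
    used = [False] * len(alts_b)
    n = 0
    for a in alts_a:
        for j, b in enumerate(alts_b):
            if not used[j] and _alterations_match(a, b, reciprocal_overlap):
                used[j] = True
                n += 1
                break
    return n


def call_clonality(
    alterations_by_cell: dict[str, list[Alteration]],
    rule: ClonalityRule | None = None,
    sample_id: str = "",
) -> ClonalCall:
    """Call clonal groups among the cells of one sample.

    Two cells are concordant when at least ``min_shared_alterations`` of
    their alterations match one-to-one (same direction, reciprocal overlap
    >= the rule's threshold). Clonal groups are connected components of the
    concordance graph with at least ``min_group_size`` members; under
    ``intersection`` semantics each member must additionally share the
    minimum number of alterations with *every* other member.
    """
    rule = rule or ClonalityRule()
    cell_ids = sorted(alterations_by_cell)
    n = len(cell_ids)
    shared = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            s = _n_shared(
                alterations_by_cell[cell_ids[i]],
                alterations_by_cell[cell_ids[j]],
                rule.reciprocal_overlap,
            )
            shared[i, j] = shared[j, i] = s
    adj = shared >= rule.min_shared_alterations
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups: list[list[str]] = []
    clonal = {c: False for c in cell_ids}
    group_id = {c: -1 for c in cell_ids}
    for comp in range(n_comp):
        members = [cell_ids[i] for i in range(n) if labels[i] == comp]
        if len(members) < rule.min_group_size:
            continue
        if rule.semantics == "intersection":
            idx = [cell_ids.index(m) for m in members]
            ok = all(
                shared[i, j] >= rule.min_shared_alterations
                for a, i in enumerate(idx)
                for j in idx[a + 1 :]
            )
            if not ok:
                continue
        gid = len(groups)
        groups.append(members)
        for m in members:
            clonal[m] = True
            group_id[m] = gid
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "clonal": [clonal[c] for c in cell_ids],
            "group_id": [group_id[c] for c in cell_ids],
        }
    )
    return ClonalCall(sample_id=sample_id, cells=cells, groups=groups)
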