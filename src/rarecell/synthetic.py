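"""Seeded synthetic liquid-biopsy cohorts and single-cell genomes.

The generator emulates the downstream data of a slide-based rare-cell
assay: per-sample rare-cell counts for each of the eight channel-based
groups, per-event channel intensities and morphometric feature vectors,
single-cell genomic bin counts carrying clonal copy-number templates, and
a configurable phenotype→genotype coupling in which CK- and Vim-related
morphometric features carry information about clonal status.

Per-group abundance is lognormal: a group with configured population mean
``m`` and log-scale standard deviation ``s`` draws rates from
``LogNormal(mu=ln(m) - s^2/2, sigma=s)`` so that the distribution mean is
exactly ``m``. Event counts are ``round(volume_ml * rate)``.

The default calibration puts the small-cell lung cancer (SCLC) cohort's
CK-only CTC rate at a mean of 411.19 cells/mL against 0.35 cells/mL in
normal donors (ND), CK|Vim at 23.82 vs 1.03, with the remaining groups
set so cohort totals are 602.39 (SCLC) and 65.67 (ND) cells/mL.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import COHORTS, LANDSCAPE, ND, SCLC, SampleMeta, ASSAY_MARKERS, assay_groups
from .cna import Alteration

__all__ = [
    "GroupAbundance",
    "CohortSpec",
    "GenomeSpec",
    "PhenoGenoCoupling",
    "default_abundance",
    "sample_group_rates",
    "generate_cohort",
    "generate_genomes",
    "apply_coupling",
    "simulate_coupled_features",
    "default_alteration_template",
]

#: default log-scale SD of the per-group abundance lognormal
DEFAULT_LOG_SD = 1.2

#: default per-group population means, cells/mL (landscape assay)
_SCLC_MEANS = {
    "CK": 411.19,
    "CK|Vim": 23.82,
    "CK|(CD45/CD31)": 15.0,
    "CK|Vim|(CD45/CD31)": 20.0,
    "Vim": 45.0,
    "Vim|(CD45/CD31)": 35.0,
    "(CD45/CD31)": 22.38,
    "DAPI": 30.0,
}  # sums to 602.39
_ND_MEANS = {
    "CK": 0.35,
    "CK|Vim": 1.03,
    "CK|(CD45/CD31)": 0.50,
    "CK|Vim|(CD45/CD31)": 0.60,
    "Vim": 20.0,
    "Vim|(CD45/CD31)": 15.0,
    "(CD45/CD31)": 13.19,
    "DAPI": 15.0,
}  # sums to 65.67

#: average nucleated cells imaged per slide, by cohort
DEFAULT_SLIDE_TOTALS = {SCLC: 2_304_659, ND: 2_116_477}

#: channel intensity distributions (arbitrary fluorescence units); the
#: static gate default of 100 sits five scaled-MADs above background
BACKGROUND_MEAN, BACKGROUND_SD = 50.0, 10.0
POSITIVE_MEAN, POSITIVE_SD = 300.0, 40.0
DAPI_MEAN, DAPI_SD = 400.0, 50.0

#: morphometric layout: 14 features per channel prefix, 56 total
FEATURES_PER_CHANNEL = 14
FEATURE_PREFIXES = ("CK", "Vim", "CD45CD31", "DAPI")


def morphometric_names(n_per_channel: int = FEATURES_PER_CHANNEL) -> list[str]:
    return [f"{p}.m{i:02d}" for p in FEATURE_PREFIXES for i in range(1, n_per_channel + 1)]


@dataclass
class GroupAbundance:
    mean_cells_per_ml: float
    log_sd: float = DEFAULT_LOG_SD

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean_cells_per_ml) and self.mean_cells_per_ml >= 0):
            raise ValueError("mean_cells_per_ml must be finite and >= 0")
        if not (math.isfinite(self.log_sd) and self.log_sd > 0):
            raise ValueError("log_sd must be finite and > 0")


def default_abundance() -> dict[tuple[str, str], GroupAbundance]:
    out = {}
    for group, m in _SCLC_MEANS.items():
        out[(SCLC, group)] = GroupAbundance(m)
    for group, m in _ND_MEANS.items():
        out[(ND, group)] = GroupAbundance(m)
    return out


@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic cohort."""

    n_sclc: int = 14
    n_nd: int = 10
    volume_ml: float = 1.0
    slide_cell_total_mean: dict = field(default_factory=lambda: dict(DEFAULT_SLIDE_TOTALS))
    group_abundance: dict = field(default_factory=default_abundance)
    seed: int = 0
    assay: str = LANDSCAPE
    #: distance between channel-group centroids in morphometric space,
    #: in within-group SD units
    group_separation: float = 8.0

    def validate(self) -> None:
        if self.n_sclc < 0 or self.n_nd < 0:
            raise ValueError("cohort sizes must be >= 0")
        if not (math.isfinite(self.volume_ml) and self.volume_ml > 0):
            raise ValueError("volume_ml must be finite and > 0")
        groups = assay_groups(self.assay)
        for cohort in COHORTS:
            for g in groups:
                if (cohort, g) not in self.group_abundance:
                    raise ValueError(f"missing abundance for ({cohort}, {g})")


def sample_group_rates(
    abundance: GroupAbundance, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-mL rates from the group's lognormal (mean-preserving
    parameterization). A zero-mean group yields all-zero rates."""
    if abundance.mean_cells_per_ml == 0:
        return np.zeros(n)
    mu = math.log(abundance.mean_cells_per_ml) - abundance.log_sd**2 / 2
    return rng.lognormal(mu, abundance.log_sd, size=n)


def _group_centroids(groups: list[str], n_features: int, separation: float) -> dict:
    """Deterministic per-group morphometric centroids, ``separation``
    apart in expectation (unit directions from a fixed generator)."""
    centroids = {}
    for i, g in enumerate(groups):
        local = np.random.default_rng(10_000 + i)
        v = local.standard_normal(n_features)
        centroids[g] = separation * v / np.linalg.norm(v)
    return centroids


def generate_cohort(spec: CohortSpec) -> tuple[list[SampleMeta], pd.DataFrame]:
    """Generate sample metadata and the per-cell event table.

    Each event carries channel intensities consistent with its group
    (positive channels above the 100-unit static gate, negative channels
    at background) and a 56-dimensional morphometric vector clustered by
    group. Deterministic given ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    groups = assay_groups(spec.assay)
    markers = ASSAY_MARKERS[spec.assay]
    feat_names = morphometric_names()
    centroids = _group_centroids(groups, len(feat_names), spec.group_separation)

    metas: list[SampleMeta] = []
    frames: list[pd.DataFrame] = []
    samples = [(f"SCLC-{i + 1:03d}", SCLC) for i in range(spec.n_sclc)] + [
        (f"ND-{i + 1:03d}", ND) for i in range(spec.n_nd)
    ]
    for sample_id, cohort in samples:
        slide_ids = (f"{sample_id}-S1", f"{sample_id}-S2")
        slide_totals = rng.poisson(spec.slide_cell_total_mean[cohort], size=2)
        meta = SampleMeta(
            sample_id=sample_id,
            cohort=cohort,
            volume_ml=spec.volume_ml,
            slide_ids=slide_ids,
            nucleated_cells=int(slide_totals.sum()),
        )
        metas.append(meta)
        cell_counter = 0
        for g in groups:
            ab = spec.group_abundance[(cohort, g)]
            rate = sample_group_rates(ab, 1, rng)[0]
            n_events = int(round(spec.volume_ml * rate))
            if n_events == 0:
                continue
            positives = {col: (disp in g.split("|")) for col, disp in markers}
            intens = {
                col: np.where(
                    positives[col],
                    rng.normal(POSITIVE_MEAN, POSITIVE_SD, n_events),
                    rng.normal(BACKGROUND_MEAN, BACKGROUND_SD, n_events),
                )
                for col, _ in markers
            }
            feats = centroids[g] + rng.standard_normal((n_events, len(feat_names)))
            df = pd.DataFrame(feats, columns=feat_names)
            df.insert(0, "dapi", rng.normal(DAPI_MEAN, DAPI_SD, n_events))
            for col, _ in reversed(markers):
                df.insert(1, col, intens[col])
            df.insert(0, "group_true", g)
            df.insert(0, "cohort", cohort)
            df.insert(
                0,
                "slide_id",
                [slide_ids[(cell_counter + j) % 2] for j in range(n_events)],
            )
            df.insert(0, "sample_id", sample_id)
            df.insert(
                0,
                "cell_id",
                [f"{sample_id}-c{cell_counter + j:05d}" for j in range(n_events)],
            )
            cell_counter += n_events
            frames.append(df)
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        cols = ["cell_id", "sample_id", "slide_id", "cohort", "group_true", "dapi"]
        cols += [c for c, _ in markers] + feat_names
        events = pd.DataFrame(columns=cols)
    return metas, events


# ---------------------------------------------------------------------------
# genomes


def default_chromosomes(n_chroms: int = 22, bins_per_chrom: int = 100) -> list[tuple[str, int]]:
    return [(f"chr{i + 1}", bins_per_chrom) for i in range(n_chroms)]


def default_alteration_template() -> list[Alteration]:
    """Clonal SCLC template: losses on 3p, 10q, 13q and 17p (RASSF1, PTEN,
    RB1, TP53) and gains on 1q, 3q, 5p and 8q (BCL9/MUC1, PIK3CA/p63,
    TERT, MYC), mapped onto the abstract 100-bin chromosomes (p arm =
    low bin indices)."""
    return [
        Alteration("chr3", 0, 19, 1),
        Alteration("chr10", 60, 79, 1),
        Alteration("chr13", 40, 59, 1),
        Alteration("chr17", 0, 19, 1),
        Alteration("chr1", 60, 79, 3),
        Alteration("chr3", 70, 89, 3),
        Alteration("chr5", 0, 19, 3),
        Alteration("chr8", 60, 79, 3),
    ]


@dataclass
class GenomeSpec:
    """Synthetic genome layout and read-depth model."""

    chromosomes: list = field(default_factory=default_chromosomes)
    bin_size: int = 1_000_000
    alteration_template: list = field(default_factory=default_alteration_template)
    mean_reads_per_bin: float = 200.0
    noise_model: str = "poisson"

    def validate(self) -> None:
        sizes = dict(self.chromosomes)
        if any(n < 1 for n in sizes.values()):
            raise ValueError("each chromosome needs >= 1 bin")
        if self.noise_model not in ("noiseless", "poisson"):
            raise ValueError("noise_model must be 'noiseless' or 'poisson'")
        if not (math.isfinite(self.mean_reads_per_bin) and self.mean_reads_per_bin > 0):
            raise ValueError("mean_reads_per_bin must be finite and > 0")
        for alt in self.alteration_template:
            if alt.chrom not in sizes:
                raise ValueError(f"template chromosome {alt.chrom} not in genome")
            if not (0 <= alt.start_bin <= alt.end_bin < sizes[alt.chrom]):
                raise ValueError(f"template region {alt} outside chromosome bounds")


@dataclass
class PhenoGenoCoupling:
    """How clonal genotype shows through the phenotype.

    ``p_clonal_by_group`` gives each channel group's probability that one
    of its cells carries the clonal template; ``informative_features``
    lists (morphometric feature, shift in pooled-SD units) pairs applied
    to clonal cells; the remaining features are uninformative noise.
    """

    p_clonal_by_group: dict = field(
        default_factory=lambda: {
            "CK": 0.8,
            "CK|Vim": 0.5,
            "CK|(CD45/CD31)": 0.5,
            "CK|Vim|(CD45/CD31)": 0.5,
            "Vim": 0.3,
            "Vim|(CD45/CD31)": 0.3,
            "(CD45/CD31)": 0.1,
            "DAPI": 0.1,
        }
    )
    informative_features: list = field(
        default_factory=lambda: [(f"CK.m{i:02d}", 1.5) for i in range(1, 13)]
        + [(f"Vim.m{i:02d}", 1.5) for i in range(1, 8)]
    )
    n_noise_features: int = 37
    #: force per-group clonal counts to round(p * n) instead of Bernoulli
    exact_allocation: bool = False

    def validate(self) -> None:
        for g, p in self.p_clonal_by_group.items():
            if not (0 <= p <= 1):
                raise ValueError(f"p_clonal for {g} outside [0, 1]")
        for name, shift in self.informative_features:
            if not math.isfinite(shift):
                raise ValueError(f"non-finite shift for {name}")


def _bin_grid(gspec: GenomeSpec) -> pd.DataFrame:
    rows = []
    for chrom, n_bins in gspec.chromosomes:
        for b in range(n_bins):
            rows.append((chrom, b * gspec.bin_size, (b + 1) * gspec.bin_size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _expected_counts(gspec: GenomeSpec, clonal: bool) -> np.ndarray:
    """Per-bin expected read counts: mean_reads_per_bin * CN / 2."""
    cn = {}
    for chrom, n_bins in gspec.chromosomes:
        cn[chrom] = np.full(n_bins, 2.0)
    if clonal:
        for alt in gspec.alteration_template:
            cn[alt.chrom][alt.start_bin : alt.end_bin + 1] = alt.cn
    parts = [cn[chrom] for chrom, _ in gspec.chromosomes]
    return gspec.mean_reads_per_bin * np.concatenate(parts) / 2.0


def generate_genomes(
    gspec: GenomeSpec,
    cells: pd.DataFrame,
    coupling: PhenoGenoCoupling | None = None,
    seed: int = 0,
    n_wbc_per_sample: int = 0,
    alignment_rate: float = 0.97,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate single-cell bin counts for the given events.

    Each cell is clonal with its group's probability (or an exact
    round(p*n) allocation); clonal cells carry the template's copy-number
    blocks, everything else is flat diploid, as are the optional
    white-blood-cell controls added per sample.

    Returns ``(bin_counts, truth)``: long-format counts
    (cell_id, chrom, start, end, count) and per-cell truth labels
    (cell_id, sample_id, group, clonal, template, total_reads,
    alignment_rate, is_wbc).
    """
    gspec.validate()
    coupling = coupling or PhenoGenoCoupling()
    coupling.validate()
    rng = np.random.default_rng(seed)
    grid = _bin_grid(gspec)
    exp_clonal = _expected_counts(gspec, clonal=True)
    exp_flat = _expected_counts(gspec, clonal=False)

    # clonal assignment per (sample, group), in stable order
    clonal_flags: dict[str, bool] = {}
    for (sample_id, group), sub in cells.groupby(["sample_id", "group_true"], sort=True):
        p = coupling.p_clonal_by_group.get(group, 0.0)
        ids = list(sub["cell_id"])
        if coupling.exact_allocation:
            k = int(round(p * len(ids)))
            flags = [i < k for i in range(len(ids))]
        else:
            flags = list(rng.random(len(ids)) < p)
        clonal_flags.update(zip(ids, flags))

    rows_truth = []
    count_frames = []

    def emit(cell_id, sample_id, group, clonal, is_wbc):
        exp = exp_clonal if clonal else exp_flat
        if gspec.noise_model == "noiseless":
            counts = exp.copy()
        else:
            counts = rng.poisson(exp).astype(float)
        df = grid.copy()
        df.insert(0, "cell_id", cell_id)
        df["count"] = counts
        count_frames.append(df)
        rows_truth.append(
            {
                "cell_id": cell_id,
                "sample_id": sample_id,
                "group": group,
                "clonal": clonal,
                "template": "sclc_clonal" if clonal else "none",
                "total_reads": float(counts.sum()),
                "alignment_rate": alignment_rate,
                "is_wbc": is_wbc,
            }
        )

    for _, row in cells.iterrows():
        emit(row["cell_id"], row["sample_id"], row["group_true"],
             bool(clonal_flags[row["cell_id"]]), False)
    for sample_id in sorted(cells["sample_id"].unique()):
        for i in range(n_wbc_per_sample):
            emit(f"{sample_id}-wbc{i + 1:02d}", sample_id, "WBC", False, True)

    if count_frames:
        bin_counts = pd.concat(count_frames, ignore_index=True)
    else:
        bin_counts = pd.DataFrame(columns=["cell_id", "chrom", "start", "end", "count"])
    truth = pd.DataFrame(
        rows_truth,
        columns=[
            "cell_id", "sample_id", "group", "clonal", "template",
            "total_reads", "alignment_rate", "is_wbc",
        ],
    )
    return bin_counts, truth


def apply_coupling(
    events: pd.DataFrame,
    truth: pd.DataFrame,
    coupling: PhenoGenoCoupling,
    seed: int = 0,
) -> pd.DataFrame:
    """Shift the informative morphometric features of clonal cells.

    Morphometric noise is unit-SD by construction, so a shift of ``s``
    pooled-SD units is an additive offset of ``s``. Returns a copy of the
    event table."""
    events = events.copy()
    clonal_ids = set(truth.loc[truth["clonal"], "cell_id"])
    mask = events["cell_id"].isin(clonal_ids)
    for name, shift in coupling.informative_features:
        if name in events.columns:
            events.loc[mask, name] = events.loc[mask, name] + shift
    return events


def simulate_coupled_features(
    coupling: PhenoGenoCoupling,
    n_clonal: int,
    n_not: int,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Standalone phenotype→genotype benchmark matrix.

    All features are standard normal; the coupling's informative features
    are shifted in the clonal class. Feature set = informative features
    plus ``n_noise_features`` drawn from the remaining morphometric names.
    Returns (features, labels) with labels 1 for clonally altered.
    """
    coupling.validate()
    rng = np.random.default_rng(seed)
    informative = [name for name, _ in coupling.informative_features]
    pool = [n for n in morphometric_names() if n not in informative]
    if coupling.n_noise_features > len(pool):
        extra = coupling.n_noise_features - len(pool)
        pool = pool + [f"Noise.m{i:02d}" for i in range(1, extra + 1)]
    noise = pool[: coupling.n_noise_features]
    names = informative + noise
    n = n_clonal + n_not
    X = rng.standard_normal((n, len(names)))
    y = np.concatenate([np.ones(n_clonal, dtype=int), np.zeros(n_not, dtype=int)])
    for j, (name, shift) in enumerate(coupling.informative_features):
        X[: n_clonal, j] += shift
    features = pd.DataFrame(X, columns=names)
    return features, y
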