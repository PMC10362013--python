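# Methods

This note documents the models, parameter choices and numerical details
behind `rarecell`, and what the synthetic benchmarks do and do not show.

## Synthetic cohorts

The generator emulates the *downstream* data of a slide-based
direct-imaging liquid biopsy: the entry point is the extracted per-cell
feature table, never images.

**Abundance model.** Each (cohort, channel-group) pair draws a per-sample
rate from a lognormal with population mean `m` and log-scale SD `s`,
parameterized mean-preservingly (`mu = ln m − s²/2`). The event count of a
sample-group is `round(volume_ml × rate)`. The CK and CK|Vim means are
set to the study's printed values (SCLC 411.19 / 23.82 cells/mL, ND
0.35 / 1.03); the six remaining landscape groups are not individually
printed, so their defaults were chosen once so that cohort totals equal
the printed totals (602.39 SCLC, 65.67 ND cells/mL), with mesenchymal and
immune groups overlapping between cohorts the way the box plots suggest.
The lognormal family itself is a modeling choice — only means and ranges
are reported, which do not pin down a distribution; `log_sd = 1.2`
makes printed-scale ranges (5–3,402 cells/mL over 14 draws for CK)
plausible. Volume defaults to 1.0 mL-equivalent per test and is stored
per sample; the slide-to-volume conversion of the assay is not public.

**Events.** Positive channels draw intensities from N(300, 40²),
negative channels from the N(50, 10²) background, DAPI from N(400, 50²),
all in arbitrary fluorescence units; the static gate default of 100
sits five scaled-MADs above background. Morphometrics are 56-dimensional
(14 features per channel prefix CK./Vim./CD45CD31./DAPI.), modeled as a
deterministic per-group centroid (groups `group_separation = 8`
within-group SDs apart) plus unit isotropic noise. The separation makes
morphological clusters recoverable by the hierarchy — the working
assumption of the stratification procedure, not a claim about effect
sizes in real images.

**Genomes.** The default genome is 22 abstract autosomes × 100 bins
(2,200 bins, nominal 1 Mb each) rather than hg19 coordinates; real bin
grids can be supplied externally. The clonal template carries the
SCLC-typical events: losses on 3p, 10q, 13q, 17p (RASSF1, PTEN, RB1,
TP53) and gains on 1q, 3q, 5p, 8q (BCL9/MUC1, PIK3CA/p63, TERT, MYC),
mapped to the abstract chromosomes with the p-arm at low bin indices.
Expected depth is `mean_reads_per_bin × CN/2` (default 200 reads/bin →
~440,000 reads/cell, comfortably above the 50,000-read QC floor); noise
is Poisson or exactly zero (`noiseless`), the latter giving profiles the
caller must recover with zero error. A cell is clonal with its group's
probability (default CK 0.8, matching the worked example of 16/20 clonal
CK CTCs); `exact_allocation` forces `round(p·n)` per group for
deterministic fixtures. White-blood-cell controls are flat diploid.

**Phenotype–genotype coupling.** Clonal cells have 12 CK- and 7
Vim-prefixed morphometric features shifted +1.5 pooled SDs (noise is
unit-SD, so the shift is additive); 37 features are uninformative. This
plumbing exists to make channel attribution of importances testable; the
shift size is the "strong coupling" benchmark condition, not an estimate
from data.

## Channel gating

A marker is positive iff intensity strictly exceeds its gate; the three
binary markers map bijectively onto the eight groups, and events not
above the DAPI gate are flagged as non-cells rather than classified. No
numeric gates are published for the assay, so the default is a robust
per-slide rule — median + 5 × scaled-MAD of a background (common-cell)
population — with static thresholds always available as overrides.
Cells-per-million uses the nucleated cells imaged across both slides of a
test as denominator. Cohort comparison is a two-sided Mann–Whitney U:
exact null enumeration when there are no ties and n₁n₂ ≤ 10,000,
otherwise the tie-corrected normal approximation; identical pooled values
short-circuit to p = 1. Raw p-values at the usual star levels are
reported by default; Benjamini–Hochberg adjustment is behind a flag since
the original analysis reports unadjusted significance.

## Patient stratification

The original procedure assigned events through a pre-constructed
multi-cancer t-SNE reference map; that artifact is not available, so the
morphological hierarchy is built de novo: Ward linkage, Euclidean metric,
z-scored morphometrics, constant features dropped. This preserves the
structure of the procedure (hierarchy → k-cut → count matrix → forest)
without external dependencies. For each k in 2..k_max (default 100,
configurable; the scan is capped at the event count) the sample × cluster
matrix of per-mL counts (per-million optional) feeds a seeded
1000-tree forest; the k minimizing OOB error wins, ties to the smaller k.
Pruning refits on the top-m clusters of the impurity-importance ranking
for every m and keeps the smallest m attaining the lowest OOB error.
Per-sample predictions are the OOB votes of the final forest — each
sample is predicted only by trees that never saw it, the small-cohort
substitute for a held-out test set. Impurity importance is the default
(the original does not specify the measure).

Desk-scale benchmark: the acceptance runs use k_max = 40 and 500 trees
on the 24-sample cohort, which finishes in well under a minute per scan
while leaving the selection behavior unchanged on this problem size.

## Single-cell copy number

`ratio_i = count_i / mean(count)` (scale-invariant; mean ratio 1).
Segmentation is CBS-style recursive binary splitting per chromosome: the
candidate breakpoint maximizes the pooled-variance two-sample t
statistic; it is accepted when its permutation p-value (default 1,000
shuffles, seeded) is below α = 0.01 and both sides keep ≥ 5 bins. Two
guards make the recursion robust: a zero-variance step yields t = +∞ and
splits immediately without permutations, and splits whose mean gap is
below 10⁻⁶ are rejected as floating-point jitter (real copy-number steps
are ≥ 0.25 ratio units at any plausible ploidy). Integer calling scans
ploidy P over [1.5, 5.0] in 0.05 steps, minimizing the length-weighted
squared distance of `ratio × P` from integers; exact ties (flat diploid
profiles fit every integer ploidy) resolve to the P nearest 2.

The assay's in-house quality score is proprietary; QS = 1/MAPD is used
instead, where MAPD is the median absolute difference of adjacent
within-chromosome ratios, so the published inclusion threshold of 2.5
maps to the interpretable MAPD ≤ 0.4. Under Poisson depth m the
adjacent-ratio difference has SD ≈ √(2/m), putting the pass boundary
near m ≈ 6 reads/bin — the default 200 reads/bin passes with a wide
margin. "Reads across the whole genome" is operationalized as ≥ 95% of
bins nonzero. QC passes iff reads > 50,000, alignment > 0.5, QS ≥ 2.5
(inclusive) and coverage ≥ 0.95.

Alterations are maximal runs of constant non-diploid integer CN spanning
≥ 5 bins; runs separated by even one diploid bin stay separate. Two
alterations match when they share chromosome and direction and overlap
reciprocally by ≥ 50%; two cells are concordant when ≥ 3 alterations
match one-to-one; clonal groups are connected components of the
concordance graph with ≥ 3 members ("more than two cells"). Whether the
three shared alterations must be common to *all* members or only
pairwise is ambiguous in the original wording; pairwise components are
the default and an `intersection` semantics is available on the rule
object.

## Phenotype→genotype model

Feature grouping at |r| > 0.9 is formalized as connected components of
the correlation graph (transitive closure; a greedy variance-ordered
alternative is available), with the highest-variance member as
representative and name order breaking ties — making the selection
idempotent and order-invariant. The published "final set of 56 features"
is a property of the study's data; it is reproduced here only through an
engineered 90-feature fixture (34 near-duplicate pairs + 22 independent
features) and never hard-coded. Evaluation is stratified 5-fold
cross-validation with pooled out-of-fold probabilities scored as a single
AUC (the original does not state its protocol; pooling is the stable
choice at a few hundred cells). Importances come from a forest refitted
on all cells and are channel-tagged by name prefix.

## What the benchmarks show — and don't

Passing tests demonstrate that the *procedures* are implemented correctly
and behave as designed under the stated statistical structure: lognormal
group abundances at the printed means, well-separated morphological
clusters, clean copy-number templates, additive feature shifts. They do
not validate the biology: real rare-cell morphometrics are not isotropic
Gaussians, real single-cell depth profiles carry GC and amplification
bias beyond Poisson noise (an optional LOWESS GC correction hook exists
but real WGA artifacts are richer), and the perfect 24/24 stratification
reflects the large configured effect sizes as much as the method. The
null-control tests (label permutation at both the patient and cell level)
guard against leakage, which is the failure mode this design can actually
rule out.

## Determinism

Every stochastic step takes a seed: cohort and genome generation,
segmentation permutations, forest fits, CV splits. Identical seeds give
byte-identical outputs end to end; reports are stamped with the seed and
a configuration hash.
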