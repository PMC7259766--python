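# Methods

This note documents the models, estimators and numerical choices behind
`cienet`, and what the synthetic-data tests do and do not establish about
real data.

## Study design and data model

A single brain region of a 2×2 design: vapor exposure (CIE vs Air) crossed
with 2-bottle-choice drinking (Drinking vs NonDrinking), default 12 mice
per group. Behavioral data are daily ethanol intakes (g/kg) over six
baseline weeks and four CIE cycles, five drinking days per phase.
Expression data are a complete log2 matrix (probesets × samples), assumed
already background-corrected, normalized across arrays and batch-corrected;
`quantile_normalize` is provided, ComBat-style batch correction is an
ingest-side hook, and probe-level processing is out of scope. All
statistics are at probeset level; probeset→gene collapsing is deliberately
not performed.

## Differential expression

Pairwise contrasts come from one 4-group cell-means model per probeset:
log-ratio = difference of group means; t uses the residual variance pooled
across all four groups (df = n − 4); p two-sided from the t distribution;
BH step-up FDR within each contrast. The contrast labels are fixed:
C1 CIE-D vs Air-D, C2 CIE-ND vs Air-ND, C3 CIE-D vs CIE-ND, C4 CIE-D vs
Air-ND, C5 CIE-ND vs Air-D, C6 Air-D vs Air-ND. The two-factor model is
effect-coded (±1), so with a balanced design the main-effect and
interaction tests are Type-III; coefficients are reported on the
level-difference scale (2 × effect-coded β). Zero-variance probesets are
flagged and assigned p = 1 rather than dropped. Empirical-Bayes variance
moderation is optional (off by default): per-gene variances are shrunk
toward a scaled inverse-χ² prior fitted by moments of log s²; the pipeline
contracts hold either way.

The network input universe follows the one-way-ANOVA rule: probesets with
4-group ANOVA BH-FDR ≤ 0.01 in any region, unioned across regions
(`anova_filter` / `union_filter`). For the synthetic flagship run the
universe is configured to all probesets, because planted module factors are
deliberately orthogonal to the group design and would be stripped by a
group-mean filter; the filter itself is validated separately for power
(planted δ = 2 shifts retained ≥ 95%) and null behavior (retained fraction
at the FDR level).

## Drinking traits

Weekly baseline means b1–b6 and cycle means t1–t4 are arithmetic means of
the five daily intakes per phase. The change measures use baseline
reference = mean(b1..b6) by default (`lastweek` uses b6 only):
abs_change_c = t_c − baseline, pct_change_c = 100·(t_c − baseline)/baseline.
NonDrinking mice carry all-zero traits (their intake), keeping trait
vectors defined over every sample; percent change is flagged undefined when
baseline = 0. Correlations therefore default to all samples — the large-n
regime that strong module–drinking p-values require — with a drinkers-only
option.

## Network construction and modules

Unsigned weighted adjacency a_ij = |cor|^β (signed option ((1+cor)/2)^β),
default β = 6; candidate powers are scored by the scale-free fit: bin the
connectivity k into ~10 bins, regress log10(frequency) on log10(mean k),
report signed R² = −sign(slope)·R², choose the smallest power with signed
R² ≥ 0.80 unless overridden. TOM as in the README formula; the matrix
implementation is verified against a brute-force triple loop to 1e-10.

Module detection cuts the average-linkage dendrogram of 1 − TOM with a
native dynamic-hybrid-style procedure:

1. Branches joining above a static cut height (0.99 × max merge height) are
   always separated.
2. Below it, a branch splits into its two children only when both are at
   least `min_module_size` (default 30), both have core scatter (mean
   intra-branch dissimilarity) below the deep-split preset, and both attach
   to the parent with a height gap above the preset minimum.
3. Clusters below the minimum size or above the scatter bound become grey.
4. Each surviving cluster is trimmed: members whose mean TOM similarity to
   the rest of the cluster falls below 0.5 × the cluster median are
   iteratively removed (dendrogram branches pick up stragglers that join
   near the cut height; their intra-cluster overlap is far below genuine
   members', so the relative threshold removes them without touching the
   core).

Deep-split presets 0–3 map to (max core scatter, min gap) fractions of the
height range above its 5th percentile: (0.64, 0.27), (0.73, 0.2025),
(0.82, 0.135), (0.91, 0.0675) — higher deep split tolerates looser branches
and smaller gaps, giving more and smaller modules. Exact label equivalence
with the reference R implementation is not promised; the test surface is
parameter recovery (ARI ≥ 0.8 on planted modules; ≥ 90% grey on pure
noise; module count non-decreasing in deep split on nested blocks). Module
labels follow the conventional color sequence in descending size order;
ties break deterministically by smallest gene index. No eigengene merging
by default; `merge_height` optionally merges modules by mean inter-module
TOM similarity.

Eigengenes are the leading right-singular vector of the standardized member
submatrix, centered to zero mean over samples, unit SD, sign-oriented to
correlate positively with the module's mean profile (size-1 modules use the
gene's standardized profile). Connectivity: kTotal = adjacency row sum
minus self; kIM = adjacency summed within the gene's module; kME =
correlation with the module eigengene. Grey genes keep kTotal only.

## Module validation

Observed mean off-diagonal TOM per module is compared with 100 random
pseudo-modules of the same size sampled without replacement from the whole
network universe (grey included). Z = (obs − μ)/σ; p one-sided from the
normal approximation; BH across modules; validated at FDR ≤ 0.2. Grey is
always reported with FDR 1. On a structureless network the null Z is close
to standard normal; on a network with strong planted modules the null mean
overlap is right-skewed (random draws hit module genes), which the Z-based
p absorbs only approximately — the validated/not-validated decision is
insensitive to this because planted-module Z values are two orders of
magnitude above the null.

## Module disruption

For groups A and B (default CIE Drinking vs Air NonDrinking): per-group
connectivity is recomputed from that group's samples only (same β; kIM
within the full-network module; kME against the eigengene recomputed on
those samples — a `ktotal` reading of kME is also provided). Observed
statistic: Pearson correlation over member genes of the two groups' kIM
(and kME) vectors. Null: 200 bootstrap networks from sample subsets of size
min(|A|, |B|) drawn without replacement ignoring group labels; μ and σ are
the mean and SD of the correlations between bootstrap-network pairs.
By default only sample-disjoint pairs enter the null: the observed
comparison is between two disjoint sample sets, and overlapping bootstrap
pairs share estimation noise, which inflates μ and shrinks σ — with
overlapping pairs the permuted-label false-flag rate at Z ≤ −2 is ~20%,
versus the nominal ~2% with disjoint pairs. `pair_mode="all"` restores the
overlapping-pairs variant; `max_pairs` subsamples pairs. Modules with
Z_cor.kIM ≤ −2 are flagged as disrupted (kIM gives the primary criterion;
kME results are reported alongside).

**Power limitation.** With 12 samples per group and β = 6, single-pair
adjacency estimates are strongly noise-amplified (relative error ≈ 6·Δr/r),
and the estimation error of a gene's kIM is dominated by that gene's own
sample noise, which does not average out over module partners. The
cross-group kIM concordance of an intact 100-gene module consequently has
an intrinsic ceiling near 0.35 at this sample size — it rises to ~0.55 at
50/group and ~0.85 at 200/group — which bounds the separation achievable by
the Z statistic regardless of how clean the underlying modules are. At the
default study size, a module with 80% of its genes decorrelated in one
group is flagged in only a minority of replicates without any undisrupted
module being co-flagged. This is a property of the statistic at the
design's sample size, reported as measured.

## Enrichment

Exact upper-tail hypergeometric p (P(X ≥ k), X ~ Hypergeom(N, n, m)) for
each module × list cell, corrected over the full table: BH at 0.05 for
module/list overlaps, Bonferroni at 0.05 for cell-type marker lists. The
default universe is the probeset set that entered the network, so
enrichment conditions on what could have been assigned; a full-array
universe is configurable. Lists are intersected with the universe before
testing; empty lists are flagged and excluded from correction.

## Synthetic-data generator

Gene g in module q: x_gs = μ_g + λ_g f_q(s) + δ·1[s ∈ DE groups] + ε_gs,
with μ_g ~ U(6, 10) (log2 scale), loadings λ_g ~ U(0.5, 0.9), factors
standardized over the pooled samples, ε ~ N(0, noise_sd²) with default
noise_sd 0.5 (within-module correlations ≈ 0.5–0.75, the range typical of
microarray coexpression modules); background genes are pure noise. The
trait-linked factor is a blend a·z(trait) + √(1−a²)·noise with the mixing
weight calibrated numerically (Monte-Carlo over the noise, dedicated RNG)
so the population Spearman ρ against the cycle-4 change-from-baseline trait
hits the configured target despite the trait's tied zeros. Disruption
replaces, for the chosen fraction of member genes and only in the affected
group's samples, the shared-factor term with an independent per-gene factor
(re-drawn loading, random sign): a pure sign-flip of loadings would leave
an unsigned network exactly invariant, so decorrelation is the
implementable meaning of "breaking within-module correlation in that group
only". DE genes are background genes shifted by δ (default 0.8 log2) in
CIE Drinking, hence significant in C1/C3/C4. Drinking: daily intake =
phase mean + N(0, 0.4²) truncated at 0; phase means are 2.5 g/kg at
baseline, escalating by 0.35 g/kg per cycle for CIE Drinking and 0.08 for
Air Drinking (matching the qualitative escalation pattern of the CIE
model); NonDrinking mice are identically zero. DE effect sizes and noise
levels are testability choices, not estimates from data.

What the generator does **not** emulate: probe-level intensities, batch
artifacts, array outliers, multiple regions with shared biology,
correlated module factors, or heavy-tailed expression noise. Passing
parameter-recovery tests therefore shows the estimators are correct and
calibrated under the assumed factor model — not that real microarray data
satisfy that model.

## Determinism and seeds

Every stochastic stage derives its generator from
`SeedSequence([seed, stage_id])` with fixed per-stage ids, so one config
seed reproduces the whole run; pipeline outputs contain no timestamps and
reruns are byte-identical. Hierarchical-clustering ties are broken by index
order; all thresholds (DE FDR 0.01, ANOVA FDR 0.01, validation FDR 0.2,
disruption Z −2, enrichment FDR 0.05, trait p 0.01) are config fields with
these defaults.

## Problem sizes used in verification

The shipped verification suite uses a 2,000-gene, 48-sample study for
module recovery, validation calibration, trait-ρ recovery and disruption
replicates; 10,000 null probesets for type-I calibration; a 400-gene
pipeline for byte-level determinism; and exhaustive enumeration up to
N = 60 for the hypergeometric oracle.
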