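# Methods

## Scope and data model

`dnmeta` operates on gene-level log2 expression matrices (genes × samples)
with per-sample metadata (dataset, batch, tissue ∈ {glomerulus, tubule,
cortex}, condition ∈ {DN, control}). Probe-level processing (RMA
background correction, median polish) is out of scope: inputs are assumed
to be summarized intensities. A log2 heuristic (values > 30 suggest linear
scale) is not applied automatically; matrices are taken as log2.

## Synthetic study generator

The generator is the package's study stand-in, not a test convenience. One
bundle consists of several dataset/platform units. For gene *g*, sample
*i* of dataset (= batch) *b*:

    x_gi = α_g + β_g·DN_i·1[g ∈ DE(compartment_b)]
         + λ_g·f_i·1[g ∈ module] + γ_b + δ_b·ε_gi

with ε ~ N(0, noise_sd²), a per-sample latent factor f_i ~ N(0,
module_latent_sd²) and same-sign loadings λ_g ~ Uniform(0.6, 1.0), so the
module forms a dense, recoverable co-expression cluster. Glomerulus-planted
DE genes are downregulated in DN, tubule-planted genes upregulated,
matching the compartment-specific directionality of the disease signature.

Defaults (the study conditions everything downstream is measured under):

| parameter | default | rationale |
| --- | --- | --- |
| datasets | 5 glomerulus + 3 tubule + 1 cortex | mirrors a curated DN cohort; unbalanced group sizes (3v3 … 20v10) |
| n_genes | 2000 | desk-scale stand-in for a ~15–20k-gene array |
| baseline α_g | N(8, 1.5²) log2 units | typical array intensity scale |
| DE effect | ±2 log2 units, 100 genes/compartment | comfortably past the 1.5 vote-counting cutoff |
| noise_sd | 0.5 log2 units | within-group residual SD typical of gene-level microarray data |
| batch shifts γ_b | −1.5 … +1.2 log2 | platform-generation offsets |
| batch scales δ_b | 0.85 … 1.2 | multiplicative platform noise differences |
| module | 20 genes, latent SD 1.0 | one coherent functional cluster |
| artifacts | 2 outlier arrays, 1 duplicate pair | Table-style curation losses |

Outlier arrays come in two modes: `shuffle` permutes one array's values
(destroys rank concordance, leaves the intensity distribution intact — only
concordance-based QC can flag it), `shift` adds +3 log2 to the whole array
(leaves concordance intact, exercises the Ka statistic). Duplicate pairs
overwrite one same-condition sample with another plus N(0, 0.01²) jitter.

qPCR tables follow Ct = base − log2(relative expression) with the
reference gene unaffected by treatment; 11–12 replicates per group and a
Ct SD of ~0.3 cycles emulate the validation experiment's scale.

What the generator does *not* emulate: probe-level effects, heavy-tailed
or intensity-dependent noise, correlated background structure beyond the
single planted module, missing values, and compartment contamination.
Passing tests therefore demonstrate correctness of the inference chain
under its own model assumptions, not robustness to every pathology of
real array data.

## QC screening

Each array receives a **concordance score**: the Spearman correlation of
its within-array expression ranks with the element-wise median rank
profile of all other arrays. This operationalizes interquartile-range-style
array scoring in a directly testable form: an array whose gene ranking
disagrees with the cohort scores low regardless of its marginal
distribution. Constant arrays get score 0 with a warning.

**Ka** is the two-sample Kolmogorov–Smirnov statistic between one array's
values and the pooled values of the remaining arrays; arrays above the
Tukey upper fence (Q3 + 1.5·IQR of all Ka) are candidates.

Formal outlier calls on the concordance scores use the generalized ESD
(Rosner) test when n > 7 and Dixon's Q otherwise (two-sided, α = 0.05,
k = ⌈0.1·n⌉ for ESD; Dixon ratio variant switched by sample size with
published two-sided critical values).

Two practical-significance guards temper the statistical flags, because
both the Tukey fence and a two-sided ESD at α = 0.05 routinely fire on the
natural spread of clean cohorts: a Ka flag counts only if Ka > 0.1, and an
ESD/Dixon flag only if the array's concordance lies more than 0.1 below
the cohort median. Both margins sit far from both populations the screen
must separate (clean arrays concentrate near Ka ≈ 0.03 and concordance
≈ 0.95; corrupted arrays at Ka ≈ 0.9 or concordance ≈ 0).

Duplicates are *reported* as pairs (Pearson r ≥ 0.99 on the 2000 most
variable genes), not auto-deleted; the pipeline's drop policy removes the
second member of each pair. Which member is "the copy" is unidentifiable
from expression alone.

## Batch adjustment

The parametric EB location/scale model. Standardize Z = (X − α̂ −
design·β̂)/σ̂ with gene grand means weighted by batch size, condition kept
as a covariate (a flag disables it), and σ̂² pooled from full-model
residuals. Per batch, additive effects get a normal prior and scale
effects an inverse-gamma prior, both moment-matched across genes;
posterior estimates iterate to convergence (Σ|Δδ*²| < 1e-4, ≤ 100 steps).
Adjusted data: σ̂·(Z − γ*)/δ* + α̂ + design·β̂.

Mean-only mode is available but off by default. Single-batch input is
returned unchanged with a warning; a batch of size one is an error.
EB adjustment is *approximately* idempotent: a second pass re-estimates
small nonzero parameters from finite data, changing values by roughly two
orders of magnitude less than the first pass (this is inherent to
shrinkage, not an implementation artifact, and is what the test asserts).

## Moderated differential expression

Two-group contrast (DN − control) only, matching the study design. The
prior (d₀, s₀²) is fitted by matching the first two moments of log s²_g to
a scaled-F distribution via digamma/trigamma inversion (Newton iteration
on the trigamma inverse). When the log-variances have exactly zero spread
the degenerate limit d₀ = ∞, s₀² = the common variance is used; d₀ = ∞
otherwise yields s̃² = s₀² with normal-reference p-values. Zero residual
variances are replaced by the smallest positive variance with a warning.
BH adjustment is delegated to statsmodels (`fdr_bh`) and cross-checked
against the step-up definition in the tests; the whole moderated fit is
cross-checked against an independent R reference implementation.

## Consensus and aggregates

A vote requires q < 0.05 *and* |log₂FC| ≥ 1.5 in a dataset; core status
requires ≥ 2 direction-consistent votes within a single compartment —
direction consistency is imposed because down- and up-votes are tallied
separately. The kidney-cortex dataset never votes (it is not one of the
two compartments the rule names). The combined (merged + adjusted) bundle
can contribute per-compartment votes behind an opt-in flag; it is off by
default because pooling dilutes compartment-specific effects ~2× and its
vote weight is a design choice, not a data property.

Meta fold-change is the unweighted mean of per-dataset log₂FC (median by
flag); sign consistency is max(#positive, #negative); evidence combines by
Fisher's method with the χ² df equal to twice the number of datasets the
gene is measured in. Exact zero p-values are clamped to 1e-300 with a
warning.

Aggregates: Ward.D2 hierarchical clustering (scipy's `ward` linkage on the
gene × dataset fold-change matrix, missing entries imputed as 0), cut into
k = 2 groups; label 1 goes to the cluster with the lower mean meta log₂FC
(the downregulated aggregate).

## Enrichment

Database-agnostic ORA over GMT collections: p = P(X ≥ k) for X ~
Hypergeometric(N, K, n), BH across tested sets, both p and q cutoffs at
0.05. The universe defaults to the genes measured in the analysis — the
question asked is "enriched relative to what could have been detected",
and the original's choice of universe is not recoverable. Set-size filter
5–500 by default.

## Network inference and MCODE

Profiles are discretized into B = max(2, ⌊n^{1/3}⌋) equal-frequency bins
(capped at 5; ties broken by stable rank order), and the plug-in MI in
bits is computed for every pair. Significance uses the G-test: G =
2N·MI·ln2 is asymptotically χ² with (B−1)² df for the B×B table. At the
cell counts of small cohorts the raw G is slightly inflated, so the
default p-value divides G by Williams' correction factor
q = 1 + (B²−1)²/(6N(B−1)²) before the χ² lookup; this brings the measured
type-I rate at α = 0.01 (n = 60, B = 3) from ~0.0145 to ~0.011, inside
the binomial 99% band. The uncorrected tail remains available
(`williams=False`), and a permutation mode (p̂ = (1+#{MI_perm ≥ MI})/(E+1))
validates calibration at moderate α — a pure permutation p cannot resolve
the 10⁻⁷ edge threshold at feasible E.

The 10⁻⁷ threshold at these df is an MI floor of ~0.5 bits at n = 60:
only near-deterministic pairs qualify in a single small cohort. Module
detection is therefore performed (and validated) on the merged,
batch-adjusted bundle (~150 samples, B = 5), where a latent-factor module
with pair correlations ~0.7–0.8 is recovered essentially completely with
zero background edges. Edges are computed among a caller-chosen gene
subset (core genes, or module + background in the validation), keeping
O(G²) tractable; layout is left to external viewers (GraphML export).

MCODE follows the k-core weighting scheme: each vertex is weighted by the
core number of the densest k-core of its closed neighbourhood times that
core's density; complexes grow from seeds in decreasing weight over
neighbours with weight ≥ (1 − vwp)·seed (vwp = 0.2), each vertex used
once; haircut (on by default) removes members with fewer than two
within-complex links; fluff (off) pads with dense-neighbourhood
neighbours. Scores are density × size with loopless undirected density;
ties break lexicographically so results are deterministic.

## Livak quantification

Technical replicate Ct rows per (sample, gene) are averaged; ΔCt =
Ct_target − Ct_reference per sample; ΔΔCt subtracts the arithmetic mean of
control ΔCt (so the control geometric-mean rq is exactly 1); rq = 2^−ΔΔCt
with amplification efficiency fixed at 2. Group means ± SEM are reported
on the rq scale. Replicates are treated as biological replicates. The
Wilcoxon rank-sum test enumerates all arrangements exactly when n_a + n_b
≤ 12 with no ties, otherwise uses the normal approximation with tie and
continuity corrections.

## Problem sizes used in validation

The test-suite and the acceptance script run at sizes chosen to keep a
full validation under a few minutes while leaving every rate estimate
well-resolved: 20-seed QC screens on full nine-dataset bundles (2000
genes), batch recovery on 1000 genes × 2 batches of 20, core-gene
recovery on 600 genes × (3 glomerulus + 2 tubule) datasets of 10v10,
10,000 independent pairs for G-test calibration, 5,000 genes for Fisher
uniformity, 20 null bundles of 1000 genes for BH calibration, and 50
seeds for qPCR power.

## Known limitations

- Two-group contrasts only; no multi-factor designs, no trend/robust
  variants of the variance moderation.
- Parametric EB priors only in the batch model; no reference-batch mode,
  no surrogate-variable estimation.
- The MI estimator is the plug-in on equal-frequency bins; no bias
  correction beyond Williams' factor, no ARACNE/CLR-style post-processing.
- ORA treats gene sets as flat lists; no ontology DAG propagation or
  semantic similarity.
- The QC practical-significance margins (Ka > 0.1, concordance gap > 0.1)
  are tuned to log2 microarray scale; other data scales may need
  different floors.
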