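# Methods

## Data model and preprocessing

A cohort consists of `n_case + n_control` individuals (defaults 12 + 28)
with `n_replicates` (default 3) two-channel arrays each. The methylation
signal is the log2 ratio of the bound (Cy5, methylation-enriched) over the
input (Cy3) channel; non-positive or missing intensities propagate as
missing log ratios, and probes missing in more than 20% of arrays are
dropped (a conservative default — the threshold is not principled, merely
protective). Arrays are quantile-normalized to their common mean
distribution under the assumption that all samples share the same overall
methylation level; tied values within a column receive the mean of the
reference values their tie group spans (order-independent), and columns
with missing entries are matched on the quantile scale by linear
interpolation, which makes the procedure idempotent to floating tolerance.
Replicates are averaged after normalization, and all group statistics are
computed on the individual-averaged matrix — averaging avoids treating
technical replicates as biological samples (pseudo-replication); fitting on
all arrays instead is possible by passing the un-averaged matrix, but it is
deliberately not the default.

Per-array QC summarizes the MvA representation (M = log2 Cy5/Cy3,
A = log2 Cy5·Cy3): median M, IQR of M, median A, and the least-squares
slope of M on A as the dye-bias statistic. The generator injects dye bias
as a linear trend in standardized A with configurable amplitude (default
0), which the slope statistic tracks monotonically.

## Probe-level inference

The per-probe statistic is the empirical-Bayes moderated t (Smyth 2004).
With pooled two-group variance s²_g on d_g = n₁ + n₂ − 2 degrees of
freedom, the prior (d₀, s₀²) is estimated by the closed-form method of
moments on z = log s²: with e = z − ψ(d/2) + log(d/2), solve
ψ′(d₀/2) = Var(e) − ψ′(d/2) by trigamma inversion (safeguarded Newton) and
s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2)); when the empirical dispersion
does not exceed the sampling term, d₀ = ∞ and the statistic becomes a
z-score against s₀². Zero-variance probes are excluded from estimation but
still scored. The implementation is validated against the Bioconductor
limma reference to ~1e-8 relative in a test; limma is never used as the
implementation. p-values are two-sided from t(d₀ + d_g) (normal at d₀ = ∞).
A probe is called differentially methylated at raw p < 0.05 (the threshold
is interpreted as unadjusted) with |log2 fold-difference| ≥ 0.25.

## Two-tier promoter calls

The promoter shift test ranks the promoter's moderated t values within the
whole-array pool; the null is n₁ ranks drawn without replacement from N.
For a background disjoint from the member values this reduces to the
standard two-sample Wilcoxon rank-sum test. Exact enumeration is used when
both effective samples are ≤ 8; otherwise a normal approximation with tie
and continuity corrections (cross-checked against scipy's asymptotic
implementation). The background deliberately includes the promoter's own
probes — they are 13 of tens of thousands, and a common pool keeps the
reference identical across promoters. BH FDR is computed once across all
promoters with a shift test, not per direction. The default call requires a
member probe passing the probe thresholds AND promoter q < 0.20; the strict
tier requires member probe p < 0.01 (same fold cut) and q < 0.05, with the
strict q interpreted as the same promoter-level BH q. Member-probe
direction is not required to match the shift direction (the two criteria
are independent); direction is the promoter median against the array
median. The representative probe per promoter is the member with smallest
p, ties broken by larger |log2 fold-difference|, then lexicographic id.
Sample clustering uses Ward linkage on 1 − Pearson r between individual
columns (constant columns get the maximal distance 1 with a warning),
deterministic leaf order.

## Permutation null

The genome-wide call count under the true labels is compared with counts
from random partitions of the individuals into pseudo-groups of the same
sizes. Partitions are distinct and exclude the true labeling; the reported
percentile counts ties as "not below" (conservative, matching a strict
"larger than" reading). Only label-dependent stages rerun per partition:
the group model and the EB hyperparameters (variances change with the
grouping); normalization is label-free and stays outside. Because the call
count is a small discrete statistic, the conservative percentile is
sub-uniform under the null; calibration checks therefore use a
tie-randomized percentile (`randomized_percentile`), which is exactly
uniform under exchangeability, while the conservative value is what gets
reported.

## Enrichment and spatial statistics

All overlap tests are upper-tail hypergeometric (scipy) with BH FDR across
the units tested together. The gene universe is every gene with a profiled
promoter — enrichment must condition on what was measurable. A gene is
hypo-/hypermethylated if any of its called promoters has that direction.
The miRNA analysis tests, for each differentially methylated miRNA, whether
its target genes (restricted to the universe) are enriched for
hypomethylated genes; a hypermethylated miRNA whose hypo-target enrichment
passes q < 0.05 is flagged "consistent" — the signature of a lifted double
layer of repression. Window scans slide 750 kb windows on a 250 kb grid
over promoter TSS positions (promoter position = TSS throughout);
chromosome mode tests each chromosome as one window per direction. The
distance-correlation profile pools all same-chromosome promoter pairs per
500 kb distance bin (to 2 Mb), computing a symmetrized Pearson r of the
representative-probe statistics (both orientations of each unordered pair)
with Fisher-z 95% CIs on the unordered pair count; bins under 10 pairs are
omitted. Normalized CpG frequency is (#CpG × L)/(#C × #G) over the tiled
−1000..+250 region, invariant under reverse complement; group contrasts use
two-sided Welch t-tests. Per-probe group differences export as UCSC
variableStep wiggle (1-based positions, span = probe length).

Cross-design probe pairing is mutual nearest neighbor on start coordinates
per chromosome with a 150 bp cap — mutual-NN guarantees the 1-1 property
that "closest" alone does not; ties resolve to the lower coordinate for
determinism. Site-level validation uses per-CpG one-sided Welch t-tests
(direction fixed a priori by the discovery screen; Welch rather than pooled
because group sizes are unequal, a config flag restores pooled), BH FDR per
region, and the q < 0.025/0.05/0.1/0.2 significance tiers.

## Synthetic cohort generator

The generator emulates the study design rather than array physics. Each
promoter gets 13 probes at offsets −1000..+200 (step 100, probe length
50 bp) from the TSS, strand-aware, on two 50 Mb chromosomes (enough span
for window and distance statistics at desk scale). Per probe and array,
input ~ 2^N(11, 0.8) and bound = input × 2^(m + δ·case + individual +
replicate + bias), so the log ratio carries the methylation signal and the
input level cancels. The baseline m is drawn per promoter (N(0.3, 0.4))
with small per-probe jitter (sd 0.1), reflecting promoter-level coherence.
Planted effects δ (default |δ| = 0.5 log2 units — an engineering choice,
effect magnitudes in log2 units are not established for this assay) apply
uniformly across a promoter's probes, hypermethylated with probability 0.31
to mirror the emulated study's hyper/hypo split; 5% of promoters are
differential, partly concentrated in two single-direction 750 kb blocks of
20 promoters on the 250 kb grid, with 8 planted miRNA promoters (79%
hypermethylated). Noise: individual-level biological deviation
N(0, 0.25) per probe per individual (shared across that individual's
replicates) and replicate-level technical noise N(0, 0.25) — both plausible
magnitudes for log2 MeDIP ratios. The individual deviation is drawn
independently per probe, not shared across a promoter's probes: the
promoter rank-sum test treats probes as exchangeable with the array pool,
and promoter-shared biological noise would make its p-values
anti-conservative by construction. Real arrays do exhibit within-promoter
correlation beyond the planted effect, so passing recovery tests here shows
the machinery is correct under its own assumptions, not that FDR control is
guaranteed on real data.

Target maps give every miRNA 50 targets; planted-consistent miRNAs (the
first 4 hypermethylated planted miRNAs) sample targets with 5-fold odds on
hypomethylated planted genes. The miRNA recovery analyses run on a
generator configuration with a larger differential fraction (20% of 1,500
promoters), chosen by a power calculation: with the default 3.5% hypo-gene
pool, a 50-target/odds-5 set yields ≈8 expected hypo targets against a null
mean of ≈1.8, too close for reliable q < 0.05 detection of every planted
miRNA, whereas a ≈14% pool separates them cleanly. Promoter sequences
(1250 bp) come from a first-order Markov chain with P(C|·) = 0.25 and the
C→G probability solved so the stationary CpG observed/expected ratio hits
the class target (0.86 hypomethylated, 0.38 hypermethylated, 0.42
background — the emulated study conditions); realized per-promoter means
match targets to ~0.01 at scale.

## Numerical choices and degenerate inputs

Log base 2 everywhere. BH FDR delegates to statsmodels; hypergeometric
tails to scipy (log-space internally); both are oracle-tested against
hand-written implementations. p-values are clipped to (tiny, 1]. Zero
posterior variance yields the smallest representable p with a warning.
Promoters with fewer than 2 scored probes are skipped with a logged reason;
gene sets empty after universe filtering are dropped with a warning; probes
missing a whole group are excluded with a logged count. All randomness
flows from explicit integer seeds (numpy default_rng); reruns are
byte-identical.

## Problem sizes

The test and acceptance analyses use 2,000-promoter (26,000-probe) cohorts,
20 Monte-Carlo repetitions for recovery/calibration claims, and
100-partition permutation nulls — sizes at which the Monte-Carlo error of
the checked quantities is comfortably below the asserted margins while the
whole suite stays desk-scale. The emulated study's full scale (~20,000 gene
promoters, 500 partitions) is reachable by config.

## Known limitations

No within-array spatial or print-tip normalization; no multi-factor design
matrices, array weights or replicate-correlation modeling; no covariate
adjustment in the default model (the emulated design controls
socio-economic position by sample selection — covariate columns exist for
sensitivity analyses); gene identifiers match exactly after upper-casing
(no alias resolution); the generator does not simulate scanner images,
probe sequence affinity, or hybridization artifacts beyond dye bias.
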