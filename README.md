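# medipdiff

Differential promoter methylation analysis for two-channel MeDIP tiling
arrays, built for case/control cohort studies of the epigenome — e.g.
asking whether an early-life exposure leaves a genome-wide promoter
methylation signature in adult blood DNA.

MeDIP (methylated DNA immunoprecipitation) enriches methylated fragments
with a 5-methylcytosine antibody; the log2 ratio of the bound (Cy5) over
the input (Cy3) channel of a tiling microarray proxies the methylation
level of each probe. `medipdiff` implements the complete analysis chain for
such data, plus a synthetic-cohort generator with planted ground truth so
every stage can be validated end to end.

## The statistics at the core

For probe *g* with case-minus-control mean difference β<sub>g</sub> and
pooled variance s²<sub>g</sub> on d<sub>g</sub> degrees of freedom, an
empirical-Bayes prior (scaled inverse-χ², parameters d₀ and s₀² estimated
from all probes by closed-form moments on log s²) gives the **moderated
t-statistic**

&nbsp;&nbsp;&nbsp;&nbsp;s̃²<sub>g</sub> = (d₀s₀² + d<sub>g</sub>s²<sub>g</sub>) / (d₀ + d<sub>g</sub>),&nbsp;&nbsp;
t<sub>g</sub> = β<sub>g</sub> / √(s̃²<sub>g</sub>(1/n₁ + 1/n₂)) ~ t(d₀ + d<sub>g</sub>).

A probe is differentially methylated when p < 0.05 **and**
|β<sub>g</sub>| ≥ 0.25 (log2). A **promoter** is called under the two-tier
rule: it must contain a differentially methylated probe **and** its probes'
t-statistics must shift significantly against the whole-array pool
(Wilcoxon rank-sum, Benjamini–Hochberg FDR < 20% across promoters; strict
tier: probe p < 0.01 and q < 0.05). Downstream analyses — label-permutation
null for the genome-wide call count, hypergeometric gene-set / miRNA-target
enrichment, megabase window scans, distance-correlation profiles, CpG
observed/expected density, cell-type confound intersections and per-CpG
validation statistics — all operate on these calls.

## Worked example

```bash
python analysis/01_simulate_cohort.py        # 12 vs 28 individuals, 3 replicates
python analysis/02_normalize_and_qc.py
python analysis/03_differential_promoters.py
python analysis/04_permutation_null.py
```

which prints (seed 1):

```
planted 100 differential promoters (67 hyper / 33 hypo), 2 cluster blocks
variance explained by individual on top-500 probes: 68.1%
empirical-Bayes prior: d0 = inf, s0^2 = 0.0832
two-tier call: 112 promoters (70 hyper / 42 hypo); strict tier: 104
vs planted truth: sensitivity 100.0%, empirical FDR 10.7%
observed 112 called promoters with the true labels
null over 100 random 12-vs-28 partitions: median 2, max 105
observed count exceeds 100% of random partitions
```

i.e. the caller recovers every planted promoter at an empirical false
discovery proportion comfortably below the nominal 20%, and the observed
genome-wide count dwarfs what random relabelings of the cohort produce.
`analysis/05..07` continue with enrichment, miRNA-target consistency,
genomic clustering, CpG density and confound checks. The same stages are
available as `medipdiff` subcommands (`simulate`, `qc`, `run`, `permute`,
`validate-sites`) driven by a YAML config, for use on real array data
converted to the documented TSV dialect.

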