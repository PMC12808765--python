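# Methods notes

This note records the modeling choices behind `grsig`: what each stage
assumes, which parameters matter and why their defaults were chosen, what the
synthetic generators do and do not emulate, and the numerical conventions
that make results reproducible.

## Count model and normalization

Counts are treated as negative binomial with the mean–dispersion
parameterization Var = μ + φμ²; the dispersion φ is shared across genes by
default (a per-gene vector is accepted), matching the count model that
standard RNA-seq DE tools assume. TMM normalization follows the published
recipe exactly: the reference sample is the one whose 75th-percentile CPM is
closest to the mean across samples; gene-wise log ratios M and abundances A
are computed over genes nonzero in both samples; the M values are doubly
trimmed (30 % on M, 5 % on A, rank-based with average ranks for ties) and
averaged with inverse delta-method-variance weights; factors are rescaled to
geometric mean 1. A sample with no counts, or no nonzero gene shared with the
reference, is an error naming the sample. The implementation reproduces
edgeR's `calcNormFactors` to ~1e-10 on random matrices (asserted in the test
suite via `Rscript`).

logCPM uses a prior count c = 0.5 against the TMM-effective library size:
log2((y + c)/(N·f + 2c)·10⁶). The `+2c` denominator keeps the transform
finite and monotone at zero counts. Low-expression filtering keeps a gene if
CPM ≥ 1 in at least as many samples as the smallest experimental group
(model × treatment × timepoint); the named-tool original does not publish its
effective arguments, so the rule is explicit and configurable here.

## Differential expression

Each contrast (model × timepoint, Dex vs vehicle) is tested per gene on
logCPM. With three replicates per arm a plain Welch t has at most ~4 degrees
of freedom, and its smallest attainable p-values (~1e-5) cannot survive
Benjamini–Hochberg at FDR < 0.01 among thousands of genes — the derivation
thresholds (|log2FC| > 2, FDR < 0.01) would select nothing at realistic
effect sizes. `de_test` therefore moderates the pooled per-gene variances by
empirical Bayes before forming the t statistic: a scaled inverse-chi-square
prior is fitted to the observed variances by the method of moments on their
logarithms (trigamma inversion by Newton's method), each variance is shrunk
to (d₀s₀² + d·s²)/(d₀ + d), and the statistic is referred to a t with d + d₀
degrees of freedom. Under the null this calibration is exact when the
log-expression is approximately normal; the suite checks Kolmogorov–Smirnov
uniformity of null p-values at 2,000 genes. `moderated=False` restores the
plain Welch t. Zero-variance genes with equal means give t = 0, p = 1, so no
NaNs propagate.

BH adjustment is the step-up definition (delegated to statsmodels and
verified against a brute-force oracle). All thresholding is strict:
|log2FC| > 2 excludes a gene at exactly 2, FDR < 0.01 excludes exactly 0.01.

## Signature derivation

The shared-effect filter requires a gene to pass the thresholds at 24 h in
*both* cell-line models with the *same* fold-change sign
(`require_sign_concordance=True`; discordant genes do not share an effect and
the signature is unidirectional by construction — the flag exists because the
original selection is ambiguous on this point). k-means runs on the
mean-centered logCPM profiles across all 24 samples: Lloyd's algorithm,
k-means++ initialization, 50 restarts keeping the lowest inertia, 300
iterations maximum, fixed seed. Cluster labels are arbitrary; selection uses
only the onset score: the mean over cluster genes of (mean logCPM in Dex 8 h
samples − mean logCPM in vehicle samples). `control_scope` decides whether
"vehicle" means all vehicle samples (default; the onset is then robust to
slow drift in the controls) or vehicle 8 h only; `onset_stat` offers a median
alternative to the mean. The argmax-onset cluster must have onset > 0 —
otherwise the derivation errs rather than return a downregulated
"signature". Ties in onset break by the larger Dex 24 h − vehicle
difference, then by the smaller cluster label.

Scoring is the plain sum of log-expression over signature genes. Up to half
the signature may be missing from a target matrix (cross-platform
application): missing genes warn, more than half errs and lists them.

## Survival analysis

Stratification uses type-7 (linear-interpolation) quantiles — a concrete,
testable convention; boundary ties are inclusive on both sides (score ≤ Q1 is
Low, score ≥ Q3 is High), and the degenerate case Q1 = Q3 assigns everyone to
Intermediate with a warning. Kaplan–Meier and the log-rank test are delegated
to lifelines. The Cox model is fitted in-house: scalar Newton iterations on
the Breslow partial likelihood to gradient < 1e-8, Wald standard error from
the observed information. Breslow tie handling was chosen (over lifelines'
Efron) because it makes the estimate exactly invariant to duplicating every
patient, a property the suite asserts; on tie-free data the two agree to
about 1e-7. Divergence (|β| > 50) and non-convergence raise errors —
complete separation has no finite maximizer. The High-vs-Low expression
comparison uses the independent-sample two-sided rank-sum test: the strata
are independent patients, so a matched-pairs test would be inappropriate; a
constant gene returns p = 1.

## Cistrome

All coordinates are BED-style 0-based half-open. Peak enrichment filtering
is strict (> 2 in ≥ 1 sample); the log base of the enrichment columns is
whatever the caller provides (the generator writes log2 over input).
Regulatory domains follow basal-plus-extension: basal = 5 kb upstream / 1 kb
downstream of the TSS, strand-oriented; each basal edge then extends outward
by at most `distal_limit`. Two conventions are deliberate:

- The default `distal_limit` is 1,000 bp. The method this mirrors
  conventionally uses a megabase-scale distal limit, but the analysis being
  reproduced states 1 kb; the parameter is explicit so either regime is one
  argument away.
- Extensions never cross the midpoint of the gap between neighboring basal
  domains (both neighbors use the same floored midpoint, so adjacent domains
  can abut but only *basal* regions may overlap). Unrestricted
  extension-to-neighbor-basal would let both flanking genes claim the entire
  gap; the midpoint split keeps assignments disjoint outside basal regions
  and makes the construction order-independent.

A peak belongs to every gene whose domain contains its midpoint,
floor((start + end)/2), with half-open containment; midpoint membership (not
any-overlap) keeps each peak's gene set small and deterministic, and an
any-overlap variant is a one-line change in `assign_peaks`. ER/GR co-binding
first merges overlapping peaks within each factor, then labels a merged
region `shared` on ≥ 1 bp cross-factor overlap, merging the shared pieces
across factors.

## Enrichment

Weight p = 1 by default (the pre-ranked default of the tool family),
configurable to 0. The null permutes gene labels (random same-size sets), not
samples, because the pipeline runs on pre-ranked statistics. The p-value is
sign-stratified — (1 + #{same-sign permutation ES at least as extreme}) /
(1 + #same-sign permutations) — so its smallest attainable value depends on
how many permutations land on the observed sign; NES divides ES by the mean
|same-sign permutation ES|. Exact magnitude ties between the positive and
negative running-sum extrema resolve to the positive deviation (tolerance
1e-9, shared by the O(k) permutation path and the full walk). The leading
edge contains the hits up to the positive extremum, or from the negative
extremum onward. Note the classic monotonicity property ("promoting a member
never decreases ES") is a theorem only at weight 0; at weight 1 the promoted
member's |statistic| changes with its position, so the property test runs
unweighted.

## Proteomics

Channel equalization scales every channel to the mean channel total —
within-channel ratios are preserved exactly, and the operation is idempotent.
Rollup sums PSM intensities per protein and channel; unmapped PSMs are
excluded and counted. Differential abundance works on log2(x + 1)
intensities with a Welch t (an optional pooled-variance moderation with prior
df = 4 approximates the moderated statistic of the original tooling);
significance is strict |log2FC| > 0.5 and FDR < 0.05. Reporter-ion impurity
adjustment is out of scope — normalization starts at channel equalization.

## Synergy

The combination index CI = (AB·C)/(A·B) is unit-free, symmetric in the two
drugs, and compared strictly to 1 (an ε tolerance is available but defaults
to 0, matching the bare inequality). Replicates are averaged per arm before
the test; a seeded bootstrap over replicates provides a percentile interval
when requested.

## What the generators emulate — and what they do not

The count generator reproduces the *design* of the experiment (2 models ×
{vehicle, Dex} × {8 h, 24 h} × 3 replicates = 24 samples) with four planted
classes — early classes respond at both timepoints, late classes only at
24 h — and per-model fold-change jitter (SD 0.1 log2) so the both-models
intersection is a real filter. Defaults (5,000 genes, 60 genes per class,
effect 3 log2, φ = 0.1, library sizes 5–15 M) are artifact choices at
desk scale: large enough for stable BH behavior and k-means geometry, small
enough that the whole derivation runs in under a second. Mean vectors are
renormalized to the target depth after planting effects, so composition bias
is present and TMM has real work to do. Not emulated: read-level data, GC or
length bias, batch effects, outlier samples, correlated genes.

The cohort generator draws iid normal log-expression around fixed gene
means, plants the hazard on the *standardized true score*
(h = h₀·e^{βz}, exponential event times, administrative censoring), and
solves h₀ by Gauss–Hermite quadrature so the expected event fraction is 60 %
— which keeps log-rank power stable at the default n = 800. *ESR1* is a
designated column, α − γz + noise, with γ = 0.6 planting the anti-correlation
the clinical comparison looks for. Not emulated: covariate-dependent
censoring, non-proportional hazards, cohort substructure.

The genome generator places genes with ≥ 10 kb spacing on two 1.5 Mb
chromosomes, gives 60 % of genes a GR peak whose midpoint falls inside the
basal domain, adds background peaks with low enrichment (so the enrichment
filter is exercised), and retains 40 % of ER 1 h peaks at 24 h — a
qualitative echo of the genome-wide ER-binding loss after prolonged Dex. The
TMT generator plants 10 % of 400 proteins at ±2 log2 with channel load
factors spanning 0.7–1.4; the viability generator produces C, aC, bC and
abC(1 − σ) with σ = 0.3 and 5 % multiplicative noise over 5 replicates.
Passing tests therefore demonstrate that the *algorithms* recover planted
structure under their stated models — not that real cohorts or cistromes
satisfy those models.

## Reproducibility conventions

Every generator draws from a named substream of one integer seed
(`default_rng([seed, crc32(name)])`), so partial reruns are bit-identical
and independent across generators. Simulation sizes used by the test suite
and the acceptance script (10 derivation seeds, 200 Cox recovery
simulations, 1,000 scaled-down log-rank null cohorts at n = 200, 100 random
toy genomes, 200 random enrichment instances) are the package's chosen
compromise between statistical resolution and a suite that completes in
about a minute on one CPU.

## Known limitations

- The DE statistic is a moderated t on logCPM, not a count-likelihood model;
  at very low counts its calibration degrades before a GLM's would.
- The Cox fit is univariate by design; multivariate adjustment and competing
  risks are out of scope.
- Regulatory domains implement the literal 1 kb distal default, so distal
  enhancer assignments require raising `distal_limit`.
- The permutation p-value is fixed-n (no adaptive refinement); its floor is
  set by `n_perm` and the sign split.
- The exact published 52-gene signature is not reproducible here: it depends
  on the original raw data and tool versions. The pipeline reproduces the
  *procedure* and is validated by planted-truth recovery instead.
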