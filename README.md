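# grsig

Glucocorticoid-receptor (GR) activation by dexamethasone (Dex) silences
estrogen receptor (ER) signaling in ER+ breast cancer. `grsig` is a tested
reimplementation of the computational pipeline behind that observation, for
computational biologists who want to derive a **GR activity gene signature**
from a Dex time-course RNA-seq experiment and evaluate it clinically and
mechanistically:

- **normde** — TMM normalization, logCPM, low-expression filtering, and
  per-contrast differential expression (moderated t on logCPM with
  Benjamini–Hochberg correction).
- **signature** — signature derivation: genes with a shared effect in both
  cell-line models at 24 h (|log2FC| > 2, FDR < 0.01, concordant sign),
  k-means (k = 4) on mean-centered logCPM, and selection of the cluster with
  the strongest expression onset (Dex 8 h vs vehicle); plus early/late
  response-timing classification and total-log-expression scoring.
- **survival** — quartile stratification (High / Intermediate / Low),
  Kaplan–Meier curves, log-rank test, and a univariate Cox
  proportional-hazards fit (Breslow ties); per-gene comparison across strata
  (e.g. *ESR1*).
- **cistrome** — ChIP-seq peak filtering (chrM/chrX/chrY, blacklist,
  log-enrichment > 2 in ≥ 1 sample), ER/GR co-binding classes, GREAT-style
  basal-plus-extension regulatory domains (5 kb up, 1 kb down, distal cap),
  midpoint peak-to-gene assignment and gene-set proximity fractions.
- **enrich** — pre-ranked gene-set enrichment: weighted Kolmogorov–Smirnov
  running sum, gene-permutation null, sign-stratified p, NES, BH across sets.
- **proteome** — TMT reporter-channel equalization, PSM→protein rollup,
  differential abundance (|log2FC| > 0.5, FDR < 0.05), RNA–protein logFC
  concordance.
- **synergy** — the four-arm viability rule AB/C < (A/C)(B/C), i.e.
  combination index CI = (AB·C)/(A·B) < 1.
- **simulate** — generators for every input with planted ground truth
  (negative-binomial counts with early/late up/down classes, cohorts with a
  planted log-hazard per SD of signature score and planted *ESR1*
  anti-correlation, toy genomes with factor peak sets, TMT reporter matrices
  with channel loading biases, viability plates with planted synergy), so the
  whole pipeline is testable without any external download.

## The model in brief

Counts are NB(μ, φ) with Var = μ + φμ². Normalization factors are trimmed
means of M-values (double trim 30 % on M, 5 % on A, precision-weighted,
75th-percentile reference), and
logCPM<sub>gs</sub> = log2((y<sub>gs</sub> + c) / (N̂<sub>s</sub> + 2c) · 10⁶)
with effective library size N̂<sub>s</sub> = N<sub>s</sub>·f<sub>s</sub> and
prior count c = 0.5. Cohort event times are exponential with hazard
h₀·exp(β·z), z the standardized signature score; the Cox partial likelihood is
maximized by Newton's method. The enrichment running sum increments by
|r|^p/N<sub>R</sub> at set members and decrements by 1/(N − N<sub>hits</sub>)
otherwise; ES is the signed maximum-magnitude deviation.

## Worked example

```python
from grsig import simulate, signature, survival, synergy

counts, samples, truth = simulate.simulate_counts(simulate.SimCountConfig(seed=1))
sig = signature.derive_signature(counts, samples, signature.SignatureParams(seed=1))

cfg = simulate.SimCohortConfig(seed=1)
cohort, _ = simulate.simulate_cohort(cfg)
cosig = signature.Signature(gene_ids=tuple(cfg.resolved_signature()),
                            cluster_label=0, onset_scores={0: 1.0}, inertia=0.0)
scores = signature.score_cohort(cohort, cosig)
z = (scores - scores.mean()) / scores.std(ddof=0)
fit = survival.cox_fit(cohort["time"], cohort["event"], z)

plate, _ = simulate.simulate_viability(simulate.SimViabilityConfig(seed=1))
res = synergy.synergy_table(plate)
```

prints (via the surrounding report statements):

```
signature: 59 genes from cluster 3 (onset 2.97 log2 units)
stage counts: 5000 genes -> 4996 after filtering -> 237 shared-effect -> 59 in signature
Jaccard vs planted early-up genes: 0.983
Cox HR per SD of score: 0.416 [0.375, 0.462], log-rank p = 4.71e-50
combination index: 0.728 (synergistic: True)
```

The derived signature recovers the planted early-upregulated class almost
exactly (Jaccard 0.98); a one-SD increase of the signature score more than
halves the hazard (HR 0.42, planted β = −0.8 ⇒ HR 0.45), the three score
strata separate sharply in survival, and the plate with planted synergy depth
0.3 yields CI ≈ 0.7 < 1.

The same steps are available from the shell via the `grsig` command
(`grsig simulate counts …`, `grsig derive-signature …`, `grsig survival …`,
`grsig synergy …`; see `grsig --help`).

## Layout

```
src/grsig/        library modules (simulate, normde, signature, survival,
                  cistrome, enrich, proteome, synergy, io, cli)
tests/            pytest suite, incl. brute-force oracles in tests/oracles.py
scripts/          acceptance.py
docs/methods.md   modeling choices, defaults and limitations
```
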