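# Methods

## Scope and data model

The package analyses biparental F1 populations genotyped on a fixed panel
of biallelic SNP markers, with a single quantitative phenotype (fruit
weight, grams). Genotypes are stored as call codes (0 hom-reference,
1 heterozygous, 2 hom-alternate, −1 missing); on disk they are two-letter
allele strings ("AA", "CA", "CC", with "CA" ≡ "AC") in TSV, a numeric
0/1/2 dosage dialect, or biallelic VCF. Missing data are excluded
per-marker from all frequency counts, per-individual from association
grouping, and contribute zero terms (tallied) in prediction.

## Phenotype variation statistics

For n F1 weights with mean X̄ and sample SD S (n − 1 denominator; the
convention is not forced by the formulas, sample SD is the standard
choice for breeding-population CV):

* CV% = S/X̄ · 100; scale-invariant.
* MP = (female mean + male mean)/2; always recomputed from the parental
  means, never taken from a report.
* Ta% = X̄/MP · 100 and H% = (X̄ − MP)/MP · 100; Ta − H = 100 identically,
  which the tests assert.
* RH%/RL% count individuals **strictly** above the high parent / below
  the low parent; ties count as neither (the verbal definitions
  "exceeding"/"below" leave ties open; the strict reading is the
  conservative one).
* Normality: one-sample Kolmogorov–Smirnov against a normal with
  sample-estimated mean and SD — the classic SPSS-style test. Because
  estimating the parameters from the same sample makes plain KS
  anti-conservative, a Lilliefors-corrected p (statsmodels) is available
  via `ks_normality(..., lilliefors=True)`; the default stays plain KS
  for comparability with common practice.

## Marker diversity

With reference-allele frequency p estimated from the called genotypes
(p = (2·hom_ref + het)/(2N)) and q = 1 − p:

* PIC = 1 − (p² + q²) − 2p²q² (general multi-allele double-sum evaluated
  for two alleles; biallelic maximum 0.375 at p = 0.5). Clamped at 0
  against floating-point cancellation near p ∈ {0, 1}.
* Ne = 1/(p² + q²); Ho = het/N; He = 1 − (p² + q²); hence
  Ne = 1/(1 − He) ∈ [1, 2], asserted as a property.
* Hardy–Weinberg: χ² = Σ(O − E)²/E over the three genotype classes with
  E = N(p², 2pq, q²), df = 1, allele frequency estimated from the same
  sample. No Yates continuity correction by default (the plain statistic
  is the textbook form); `yates=True` provides the corrected variant.
  Monomorphic markers raise a distinct error and are reported with NaN
  HWE fields rather than p = 1, so "no information" is distinguishable
  from "conforming".
* Polymorphism classes: low (PIC < 0.25), moderate (0.25 ≤ PIC < 0.5),
  high (≥ 0.5, unreachable for a biallelic locus but kept for
  generality). The screening boundary is **inclusive** (PIC ≥ 0.25),
  with a strict variant behind `strict_pic`; the inclusive reading
  matches the class definition that moderate polymorphism *starts* at
  0.25.

## Marker-trait association

Markers eligible for testing are, by default, the moderate-PIC,
HWE-conforming loci of the population (`mta_all_polymorphic=True` tests
every polymorphic locus instead). Per marker:

1. Individuals are grouped by genotype; groups below `min_group_n = 3`
   are dropped (Shapiro–Wilk is undefined below 3); markers with fewer
   than two surviving groups are recorded as untested.
2. Shapiro–Wilk per group and Levene's test (mean-centred; median-centred
   Brown–Forsythe behind a flag) gate the test choice at
   `assumption_alpha = 0.05`: ANOVA (≥ 3 groups) or t-test (2 groups)
   when all pass, otherwise Kruskal–Wallis or Mann–Whitney U (midranks,
   tie-corrected).
3. Significant ANOVAs get Tukey HSD pairwise comparisons; significant
   Kruskal–Wallis tests get Dunn's test with Bonferroni adjustment
   (implemented directly: pooled midranks, tie-corrected variance
   S² = N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided normal p times the
   number of pairs, capped at 1).
4. Benjamini–Hochberg step-up q-values are computed across **all tested
   markers of one population** (per-population correction matches
   per-population reporting; a pooled-across-populations analysis can be
   assembled by concatenating groups, but is not the default).
   Association is significant at raw p < 0.05 **and** q < 0.05.

`bh_adjust` is implemented directly (sorted p·m/rank with a reverse
cumulative minimum); tests verify it against the O(m²) step-up
definition and against statsmodels. Note BH is *not* idempotent —
re-adjusting q-values inflates them (e.g. [1.0, 0.25] → [1.0, 0.5] →
[1.0, 1.0]) — so no such property is claimed.

## Marker combinations

Per population: `full` (whole panel, panel order), `pic_hwe` (PIC ≥ 0.25
and HWE p > 0.001 — the severe-deviation screen), `mta` (FDR-significant
markers; may be empty). With defaults, mta ⊆ pic_hwe ⊆ full. Sizes are
entirely data-driven; no published per-population counts are encoded.

## GAP model

GPV = α·Fx + γ·Σᵢ GnEᵢ + μ + β.

* **μ** — training-population phenotypic mean.
* **GnE** — the genotype effect of a non-fixed marker, estimated as the
  mean training phenotype of carriers of that genotype minus μ. This
  marginal (per-marker) estimator is the most direct reading of
  "genotype effects"; it is *not* a joint fit, so each marker's effect
  absorbs a little of the other markers' genetic variance. On noiseless
  additive data with 10 comparable markers at n = 300 this caps
  training-set self-consistency near r ≈ 0.98 rather than 1.0 — a known
  and accepted property of the estimator.
* **γ** — shrinkage coefficient, chosen from a grid (default 0.1–1.0 in
  steps of 0.1) by 5-fold cross-validation of the raw score μ + γ·ΣGnE,
  with effects re-estimated within each training fold; folds are
  shuffled under the caller's seed.
* **Fx, α** — the panel studied here declares no fixed-effect markers,
  so the default fixed set is empty and α is recorded as 0. When fixed
  markers are declared, their summed genotype effects form Fx and (α, β)
  are estimated jointly by least squares of the residual
  y − (μ + γ·ΣGnE) on Fx.
* **β** — with no fixed markers, the least-squares intercept of the
  final score with slope held at 1, i.e. the mean training residual
  (≈ 0 when effects are mean deviations). An unconstrained slope would
  have nowhere to live in the GPV formula, whose ΣGnE coefficient is γ
  by definition.
* **Prediction** — genotypes unseen in training and missing genotypes
  contribute 0 and are tallied per individual; an individual with every
  combination genotype missing degenerates to GPV = μ + β and is
  flagged.
* **Accuracy** — Pearson r between GPV and OPV on paired individuals,
  two-sided p from the t distribution with n − 2 df, stars at
  0.05/0.01/0.001. Undefined (reported NA) below 3 pairs or when either
  series is constant — notably when the mta combination is empty.
  Negative r is reported as-is, never folded to |r|.
* **Evaluation protocols** — because an external training population
  with pre-estimated effects is not among the package's inputs, the
  pipeline estimates within-population accuracy by k-fold
  cross-validation (each individual's GPV comes from a model fitted
  without it; default 5 folds). Train-on-one-population /
  predict-another is available through `gap-fit` / `gap-predict`.
  Whether α/β should be refit per validation population is left to the
  caller; both modes exist (`fit_gap` on the validation data refits,
  serialised models freeze them).

## Synthetic study generator

`simdata.default_config(seed)` defines the study conditions:

* **Design** — six biparental F1 populations of 80, 75, 137, 113, 80 and
  88 offspring (573 total), 70 biallelic SNPs across 17 chromosomes,
  simulated unlinked (no linkage map is imposed; a per-chromosome
  correlation model is out of scope).
* **Mendelian segregation** — each offspring receives one uniformly
  random allele from each parent per marker, so markers segregate 1:2:1
  (het × het), 1:1 (hom × het), all-het (opposite homozygotes) or not at
  all, depending on the parents.
* **Parents** — 30% of markers are fixed for their major allele in every
  parent, emulating panel markers ascertained in unrelated mapping
  populations; at the remaining markers the five cultivar × cultivar
  crosses draw parents with heterozygote probability 0.10 and
  minor-homozygote probability 0.05, and the wild × cultivar cross
  (QxRX) with 0.22/0.12. This yields ~40/70 markers polymorphic
  somewhere in the study and roughly 8–32 moderately polymorphic loci
  per population, with the wild cross the most diverse — the structure
  reported for real multi-family apple panels.
* **Phenotypes** — weight = 180 g + Σ dosage·effect + N(0, 25 g),
  clipped below at 1 g. Ten causal markers (every 7th panel position)
  carry additive effects of 7–15 g per alt allele, alternating sign.
  Across the whole panel this implies h² ≈ 0.45 *when all causal loci
  segregate*; in any one population most causal loci are monomorphic, so
  realized per-population heritability and CV (≈ 10–12%) are lower than
  in wide real crosses (CV 20–44%) — a deliberate portrait of a panel
  with population-specific usefulness rather than of maximal diversity.
* **Missingness** — 2% of calls at random (applied after phenotype
  generation, so phenotypes reflect true genotypes).
* **Determinism** — all randomness flows from `SimConfig.seed` through
  spawned SeedSequences; identical configs give byte-identical files.

### What the generator does and does not emulate

It reproduces the study *structure* (population sizes, panel size,
population-specific monomorphism, segregation classes, additive effects,
environmental noise). It does not imitate real allele frequencies,
linkage, dominance or epistasis, genotyping error, or shared parentage
between crosses beyond the fixed-marker backbone. Passing tests
demonstrate that the statistics and the screening logic behave correctly
under Mendelian additive conditions, not that any particular real panel
will achieve a particular accuracy.

## Simulation studies (studies.py)

* **Published-cross arithmetic** — the six published apple crosses'
  parental and F1 means are inputs; MP, Ta and H are recomputed through
  the variation-summary code path. One published row (YxH) is internally
  inconsistent (its printed MP is not the mean of its printed parent
  means) and is flagged, not reproduced; a second (QxRX) has an
  inconsistent MP but Ta/H consistent with the recomputed MP, so only
  those are compared.
* **Global null** — 2,000 replicates of a fully segregating 70-marker
  cross (n = 100) with pure-noise phenotypes; measures the raw
  p < 0.05 rate (nominal 0.05) and the mean count of FDR-significant
  markers per study. The observed raw rate sits a hair above 0.05
  (≈ 0.0515) because the rank tests' asymptotic p-values are slightly
  liberal at these group sizes; it stays within 3 binomial SDs of
  nominal at 140,000 tests.
* **Screening benefit** — 50 replicates at h² = 0.9: 10 causal
  markers (effect 10 g) among 70, training and validation crosses of
  n = 500. Non-causal markers are split between 1:2:1 segregation
  (retained by the PIC+HWE screen, removed only by MTA) and 1:1
  backcross-type segregation (removed by the HWE screen, since a 1:1
  population deviates sharply from Hardy–Weinberg proportions at
  n = 500), so the three tiers differ genuinely. Mean validation r runs
  ≈ 0.85 (full) < 0.88 (PIC+HWE) < 0.93 (MTA), the screening benefit the
  workflow exists to deliver.
* **Mendelian conformance** — χ² goodness-of-fit of simulated 1:2:1 and
  1:1 segregation at n = 10,000.

Problem sizes above are the package's reference sizes; the
`analysis/06` driver runs scaled-down versions (200 and 20 replicates)
for a quick look, and `scripts/acceptance.py` runs the full sizes.

## Numerical and degenerate-input choices

* Sample SD throughout (ddof = 1); variation summary requires n ≥ 2,
  KS requires n ≥ 5 and non-constant data.
* HWE on a monomorphic marker: distinct error, NaN in tables; such
  markers can never enter the PIC+HWE tier anyway (PIC = 0).
* A combination marker monomorphic in training collapses to one effect
  entry and contributes a constant to every GPV (harmless).
* `bh_adjust` uses a stable mergesort so tied p-values keep input order.
* Thresholds in effect are echoed into every CLI report header.

## Known limitations

* The GnE estimator is marginal, not joint; correlated markers
  double-count shared signal. Fine for unlinked panels, biased under
  linkage.
* MTA is group-comparison only — no kinship or mixed-model correction,
  so it is a within-family tool, not a GWAS.
* Accuracy by within-population CV answers "how well does a model
  trained in this family predict this family"; transfer to other
  families must be measured with the two-population protocol.
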