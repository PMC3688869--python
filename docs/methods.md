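# Methods

This note records the models, conventions and numerical choices behind
`mircohort`, and what the synthetic cohorts do and do not establish about
real data.

## Synthetic cohort model

The generator emulates the statistical structure of a deep-sequenced
tumor miRNA cohort. Its defaults are the study conditions every
calibration test runs under:

| parameter | default | meaning |
|---|---|---|
| `n_mirnas` | 523 | expressed mature miRNAs |
| `n_samples` | 88 | patients |
| `reads_per_sample` | 20 000 | mean sequencing depth (Poisson) |
| `top5_share` | 0.537 | expected share of miRNA reads in the top 5 |
| `frac_core_length` | 0.979 | read lengths in 19–23 nt |
| `class_props` | 0.61 / 0.04 / 0.02 / 0.3295 / 0.0005 | mature / hairpin / snoRNA / intronic-intergenic / other |
| `multimap_frac` | 0.10 | miRNA reads with > 1 alignment |
| `mismatch_rate` | 0.05 | reads aligned with one mismatch |
| `n_clusters` | 5 | miRNA gene pairs placed < 10 kb apart |

**Expression profile.** Per-miRNA weights follow a truncated power law
over ranks, w_i ∝ i^(−s), with the exponent solved numerically so the
expected top-5 share equals `top5_share` (s ≈ 1.26 at the defaults).
One parameter reproduces the observed extreme top-heaviness; the rest of
the concentration curve is then emergent, not fitted (the implied top-20
share is ≈ 73%). Per-sample RNA-class proportions are Dirichlet-drawn
around `class_props` with concentration `class_dispersion = 35`, chosen
so the mature fraction spans roughly 0.4–0.8 across 88 samples with its
median near 0.61.

**Sequencing depth.** The generator works at a mean depth of 20 000
reads per sample rather than the millions typical of a production run;
all per-read structure (lengths, classes, multimapping, mismatches) is
depth-independent, so calibration statistics are unchanged while the
whole cohort generates in seconds. Count-level noise is correspondingly
larger than at production depth, which the operating-characteristic
simulations inherit — power figures are therefore conservative.

**Annotation layout.** One synthetic chromosome. Each mature interval
(22–25 nt) sits inside a hairpin precursor with ≥ 35 nt of flank on the
3′ side, so hairpin-class reads (≤ 29 nt) always fit outside the mature
interval. Non-clustered miRNA genes are ≥ 10 kb apart; the `n_clusters`
pairs are 0.2–6 kb apart, making clustered pairs the only matures within
10 kb of each other. Read lengths are drawn from the global length
distribution and clipped to the mature length (a read is at most the
full mature sequence); mature lengths start at 22 nt so the clipping
moves < 0.5% of length mass into the 19–23 nt core.

**Multi-mapping.** 30% of miRNAs belong to paralog families of 2–4
members sharing one mature length; a family read gains alignments at the
homologous offset of every other member with a probability chosen so the
overall multimapped fraction equals `multimap_frac`, capped at 0.85 so
every family keeps uniquely-mapping reads in expectation — the
unique-ratio assignment rule is undefined without them. Requested
multimap fractions up to ≈ 0.25 are expressible without degeneracy.

**Clinical covariates and survival.** Eight clinicopathological
covariates are allocated by exact largest-remainder quotas from
cohort-like marginal frequencies (e.g. TNM 10/51/27 of 88) and shuffled;
`covariates` can be overridden (the test suite uses a 50/50 binary group
for balanced contrasts). Survival times follow a proportional-hazards
model with exponential baseline λ₀ = 1.6/follow-up and independent
Uniform(0, follow-up) censoring, giving P(event) = 1 − (1 − e^(−1.6))/1.6
≈ 0.50 in closed form. Planted expression effects multiply a named
miRNA's weight in a covariate stratum; planted survival effects
contribute β · (z − z̄) to the linear predictor, z the log2 expected
expression, so the downstream Cox coefficient estimates the planted β
directly.

**Randomness.** All streams derive from one seed: annotation, clinical,
per-sample biology, and per-run read noise are separate sub-streams, so
`run_id` 0/1 yields technical replicates with shared libraries and
independent sampling noise.

## Quantification conventions

- "Within a mature miRNA sequence" is read as *full containment* of the
  alignment interval, same strand. Overhang handling is genuinely
  ambiguous; containment is the strictest reading and is what the hit
  tests pin down. Overhanging reads from a mature locus still fall
  inside the hairpin and are classified as precursor reads.
- The ≥ 10-locus exclusion counts distinct loci after merging identical
  coordinates (keeping the best mismatch count), before precedence.
- "Unique" means: exactly one mature miRNA hit after perfect-match
  precedence. A read hitting the same miRNA at two loci counts once.
- Multimapped reads are pooled per distinct hit-set and split by unique
  ratios; groups with no unique reads are split equally, with a warning.
  Counts stay fractional — rounding would break mass conservation.
- Non-miRNA reads are classified by containment with priority
  mature > premature > other annotated classes > intronic/intergenic.
- A missing NM tag on input is treated as 0 mismatches with a warning.

**Known limitation — family flattening.** When per-sample unique counts
inside a paralog family approach zero (low depth × high multimap rate),
ratio assignment converges to an equal split and per-member differences
are attenuated; family *totals* remain correct. This is a property of
the assignment rule itself, visible at simulated depth, and is why the
statistical power checks plant effects on uniquely-mappable miRNAs.

## Normalization and filtering

- Factor = denominator/10⁶; four denominators are carried per sample and
  any can be selected; with the miRNA-mapped denominator every sample's
  miRNA total is exactly 10⁶.
- "Fewer than 10 reads across all samples" is implemented as *row sum
  < 10* (the stricter reading); `mode="all"` gives the per-sample
  reading. The statistic is computed on raw counts while the zeroing is
  applied to the normalized matrix, matching a filter defined on read
  counts but applied after normalization.
- log2(x+1): the pseudocount keeps zeros at zero; no claim is made about
  variance stabilisation.

## SAM test

- s₀ is chosen by the percentile-minimisation rule: candidates are the
  0, 5, …, 100th percentiles of the per-feature pooled SE; the candidate
  minimising the coefficient of variation of the median absolute d
  across 100 SE-quantile bins wins. A fixed s₀ can be supplied.
- The permutation null enumerates all C(n, n₂) label assignments when
  there are no more than the requested permutations, otherwise samples
  that many distinct assignments without replacement.
- q_i = (median over permutations of null |d| exceedances of |d_i|) /
  (observed exceedances), capped at 1, then cumulative-minimised from the
  smallest |d| threshold upward so q never increases with |d|. No π₀
  estimate is applied (π₀ = 1), which is conservative under the null.
- Constant features (e.g. rows zeroed by the filter) get d = 0 by
  convention rather than 0/0.
- Fold changes are computed on normalized un-logged values with the
  signed convention r vs −1/r; when exactly one group mean is zero both
  means get the +1 pseudocount; when both are zero the fold change is
  NaN.

## Survival screens

- Univariate Cox: single-covariate Newton iteration on the partial
  likelihood, Breslow ties by default (Efron available), convergence at
  |score| < 10⁻⁸ with steps clipped to ±2 for stability, covariate
  centred before exponentiation. Wald p-values; BH adjustment across
  miRNAs. Non-identifiable rows (no events, constant covariate) raise,
  or are reported as NaN by the screen.
- LASSO Cox: coordinate-descent path via scikit-survival's Coxnet
  (l1_ratio = 1), 50 penalties, `alpha_min_ratio = 0.01`. Cross-validated
  partial likelihood uses the Verweij–van Houwelingen decomposition
  (full-data log PL minus training log PL at the training fit), with
  folds re-drawn until every training part has ≥ 2 events.
- Penalty choice defaults to the **one-standard-error rule**: the
  strongest penalty whose CV curve is within one SE of the optimum. The
  plain CV maximiser is available (`rule="max"`), but near its top the
  CV curve is flat relative to its fold-to-fold SE and the argmax then
  picks up noise covariates: on null 300-miRNA/88-sample cohorts the max
  rule returned a non-empty selection in about half of the runs, while
  the 1-SE rule returns the empty set essentially always — the behaviour
  a sparse selector should have under the null.
- Expression enters both screens as log2(normalized + 1).

## Clustering and concordance

- Two-way clustering is independent WPGMA on rows and columns of the
  same matrix (the standard heatmap double dendrogram), Euclidean
  distance, tie-breaks by smallest pair of node ids so merge histories
  are deterministic and oracle-comparable.
- Replicate concordance regresses run 2 on run 1 per-miRNA totals
  (normalized, log2). Identical replicates give slope 1, intercept 0,
  R² = 1 — the identity line, which is what "excellent agreement"
  corresponds to.
- qRT-PCR relative expression is 2^(−ΔCt) against the reference assay;
  undetected wells propagate as missing, never as zero. Platform
  regression reports per-assay OLS R² (symmetric in simple OLS, so the
  direction choice does not affect it).

## Enrichment

Plain one-sided hypergeometric tail (EASE-style overlap−1 variant behind
a flag); the universe defaults to all genes in the GMT. p-values are BH
adjusted across sets after dropping sets below the overlap floor.
Target lists are user input: miRNA→target databases are out of scope, so
specific pathway p-values from any particular database vintage are not
reproducible quantities and are not claimed.

## What the tests do and do not show

Passing calibration and operating-characteristic tests shows the
pipeline is internally consistent and recovers known truth under the
generator's assumptions: Poisson sampling of a fixed per-sample profile,
exact power-law concentration, alignment noise limited to one mismatch
and discrete paralog families, independent censoring. Real cohorts add
isomiR end-heterogeneity, adapter artefacts, batch effects, overdispersed
biological variation and non-independent censoring, none of which are
modelled; results on real data depend on upstream alignment quality,
which this package deliberately treats as input.
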