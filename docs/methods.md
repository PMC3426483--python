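# Methods

`radscan` re-implements, as a tested pipeline, the analysis chain of a
two-population RAD-seq genome scan: consensus genotyping of read stacks,
per-SNP F_ST estimation, minor-allele-count filtering, threshold sweeps,
LOESS differentiation profiles and the sister-RAD-site correlation
diagnostic — together with a synthetic-data generator whose purpose is to
reproduce the statistical structure that makes "uninformative"
(low-minor-allele-frequency) polymorphisms bias such scans.

## Consensus genotyping

A read stack is the set of aligned reads one individual contributed to one
RAD site. Genotyping proceeds in two steps:

1. **Base filtering.** Bases with a calling error probability strictly
   greater than `max_base_error` (default 0.01) are masked.
2. **Consensus calling.** Depth is the number of quality-passing reads
   covering the site. With depth ≥ `min_diploid_depth` (default 10) a
   diploid consensus is called: per position, the two most frequent bases
   enter a binomial test, and the position is heterozygous iff the binomial
   point probability of the observed split under p = 0.5 exceeds
   `het_likelihood_threshold` (default 0.01). Below that depth only a
   haploid majority consensus is called — the binomial test has too little
   power there.

The "likelihood" is the binomial pmf, not a tail probability. A
consequence worth knowing: at depth 10 a 9/1 split is homozygous
(10/1024 ≈ 0.0098 < 0.01) while 8/2 is heterozygous (45/1024 ≈ 0.044).
The depth rule is applied per site after quality masking, with
per-position missingness where no base passes. Ties (majority base, or
second-most-frequent base) are broken by the lower summed error
probability, then alphabetically, so calls are deterministic. Positions
with more than two observed bases keep the two most frequent; the rest
are treated as presumptive errors.

## F_ST estimators

Two estimators for the two-population, biallelic case:

**Weir–Cockerham theta** (`wc_theta`), the variance-components estimator
theta = a / (a + b + c) with the standard among-population (a),
among-individual (b) and within-individual (c) components for r = 2,
computed from observed genotype counts (observed heterozygote
frequencies, no Hardy–Weinberg assumption). It requires diploid
genotypes; on mixed haploid/diploid pools it is computed on the diploid
individuals only.

**Haplotype-diversity F_ST** (`haplotype_fst`), the default for consensus
pools that mix ploidies: each diploid genotype contributes two haploid
genomes and each haploid one. With unbiased diversity
H = (n/(n−1))(1 − Σ p_k²) — exactly the probability that two genomes
drawn without replacement differ — the estimate is (H_T − H_S)/H_T,
where H_T is the pooled-sample diversity and H_S combines the two
within-population diversities.

H_S weighting is a configurable formula slot; the default weights the
population diversities by their genome counts. The weighted form pins a
pooled singleton at exactly zero F_ST for *any* sample sizes
(H_S = H_T = 2/N), which is the property that makes rare alleles
uninformative; the unweighted mean loses it under unbalanced sampling (a
singleton in the larger of two populations of n_a < n_b genomes reaches
(n_b − n_a)/(2 n_b), e.g. 0.275 at 27 vs 60). Since the study design this
package emulates had strongly unequal coverage between populations, the
weighted form is the default and the unweighted mean remains available via
`hs_weighting="unweighted"`.

Raw estimates may be negative; they are clipped to [0, 1] downstream, per
position, *before* per-site aggregation. For RAD sites with multiple SNPs
the default aggregation keeps the maximum clipped value (ties: leftmost
position); mean and random-SNP aggregation are provided as alternatives.

## Marker filters

- **Coverage gate:** a RAD site enters the analysis only if every
  population contributed at least `min_genomes_per_pop` haploid consensus
  genomes (default 27 — one genome per sampled individual on average when
  27 individuals are sampled).
- **Minor-allele-count threshold n:** a SNP is retained iff its less
  frequent allele occurs at least n times in the pooled two-population
  sample (inclusive boundary; on an exact 50/50 split either allele
  qualifies). n = 1 keeps everything; n = 2 removes exactly the singleton
  loci; retained sets are nested in n. The gate applies per variable
  position before per-site aggregation. A proportional (frequency-based)
  threshold is available as a convenience flag but is not the tested
  default.

## Genome-scan outputs

- **Threshold sweep:** per n, the number of retained SNPs and the mean
  clipped F_ST (over per-site aggregated values by default; per-SNP with a
  flag).
- **LOESS profile:** locally weighted quadratic regression with tricube
  weights, neighbourhood = `floor(span · n_records)` nearest records
  (span default 0.4, degree default 2), no robustness iterations,
  evaluated at record positions plus a uniform 1-kb grid, fitted per
  chromosome. The implementation agrees with R's `loess`
  (`degree = 2`, `span = 0.4`, `family = "gaussian"`,
  `surface = "direct"`) to ~1e-15 on random data; that cross-check is a
  test, not the implementation. "Band width 0.4" is interpreted as the
  span fraction of records, the convention of the named R facility, not a
  physical window.
- **Sister diagnostic:** Pearson correlation, per n, of aggregated F_ST
  between the two RAD sites flanking the same restriction cut, over pairs
  where both sides retain a passing SNP; reported missing below 10
  complete pairs. Rising correlation under filtering indicates that
  retained markers measure locus-level differentiation reliably.

## Synthetic data: the stated world

One candidate SNP per RAD site, with:

- **Site-frequency spectrum:** a mixture of the discretised neutral
  spectrum (P(i) ∝ 1/i over derived counts i = 1..G−1 in G pooled
  genomes) and a near-fixed component at frequency 1/(4G). The mixing
  weight is solved in closed form so that the expected singleton fraction
  among polymorphic loci equals `singleton_fraction_target` (default
  0.465, the fraction implied by the empirical 46.5% SNP-count drop when
  singletons are removed). Pooled counts under beta + binomial sampling
  are beta-binomial marginals, so the component singleton and
  polymorphism probabilities — and hence the weight — are exact; nothing
  is tuned by simulation.
- **Drift:** population frequencies follow the Balding–Nichols beta model
  around the ancestral frequency with a single differentiation parameter
  `drift_F` (default 0.05); under it E[theta] = F (identity-probability
  argument), which is what the parameter-recovery test checks.
  The near-fixed component deliberately bypasses the beta spread: it
  models *recent* mutations that have not yet experienced the
  between-population split (under the full drift model the singleton
  fraction conditional on polymorphism saturates near 0.43 at F = 0.05,
  below empirically observed values). These loci therefore carry no drift
  signal — which is precisely why they are uninformative.
- **Hitchhiking:** inside a selected region the two population
  frequencies are displaced toward opposite fixation by
  `max_effect · exp(−decay_per_bp · distance) · 4x̄(1−x̄)`.
  The heterozygosity factor is essential: the first-order response of a
  linked neutral marker to a sweep is proportional to x(1−x), so a rare
  marker allele — almost never associated with the favoured QTL allele —
  stays undifferentiated while a balanced marker picks up the full
  effect. Without it, every rare site near a sweep would acquire strong
  differentiation, contradicting the premise the package exists to
  demonstrate. Out-of-range frequencies are clamped with a warning
  (or rejected with `strict_frequencies=True`).
- **Sister pairs:** in sister mode the two sites flanking a cut share
  their Balding–Nichols quantiles (a copula on the drift deviation) while
  each site draws its own ancestral frequency and its own genotypes.
  Linked markers thus experience the same drift history but can differ in
  informativeness — the situation the sister diagnostic is designed to
  detect. Sharing the frequencies themselves would make pairs always
  concordant (clusters at (0, 0)) and the correlation would *fall* with
  filtering instead of rising.
- **Sequencing layer:** per individual and site, read depth is
  negative-binomial with the population's mean coverage (defaults 27 and
  31 reads) and dispersion 5 (Poisson in the limit of infinite
  dispersion); each 76-bp read copies one of the individual's two
  haplotypes uniformly; each base is miscalled with `base_error_rate`
  (default 0.001, roughly Q30) to a uniformly chosen other base.

All randomness derives from one root seed through named `SeedSequence`
substreams, so each stage is individually reproducible and two runs with
the same configuration are byte-identical.

### What the generator does not emulate

No linkage or recombination map beyond the pairwise sister copula; no
multi-SNP haplotype structure within a RAD site (one candidate SNP per
site); no PCR duplicates, allele-specific bias, indels or alignment
artifacts; no demography beyond the single drift parameter (no growth,
migration or bottlenecks); selection is a deterministic frequency
displacement, not a forward simulation. A green test therefore
establishes that the *analysis chain* behaves as described on data with
the stated frequency-spectrum and drift structure — not that any
particular empirical system matches that structure.

## Numerical choices

- Internal coordinates are 1-based inclusive; only the BEDGRAPH profile
  export converts to 0-based half-open intervals.
- theta is undefined (NaN / `ValueError`) for monomorphic loci, pools
  with a population lacking diploid genotypes, or zero total variance;
  haplotype F_ST for monomorphic pools or populations with fewer than two
  genomes. Undefined positions are skipped with a log message, never
  silently zeroed.
- LOESS solves the weighted normal equations in the locally centred and
  bandwidth-scaled coordinate, batched over evaluation points; a singular
  system falls back to the pseudoinverse, and fewer records than a
  quadratic fit needs lower the degree with a warning.
- Missing data are explicit (`None` calls, `.` on disk), never a sentinel
  allele.

## Known limitations

- Only the two-population case is implemented (matching the study
  design); the variance-components algebra is written for r = 2.
- The sequencing layer attaches the configured error rate as the per-base
  error probability (consistent with the realised miscall process) rather
  than emulating a full quality-score distribution; base-quality
  filtering is therefore exercised by constructed stacks in the tests.
- Mean F_ST at a threshold averages per-site aggregated values; whether
  an empirical mean should average per SNP or per site is a reporting
  choice, exposed as a flag.
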