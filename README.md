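# radscan

Genome scans for signatures of divergent selection compare marker
differentiation (F_ST) between two populations against a genome-wide
baseline. Polymorphisms with a very low minor allele frequency —
singletons above all — are *constrained* to show near-zero F_ST no matter
how strongly drift or hitchhiking has acted on their genomic
neighbourhood. If such "uninformative" markers are kept, the estimated
baseline is biased downward and sliding-window differentiation profiles
flatten, which can invert the conclusions of a scan. `radscan` implements
the full analysis chain of a two-population RAD-seq genome scan and a
synthetic-data generator that demonstrates this bias and the filtering
that removes it. It is aimed at population-genomics practitioners who
want a tested, scriptable reference for these steps.

## What it computes

- **Consensus genotyping** of per-individual read stacks: bases with
  calling error probability > 0.01 are excluded; ten or more passing
  reads give a diploid consensus with a binomial heterozygote test
  (heterozygous iff C(n,k)·0.5ⁿ > 0.01), fewer give a haploid majority
  consensus.
- **F_ST per SNP**, two estimators: Weir & Cockerham's
  θ = a/(a+b+c) from diploid genotype counts, and a haplotype-diversity
  F_ST = (H_T − H_S)/H_T with unbiased diversity
  H = (n/(n−1))(1 − Σp²) for pools mixing haploid and diploid calls.
  Negative estimates are clipped to zero; multi-SNP RAD sites keep the
  maximum per-site value by default.
- **Marker filtering**: a coverage gate (≥ 27 haploid genomes per
  population per site) and the minor-allele-count threshold *n* — a SNP
  is kept iff its minor allele occurs ≥ n times in the pooled sample.
- **Genome-scan outputs**: SNP counts and mean F_ST per threshold
  (n = 1..10), LOESS-smoothed chromosome profiles (2nd-order local
  polynomial, span 0.4, tricube weights, matching R's `loess`), and the
  correlation of F_ST between "sister" RAD sites flanking the same
  restriction cut — an empirical guide for choosing n.
- **Synthetic data**: two populations of 27 diploids, a rare-allele-skewed
  site-frequency spectrum with a calibrated singleton fraction,
  Balding–Nichols drift, heterozygosity-scaled hitchhiking around selected
  regions, negative-binomial coverage and sequencing error.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

Simulate a 1-Mb chromosome with 3,000 RAD sites (1,500 sister pairs),
drift F = 0.05, ~46% singleton loci and one selected region at 500 kb,
then run the whole chain:

```sh
cat > example.yaml <<EOF
seed: 7
sim:
  seed: 7
  n_individuals_per_pop: 27
  n_rad_sites: 3000
  chromosome_length: 1000000
  drift_F: 0.05
  sister_pairs: true
  selected_regions: [[500000, 0.4, 5.0e-6]]
use_stacks: false
n_range: [1, 10]
profile_thresholds: [1, 4]
EOF
radscan run --config example.yaml --outdir out
```

`out/sweep.tsv` (abridged) shows the baseline bias: half of all SNPs are
singletons, and removing them (n = 2) nearly doubles mean F_ST:

```
n   snp_count   mean_fst
1        1085   0.0322
2         561   0.0622
4         419   0.0802
10        292   0.1027
```

`out/profile_chr1_n1.bedgraph` and `..._n4.bedgraph` hold the smoothed
profiles: with every SNP included the selected region peaks at smoothed
F_ST 0.096, barely above the baseline, while filtering at n = 4 raises
the same peak to 0.241 — the flattening effect of uninformative markers.
`out/sister.tsv` shows the diagnostic rising from r ≈ 0.04 at n = 1 to
r ≈ 0.66 at n = 3–4 and stabilising, the empirical signature that
filtering has reached the informative markers.

The same stages are available as library functions
(`radscan.simulate_populations`, `radscan.call_consensus`,
`radscan.wc_theta`, `radscan.threshold_sweep`, `radscan.loess_profile`,
`radscan.sister_correlation`, ...) and as individual CLI subcommands
(`simulate`, `genotype`, `fst`, `sweep`, `scan`, `diagnose`).

For instance, the two reference genotype tables — an informative balanced
polymorphism and an uninformative nearly monomorphic one — evaluate to:

```pycon
>>> from radscan import wc_theta
>>> round(wc_theta({"TT": 5, "TC": 10, "CC": 5}, {"TT": 5, "TC": 10, "CC": 5}), 3)
-0.026
>>> round(wc_theta({"TT": 20}, {"TT": 19, "TC": 1}), 3)
0.0
```

identical allele-frequency distributions give (slightly negative,
clipped-to-zero) θ, and a singleton-bearing pool is pinned at zero even
though the populations could be strongly differentiated in its
neighbourhood.

## Acceptance script

`scripts/acceptance.py` recomputes the package's reference quantities
from scratch — it builds the two genotype tables above and runs the
Weir–Cockerham estimator on them — and writes the rounded values as
JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
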