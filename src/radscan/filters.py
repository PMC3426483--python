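"""Marker filters: coverage gate and minor-allele-count threshold.

The minor-allele-count threshold n is the filter at the heart of the
informative/uninformative marker distinction: a SNP is retained only if the
less frequent allele occurs at least n times in the pooled two-population
sample.  n = 1 keeps every SNP (the unfiltered default), n = 2 removes
exactly the singleton loci, and the sets of retained SNPs are nested as n
grows.  The coverage gate requires a minimum number of haploid consensus
genomes per population at a RAD site (a diploid genotype contributes two,
a haploid one) before any F_ST is computed.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence
from dataclasses import dataclass

from .fst import SnpSite

log = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Coverage and minor-allele filter settings.

    ``min_genomes_per_pop`` defaults to 27: with 27 sampled individuals it
    requires each individual to contribute at least one haploid consensus
    genome on average.  ``maf_threshold``, if set, additionally applies a
    frequency-based (proportional) minor-allele filter as a convenience;
    the count-based rule is the tested default.
    """

    n_min_minor: int = 1
    min_genomes_per_pop: int = 27
    biallelic_only: bool = True
    maf_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.n_min_minor < 1:
            raise ValueError("n_min_minor must be >= 1")
        if self.maf_threshold is not None and not 0.0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5)")


def genome_counts_by_population(pool: Sequence) -> dict[str, int]:
    """Haploid genomes contributed per population (diploid = 2, haploid = 1)."""
    counts: dict[str, int] = {}
    for g in pool:
        counts[g.population_id] = counts.get(g.population_id, 0) + g.ploidy
    return counts


def coverage_gate(pool: Sequence, config: FilterConfig | None = None) -> bool:
    """Whether a pooled RAD site has enough genomes in every population.

    Passes iff each population's haploid-genome count is at least
    ``min_genomes_per_pop``.  An absent population counts as zero genomes.
    """
    config = config or FilterConfig()
    counts = genome_counts_by_population(pool)
    if len(counts) < 2:
        return config.min_genomes_per_pop <= 0
    return all(c >= config.min_genomes_per_pop for c in counts.values())


def minor_allele_gate(site: SnpSite, config: FilterConfig | None = None) -> bool:
    """Whether a SNP's pooled minor allele occurs at least n times.

    The minor allele is defined on the pooled two-population sample; with an
    exact 50/50 pooled split either allele qualifies and the gate compares n
    against that shared count.  The boundary is inclusive (>= n).
    """
    config = config or FilterConfig()
    mac = site.minor_allele_count
    if mac < config.n_min_minor:
        return False
    if config.maf_threshold is not None:
        total = int(site.genome_counts.sum())
        if total and mac / total < config.maf_threshold:
            return False
    return True
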