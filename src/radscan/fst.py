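"""Population-differentiation estimators for biallelic SNPs and RAD sites.

Two estimators are provided for the two-population case:

``wc_theta``
    Weir & Cockerham's (1984) variance-components estimator theta for tables
    of diploid genotype counts.  theta = a / (a + b + c), where a, b and c are
    the among-population, among-individual-within-population and
    within-individual components, computed with observed heterozygote
    frequencies.  The raw value may be negative.

``haplotype_fst``
    F_ST based on unbiased haplotype (allele) diversity, suitable for pools
    that mix haploid and diploid consensus genotypes: each diploid genotype
    contributes two haploid genomes and each haploid genotype one.  With
    within-population diversities combined into H_S (weighted by genome
    counts by default, so a pooled singleton is pinned at zero) and the
    pooled diversity H_T, the raw estimate is (H_T - H_S) / H_T.

Raw estimates are clipped to zero downstream (``FstRecord.fst``), the usual
convention for genome scans, and per-RAD-site values are aggregated across
variable positions (max by default, the alternative rules being mean and a
randomly selected SNP).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

ESTIMATORS = ("theta", "haplotype")
AGGREGATIONS = ("max", "mean", "random")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SnpSite:
    """One biallelic variable position with per-population allele counts.

    ``counts`` holds haploid-genome allele counts with shape (2 populations,
    2 alleles), columns ordered (major, minor) by pooled count.  ``het_counts``
    counts heterozygous *diploid* individuals per population (needed by
    theta); ``genome_counts`` is the number of haploid genomes observed per
    population.  ``diploid_counts``, when available, restricts the allele
    counts to diploid calls only so that theta can be computed on mixed
    haploid/diploid pools.
    """

    chromosome: str
    position: int  # 1-based
    site_id: str
    alleles: tuple[str, str]  # (major, minor) by pooled count
    counts: np.ndarray
    het_counts: np.ndarray
    genome_counts: np.ndarray
    diploid_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.het_counts = np.asarray(self.het_counts, dtype=np.int64)
        self.genome_counts = np.asarray(self.genome_counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must have shape (2 populations, 2 alleles)")
        if np.any(self.counts < 0):
            raise ValueError("allele counts must be non-negative")
        if not np.array_equal(self.counts.sum(axis=1), self.genome_counts):
            raise ValueError("per-population allele counts must sum to genome_counts")
        if self.minor_allele_count < 1:
            raise ValueError("site is monomorphic (pooled minor allele count is zero)")
        if self.diploid_counts is not None:
            self.diploid_counts = np.asarray(self.diploid_counts, dtype=np.int64)

    @property
    def minor_allele_count(self) -> int:
        """Pooled count of the less frequent allele (both alleles if tied)."""
        pooled = self.counts.sum(axis=0)
        return int(pooled.min())


@dataclass(slots=True)
class FstRecord:
    """Raw and clipped F_ST for one SNP or one aggregated RAD site."""

    site_id: str
    estimator: str
    fst_raw: float
    minor_allele_count: int
    aggregation: str = "none"  # "none" for per-position records
    chromosome: str = ""
    position: int = 0

    @property
    def fst(self) -> float:
        """Clipped estimate: negatives rounded to zero, capped at one."""
        return float(min(max(self.fst_raw, 0.0), 1.0))

    @property
    def key(self) -> str:
        if self.aggregation == "none":
            return f"{self.chromosome}:{self.position}"
        return self.site_id


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------

def wc_theta_from_genotype_counts(hom1_a, het_a, hom2_a, hom1_b, het_b, hom2_b):
    """Vectorised two-population Weir & Cockerham theta from genotype counts.

    Arguments are counts of diploid individuals homozygous for allele 1,
    heterozygous, and homozygous for allele 2, in populations A and B
    (scalars or equal-shape arrays).  Returns the raw (unclipped) theta with
    NaN where the estimator is undefined (a population without genotypes,
    fewer than two individuals on average, a monomorphic locus, or a zero
    total variance a + b + c).
    """
    hom1_a, het_a, hom2_a, hom1_b, het_b, hom2_b = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (hom1_a, het_a, hom2_a, hom1_b, het_b, hom2_b))
    )
    n1 = hom1_a + het_a + hom2_a
    n2 = hom1_b + het_b + hom2_b
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = (2.0 * hom2_a + het_a) / (2.0 * n1)  # frequency of allele 2
        p2 = (2.0 * hom2_b + het_b) / (2.0 * n2)
        h1 = het_a / n1  # observed heterozygote frequencies
        h2 = het_b / n2
        nbar = (n1 + n2) / 2.0
        nc = 2.0 * nbar - (n1 * n1 + n2 * n2) / (2.0 * nbar)
        pbar = (n1 * p1 + n2 * p2) / (2.0 * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (n1 * h1 + n2 * h2) / (2.0 * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1.0 - pbar) - s2 / 2.0 - hbar / 4.0) / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar) - s2 / 2.0 - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        denom = a + b + c
        theta = a / denom
    bad = (
        (n1 < 1) | (n2 < 1) | (nbar <= 1.0)
        | (pbar <= 0.0) | (pbar >= 1.0)
        | (denom == 0.0) | ~np.isfinite(theta)
    )
    theta = np.where(bad, np.nan, theta)
    return theta if theta.ndim else float(theta)


def _parse_genotype_table(table) -> tuple[list[str], dict[tuple[str, str], int]]:
    """Normalise a genotype->count mapping to allele list and pair counts."""
    counts: dict[tuple[str, str], int] = {}
    alleles: set[str] = set()
    for geno, n in table.items():
        if isinstance(geno, str):
            pair = tuple(geno)
        else:
            pair = tuple(geno)
        if len(pair) != 2:
            raise ValueError(f"genotype {geno!r} is not diploid")
        pair = tuple(sorted(pair))
        if n < 0:
            raise ValueError("genotype counts must be non-negative")
        counts[pair] = counts.get(pair, 0) + int(n)
        if n > 0:
            alleles.update(pair)
    return sorted(alleles), counts


def wc_theta(pop_a, pop_b) -> float:
    """Weir & Cockerham theta for one biallelic locus, two populations.

    Each population is a mapping from diploid genotype (e.g. ``"TC"`` or
    ``("T", "C")``) to individual count, or a length-3 sequence
    ``(hom_allele1, het, hom_allele2)``.  Returns the raw (unclipped) theta.

    Raises ``ValueError`` if the locus is monomorphic across both
    populations, has more than two alleles, a population has no genotypes,
    or the total variance a + b + c is zero.
    """
    if isinstance(pop_a, Mapping) and isinstance(pop_b, Mapping):
        al_a, cnt_a = _parse_genotype_table(pop_a)
        al_b, cnt_b = _parse_genotype_table(pop_b)
        alleles = sorted(set(al_a) | set(al_b))
        if len(alleles) > 2:
            raise ValueError(f"locus has more than two alleles: {alleles}")
        if len(alleles) < 2:
            raise ValueError("locus is monomorphic across both populations")
        a1, a2 = alleles
        def triple(cnt):
            return (
                cnt.get((a1, a1), 0),
                cnt.get(tuple(sorted((a1, a2))), 0),
                cnt.get((a2, a2), 0),
            )
        ta, tb = triple(cnt_a), triple(cnt_b)
    else:
        ta, tb = tuple(pop_a), tuple(pop_b)
        if len(ta) != 3 or len(tb) != 3:
            raise ValueError("expected (hom1, het, hom2) genotype count triples")
    theta = wc_theta_from_genotype_counts(*ta, *tb)
    if not np.isfinite(theta):
        raise ValueError("theta is undefined for this table (monomorphic or degenerate)")
    return float(theta)


# ---------------------------------------------------------------------------
# haplotype-diversity F_ST
# ---------------------------------------------------------------------------

def haplotype_diversity(counts, unbiased: bool = True) -> float:
    """Unbiased haplotype (allele) diversity of one pool of haploid genomes.

    With sample size n and allele frequencies p_k, returns
    (n / (n - 1)) * (1 - sum p_k^2); this equals the probability that two
    genomes drawn *without* replacement from the pool differ.  NaN for
    pools of fewer than two genomes.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n < 2:
        return float("nan")
    h = 1.0 - float(((counts / n) ** 2).sum())
    if unbiased:
        h *= n / (n - 1.0)
    return float(h)


def haplotype_fst_from_counts(
    minor_a, n_a, minor_b, n_b,
    unbiased: bool = True,
    hs_weighting: str = "weighted",
):
    """Vectorised haplotype-diversity F_ST from biallelic genome counts.

    ``minor_a``/``minor_b`` count one allele (conventionally the pooled
    minor allele) and ``n_a``/``n_b`` the haploid genomes observed in each
    population.  Returns raw (unclipped) (H_T - H_S) / H_T, NaN where the
    pooled sample is monomorphic or a population has fewer than two genomes.

    The formula slot is configurable.  By default H_S weights the
    within-population diversities by their genome counts, which keeps a
    pooled singleton at exactly zero F_ST for *any* sample sizes — the
    property that makes rare alleles uninformative; the unweighted mean
    (``hs_weighting="unweighted"``) loses that guarantee when the samples
    are unbalanced.  ``unbiased=False`` drops the n/(n-1) correction.
    """
    minor_a, n_a, minor_b, n_b = np.broadcast_arrays(
        *(np.asarray(x, dtype=float) for x in (minor_a, n_a, minor_b, n_b))
    )

    def _div(c, n):
        p = np.divide(c, n, out=np.zeros_like(c), where=n > 0)
        h = 2.0 * p * (1.0 - p)
        if unbiased:
            with np.errstate(divide="ignore", invalid="ignore"):
                h = h * n / (n - 1.0)
        return h

    h_a = _div(minor_a, n_a)
    h_b = _div(minor_b, n_b)
    if hs_weighting == "weighted":
        hs = (n_a * h_a + n_b * h_b) / (n_a + n_b)
    elif hs_weighting == "unweighted":
        hs = (h_a + h_b) / 2.0
    else:
        raise ValueError(f"unknown hs_weighting {hs_weighting!r}")
    ht = _div(minor_a + minor_b, n_a + n_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = (ht - hs) / ht
    bad = (n_a < 2) | (n_b < 2) | (ht == 0.0) | ~np.isfinite(fst)
    fst = np.where(bad, np.nan, fst)
    return fst if fst.ndim else float(fst)


def haplotype_fst(site: SnpSite, **kwargs) -> float:
    """Haplotype-diversity F_ST of one :class:`SnpSite` (raw, unclipped)."""
    (maj_a, min_a), (maj_b, min_b) = site.counts
    n_a, n_b = site.genome_counts
    if n_a < 2 or n_b < 2:
        raise ValueError("haplotype F_ST requires >= 2 genomes per population")
    fst = haplotype_fst_from_counts(min_a, n_a, min_b, n_b, **kwargs)
    if not np.isfinite(fst):
        raise ValueError("F_ST undefined: pooled sample is monomorphic (H_T = 0)")
    return float(fst)


# ---------------------------------------------------------------------------
# pooled consensus genotypes -> SNP sites -> per-site records
# ---------------------------------------------------------------------------

def pool_to_snp_sites(
    pool: Sequence,
    site_id: str = "",
    chromosome: str = "",
    start_position: int = 1,
    populations: Sequence[str] | None = None,
) -> list[SnpSite]:
    """Screen a pooled set of consensus genotypes base by base for SNPs.

    ``pool`` is a sequence of :class:`~radscan.genotyping.ConsensusGenotype`
    for one RAD site across individuals of both populations.  Positions with
    more than two observed alleles are reduced to the two most frequent in
    the pooled counts (remaining alleles dropped with a warning).  Returns a
    :class:`SnpSite` per variable position; ``start_position`` is the
    1-based chromosome coordinate of the first base of the site.
    """
    if not pool:
        return []
    if populations is None:
        populations = sorted({g.population_id for g in pool})
    if len(populations) != 2:
        raise ValueError(f"expected exactly two populations, got {populations}")
    pop_index = {p: i for i, p in enumerate(populations)}
    n_positions = max(len(g.calls) for g in pool)

    sites: list[SnpSite] = []
    for j in range(n_positions):
        counts: dict[str, np.ndarray] = {}
        het = np.zeros(2, dtype=np.int64)
        dip_counts: dict[str, np.ndarray] = {}
        any_diploid = False
        for g in pool:
            if j >= len(g.calls):
                continue
            call = g.calls[j]
            if call is None:
                continue
            k = pop_index[g.population_id]
            for base in call:
                counts.setdefault(base, np.zeros(2, dtype=np.int64))[k] += 1
            if g.ploidy == 2:
                any_diploid = True
                for base in call:
                    dip_counts.setdefault(base, np.zeros(2, dtype=np.int64))[k] += 1
                if call[0] != call[1]:
                    het[k] += 1
        if len(counts) < 2:
            continue
        pooled = {b: int(c.sum()) for b, c in counts.items()}
        # order by pooled count (desc), then lexicographically for determinism
        ordered = sorted(pooled, key=lambda b: (-pooled[b], b))
        if len(ordered) > 2:
            dropped = ordered[2:]
            log.warning(
                "site %s position %d: >2 alleles, dropping %s as presumptive errors",
                site_id, start_position + j, dropped,
            )
        major, minor = ordered[0], ordered[1]
        if pooled[minor] == 0:
            continue
        cmat = np.stack([counts[major], counts[minor]], axis=1)
        dmat = None
        if any_diploid:
            zero = np.zeros(2, dtype=np.int64)
            dmat = np.stack(
                [dip_counts.get(major, zero), dip_counts.get(minor, zero)], axis=1
            )
        sites.append(
            SnpSite(
                chromosome=chromosome,
                position=start_position + j,
                site_id=site_id,
                alleles=(major, minor),
                counts=cmat,
                het_counts=het,
                genome_counts=cmat.sum(axis=1),
                diploid_counts=dmat,
            )
        )
    return sites


def snp_fst(site: SnpSite, estimator: str = "haplotype", **kwargs) -> float:
    """Raw F_ST of one SNP under the chosen estimator.

    ``theta`` is computed on diploid individuals only (it needs observed
    heterozygote frequencies); ``haplotype`` uses all genomes and is the
    default for mixed haploid/diploid pools.  Raises ``ValueError`` where
    the estimator is undefined for the site.
    """
    if estimator == "haplotype":
        return haplotype_fst(site, **kwargs)
    if estimator == "theta":
        if site.diploid_counts is None:
            raise ValueError("theta requires diploid genotype counts")
        d = site.diploid_counts
        het = site.het_counts
        hom_min = (d[:, 1] - het) / 2.0
        hom_maj = (d[:, 0] - het) / 2.0
        theta = wc_theta_from_genotype_counts(
            hom_maj[0], het[0], hom_min[0], hom_maj[1], het[1], hom_min[1]
        )
        if not np.isfinite(theta):
            raise ValueError("theta undefined for this site")
        return float(theta)
    raise ValueError(f"unknown estimator {estimator!r}")


def site_fst_records(
    snps: Sequence[SnpSite], estimator: str = "haplotype", **kwargs
) -> list[FstRecord]:
    """Per-position F_ST records for the variable positions of one site."""
    records = []
    for snp in snps:
        try:
            raw = snp_fst(snp, estimator=estimator, **kwargs)
        except ValueError as exc:
            log.debug("skipping %s:%d: %s", snp.site_id, snp.position, exc)
            continue
        records.append(
            FstRecord(
                site_id=snp.site_id,
                estimator=estimator,
                fst_raw=raw,
                minor_allele_count=snp.minor_allele_count,
                aggregation="none",
                chromosome=snp.chromosome,
                position=snp.position,
            )
        )
    return records


def aggregate_records(
    records: Sequence[FstRecord],
    aggregation: str = "max",
    rng: np.random.Generator | None = None,
) -> FstRecord | None:
    """Aggregate per-position records of one RAD site into a single record.

    Per-position values are clipped at zero *before* aggregation.  ``max``
    keeps the highest clipped value (ties broken by leftmost position),
    ``mean`` averages the clipped values, ``random`` keeps one SNP chosen
    uniformly with ``rng``.  Returns ``None`` for an empty record set.
    """
    if not records:
        return None
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"unknown aggregation {aggregation!r}")
    records = sorted(records, key=lambda r: r.position)
    if aggregation == "max":
        best = max(records, key=lambda r: (r.fst, -r.position))
        chosen, value = best, best.fst
    elif aggregation == "random":
        if rng is None:
            raise ValueError("random aggregation requires an rng")
        chosen = records[int(rng.integers(len(records)))]
        value = chosen.fst
    else:  # mean
        chosen = records[0]
        value = float(np.mean([r.fst for r in records]))
    return FstRecord(
        site_id=chosen.site_id,
        estimator=chosen.estimator,
        fst_raw=value,
        minor_allele_count=(
            chosen.minor_allele_count if aggregation != "mean"
            else min(r.minor_allele_count for r in records)
        ),
        aggregation=aggregation,
        chromosome=chosen.chromosome,
        position=chosen.position,
    )


def scan_rad_site(
    pool: Sequence,
    estimator: str = "haplotype",
    aggregation: str = "max",
    rng: np.random.Generator | None = None,
    **pool_kwargs,
) -> FstRecord | None:
    """Evaluate every variable position of one pooled RAD site and aggregate.

    ``pool`` is the coverage-gated pool of consensus genotypes for one RAD
    site (see :func:`radscan.filters.coverage_gate`).  Returns ``None`` when
    the site has no variable position.
    """
    snps = pool_to_snp_sites(pool, **pool_kwargs)
    records = site_fst_records(snps, estimator=estimator)
    return aggregate_records(records, aggregation=aggregation, rng=rng)
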