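"""Two-population synthetic data with the structure RAD genome scans see.

The generator produces, per RAD site, one candidate SNP whose ancestral
frequency is drawn from a rare-allele-skewed site-frequency spectrum, whose
population frequencies follow the Balding–Nichols beta model with a single
drift parameter F, and whose per-individual diploid genotypes are binomial
draws from the population frequencies.  On top of this neutral baseline:

* *hitchhiking*: within a selected region the two population frequencies
  are displaced toward opposite fixation by max_effect * exp(-decay * d)
  at distance d from the region centre, emulating a marker dragged along
  with a QTL under divergent selection;
* *singleton excess*: the spectrum is a mixture of the discretised neutral
  spectrum (P(i) proportional to 1/i) and a near-fixed component at
  frequency 1/G; the mixing weight is solved in closed form so that the
  expected fraction of polymorphic loci whose pooled minor allele occurs
  exactly once matches ``singleton_fraction_target`` (pooled counts under
  beta + binomial sampling are beta-binomial, so the component singleton
  and polymorphism probabilities are exact);
* *sister RAD sites*: in sister mode the two sites flanking a restriction
  cut share their population frequencies (the shared locus effect) while
  genotypes are sampled independently per site (the noise);
* *sequencing layer*: per-individual read stacks with negative-binomial
  depth, uniform haplotype sampling and uniform base-miscall errors.

All randomness derives from one root seed via independent named substreams,
so each stage is individually reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .fst import haplotype_fst_from_counts
from .genotyping import ConsensusGenotype, ReadStack

log = logging.getLogger(__name__)

_BASES = np.array(["A", "C", "G", "T"])

# fixed substream labels so every stage draws from its own reproducible stream
_STAGE_KEYS = {
    "populations": 1,
    "sequences": 2,
    "stacks": 3,
    "aggregation": 4,
}


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for one pipeline stage."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGE_KEYS[stage],))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# configuration and annotations
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of the two-population simulation.

    Defaults state the emulated study system: 27 diploid individuals per
    population, 76-bp reads, mean coverages (27, 31) reads per individual
    and RAD site, and a 46.5% singleton fraction among polymorphic loci.
    ``selected_regions`` is a sequence of (center_bp, max_effect,
    decay_per_bp) triples.  ``rare_weight`` overrides the calibrated mixing
    weight of the near-fixed spectrum component when set.
    """

    seed: int = 0
    n_individuals_per_pop: int = 27
    n_rad_sites: int = 1000
    read_length: int = 76
    chromosome: str = "chr1"
    chromosome_length: int = 1_000_000
    mean_coverage_per_pop: tuple[float, float] = (27.0, 31.0)
    coverage_dispersion: float = 5.0
    base_error_rate: float = 0.001
    drift_F: float = 0.05
    sfs_shape: object = "neutral"  # "neutral" or probability array over i = 1..G-1
    singleton_fraction_target: float = 0.465
    rare_weight: float | None = None
    rare_freq: float | None = None  # near-fixed component frequency; default 1/(4G)
    selected_regions: tuple[tuple[float, float, float], ...] = ()
    sister_pairs: bool = False
    strict_frequencies: bool = False

    def __post_init__(self) -> None:
        self.mean_coverage_per_pop = tuple(float(c) for c in self.mean_coverage_per_pop)
        self.selected_regions = tuple(tuple(r) for r in self.selected_regions)
        if self.n_individuals_per_pop < 1 or self.n_rad_sites < 1:
            raise ValueError("counts must be strictly positive")
        if self.read_length < 1 or self.chromosome_length < 2 * self.read_length:
            raise ValueError("chromosome must be longer than twice the read length")
        if len(self.mean_coverage_per_pop) != 2 or min(self.mean_coverage_per_pop) <= 0:
            raise ValueError("mean_coverage_per_pop must be two positive means")
        if self.coverage_dispersion <= 0:
            raise ValueError("coverage_dispersion must be positive")
        if not 0.0 <= self.base_error_rate <= 1.0:
            raise ValueError("base_error_rate must be a probability")
        if not 0.0 <= self.drift_F < 1.0:
            raise ValueError("drift_F must lie in [0, 1)")
        if not 0.0 <= self.singleton_fraction_target <= 1.0:
            raise ValueError("singleton_fraction_target must lie in [0, 1]")
        if self.rare_weight is not None and not 0.0 <= self.rare_weight <= 1.0:
            raise ValueError("rare_weight must lie in [0, 1]")
        if self.rare_freq is not None and not 0.0 < self.rare_freq < 1.0:
            raise ValueError("rare_freq must lie in (0, 1)")
        for center, effect, decay in self.selected_regions:
            if not 1 <= center <= self.chromosome_length:
                raise ValueError("selected-region centers must lie on the chromosome")
            if not 0.0 <= effect <= 1.0 or decay < 0.0:
                raise ValueError("selected-region effect in [0,1], decay >= 0 required")
        if self.sister_pairs and self.n_rad_sites % 2:
            raise ValueError("sister_pairs requires an even n_rad_sites")

    @property
    def n_genomes_per_pop(self) -> int:
        return 2 * self.n_individuals_per_pop

    @property
    def n_genomes_total(self) -> int:
        return 4 * self.n_individuals_per_pop

    @property
    def rare_frequency(self) -> float:
        """Frequency of the near-fixed spectrum component.

        Defaults to 1/(4G) for G pooled genomes: low enough that the
        component's polymorphic realisations are almost exclusively
        singletons, making singleton excess the dominant effect of the
        n = 2 filter, as observed empirically.
        """
        if self.rare_freq is not None:
            return self.rare_freq
        return 1.0 / (4.0 * self.n_genomes_total)


@dataclass(frozen=True)
class RadSiteAnnotation:
    """Chromosome placement of one RAD site relative to its cut site.

    Sister sites share ``chromosome`` and ``cut_position`` and carry
    opposite ``side`` values; at most two sites exist per cut position.
    The left site spans [cut_position - read_length + 1, cut_position], the
    right site [cut_position + 1, cut_position + read_length] (1-based,
    inclusive).
    """

    site_id: str
    chromosome: str
    cut_position: int
    side: str

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    def start(self, read_length: int) -> int:
        if self.side == "left":
            return self.cut_position - read_length + 1
        return self.cut_position + 1


# ---------------------------------------------------------------------------
# site-frequency spectrum and singleton calibration
# ---------------------------------------------------------------------------

def neutral_spectrum(n_genomes_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Discretised neutral spectrum: frequencies i/G with weight 1/i."""
    i = np.arange(1, n_genomes_total)
    w = 1.0 / i
    return i / n_genomes_total, w / w.sum()


def _spectrum(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(config.sfs_shape, str):
        if config.sfs_shape != "neutral":
            raise ValueError(f"unknown sfs_shape {config.sfs_shape!r}")
        return neutral_spectrum(config.n_genomes_total)
    probs = np.asarray(config.sfs_shape, dtype=float)
    if probs.ndim != 1 or len(probs) != config.n_genomes_total - 1 or probs.min() < 0:
        raise ValueError("custom sfs_shape must be non-negative weights over i=1..G-1")
    freqs = np.arange(1, config.n_genomes_total) / config.n_genomes_total
    return freqs, probs / probs.sum()


def _pool_count_pmf(k, n: int, p: np.ndarray, drift_F: float) -> np.ndarray:
    """P(allele count = k in n genomes) marginal over Balding–Nichols drift."""
    p = np.asarray(p, dtype=float)
    if drift_F == 0.0:
        return stats.binom.pmf(k, n, p)
    alpha = p * (1.0 - drift_F) / drift_F
    beta = (1.0 - p) * (1.0 - drift_F) / drift_F
    return stats.betabinom.pmf(k, n, alpha, beta)


def _component_probs(p: np.ndarray, drift_F: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-ancestral-frequency P(pooled singleton) and P(polymorphic).

    Both populations hold n genomes whose counts are (conditionally)
    independent beta-binomial draws; a singleton is a pooled count of
    exactly 1 or exactly 2n - 1.
    """
    c0 = _pool_count_pmf(0, n, p, drift_F)
    c1 = _pool_count_pmf(1, n, p, drift_F)
    ctop = _pool_count_pmf(n, n, p, drift_F)
    ctop1 = _pool_count_pmf(n - 1, n, p, drift_F)
    p_single = 2.0 * c1 * c0 + 2.0 * ctop1 * ctop
    p_poly = 1.0 - c0 * c0 - ctop * ctop
    return p_single, p_poly


def rare_mixture_weight(config: SimConfig) -> float:
    """Mixing weight of the near-fixed spectrum component.

    Solves, in closed form, for the weight w at which the expected fraction
    of singletons among polymorphic loci equals the target:
    w*A1 + (1-w)*A0 = t * (w*B1 + (1-w)*B0), where (A, B) are the singleton
    and polymorphism probabilities of the near-fixed and neutral components.
    Clamped to [0, 1] with a warning when the target is unattainable.
    """
    if config.rare_weight is not None:
        return float(config.rare_weight)
    n = config.n_genomes_per_pop
    freqs, probs = _spectrum(config)
    s0, y0 = _component_probs(freqs, config.drift_F, n)
    a0, b0 = float(s0 @ probs), float(y0 @ probs)
    p_rare = np.array([config.rare_frequency])
    # the near-fixed component models *recent* mutations that have not yet
    # experienced the between-population drift split, hence no beta spread
    s1, y1 = _component_probs(p_rare, 0.0, n)
    a1, b1 = float(s1[0]), float(y1[0])
    t = config.singleton_fraction_target
    denom = (a1 - a0) - t * (b1 - b0)
    if denom == 0.0:
        return 0.0
    w = (t * b0 - a0) / denom
    if not 0.0 <= w <= 1.0:
        log.warning(
            "singleton_fraction_target %.3f unattainable (weight %.3f); clamping",
            t, w,
        )
        w = min(max(w, 0.0), 1.0)
    return float(w)


def expected_singleton_fraction(config: SimConfig, weight: float | None = None) -> float:
    """Expected singleton fraction among polymorphic loci at a given weight."""
    if weight is None:
        weight = rare_mixture_weight(config)
    n = config.n_genomes_per_pop
    freqs, probs = _spectrum(config)
    s0, y0 = _component_probs(freqs, config.drift_F, n)
    a0, b0 = float(s0 @ probs), float(y0 @ probs)
    s1, y1 = _component_probs(np.array([config.rare_frequency]), 0.0, n)
    num = weight * float(s1[0]) + (1.0 - weight) * a0
    den = weight * float(y1[0]) + (1.0 - weight) * b0
    return num / den if den > 0 else float("nan")


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTruth:
    """True frequencies and genotypes produced by :func:`simulate_populations`.

    ``dosage`` holds alt-allele copies per individual with shape
    (n_sites, 2 populations, n_individuals).  ``pop_freq`` are the realised
    (post-selection) population frequencies of the alt allele.
    """

    config: SimConfig
    annotations: list[RadSiteAnnotation]
    cut_index: np.ndarray
    snp_offset: np.ndarray  # 0-based within the site
    snp_position: np.ndarray  # 1-based chromosome coordinate
    ancestral_freq: np.ndarray
    pop_freq: np.ndarray
    dosage: np.ndarray
    ref_base: np.ndarray
    alt_base: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.annotations)

    @property
    def site_ids(self) -> list[str]:
        return [a.site_id for a in self.annotations]

    def allele_counts(self) -> np.ndarray:
        """Alt-allele genome counts per site and population, shape (S, 2)."""
        return self.dosage.sum(axis=2)

    def pooled_minor(self) -> dict[str, np.ndarray]:
        """Pooled minor-allele bookkeeping for every site.

        Returns arrays keyed ``minor_a``/``minor_b`` (minor-allele genome
        counts per population), ``mac`` (pooled minor count) and
        ``polymorphic`` (pooled sample carries both alleles).
        """
        alt = self.allele_counts().astype(np.int64)
        n = self.config.n_genomes_per_pop
        pooled_alt = alt.sum(axis=1)
        total = 2 * n
        minor_is_alt = pooled_alt <= total - pooled_alt
        minor = np.where(minor_is_alt[:, None], alt, n - alt)
        mac = np.where(minor_is_alt, pooled_alt, total - pooled_alt)
        return {
            "minor_a": minor[:, 0],
            "minor_b": minor[:, 1],
            "mac": mac,
            "polymorphic": (pooled_alt > 0) & (pooled_alt < total),
            "minor_is_alt": minor_is_alt,
        }

    def genotype_counts(self) -> dict[str, np.ndarray]:
        """Per-population diploid genotype counts, each of shape (S, 2)."""
        return {
            "hom_ref": (self.dosage == 0).sum(axis=2),
            "het": (self.dosage == 1).sum(axis=2),
            "hom_alt": (self.dosage == 2).sum(axis=2),
        }

    def singleton_fraction_realized(self) -> float:
        pm = self.pooled_minor()
        poly = pm["polymorphic"]
        if not poly.any():
            return float("nan")
        return float((pm["mac"][poly] == 1).mean())

    def true_haplotype_fst(self) -> np.ndarray:
        """Raw haplotype-diversity F_ST per site (NaN where monomorphic)."""
        pm = self.pooled_minor()
        n = self.config.n_genomes_per_pop
        return haplotype_fst_from_counts(pm["minor_a"], n, pm["minor_b"], n)

    def to_pool(self, site_index: int) -> list[ConsensusGenotype]:
        """The site's true genotypes as a pool of diploid consensus calls."""
        out = []
        ref = self.ref_base[site_index]
        alt = self.alt_base[site_index]
        for k, pop in enumerate(("pop1", "pop2")):
            for i in range(self.config.n_individuals_per_pop):
                d = int(self.dosage[site_index, k, i])
                call = tuple(sorted([alt] * d + [ref] * (2 - d)))
                out.append(
                    ConsensusGenotype(
                        site_id=self.annotations[site_index].site_id,
                        individual_id=f"{pop}_{i:03d}",
                        population_id=pop,
                        ploidy=2,
                        calls=[call],
                        depth=0,
                    )
                )
        return out


def _distinct_sorted_ints(rng: np.random.Generator, low: int, high: int, size: int) -> np.ndarray:
    """``size`` distinct integers in [low, high), sorted."""
    if high - low < size:
        raise ValueError("range too small for the requested number of cut sites")
    draw = rng.integers(low, high, size=2 * size + 16)
    uniq = np.unique(draw)
    while len(uniq) < size:
        uniq = np.unique(np.concatenate([uniq, rng.integers(low, high, size=size)]))
    return np.sort(rng.choice(uniq, size=size, replace=False))


def simulate_populations(config: SimConfig) -> SimulatedTruth:
    """Draw true allele frequencies and diploid genotypes for two populations.

    One candidate SNP per RAD site: ancestral frequency from the (mixture)
    spectrum, population frequencies from Balding–Nichols, hitchhiking
    displacement inside selected regions, genotypes binomial per individual.
    Deterministic given ``config.seed``.
    """
    rng = stage_rng(config.seed, "populations")
    S = config.n_rad_sites
    L = config.read_length

    # --- site placement -----------------------------------------------------
    n_cut = S // 2 if config.sister_pairs else S
    cut_positions = _distinct_sorted_ints(
        rng, L + 1, config.chromosome_length - L, n_cut
    )
    annotations: list[RadSiteAnnotation] = []
    cut_index = np.empty(S, dtype=np.int64)
    if config.sister_pairs:
        for c in range(n_cut):
            for j, side in enumerate(("left", "right")):
                annotations.append(
                    RadSiteAnnotation(
                        site_id=f"site{2 * c + j:06d}",
                        chromosome=config.chromosome,
                        cut_position=int(cut_positions[c]),
                        side=side,
                    )
                )
            cut_index[2 * c : 2 * c + 2] = c
    else:
        sides = rng.choice(["left", "right"], size=S)
        for s in range(S):
            annotations.append(
                RadSiteAnnotation(
                    site_id=f"site{s:06d}",
                    chromosome=config.chromosome,
                    cut_position=int(cut_positions[s]),
                    side=str(sides[s]),
                )
            )
        cut_index[:] = np.arange(S)

    snp_offset = rng.integers(0, L, size=S)
    starts = np.array([a.start(L) for a in annotations], dtype=np.int64)
    snp_position = starts + snp_offset

    # --- ancestral and population frequencies ------------------------------
    # Each site carries its own SNP with its own spectrum draw; sister sites
    # flanking one cut share the *drift genealogy* instead of the frequency:
    # the Balding-Nichols draw uses beta quantiles of per-cut-site shared
    # uniforms, so tightly linked markers experience the same drift deviation
    # while keeping independent allele-frequency spectra.
    freqs, probs = _spectrum(config)
    w = rare_mixture_weight(config)
    rare = rng.random(S) < w
    p_anc_site = np.where(
        rare,
        config.rare_frequency,
        freqs[rng.choice(len(freqs), size=S, p=probs)],
    )
    if config.drift_F == 0.0:
        x = np.repeat(p_anc_site[:, None], 2, axis=1)
    else:
        u_cut = rng.random((n_cut, 2))
        alpha = p_anc_site * (1.0 - config.drift_F) / config.drift_F
        beta = (1.0 - p_anc_site) * (1.0 - config.drift_F) / config.drift_F
        x = stats.beta.ppf(u_cut[cut_index], alpha[:, None], beta[:, None])
        # recent rare mutations: no drift split yet, shared low frequency
        x[rare] = p_anc_site[rare, None]

    # --- hitchhiking displacement toward opposite fixation ------------------
    # The displacement is modulated by marker heterozygosity 4*x(1-x): the
    # first-order hitchhiking response of a linked neutral marker is
    # proportional to x(1-x), so a rare marker allele (almost never linked
    # to the sweeping QTL allele) stays undifferentiated while a balanced
    # marker picks up the full effect.
    if config.selected_regions:
        d_total = np.zeros(S)
        for center, effect, decay in config.selected_regions:
            d_total += effect * np.exp(-decay * np.abs(snp_position - center))
        xbar = x.mean(axis=1)
        d_eff = d_total * 4.0 * xbar * (1.0 - xbar)
        shifted = np.stack([x[:, 0] - d_eff, x[:, 1] + d_eff], axis=1)
        if config.strict_frequencies and ((shifted < 0).any() or (shifted > 1).any()):
            raise ValueError(
                "selected-region displacement pushed a frequency outside [0, 1]"
            )
        out_of_range = int(((shifted < 0) | (shifted > 1)).sum())
        if out_of_range:
            log.warning(
                "clamping %d displaced population frequencies into [0, 1]",
                out_of_range,
            )
        x = np.clip(shifted, 0.0, 1.0)

    # --- genotypes and allele identities ------------------------------------
    dosage = rng.binomial(
        2, x[:, :, None], size=(S, 2, config.n_individuals_per_pop)
    ).astype(np.int8)
    ref_idx = rng.integers(0, 4, size=S)
    alt_idx = (ref_idx + rng.integers(1, 4, size=S)) % 4

    return SimulatedTruth(
        config=config,
        annotations=annotations,
        cut_index=cut_index,
        snp_offset=snp_offset,
        snp_position=snp_position,
        ancestral_freq=p_anc_site,
        pop_freq=x,
        dosage=dosage,
        ref_base=_BASES[ref_idx],
        alt_base=_BASES[alt_idx],
    )


def simulate_sister_pairs(config: SimConfig, n_pairs: int) -> SimulatedTruth:
    """Simulate ``n_pairs`` sister RAD-site pairs with shared locus effects."""
    cfg = replace(config, sister_pairs=True, n_rad_sites=2 * n_pairs)
    return simulate_populations(cfg)


# ---------------------------------------------------------------------------
# sequencing layer
# ---------------------------------------------------------------------------

def _depth_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if math.isinf(dispersion):
        return int(rng.poisson(mean))
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_read_stacks(
    truth: SimulatedTruth,
    config: SimConfig | None = None,
    sites: Sequence[int] | None = None,
) -> list[ReadStack]:
    """Sequence the simulated genotypes into per-individual read stacks.

    Per individual and RAD site the read count is negative-binomial with the
    population's mean coverage and the configured dispersion (Poisson in the
    dispersion -> infinity limit); each read copies one of the individual's
    two haplotypes uniformly; every base is miscalled with
    ``base_error_rate`` to a uniformly chosen other base.  Attached per-base
    error probabilities equal the realised miscall rate.  Deterministic
    given the seed and the ``sites`` selection.
    """
    config = config or truth.config
    rng = stage_rng(config.seed, "stacks")
    seq_rng = stage_rng(config.seed, "sequences")
    L = config.read_length
    S = truth.n_sites

    site_seqs = _BASES[seq_rng.integers(0, 4, size=(S, L))]
    site_seqs[np.arange(S), truth.snp_offset] = truth.ref_base

    if sites is None:
        sites = range(S)
    stacks: list[ReadStack] = []
    e = config.base_error_rate
    for s in sites:
        offset = int(truth.snp_offset[s])
        alt = truth.alt_base[s]
        template = site_seqs[s]
        for k, pop in enumerate(("pop1", "pop2")):
            mean_cov = config.mean_coverage_per_pop[k]
            for i in range(config.n_individuals_per_pop):
                depth = _depth_draw(rng, mean_cov, config.coverage_dispersion)
                d = int(truth.dosage[s, k, i])
                bases = np.tile(template, (depth, 1))
                if depth:
                    # haplotype h of the individual carries the alt allele iff h < dosage
                    hap = rng.integers(0, 2, size=depth)
                    bases[hap < d, offset] = alt
                    if e > 0:
                        err = rng.random((depth, L)) < e
                        n_err = int(err.sum())
                        if n_err:
                            cur = np.searchsorted(_BASES, bases[err])
                            bases[err] = _BASES[
                                (cur + rng.integers(1, 4, size=n_err)) % 4
                            ]
                stacks.append(
                    ReadStack(
                        site_id=truth.annotations[s].site_id,
                        individual_id=f"{pop}_{i:03d}",
                        population_id=pop,
                        bases=bases,
                        error_probs=np.full((depth, L), e, dtype=float),
                    )
                )
    return stacks


# ---------------------------------------------------------------------------
# conceptual marker/QTL scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """A two-population, two-timepoint marker configuration.

    ``counts_t0``/``counts_t1`` hold (common allele, rare/focal allele)
    genome counts per population before and after a period of divergent
    selection at a linked QTL; ``fst_t0``/``fst_t1`` are the clipped
    haplotype-diversity F_ST values of the marker.
    """

    case: str
    description: str
    counts_t0: np.ndarray
    counts_t1: np.ndarray

    def _fst(self, counts: np.ndarray) -> float:
        (c1a, c2a), (c1b, c2b) = counts
        raw = haplotype_fst_from_counts(c2a, c1a + c2a, c2b, c1b + c2b)
        if not np.isfinite(raw):
            return 0.0
        return float(min(max(raw, 0.0), 1.0))

    @property
    def fst_t0(self) -> float:
        return self._fst(self.counts_t0)

    @property
    def fst_t1(self) -> float:
        return self._fst(self.counts_t1)


_SCENARIOS = {
    "A": (
        "rare marker allele unlinked to the favoured QTL allele: hitchhiking of "
        "the common-allele haplotype leaves the marker undifferentiated",
        ((1 / 54, 1 / 54), (1 / 54, 0.0)),
    ),
    "B": (
        "rare marker allele linked to the favoured QTL allele: the rare allele "
        "hitchhikes to high frequency and the marker differentiates strongly",
        ((1 / 54, 1 / 54), (1 / 54, 24 / 54)),
    ),
    "C": (
        "balanced marker: hitchhiking shifts an intermediate frequency and the "
        "marker shows clear differentiation",
        ((0.5, 0.5), (9 / 54, 0.5)),
    ),
}


def scenario_figure1(
    case: str,
    n_individuals_per_pop: int = 27,
    frequencies: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> Scenario:
    """Marker/QTL linkage scenario A, B or C.

    A: a rare marker allele unlinked to the favoured QTL allele leaves no
    marker differentiation after selection; B: the rare allele is linked and
    hitchhikes up, differentiating the marker strongly; C: a balanced marker
    starts at F_ST = 0 and differentiates clearly.  Exact frequencies are
    configurable via ``frequencies`` = ((focal-allele frequency per
    population at t0), (at t1)); defaults reproduce the qualitative pattern.
    """
    case = case.upper()
    if case not in _SCENARIOS:
        raise ValueError(f"unknown scenario case {case!r}; expected A, B or C")
    description, default_freqs = _SCENARIOS[case]
    f_t0, f_t1 = frequencies if frequencies is not None else default_freqs
    n = 2 * n_individuals_per_pop

    def counts(fr):
        rare = np.rint(np.asarray(fr, dtype=float) * n).astype(np.int64)
        return np.stack([n - rare, rare], axis=1)

    return Scenario(
        case=case,
        description=description,
        counts_t0=counts(f_t0),
        counts_t1=counts(f_t1),
    )
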