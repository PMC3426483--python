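"""Consensus genotyping of per-individual RAD read stacks.

A read stack is the set of aligned reads one individual contributed to one
RAD site.  Genotyping is quality-aware and depth-aware:

* bases with a calling error probability above 0.01 are masked first;
* with ten or more quality-passing reads a *diploid* consensus is called,
  deciding heterozygosity per position with a binomial test: the position is
  heterozygous iff the binomial point probability of the observed allele
  split under p = 0.5 exceeds 0.01 (at lower depth the test has too little
  power, hence the depth rule);
* below ten reads only a *haploid* majority consensus is called.

The likelihood is the binomial pmf of the observed split, not a tail
probability; at depth 10 this calls a 9/1 stack homozygous (pmf 10/1024 <
0.01) but an 8/2 stack heterozygous (45/1024).  Ties for the majority base
or for the second most frequent base are broken by the lower summed error
probability, then alphabetically, so calls are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
MISSING = "N"

HOMOZYGOUS = "homozygous"
HETEROZYGOUS = "heterozygous"


@dataclass
class GenotypingConfig:
    """Thresholds of the consensus-genotyping rules."""

    min_diploid_depth: int = 10
    het_likelihood_threshold: float = 0.01
    max_base_error: float = 0.01

    def __post_init__(self) -> None:
        if self.min_diploid_depth < 1:
            raise ValueError("min_diploid_depth must be >= 1")
        for name in ("het_likelihood_threshold", "max_base_error"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class ReadStack:
    """One individual's aligned reads at one RAD site.

    ``bases`` is a (reads x positions) array over {A, C, G, T, N} and
    ``error_probs`` the congruent matrix of per-base calling error
    probabilities.
    """

    site_id: str
    individual_id: str
    population_id: str
    bases: np.ndarray
    error_probs: np.ndarray

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype="<U1")
        self.error_probs = np.asarray(self.error_probs, dtype=float)
        if self.bases.ndim != 2:
            raise ValueError("bases must be a (reads x positions) matrix")
        if self.bases.shape != self.error_probs.shape:
            raise ValueError("bases and error_probs must have identical dimensions")
        if self.error_probs.size and (
            self.error_probs.min() < 0.0 or self.error_probs.max() > 1.0
        ):
            raise ValueError("error probabilities must lie in [0, 1]")

    @property
    def n_reads(self) -> int:
        return self.bases.shape[0]

    @property
    def n_positions(self) -> int:
        return self.bases.shape[1]


@dataclass
class ConsensusGenotype:
    """Per-individual consensus calls at one RAD site.

    ``calls[j]`` is an unordered base pair (diploid), a 1-tuple (haploid) or
    ``None`` (missing) for position j.  ``depth`` records the number of
    quality-passing reads that supported the call.
    """

    site_id: str
    individual_id: str
    population_id: str
    ploidy: int
    calls: list[Optional[tuple[str, ...]]] = field(default_factory=list)
    depth: int = 0

    def __post_init__(self) -> None:
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        for call in self.calls:
            if call is not None and len(call) != self.ploidy:
                raise ValueError("call length must match ploidy")


def filter_bases(stack: ReadStack, config: GenotypingConfig | None = None) -> ReadStack:
    """Mask bases whose calling error probability exceeds the threshold.

    The comparison is a strict inequality (an error probability exactly at
    the threshold is kept); dimensions are preserved, masked bases become N.
    """
    config = config or GenotypingConfig()
    bases = stack.bases.copy()
    bases[stack.error_probs > config.max_base_error] = MISSING
    return replace(stack, bases=bases, error_probs=stack.error_probs.copy())


def het_test(k: int, n: int, config: GenotypingConfig | None = None) -> str:
    """Classify an allele split as heterozygous or homozygous.

    ``k`` of ``n`` quality-passing bases show one of the two candidate
    alleles.  The position is heterozygous iff the binomial point
    probability C(n, k) 0.5^n exceeds the likelihood threshold.  The test is
    symmetric in k and n - k.
    """
    config = config or GenotypingConfig()
    if n < 1:
        raise ValueError("het_test requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    pmf = float(stats.binom.pmf(k, n, 0.5))
    return HETEROZYGOUS if pmf > config.het_likelihood_threshold else HOMOZYGOUS


def _ranked_bases(col: np.ndarray, err: np.ndarray) -> list[tuple[str, int, float]]:
    """Bases at one position ranked by (count desc, summed error asc, base)."""
    out = []
    for base in BASES:
        sel = col == base
        c = int(sel.sum())
        if c:
            out.append((base, c, float(err[sel].sum())))
    out.sort(key=lambda t: (-t[1], t[2], t[0]))
    return out


def call_consensus(stack: ReadStack, config: GenotypingConfig | None = None) -> ConsensusGenotype:
    """Call the consensus genotype of one (already base-filtered) stack.

    Depth is the number of quality-passing reads covering the site (reads
    with at least one unmasked base).  Depth >= ``min_diploid_depth`` gives
    a diploid consensus with the binomial heterozygote test on the two most
    frequent bases per position; lower depth gives a haploid majority
    consensus.  Positions with no passing base are missing.
    """
    config = config or GenotypingConfig()
    passing = stack.bases != MISSING
    depth = int(passing.any(axis=1).sum()) if stack.n_reads else 0
    ploidy = 2 if depth >= config.min_diploid_depth else 1

    calls: list[Optional[tuple[str, ...]]] = []
    for j in range(stack.n_positions):
        ranked = _ranked_bases(stack.bases[:, j], stack.error_probs[:, j])
        if not ranked:
            calls.append(None)
            continue
        if ploidy == 1:
            calls.append((ranked[0][0],))
            continue
        if len(ranked) == 1:
            calls.append((ranked[0][0], ranked[0][0]))
            continue
        # remaining bases beyond the top two are ignored as presumptive errors
        (b1, c1, _), (b2, c2, _) = ranked[0], ranked[1]
        verdict = het_test(c2, c1 + c2, config)
        if verdict == HETEROZYGOUS:
            calls.append(tuple(sorted((b1, b2))))
        else:
            calls.append((b1, b1))
    return ConsensusGenotype(
        site_id=stack.site_id,
        individual_id=stack.individual_id,
        population_id=stack.population_id,
        ploidy=ploidy,
        calls=calls,
        depth=depth,
    )
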