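import numpy as np
import pytest

from radscan.genotyping import ConsensusGenotype, ReadStack


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_stack(
    reads: list[str],
    error_prob: float | np.ndarray = 0.001,
    site_id: str = "siteX",
    individual_id: str = "ind1",
    population_id: str = "pop1",
) -> ReadStack:
    """Build a ReadStack from read strings, e.g. ["ACGT", "ACGT"]."""
    bases = np.array([list(r) for r in reads], dtype="<U1")
    if np.isscalar(error_prob):
        errs = np.full(bases.shape, float(error_prob))
    else:
        errs = np.asarray(error_prob, dtype=float)
    return ReadStack(site_id, individual_id, population_id, bases, errs)


def make_genotype(
    call: tuple[str, ...] | None,
    population_id: str,
    individual_id: str = "ind",
    ploidy: int | None = None,
    site_id: str = "siteX",
) -> ConsensusGenotype:
    """One-position consensus genotype; ploidy inferred from the call."""
    if ploidy is None:
        ploidy = len(call) if call is not None else 2
    return ConsensusGenotype(
        site_id=site_id,
        individual_id=individual_id,
        population_id=population_id,
        ploidy=ploidy,
        calls=[call],
    )


def diploid_pool(counts_a: dict[str, int], counts_b: dict[str, int], site_id="siteX"):
    """Pool of one-position diploid genotypes from genotype->count tables."""
    pool = []
    i = 0
    for pop, counts in (("pop1", counts_a), ("pop2", counts_b)):
        for geno, k in counts.items():
            for _ in range(k):
                pool.append(
                    make_genotype(tuple(sorted(geno)), pop, f"{pop}_{i:03d}", site_id=site_id)
                )
                i += 1
    return pool
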