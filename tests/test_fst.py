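"""Estimator tests: Weir-Cockerham theta and haplotype-diversity F_ST."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radscan.fst import (
    FstRecord,
    SnpSite,
    aggregate_records,
    haplotype_diversity,
    haplotype_fst,
    haplotype_fst_from_counts,
    pool_to_snp_sites,
    scan_rad_site,
    site_fst_records,
    snp_fst,
    wc_theta,
    wc_theta_from_genotype_counts,
)

from conftest import diploid_pool


# ---------------------------------------------------------------------------
# independent oracles, coded from the textbook formulas
# ---------------------------------------------------------------------------

def theta_oracle(n_hom1_a, n_het_a, n_hom2_a, n_hom1_b, n_het_b, n_hom2_b):
    """Scalar Weir-Cockerham (1984) theta, r=2, spelled out step by step."""
    r = 2
    n_i = [n_hom1_a + n_het_a + n_hom2_a, n_hom1_b + n_het_b + n_hom2_b]
    p_i = [
        (2 * n_hom2_a + n_het_a) / (2 * n_i[0]),
        (2 * n_hom2_b + n_het_b) / (2 * n_i[1]),
    ]
    h_i = [n_het_a / n_i[0], n_het_b / n_i[1]]
    n_bar = sum(n_i) / r
    n_c = (sum(n_i) - sum(n**2 for n in n_i) / sum(n_i)) / (r - 1)
    p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
    s_sq = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
    a = (n_bar / n_c) * (
        s_sq
        - (1 / (n_bar - 1))
        * (p_bar * (1 - p_bar) - ((r - 1) / r) * s_sq - h_bar / 4)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar)
        - ((r - 1) / r) * s_sq
        - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
    )
    c = h_bar / 2
    return a / (a + b + c)


def diversity_by_pair_counting(counts):
    """Fraction of unordered genome pairs that differ, counted directly."""
    n = sum(counts)
    same = sum(c * (c - 1) // 2 for c in counts)
    total = n * (n - 1) // 2
    return (total - same) / total


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pop_a, pop_b, expected",
    [
        # balanced polymorphism, no differentiation: slightly negative
        ({"TT": 5, "TC": 10, "CC": 5}, {"TT": 5, "TC": 10, "CC": 5}, -0.026),
        # nearly monomorphic pool with one heterozygote: constrained to zero
        ({"TT": 20}, {"TT": 19, "TC": 1}, 0.000),
        # fixed difference
        ({"TT": 20}, {"CC": 20}, 1.0),
    ],
)
def test_wc_theta_reference_tables(pop_a, pop_b, expected):
    assert round(wc_theta(pop_a, pop_b), 3) == expected


def test_wc_theta_accepts_count_triples():
    assert wc_theta((5, 10, 5), (5, 10, 5)) == pytest.approx(
        wc_theta({"TT": 5, "TC": 10, "CC": 5}, {"TT": 5, "TC": 10, "CC": 5})
    )


@pytest.mark.parametrize(
    "pop_a, pop_b, match",
    [
        ({"TT": 20}, {"TT": 20}, "monomorphic"),
        ({"TT": 5, "TC": 5, "CG": 5}, {"TT": 5}, "more than two alleles"),
    ],
)
def test_wc_theta_rejects_degenerate_tables(pop_a, pop_b, match):
    with pytest.raises(ValueError, match=match):
        wc_theta(pop_a, pop_b)


def test_wc_theta_matches_textbook_oracle(rng):
    """1,000 random diploid tables agree with the step-by-step formulas."""
    checked = 0
    while checked < 1000:
        tbl = rng.integers(0, 15, size=6)
        if tbl[:3].sum() < 2 or tbl[3:].sum() < 2:
            continue
        alt = 2 * (tbl[2] + tbl[5]) + tbl[1] + tbl[4]
        tot = 2 * (tbl.sum())
        if alt == 0 or alt == tot:
            continue
        expected = theta_oracle(*tbl)
        if not math.isfinite(expected):
            continue
        assert wc_theta_from_genotype_counts(*tbl) == pytest.approx(
            expected, abs=1e-12
        )
        checked += 1


@given(
    tbl=st.tuples(*[st.integers(0, 30)] * 6).filter(
        lambda t: sum(t[:3]) >= 2
        and sum(t[3:]) >= 2
        and 0 < 2 * (t[2] + t[5]) + t[1] + t[4] < 2 * sum(t)
    )
)
@settings(max_examples=200, deadline=None)
def test_wc_theta_label_symmetry(tbl):
    """theta is invariant to swapping populations and to swapping alleles."""
    base = wc_theta_from_genotype_counts(*tbl)
    pop_swap = wc_theta_from_genotype_counts(*tbl[3:], *tbl[:3])
    allele_swap = wc_theta_from_genotype_counts(
        tbl[2], tbl[1], tbl[0], tbl[5], tbl[4], tbl[3]
    )
    if math.isfinite(base):
        assert pop_swap == pytest.approx(base, abs=1e-12)
        assert allele_swap == pytest.approx(base, abs=1e-12)


# ---------------------------------------------------------------------------
# haplotype diversity and haplotype F_ST
# ---------------------------------------------------------------------------

def test_haplotype_diversity_equals_pair_enumeration():
    """Unbiased diversity is the chance two genomes drawn without
    replacement differ: exact on every pool of up to 12 genomes."""
    for n in range(2, 13):
        for split in itertools.combinations_with_replacement(range(n + 1), 2):
            for counts in set(itertools.permutations((*split, n - sum(split)))):
                if min(counts) < 0 or sum(counts) != n:
                    continue
                assert haplotype_diversity(counts) == pytest.approx(
                    diversity_by_pair_counting(counts), abs=1e-12
                )


def _site(counts, site_id="s", position=1):
    counts = np.asarray(counts)
    return SnpSite(
        chromosome="chr1",
        position=position,
        site_id=site_id,
        alleles=("T", "C"),
        counts=counts,
        het_counts=[0, 0],
        genome_counts=counts.sum(axis=1),
    )


def test_haplotype_fst_fixed_difference():
    assert haplotype_fst(_site([[30, 0], [0, 30]])) == pytest.approx(1.0)


def test_haplotype_fst_identical_pools_goes_negative():
    # H_S = (20/19)*0.5 exceeds H_T = (40/39)*0.5, so the raw value is -1/38
    raw = haplotype_fst(_site([[10, 10], [10, 10]]))
    assert raw == pytest.approx(-1.0 / 38.0)
    rec = FstRecord("s", "haplotype", raw, 10)
    assert rec.fst == 0.0


@pytest.mark.parametrize("placement", ["pop1", "pop2"])
def test_haplotype_fst_singleton_constrained(placement):
    """A pooled singleton cannot show meaningful differentiation."""
    counts = [[29, 1], [30, 0]] if placement == "pop1" else [[30, 0], [29, 1]]
    raw = haplotype_fst(_site(counts))
    assert max(raw, 0.0) < 0.02


def test_monomorphic_pool_cannot_become_a_snp_site():
    with pytest.raises(ValueError, match="monomorphic"):
        SnpSite(
            chromosome="chr1",
            position=1,
            site_id="s",
            alleles=("T", "C"),
            counts=[[30, 0], [30, 0]],
            het_counts=[0, 0],
            genome_counts=[30, 30],
        )


@given(
    ca=st.integers(0, 40),
    na=st.integers(2, 80),
    cb=st.integers(0, 40),
    nb=st.integers(2, 80),
)
@settings(max_examples=300, deadline=None)
def test_haplotype_fst_symmetry_and_range(ca, na, cb, nb):
    if ca > na or cb > nb or (ca + cb == 0) or (ca + cb == na + nb):
        return
    fst = haplotype_fst_from_counts(ca, na, cb, nb)
    assert fst == pytest.approx(haplotype_fst_from_counts(cb, nb, ca, na), abs=1e-12)
    # allele-label swap
    assert fst == pytest.approx(
        haplotype_fst_from_counts(na - ca, na, nb - cb, nb), abs=1e-12
    )
    assert min(max(fst, 0.0), 1.0) <= 1.0


# ---------------------------------------------------------------------------
# pooled genotypes -> SNP sites, aggregation
# ---------------------------------------------------------------------------

def test_pool_to_snp_sites_counts_and_ploidy():
    pool = diploid_pool({"TT": 5, "TC": 10, "CC": 5}, {"TT": 5, "TC": 10, "CC": 5})
    (snp,) = pool_to_snp_sites(pool, site_id="siteX", chromosome="chr1")
    assert snp.alleles == ("C", "T") or snp.alleles == ("T", "C")
    assert snp.genome_counts.tolist() == [40, 40]
    assert snp.het_counts.tolist() == [10, 10]
    assert snp.minor_allele_count == 40  # exact 50/50 pooled split
    # theta computed from the reconstructed diploid table matches the direct call
    assert snp_fst(snp, estimator="theta") == pytest.approx(
        wc_theta({"TT": 5, "TC": 10, "CC": 5}, {"TT": 5, "TC": 10, "CC": 5})
    )


def test_pool_to_snp_sites_mixed_ploidy_genome_counts():
    from conftest import make_genotype

    pool = [make_genotype(("T", "T"), "pop1", f"a{i}") for i in range(13)]
    pool += [make_genotype(("C",), "pop1", "a13", ploidy=1)]
    pool += [make_genotype(("T", "C"), "pop2", f"b{i}") for i in range(14)]
    (snp,) = pool_to_snp_sites(pool, site_id="s")
    assert snp.genome_counts.tolist() == [27, 28]
    assert snp.het_counts.tolist() == [0, 14]


def _rec(fst_raw, position, mac=5):
    return FstRecord("s", "haplotype", fst_raw, mac, "none", "chr1", position)


def test_aggregate_records_rules():
    records = [_rec(0.1, 10), _rec(0.4, 20), _rec(-0.2, 30)]
    assert aggregate_records(records, "max").fst == pytest.approx(0.4)
    assert aggregate_records(records, "max").position == 20
    # clipping precedes aggregation: mean of {0.1, 0.4, 0.0}
    assert aggregate_records(records, "mean").fst == pytest.approx(0.5 / 3)
    rng = np.random.default_rng(0)
    assert aggregate_records(records, "random", rng).fst in (0.1, 0.4, 0.0)
    single = [_rec(0.25, 5)]
    vals = {
        aggregate_records(single, agg, np.random.default_rng(1)).fst
        for agg in ("max", "mean", "random")
    }
    assert vals == {0.25}
    assert aggregate_records([], "max") is None


def test_aggregate_max_tie_is_leftmost():
    records = [_rec(0.4, 50), _rec(0.4, 10), _rec(0.1, 5)]
    assert aggregate_records(records, "max").position == 10


def test_scan_rad_site_end_to_end():
    pool = diploid_pool({"TT": 10, "TC": 5, "CC": 5}, {"TT": 3, "TC": 4, "CC": 13})
    rec = scan_rad_site(pool, estimator="haplotype", aggregation="max", site_id="siteX")
    assert rec.site_id == "siteX"
    assert 0.0 <= rec.fst <= 1.0
    assert rec.aggregation == "max"
    # monomorphic pool yields no record
    mono = diploid_pool({"TT": 20}, {"TT": 20})
    assert scan_rad_site(mono, site_id="m") is None
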