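"""Synthetic-data generator: spectra, drift, hitchhiking, sequencing layer."""

import dataclasses
import logging
import math

import numpy as np
import pytest

from radscan.fst import wc_theta_from_genotype_counts
from radscan.simulate import (
    SimConfig,
    expected_singleton_fraction,
    rare_mixture_weight,
    scenario_figure1,
    simulate_populations,
    simulate_read_stacks,
    simulate_sister_pairs,
)


def small_config(**kwargs) -> SimConfig:
    defaults = dict(seed=11, n_rad_sites=50, read_length=30, n_individuals_per_pop=14)
    defaults.update(kwargs)
    return SimConfig(**defaults)


# ---------------------------------------------------------------------------
# determinism and structure
# ---------------------------------------------------------------------------

def test_same_seed_same_config_is_bit_identical(tmp_path):
    from radscan.io import write_stacks_tsv

    paths = []
    for run in ("a", "b"):
        cfg = small_config(mean_coverage_per_pop=(8, 8))
        truth = simulate_populations(cfg)
        stacks = simulate_read_stacks(truth, cfg)
        p = tmp_path / f"stacks_{run}.tsv"
        write_stacks_tsv(stacks, p)
        paths.append(p)
    t1 = simulate_populations(small_config())
    t2 = simulate_populations(small_config())
    assert np.array_equal(t1.dosage, t2.dosage)
    assert np.array_equal(t1.pop_freq, t2.pop_freq)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_different_seed_differs():
    t1 = simulate_populations(small_config(seed=1))
    t2 = simulate_populations(small_config(seed=2))
    assert not np.array_equal(t1.dosage, t2.dosage)


def test_sister_annotations_share_cut_and_oppose_sides():
    truth = simulate_sister_pairs(small_config(), 10)
    ann = truth.annotations
    assert len(ann) == 20
    by_cut: dict[int, list] = {}
    for a in ann:
        by_cut.setdefault(a.cut_position, []).append(a)
    for sites in by_cut.values():
        assert len(sites) == 2
        assert {s.side for s in sites} == {"left", "right"}


def test_snp_positions_lie_within_their_sites():
    cfg = small_config()
    truth = simulate_populations(cfg)
    for i, a in enumerate(truth.annotations):
        start = a.start(cfg.read_length)
        assert start <= truth.snp_position[i] < start + cfg.read_length


# ---------------------------------------------------------------------------
# frequency spectrum and singleton calibration
# ---------------------------------------------------------------------------

def test_singleton_fraction_hits_target():
    cfg = SimConfig(seed=5, n_rad_sites=20000, singleton_fraction_target=0.45)
    truth = simulate_populations(cfg)
    assert truth.singleton_fraction_realized() == pytest.approx(0.45, abs=0.02)


def test_singleton_fraction_monotone_in_mixing_weight():
    cfg = SimConfig(seed=5, n_rad_sites=20000)
    weights = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    expected = [expected_singleton_fraction(cfg, w) for w in weights]
    assert expected == sorted(expected)
    realized = [
        simulate_populations(
            dataclasses.replace(cfg, rare_weight=w)
        ).singleton_fraction_realized()
        for w in (0.2, 0.8)
    ]
    assert realized[0] < realized[1]


def test_calibrated_weight_reproduces_target_analytically():
    cfg = SimConfig(seed=0, singleton_fraction_target=0.4)
    w = rare_mixture_weight(cfg)
    assert expected_singleton_fraction(cfg, w) == pytest.approx(0.4, abs=1e-9)


# ---------------------------------------------------------------------------
# drift
# ---------------------------------------------------------------------------

def test_no_drift_no_selection_yields_no_differentiation():
    # all loci at ancestral frequency 0.5, no drift: mean theta ~ 0 and mean
    # clipped haplotype F_ST of informative loci < 0.01
    G = 4 * 27
    sfs = np.zeros(G - 1)
    sfs[G // 2 - 1] = 1.0  # point mass at frequency 1/2
    cfg = SimConfig(
        seed=42, n_rad_sites=10000, drift_F=0.0, rare_weight=0.0, sfs_shape=sfs
    )
    truth = simulate_populations(cfg)
    assert np.allclose(truth.pop_freq, 0.5)
    g = truth.genotype_counts()
    theta = wc_theta_from_genotype_counts(
        g["hom_ref"][:, 0], g["het"][:, 0], g["hom_alt"][:, 0],
        g["hom_ref"][:, 1], g["het"][:, 1], g["hom_alt"][:, 1],
    )
    assert abs(np.nanmean(theta)) < 0.01
    pm = truth.pooled_minor()
    fst = truth.true_haplotype_fst()
    informative = pm["polymorphic"] & (pm["mac"] >= 4) & np.isfinite(fst)
    assert informative.sum() > 9000
    assert np.clip(fst[informative], 0.0, 1.0).mean() < 0.01


# ---------------------------------------------------------------------------
# hitchhiking
# ---------------------------------------------------------------------------

def test_selected_region_effect_decays_with_distance():
    """Mean true differentiation |x1 - x2| is largest near the region centre
    and decays monotonically across distance bins (averaged over 100
    replicate simulations)."""
    center, decay = 500_000, 5e-6
    edges = np.array([0, 100_000, 250_000, 500_000])
    sums = np.zeros(3)
    counts = np.zeros(3)
    for rep in range(100):
        cfg = SimConfig(
            seed=9000 + rep,
            n_rad_sites=300,
            drift_F=0.0,
            rare_weight=0.0,
            selected_regions=((center, 0.8, decay),),
        )
        truth = simulate_populations(cfg)
        dist = np.abs(truth.snp_position - center)
        diff = np.abs(truth.pop_freq[:, 0] - truth.pop_freq[:, 1])
        for b in range(3):
            sel = (dist >= edges[b]) & (dist < edges[b + 1])
            sums[b] += diff[sel].sum()
            counts[b] += sel.sum()
    means = sums / counts
    assert means[0] > means[1] > means[2]


def test_strict_frequencies_raises_on_clamp():
    cfg = SimConfig(
        seed=3, n_rad_sites=500,
        selected_regions=((500_000, 1.0, 1e-6),),
        strict_frequencies=True,
    )
    with pytest.raises(ValueError, match="outside"):
        simulate_populations(cfg)


# ---------------------------------------------------------------------------
# sequencing layer
# ---------------------------------------------------------------------------

def test_error_free_homozygote_reads_are_uniform():
    cfg = small_config(base_error_rate=0.0, mean_coverage_per_pop=(10, 10))
    truth = simulate_populations(cfg)
    stacks = simulate_read_stacks(truth, cfg, sites=[0])
    site = truth.annotations[0].site_id
    offset = int(truth.snp_offset[0])
    pops = {"pop1": 0, "pop2": 1}
    for stack in stacks:
        assert stack.site_id == site
        ind = int(stack.individual_id.split("_")[1])
        d = int(truth.dosage[0, pops[stack.population_id], ind])
        if stack.n_reads and d in (0, 2):
            expect = truth.alt_base[0] if d == 2 else truth.ref_base[0]
            assert (stack.bases[:, offset] == expect).all()


def test_mean_depth_matches_configured_coverage():
    cfg = SimConfig(
        seed=21, n_rad_sites=20, n_individuals_per_pop=27, read_length=10,
        mean_coverage_per_pop=(30.0, 30.0), coverage_dispersion=5.0,
    )
    truth = simulate_populations(cfg)
    stacks = simulate_read_stacks(truth, cfg)
    depths = np.array([s.n_reads for s in stacks])
    assert len(depths) >= 1000
    assert depths.mean() == pytest.approx(30.0, rel=0.05)


def test_deep_heterozygote_is_balanced():
    cfg = SimConfig(
        seed=4, n_rad_sites=1, n_individuals_per_pop=1, read_length=10,
        mean_coverage_per_pop=(1000.0, 1000.0), base_error_rate=0.0,
    )
    truth = simulate_populations(cfg)
    truth.dosage[:] = 1  # force heterozygotes
    stacks = simulate_read_stacks(truth, cfg)
    offset = int(truth.snp_offset[0])
    for stack in stacks:
        frac = (stack.bases[:, offset] == truth.alt_base[0]).mean()
        assert abs(frac - 0.5) < 0.05


# ---------------------------------------------------------------------------
# conceptual scenarios
# ---------------------------------------------------------------------------

def test_scenario_a_marker_stays_undifferentiated():
    sc = scenario_figure1("A")
    assert sc.fst_t0 < 0.05
    assert sc.fst_t1 < 0.05


def test_scenario_c_starts_at_exact_zero_and_differentiates():
    sc = scenario_figure1("C")
    assert sc.fst_t0 == 0.0  # identical allele counts in both populations
    assert sc.fst_t1 > 0.05


def test_scenario_b_exceeds_scenario_a_after_selection():
    assert scenario_figure1("B").fst_t1 > scenario_figure1("A").fst_t1


def test_scenario_rejects_unknown_case():
    with pytest.raises(ValueError, match="unknown scenario"):
        scenario_figure1("D")


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "kwargs",
    [
        dict(drift_F=1.0),
        dict(base_error_rate=1.5),
        dict(coverage_dispersion=0.0),
        dict(selected_regions=((2_000_000, 0.5, 1e-6),)),  # off-chromosome centre
        dict(selected_regions=((100, 1.5, 1e-6),)),
        dict(n_rad_sites=0),
        dict(sister_pairs=True, n_rad_sites=7),
    ],
)
def test_invalid_configs_rejected(kwargs):
    with pytest.raises(ValueError):
        SimConfig(seed=0, **kwargs)
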