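"""Gene-drop simulation, cohort chromosomes, ERG/morphometry generators."""

import numpy as np
import pytest

from clccmap.intervals import GenomicInterval
from clccmap.linkage import GeneticModel
from clccmap.markers import haldane_recomb_fraction
from clccmap.pedigree import Individual, mendelian_consistent
from clccmap.simulate import (
    FOUNDER_HAPLOTYPE_LABEL,
    ERGSimConfig,
    auto_carrier_founders,
    build_pedigree,
    default_marker_map,
    fig7_morphometry_config,
    gene_drop,
    simulate_cohort_chromosomes,
    simulate_erg,
    simulate_morphometry,
    simulate_rescue_outcomes,
)

REGION = GenomicInterval("chr1", 108_820_610, 109_142_651)
MODEL = GeneticModel()


def small_study_map():
    return default_marker_map(n_markers=200, spacing_bp=20_000)


def test_build_pedigree_templates():
    nuc = build_pedigree("nuclear", 2, 1)
    assert len(nuc.individuals) == 5
    assert nuc.affected_ids == ["K1", "K2"]
    fc = build_pedigree("first_cousin", 1, 0)
    assert fc.is_consanguineous()
    dfc = build_pedigree("double_first_cousin", 1, 0)
    assert dfc.is_consanguineous()
    with pytest.raises(ValueError):
        build_pedigree("avuncular", 1, 0)


def test_custom_template_rejects_affected_founder():
    with pytest.raises(ValueError, match="founder"):
        build_pedigree(
            "custom",
            0,
            0,
            custom_individuals=[Individual("X", affection="affected")],
        )


def test_auto_carrier_founders():
    fc = build_pedigree("first_cousin", 1, 0)
    assert auto_carrier_founders(fc) == {"GP1": 1}
    nuc = build_pedigree("nuclear", 1, 0)
    assert auto_carrier_founders(nuc) == {"F": 1, "M": 1}


def test_gene_drop_conditions_and_truth():
    ped = build_pedigree("first_cousin", 2, 1, seed=1)
    marker_map = small_study_map()
    truth = gene_drop(ped, marker_map, MODEL, REGION, seed=11)
    # every affected is disease-homozygous, no unaffected is
    for iid, g in truth.disease_genotypes.items():
        if iid in ped.affected_ids:
            assert tuple(g) == (1, 1)
        elif ped.by_id[iid].affection == "unaffected":
            assert tuple(g) != (1, 1)
    # marker genotypes are Mendelian-consistent
    assert mendelian_consistent(ped, truth.genotypes)
    # the truth IBD segment of every affected covers the planted region
    for iid in ped.affected_ids:
        assert any(
            seg.contains_interval(REGION)
            for seg in truth.true_ibd_segments[iid]
        )
        # and the genotypes there are homozygous for the planted haplotype
        g = truth.genotypes[iid][truth.region_marker_indices]
        assert np.all(g[:, 0] == g[:, 1])
        assert np.all(g[:, 0] == truth.founder_haplotype)


def test_gene_drop_bit_reproducible():
    ped = build_pedigree("nuclear", 1, 1, seed=0)
    marker_map = small_study_map()
    t1 = gene_drop(ped, marker_map, MODEL, REGION, seed=7)
    t2 = gene_drop(ped, marker_map, MODEL, REGION, seed=7)
    assert t1.attempts == t2.attempts
    for iid in t1.genotypes:
        assert np.array_equal(t1.genotypes[iid], t2.genotypes[iid])


def test_gene_drop_rejection_budget():
    ped = build_pedigree("nuclear", 2, 0, seed=0)
    with pytest.raises(RuntimeError, match="attempts"):
        gene_drop(ped, small_study_map(), MODEL, REGION, seed=0, max_attempts=1)


def test_founder_allele_draws_match_frequencies():
    """Unconditioned founder draws at a SNP reproduce its allele frequency
    within 3 binomial SE (law-of-large-numbers check)."""
    marker_map = small_study_map()
    chroms = simulate_cohort_chromosomes(
        marker_map, list(range(8)), np.zeros(8, dtype=int),
        founder_frequency=0.0, n_individuals=5_000, seed=2,
    )
    # use SNP 1 (index 0 is all-zeros == the excluded 'founder haplotype')
    freq_cfg = marker_map[1].allele_freqs[1]
    draws = np.array([c[1] for c in chroms]).ravel()
    p_hat = draws.mean()
    se = np.sqrt(freq_cfg * (1 - freq_cfg) / draws.size)
    assert abs(p_hat - freq_cfg) <= 3 * se


def test_empirical_recombination_matches_map_distance():
    """>= 10^4 meioses between two markers reproduce the Haldane theta
    within 3 binomial SE.  Origin labels switch between the two parental
    chromosome labels exactly at crossovers."""
    ped = build_pedigree("nuclear", 1, 0, seed=0)
    marker_map = default_marker_map(n_markers=80, spacing_bp=40_000)
    i, j = 0, 25  # 1 Mb apart
    theta = haldane_recomb_fraction(
        marker_map[j].position_bp - marker_map[i].position_bp
    )
    n_rec = 0
    n_meioses = 0
    for seed in range(5_000):
        truth = gene_drop(ped, marker_map, MODEL, REGION, seed=seed)
        labels = truth.origin_labels["K1"]
        for chrom in range(2):
            n_meioses += 1
            if labels[i, chrom] != labels[j, chrom]:
                n_rec += 1
    p_hat = n_rec / n_meioses
    se = np.sqrt(theta * (1 - theta) / n_meioses)
    assert n_meioses == 10_000
    assert abs(p_hat - theta) <= 3 * se


def test_cohort_chromosomes_plant_frequency():
    marker_map = small_study_map()
    fh = np.array([0, 1, 0, 1, 1, 0, 0, 1])
    chroms = simulate_cohort_chromosomes(
        marker_map, list(range(8)), fh, 0.3, 2_000, seed=9
    )
    count = 0
    for c in chroms:
        for k in range(2):
            if np.array_equal(c[:, k], fh):
                count += 1
    p_hat = count / 4_000
    se = np.sqrt(0.3 * 0.7 / 4_000)
    assert abs(p_hat - 0.3) <= 3 * se


def test_simulate_erg_grid_and_determinism():
    cfg = ERGSimConfig(seed=5)
    from clccmap.simulate import default_wt_cone_params

    df = simulate_erg(cfg, {"wt": default_wt_cone_params()})
    assert len(df) == 9 * 7 * 4
    assert df["wavelength_nm"].nunique() == 9
    assert df["irradiance"].nunique() == 7
    df2 = simulate_erg(cfg, {"wt": default_wt_cone_params()})
    assert df.equals(df2)
    # zero noise -> exact forward-model values, replicates identical
    quiet = simulate_erg(
        ERGSimConfig(noise_sd_floor=0.0, noise_sd_frac=0.0),
        {"wt": default_wt_cone_params()},
    )
    per_cell = quiet.groupby(["wavelength_nm", "irradiance"])["amplitude_uv"]
    assert (per_cell.nunique() == 1).all()


def test_morphometry_presets_and_lln():
    cfg = fig7_morphometry_config(seed=3)
    df = simulate_morphometry(cfg)
    assert set(df["group"]) == {"clcc1-MO", "MM-MO"}
    sub = df[(df["measure"] == "eye_area_mm2") & (df["group"] == "clcc1-MO")]
    assert len(sub) == 40  # Fig 7 group size
    # zero-sd config gives exactly the mean
    from clccmap.simulate import GroupSpec, MorphoSimConfig

    det = MorphoSimConfig(
        measures={"m": (GroupSpec("a", 1.5, 0.0, 10), GroupSpec("b", 2.0, 0.0, 4))},
        seed=0,
    )
    dd = simulate_morphometry(det)
    assert set(dd[dd["group"] == "a"]["value"]) == {1.5}
    # large-sample mean within 3 SE
    big = MorphoSimConfig(
        measures={"m": (GroupSpec("a", 10.0, 2.0, 100_000),)}, seed=1
    )
    vals = simulate_morphometry(big)["value"].to_numpy()
    assert abs(vals.mean() - 10.0) <= 3 * 2.0 / np.sqrt(vals.size)


def test_rescue_outcomes():
    outcomes = simulate_rescue_outcomes(p_normal=0.87, n_embryos=100, seed=2)
    assert len(outcomes) == 100
    assert set(outcomes) <= {"normal", "abnormal"}
    assert outcomes == simulate_rescue_outcomes(0.87, 100, seed=2)
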