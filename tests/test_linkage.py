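"""Two-point likelihood and LOD: known values, properties and the
independent full-enumeration oracle."""

import math

import numpy as np
import pytest

from clccmap.linkage import (
    DEFAULT_THETA_GRID,
    GeneticModel,
    max_lod_curve,
    pedigree_likelihood,
    pedigree_loglikelihood,
    two_point_lod,
)
from clccmap.pedigree import Individual, Pedigree
from oracles import brute_force_likelihood, state_space_size

MODEL = GeneticModel()


def test_single_het_founder_is_hardy_weinberg():
    ped = Pedigree("X", [Individual("A")])
    # equal-frequency biallelic marker: P(het) = 2 * 0.5 * 0.5
    for theta in (0.0, 0.1, 0.5):
        assert pedigree_likelihood(
            ped, {"A": (0, 1)}, MODEL, theta
        ) == pytest.approx(0.5)


def test_all_missing_likelihood_is_one(nuclear_ped):
    ped = Pedigree(
        "X",
        [
            Individual("F"),
            Individual("M"),
            Individual("C", "F", "M"),
        ],
    )
    for theta in (0.0, 0.25, 0.5):
        assert pedigree_likelihood(ped, {}, MODEL, theta) == pytest.approx(1.0)


def test_likelihood_invalid_theta():
    ped = Pedigree("X", [Individual("A")])
    with pytest.raises(ValueError):
        pedigree_loglikelihood(ped, {}, MODEL, 0.7)


def test_pedigree_size_limit():
    inds = [Individual(f"I{k}") for k in range(15)]
    with pytest.raises(ValueError):
        pedigree_loglikelihood(Pedigree("X", inds), {}, MODEL, 0.1)


def _obligate_recombinant_family():
    """Two affected sibs drawing opposite parental marker alleles: at
    theta=0 the single disease-bearing chromosome of each parent cannot
    carry both marker alleles."""
    ped = Pedigree(
        "REC",
        [
            Individual("F", sex="male", affection="unaffected"),
            Individual("M", sex="female", affection="unaffected"),
            Individual("K1", "F", "M", "male", "affected"),
            Individual("K2", "F", "M", "female", "affected"),
        ],
    )
    geno = {"F": (0, 1), "M": (0, 1), "K1": (0, 0), "K2": (1, 1)}
    return ped, geno


def test_obligate_recombinant_gives_minus_inf_at_zero():
    ped, geno = _obligate_recombinant_family()
    assert pedigree_loglikelihood(ped, geno, MODEL, 0.0) == -math.inf
    assert pedigree_loglikelihood(ped, geno, MODEL, 0.1) > -math.inf
    result = two_point_lod([(ped, geno)], MODEL)
    assert result.lod[result.theta_grid.index(0.0)] == -math.inf


def test_lod_is_zero_at_half_and_families_sum(first_cousin_ped, nuclear_ped):
    fams = [
        (nuclear_ped, {"F": (0, 1), "M": (0, 1), "A1": (1, 1), "U1": (0, 1)}),
        (
            first_cousin_ped,
            {
                "C1": (0, 1), "C2": (0, 1),
                "K1": (1, 1), "K2": (1, 1), "K3": (0, 1),
            },
        ),
    ]
    result = two_point_lod(fams, MODEL)
    i_half = result.theta_grid.index(0.5)
    assert result.lod[i_half] == pytest.approx(0.0, abs=1e-12)
    for curve in result.per_family.values():
        assert curve[i_half] == pytest.approx(0.0, abs=1e-12)
    for i in range(len(result.theta_grid)):
        pooled = sum(result.per_family[f][i] for f in result.per_family)
        assert result.lod[i] == pytest.approx(pooled, rel=1e-12, abs=1e-12)
    # a linked marker yields a positive LOD at small theta
    assert result.max_lod > 0.0
    assert result.argmax_theta < 0.5


def test_mendelian_inconsistent_family_raises(nuclear_ped):
    geno = {"F": (0, 0), "M": (0, 0), "A1": (1, 1), "U1": (0, 0)}
    with pytest.raises(ValueError, match="Mendelian"):
        two_point_lod([(nuclear_ped, geno)], MODEL)


def test_theta_grid_must_include_half(nuclear_ped):
    with pytest.raises(ValueError):
        two_point_lod([(nuclear_ped, {})], MODEL, theta_grid=[0.0, 0.1])


def test_max_lod_tie_goes_to_smallest_theta():
    assert max_lod_curve([0.0, 0.1, 0.5], [1.0, 1.0, 0.0]) == (1.0, 0.0)


# ---------------------------------------------------------------------------
# oracle comparison on random pedigrees


def _random_pedigree(rng):
    """Random 4-10 member pedigree: a core couple, children, and possibly a
    married-in spouse with grandchildren (keeps loops out; the consanguineous
    case is covered separately via the first-cousin template)."""
    inds = [
        Individual("F", sex="male"),
        Individual("M", sex="female"),
    ]
    n_children = int(rng.integers(2, 5))
    for k in range(n_children):
        inds.append(Individual(f"C{k}", "F", "M"))
    if rng.random() < 0.5 and len(inds) + 2 <= 10:
        inds.append(Individual("SP", sex="female"))
        for g in range(int(rng.integers(1, min(3, 10 - len(inds))))):
            inds.append(Individual(f"G{g}", "C0", "SP"))
    return inds


def _simulate_two_locus(inds, rng, theta_sim, q_sim, n_alleles):
    """Forward gene drop at a disease locus and a linked marker; affection
    follows the fully penetrant recessive model."""
    haps = {}  # id -> ((d, a), (d, a))
    marker_freqs = rng.dirichlet(np.ones(n_alleles) * 5)
    by_id = {i.id: i for i in inds}

    def gamete(state):
        i = rng.integers(2)
        d = state[i][0]
        a = state[i][1] if rng.random() > theta_sim else state[1 - i][1]
        return (d, a)

    geno = {}
    affection = {}
    for ind in inds:
        if ind.father_id == "0":
            h = tuple(
                (int(rng.random() < q_sim), int(rng.choice(n_alleles, p=marker_freqs)))
                for _ in range(2)
            )
        else:
            h = (gamete(haps[ind.father_id]), gamete(haps[ind.mother_id]))
        haps[ind.id] = h
        affection[ind.id] = (
            "affected" if h[0][0] == 1 and h[1][0] == 1 else "unaffected"
        )
        if rng.random() < 0.85:  # 15% missing marker genotypes
            geno[ind.id] = (h[0][1], h[1][1])
    new_inds = [
        Individual(i.id, i.father_id, i.mother_id, i.sex, affection[i.id])
        for i in inds
    ]
    return new_inds, geno, marker_freqs


def test_likelihood_matches_brute_force_on_random_pedigrees():
    rng = np.random.default_rng(20260101)
    n_checked = 0
    draws = 0
    while n_checked < 50:
        draws += 1
        assert draws < 500, "pedigree generator failed to produce cases"
        n_alleles = int(rng.integers(2, 4))
        inds, geno, mfreqs = _simulate_two_locus(
            _random_pedigree(rng),
            rng,
            theta_sim=float(rng.uniform(0, 0.5)),
            q_sim=0.35,
            n_alleles=n_alleles,
        )
        ped = Pedigree(f"R{draws}", inds)
        model = GeneticModel(
            disease_allele_freq=float(rng.choice([1e-5, 0.01, 0.2])),
            marker_allele_freqs=tuple(mfreqs),
        )
        if state_space_size(ped, geno, model, n_alleles) > 50_000:
            continue
        for theta in (0.0, float(rng.uniform(0.01, 0.45)), 0.5):
            ours = pedigree_likelihood(ped, geno, model, theta, n_alleles)
            oracle = brute_force_likelihood(ped, geno, model, theta, n_alleles)
            assert ours == pytest.approx(oracle, rel=1e-12, abs=1e-300)
        n_checked += 1
    assert n_checked == 50


def test_likelihood_matches_brute_force_on_consanguineous_pedigree():
    """Looped pedigree (first cousins) against the full enumeration."""
    from clccmap.simulate import build_pedigree

    ped = build_pedigree("first_cousin", 1, 1, seed=3, family_id="LOOP")
    geno = {
        "GP1": (0, 1), "GP2": (0, 0), "P1": (0, 1), "P2": (0, 1),
        "S1": (0, 0), "S2": (0, 0), "C1": (0, 1), "C2": (0, 1),
        "K1": (1, 1), "K2": (0, 1),
    }
    model = GeneticModel(disease_allele_freq=0.01)
    for theta in (0.0, 0.05, 0.2, 0.5):
        ours = pedigree_likelihood(ped, geno, model, theta)
        oracle = brute_force_likelihood(ped, geno, model, theta)
        assert ours == pytest.approx(oracle, rel=1e-12)


def test_default_theta_grid_contents():
    assert DEFAULT_THETA_GRID == (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)
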