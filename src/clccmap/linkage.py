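"""Two-point pedigree likelihood and LOD scores for a recessive trait.

The likelihood is the classic two-locus pedigree likelihood: a sum over all
phased disease-locus x marker-locus genotype assignments of

    prod founder priors (HWE at both loci, linkage equilibrium)
  x prod transmission probabilities with recombination theta
  x prod penetrance terms
  x prod marker-genotype indicator terms.

It is computed *exactly* by discrete variable elimination (sum-product) over
the pedigree factor graph: one variable per individual (its phased two-locus
genotype), one prior factor per founder, one transmission factor per
non-founder linking it to both parents.  Elimination is exact for arbitrary
pedigree topology, so consanguinity loops need no special handling.  Factors
are rescaled by their maximum after each elimination and the log-scale is
accumulated, which keeps the computation stable at disease allele
frequencies as small as 1e-5.

Conventions: disease allele frequency default 0.00001, full penetrance
(0, 0, 1), sex-averaged theta.  A state is ((d_pat, a_pat), (d_mat, a_mat))
with d in {0,1} (1 = disease allele) and a a 0-based marker allele index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .pedigree import Individual, Pedigree

DEFAULT_THETA_GRID = (0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class GeneticModel:
    """Single-locus disease model plus marker allele frequencies."""

    disease_allele_freq: float = 0.00001
    penetrance: tuple[float, float, float] = (0.0, 0.0, 1.0)  # +/+, +/d, d/d
    marker_allele_freqs: tuple[float, ...] | str = "equal"

    def __post_init__(self) -> None:
        if not 0.0 < self.disease_allele_freq < 1.0:
            raise ValueError("disease_allele_freq must be in (0, 1)")
        if any(not 0.0 <= p <= 1.0 for p in self.penetrance):
            raise ValueError("penetrances must be in [0, 1]")

    def marker_freqs(self, n_alleles: int) -> np.ndarray:
        if isinstance(self.marker_allele_freqs, str):
            if self.marker_allele_freqs != "equal":
                raise ValueError(self.marker_allele_freqs)
            return np.full(n_alleles, 1.0 / n_alleles)
        freqs = np.asarray(self.marker_allele_freqs, dtype=float)
        if len(freqs) != n_alleles:
            raise ValueError("marker_allele_freqs length mismatch")
        return freqs


@dataclass
class LODResult:
    theta_grid: list[float]
    lod: list[float]  # -inf allowed
    max_lod: float
    argmax_theta: float
    per_family: dict[str, list[float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# factor-graph machinery

State = tuple[tuple[int, int], tuple[int, int]]


class _Factor:
    __slots__ = ("vars", "table")

    def __init__(self, vars_: tuple[int, ...], table: np.ndarray):
        self.vars = vars_
        self.table = table


def _multiply(a: _Factor, b: _Factor) -> _Factor:
    vars_ = a.vars + tuple(v for v in b.vars if v not in a.vars)
    # expand both tables to the union axis order
    sa = [slice(None) if v in a.vars else np.newaxis for v in vars_]
    ta = np.transpose(
        a.table, [a.vars.index(v) for v in vars_ if v in a.vars]
    )[tuple(sa)]
    sb = [slice(None) if v in b.vars else np.newaxis for v in vars_]
    tb = np.transpose(
        b.table, [b.vars.index(v) for v in vars_ if v in b.vars]
    )[tuple(sb)]
    return _Factor(vars_, ta * tb)


def _sum_out(f: _Factor, var: int) -> _Factor:
    ax = f.vars.index(var)
    return _Factor(
        tuple(v for v in f.vars if v != var), f.table.sum(axis=ax)
    )


def _states_for(
    ind: Individual,
    observed: tuple[int, int] | None,
    model: GeneticModel,
    n_alleles: int,
) -> tuple[list[State], np.ndarray]:
    """Allowed phased two-locus states and their unary weights
    (penetrance x marker-observation indicator)."""
    pen = model.penetrance
    states: list[State] = []
    weights: list[float] = []
    obs = None
    if observed is not None:
        a1, a2 = int(observed[0]), int(observed[1])
        if a1 >= 0 and a2 >= 0:
            obs = tuple(sorted((a1, a2)))
    for dp in (0, 1):
        for dm in (0, 1):
            if ind.affection == "affected":
                w = pen[dp + dm]
            elif ind.affection == "unaffected":
                w = 1.0 - pen[dp + dm]
            else:
                w = 1.0
            if w == 0.0:
                continue
            for ap in range(n_alleles):
                for am in range(n_alleles):
                    if obs is not None and tuple(sorted((ap, am))) != obs:
                        continue
                    states.append(((dp, ap), (dm, am)))
                    weights.append(w)
    return states, np.asarray(weights)


def _gamete_probs(states: list[State], theta: float, n_alleles: int) -> np.ndarray:
    """P(transmitted haplotype (d, a) | parent state), shape
    (n_states, 2, n_alleles)."""
    out = np.zeros((len(states), 2, n_alleles))
    same = 0.5 * (1.0 - theta)
    diff = 0.5 * theta
    for s, ((d1, a1), (d2, a2)) in enumerate(states):
        # choose the chromosome supplying the disease locus, then the marker
        # comes from the same chromosome (1-theta) or the other (theta)
        out[s, d1, a1] += same
        out[s, d1, a2] += diff
        out[s, d2, a2] += same
        out[s, d2, a1] += diff
    return out


def pedigree_loglikelihood(
    ped: Pedigree,
    genotypes: Mapping[str, Sequence[int]],
    model: GeneticModel,
    theta: float,
    n_marker_alleles: int | None = None,
    max_individuals: int = 14,
) -> float:
    """Natural-log two-point pedigree likelihood; -inf when the observed
    genotypes are Mendelian-inconsistent (or otherwise impossible).

    `genotypes` maps individual id -> (allele1, allele2) 0-based indices at
    the marker; -1 or an absent id means missing.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 0.5]")
    if len(ped.individuals) > max_individuals:
        raise ValueError(
            f"pedigree {ped.family_id} has {len(ped.individuals)} individuals,"
            f" above the exact-computation limit of {max_individuals}"
        )
    if n_marker_alleles is None:
        n_marker_alleles = 2
        for g in genotypes.values():
            for a in g:
                n_marker_alleles = max(n_marker_alleles, int(a) + 1)
    mfreq = model.marker_freqs(n_marker_alleles)
    q = model.disease_allele_freq
    dfreq = np.array([1.0 - q, q])

    order = {ind.id: i for i, ind in enumerate(ped.individuals)}
    states: dict[int, list[State]] = {}
    factors: list[_Factor] = []
    for ind in ped.individuals:
        v = order[ind.id]
        obs = genotypes.get(ind.id)
        st, w = _states_for(ind, obs, model, n_marker_alleles)
        if not st:
            return -math.inf
        states[v] = st
        if ind.is_founder:
            prior = np.array(
                [
                    dfreq[dp] * mfreq[ap] * dfreq[dm] * mfreq[am]
                    for (dp, ap), (dm, am) in st
                ]
            )
            factors.append(_Factor((v,), prior * w))
    for ind in ped.nonfounders:
        v = order[ind.id]
        vf, vm = order[ind.father_id], order[ind.mother_id]
        gf = _gamete_probs(states[vf], theta, n_marker_alleles)
        gm = _gamete_probs(states[vm], theta, n_marker_alleles)
        child = states[v]
        tab = np.zeros((len(child), len(states[vf]), len(states[vm])))
        for ci, ((dp, ap), (dm, am)) in enumerate(child):
            tab[ci] = np.outer(gf[:, dp, ap], gm[:, dm, am])
        _, w = _states_for(
            ped.by_id[ind.id], genotypes.get(ind.id), model, n_marker_alleles
        )
        factors.append(_Factor((v, vf, vm), tab * w[:, None, None]))

    # greedy variable elimination, smallest resulting table first
    log_scale = 0.0
    remaining = set(states)
    while remaining:
        best_var, best_cost = None, None
        for v in remaining:
            involved = [f for f in factors if v in f.vars]
            vars_union: set[int] = set()
            for f in involved:
                vars_union.update(f.vars)
            cost = 1
            for u in vars_union:
                cost *= len(states[u])
            if best_cost is None or cost < best_cost:
                best_var, best_cost = v, cost
        assert best_var is not None
        involved = [f for f in factors if best_var in f.vars]
        factors = [f for f in factors if best_var not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = _multiply(prod, f)
        summed = _sum_out(prod, best_var)
        peak = summed.table.max() if summed.table.size else 0.0
        if peak <= 0.0:
            return -math.inf
        log_scale += math.log(peak)
        summed.table = summed.table / peak
        factors.append(summed)
        remaining.discard(best_var)

    total = 1.0
    for f in factors:
        total *= float(f.table)  # all scalar now
    if total <= 0.0:
        return -math.inf
    return math.log(total) + log_scale


def pedigree_likelihood(
    ped: Pedigree,
    genotypes: Mapping[str, Sequence[int]],
    model: GeneticModel,
    theta: float,
    n_marker_alleles: int | None = None,
    max_individuals: int = 14,
) -> float:
    """Likelihood on the natural scale (0 for Mendelian-inconsistent data;
    may underflow to 0 for very unlikely configurations)."""
    ll = pedigree_loglikelihood(
        ped, genotypes, model, theta, n_marker_alleles, max_individuals
    )
    return 0.0 if ll == -math.inf else math.exp(ll)


def two_point_lod(
    families: Sequence[tuple[Pedigree, Mapping[str, Sequence[int]]]],
    model: GeneticModel,
    theta_grid: Sequence[float] = DEFAULT_THETA_GRID,
    n_marker_alleles: int | None = None,
    max_individuals: int = 14,
) -> LODResult:
    """Pooled two-point LOD curve, LOD(theta) = log10 L(theta) - log10 L(0.5)
    summed over independent families."""
    if not families:
        raise ValueError("empty family list")
    grid = list(theta_grid)
    if 0.5 not in grid:
        raise ValueError("theta grid must include 0.5 (the null)")
    per_family: dict[str, list[float]] = {}
    for ped, geno in families:
        ll_half = pedigree_loglikelihood(
            ped, geno, model, 0.5, n_marker_alleles, max_individuals
        )
        if ll_half == -math.inf:
            raise ValueError(
                f"family {ped.family_id}: genotypes are Mendelian-inconsistent"
            )
        curve = []
        for th in grid:
            ll = pedigree_loglikelihood(
                ped, geno, model, th, n_marker_alleles, max_individuals
            )
            curve.append(
                -math.inf if ll == -math.inf else (ll - ll_half) / math.log(10)
            )
        per_family[ped.family_id] = curve
    pooled = [
        sum(per_family[f][i] for f in per_family) for i in range(len(grid))
    ]
    best, best_theta = max_lod_curve(grid, pooled)
    return LODResult(grid, pooled, best, best_theta, per_family)


def max_lod_curve(
    theta_grid: Sequence[float], lod: Sequence[float]
) -> tuple[float, float]:
    """(max LOD, argmax theta); ties broken toward the smallest theta."""
    if not theta_grid:
        raise ValueError("empty theta grid")
    pairs = sorted(zip(theta_grid, lod))
    best_t, best_l = pairs[0]
    for t, l in pairs[1:]:
        if l > best_l:
            best_t, best_l = t, l
    return best_l, best_t


def max_lod(result: LODResult) -> tuple[float, float]:
    return max_lod_curve(result.theta_grid, result.lod)
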