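"""Independent reference implementations used only by the test suite.

These deliberately use different algorithms from the package (full joint
enumeration instead of variable elimination, position-wise membership
instead of interval arithmetic, 1-D grid search instead of EM) so that
agreement is meaningful.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from clccmap.linkage import GeneticModel
from clccmap.pedigree import Pedigree

Hap = tuple[int, int]  # (disease allele, marker allele)


def _unary_states(
    ind, observed, model: GeneticModel, n_alleles: int
) -> list[tuple[Hap, Hap, float]]:
    """All phased (paternal hap, maternal hap) states with their penetrance
    x observation weight."""
    pen = model.penetrance
    obs = None
    if observed is not None:
        a1, a2 = int(observed[0]), int(observed[1])
        if a1 >= 0 and a2 >= 0:
            obs = tuple(sorted((a1, a2)))
    out = []
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
                    out.append(((dp, ap), (dm, am), w))
    return out


def _transmit_prob(state: tuple[Hap, Hap], hap: Hap, theta: float) -> float:
    """P(parent with phased state transmits gamete hap)."""
    (d1, a1), (d2, a2) = state
    p = 0.0
    for d, a_same, a_other in ((d1, a1, a2), (d2, a2, a1)):
        if hap[0] == d:
            if hap[1] == a_same:
                p += 0.5 * (1.0 - theta)
            if hap[1] == a_other:
                p += 0.5 * theta
    return p


def brute_force_likelihood(
    ped: Pedigree,
    genotypes: Mapping[str, Sequence[int]],
    model: GeneticModel,
    theta: float,
    n_alleles: int = 2,
) -> float:
    """Full-joint enumeration of the two-point pedigree likelihood by
    depth-first search over every individual's phased two-locus state."""
    inds = ped.topological_order()
    q = model.disease_allele_freq
    dfreq = (1.0 - q, q)
    mfreq = model.marker_freqs(n_alleles)
    statelists = [
        _unary_states(ind, genotypes.get(ind.id), model, n_alleles)
        for ind in inds
    ]
    assignment: dict[str, tuple[Hap, Hap]] = {}
    total = 0.0

    def rec(i: int, prob: float) -> None:
        nonlocal total
        if i == len(inds):
            total += prob
            return
        ind = inds[i]
        for hp, hm, w in statelists[i]:
            if ind.is_founder:
                pr = (
                    dfreq[hp[0]] * mfreq[hp[1]]
                    * dfreq[hm[0]] * mfreq[hm[1]]
                )
            else:
                pr = _transmit_prob(
                    assignment[ind.father_id], hp, theta
                ) * _transmit_prob(assignment[ind.mother_id], hm, theta)
            p = prob * pr * w
            if p == 0.0:
                continue
            assignment[ind.id] = (hp, hm)
            rec(i + 1, p)
        assignment.pop(ind.id, None)

    rec(0, 1.0)
    return total


def state_space_size(
    ped: Pedigree,
    genotypes: Mapping[str, Sequence[int]],
    model: GeneticModel,
    n_alleles: int = 2,
) -> int:
    """Product of per-individual state counts (brute-force cost bound)."""
    size = 1
    for ind in ped.individuals:
        size *= max(
            1, len(_unary_states(ind, genotypes.get(ind.id), model, n_alleles))
        )
    return size


# ---------------------------------------------------------------------------
# position-wise interval intersection


def positionwise_intersection(
    segment_sets: Sequence[Sequence[tuple[int, int]]], n_positions: int
) -> np.ndarray:
    """Boolean membership (1-based positions 1..n_positions) of the
    intersection of per-individual segment unions."""
    shared = np.ones(n_positions, dtype=bool)
    for segments in segment_sets:
        member = np.zeros(n_positions, dtype=bool)
        for start, end in segments:
            member[start - 1 : end] = True
        shared &= member
    return shared


# ---------------------------------------------------------------------------
# two-SNP haplotype-frequency grid search


def two_snp_grid_mle(
    genotypes: Sequence[np.ndarray], step: float = 1e-4
) -> dict[tuple[int, int], float]:
    """Maximum-likelihood 4-haplotype frequencies for complete two-SNP
    genotypes by 1-D grid search over f(1,1).

    With complete genotype data the MLE allele frequencies equal the observed
    ones, leaving one free parameter; double heterozygotes are the only
    ambiguous class.
    """
    g = np.asarray(genotypes)  # (n, 2 snps, 2 alleles)
    if g.ndim != 3 or g.shape[1] != 2 or np.any(g < 0):
        raise ValueError("need complete two-SNP genotypes")
    p1 = g[:, 0, :].mean()  # freq of allele 1 at SNP 1
    p2 = g[:, 1, :].mean()
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)

    def loglik(f11: float) -> float:
        f = {
            (1, 1): f11,
            (1, 0): p1 - f11,
            (0, 1): p2 - f11,
            (0, 0): 1.0 - p1 - p2 + f11,
        }
        ll = 0.0
        for ind in g:
            opts1 = {tuple(sorted(ind[0]))}
            opts2 = {tuple(sorted(ind[1]))}
            (a1, b1) = next(iter(opts1))
            (a2, b2) = next(iter(opts2))
            pairs = {
                tuple(sorted((hap_a, hap_b)))
                for hap_a, hap_b in (
                    ((a1, a2), (b1, b2)),
                    ((a1, b2), (b1, a2)),
                )
            }
            p = 0.0
            for ha, hb in pairs:
                fa, fb = f[ha], f[hb]
                p += fa * fb if ha == hb else 2.0 * fa * fb
            if p <= 0.0:
                return -math.inf
            ll += math.log(p)
        return ll

    grid = np.arange(lo, hi + step / 2, step)
    best = max(grid, key=loglik)
    return {
        (1, 1): float(best),
        (1, 0): float(p1 - best),
        (0, 1): float(p2 - best),
        (0, 0): float(1.0 - p1 - p2 + best),
    }


# ---------------------------------------------------------------------------
# Govardovskii alpha-band template, transcribed independently


def govardovskii_reference(lambda_max: float, lam: float) -> float:
    """Unnormalised Govardovskii et al. (2000) A1 alpha-band absorbance."""
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    b, c = 0.922, 1.104
    a = 0.8795 + 0.0459 * math.exp(-((lambda_max - 300.0) ** 2) / 11940.0)
    x = lambda_max / lam
    return 1.0 / (
        math.exp(A * (a - x))
        + math.exp(B * (b - x))
        + math.exp(C * (c - x))
        + D
    )
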