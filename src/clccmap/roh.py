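"""Runs of homozygosity (ROH) and cross-individual autozygosity mapping.

In offspring of consanguineous unions, long runs of homozygous genotypes mark
chromosome segments inherited identical-by-descent from a shared ancestor.
Intersecting those runs across all affected individuals, then insisting on an
identical shared homozygous haplotype, localises a recessive disease allele.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, intersect_segment_sets
from .markers import MarkerMap


@dataclass(frozen=True)
class ROHParams:
    """Thresholds a run must satisfy to be called.

    Defaults (25 SNPs / 500 kb / 0 hets / 2 missing) are tuned to detect the
    multi-megabase autozygous segments of consanguineous offspring at
    SNP-array density; they are deliberately conservative.
    """

    min_snps: int = 25
    min_length_bp: int = 500_000
    max_het: int = 0
    max_missing: int = 2

    def __post_init__(self) -> None:
        if min(self.min_snps, self.min_length_bp, self.max_het, self.max_missing) < 0:
            raise ValueError("ROH thresholds must be >= 0")


@dataclass(frozen=True)
class ROHSegment:
    interval: GenomicInterval
    snp_count: int


def _call_codes(genotypes: np.ndarray) -> np.ndarray:
    """Per-SNP call code: 0 = homozygous, 1 = heterozygous, 2 = missing."""
    g = np.asarray(genotypes)
    missing = (g[:, 0] < 0) | (g[:, 1] < 0)
    het = (~missing) & (g[:, 0] != g[:, 1])
    return np.where(missing, 2, np.where(het, 1, 0))


def detect_roh(
    genotypes: np.ndarray,
    marker_map: MarkerMap,
    params: ROHParams = ROHParams(),
) -> list[ROHSegment]:
    """Maximal runs of homozygosity for one individual.

    `genotypes` is an (n_markers, 2) array of allele indices aligned to the
    map order (-1 = missing).  Runs are grown left to right: a window is
    extended while its heterozygote and missing counts stay within budget,
    trimmed so that both boundaries sit on homozygous SNPs, and reported when
    it meets the SNP-count and physical-length thresholds.  Reported
    segments are non-overlapping and sorted.
    """
    g = np.asarray(genotypes)
    if g.shape[0] != len(marker_map):
        raise ValueError(
            f"genotype length {g.shape[0]} != map length {len(marker_map)}"
        )
    codes = _call_codes(g)
    pos = marker_map.positions_bp
    chroms = [m.chromosome for m in marker_map.markers]
    segments: list[ROHSegment] = []
    n = len(codes)
    i = 0
    while i < n:
        if codes[i] != 0:
            i += 1
            continue
        chrom = chroms[i]
        het = miss = 0
        j = i
        last_hom = i
        while j + 1 < n and chroms[j + 1] == chrom:
            c = codes[j + 1]
            if c == 1 and het + 1 > params.max_het:
                break
            if c == 2 and miss + 1 > params.max_missing:
                break
            j += 1
            if c == 1:
                het += 1
            elif c == 2:
                miss += 1
            else:
                last_hom = j
        j = last_hom  # trim trailing non-homozygous calls
        snp_count = j - i + 1
        length = pos[j] - pos[i] + 1
        if snp_count >= params.min_snps and length >= params.min_length_bp:
            segments.append(
                ROHSegment(GenomicInterval(chrom, int(pos[i]), int(pos[j])), snp_count)
            )
        i = j + 1
    return segments


def shared_autozygous_interval(
    roh_by_affected: Mapping[str, Sequence[ROHSegment]],
    require_all: bool = True,
) -> list[GenomicInterval]:
    """Maximal intervals covered by at least one ROH of every affected
    individual (when ``require_all``; otherwise the union)."""
    sets = [
        [seg.interval for seg in segs] for segs in roh_by_affected.values()
    ]
    if not sets:
        return []
    if require_all:
        return intersect_segment_sets(sets)
    from .intervals import merge_intervals

    return merge_intervals([iv for s in sets for iv in s])


def refine_by_haplotype(
    interval: GenomicInterval,
    genotypes_by_affected: Mapping[str, np.ndarray],
    marker_map: MarkerMap,
) -> GenomicInterval | None:
    """Largest sub-interval in which every affected individual is homozygous
    for the *same* allele at every SNP (the shared founder haplotype).

    Ties between equally long concordant runs go to the leftmost run.
    Returns None when no SNP shows concordant homozygosity.
    """
    idx = [
        i
        for i, m in enumerate(marker_map.markers)
        if interval.contains(m.chromosome, m.position_bp)
    ]
    if not idx:
        return None
    concordant = []
    for i in idx:
        alleles = set()
        ok = True
        for g in genotypes_by_affected.values():
            a, b = int(g[i][0]), int(g[i][1])
            if a < 0 or b < 0 or a != b:
                ok = False
                break
            alleles.add(a)
        concordant.append(ok and len(alleles) == 1)
    # longest run of True, leftmost on ties
    best = (0, -1, -1)  # (length, start, end) over idx positions
    run_start = None
    for k, c in enumerate(concordant + [False]):
        if c and run_start is None:
            run_start = k
        elif not c and run_start is not None:
            length = k - run_start
            if length > best[0]:
                best = (length, run_start, k - 1)
            run_start = None
    if best[0] == 0:
        return None
    pos = marker_map.positions_bp
    return GenomicInterval(
        interval.chromosome, int(pos[idx[best[1]]]), int(pos[idx[best[2]]])
    )
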