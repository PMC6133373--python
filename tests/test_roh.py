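"""ROH detection, shared-interval intersection and haplotype refinement."""

import numpy as np
import pytest

from clccmap.intervals import GenomicInterval
from clccmap.roh import (
    ROHParams,
    detect_roh,
    refine_by_haplotype,
    shared_autozygous_interval,
)
from conftest import het, hom, make_map


def plant_block(n, start, end, rng=None, allele=0):
    """Heterozygous background with a homozygous block at marker indices
    [start, end] (inclusive)."""
    g = het(n)
    g[start : end + 1] = allele
    return g


def test_planted_block_recovered_exactly(small_map):
    g = plant_block(len(small_map), 30, 69)
    segs = detect_roh(g, small_map, ROHParams(25, 100_000, 0, 0))
    assert len(segs) == 1
    seg = segs[0]
    assert seg.snp_count == 40
    assert seg.interval.start_bp == small_map[30].position_bp
    assert seg.interval.end_bp == small_map[69].position_bp


def test_short_blocks_filtered_by_both_thresholds(small_map):
    g = plant_block(len(small_map), 10, 20)  # 11 SNPs, 100 kb
    assert detect_roh(g, small_map, ROHParams(25, 100_000, 0, 0)) == []
    assert detect_roh(g, small_map, ROHParams(5, 200_000, 0, 0)) == []
    assert len(detect_roh(g, small_map, ROHParams(5, 100_000, 0, 0))) == 1


def test_het_budget_splits_runs(small_map):
    g = plant_block(len(small_map), 20, 79)
    g[50] = [0, 1]  # single embedded het
    strict = detect_roh(g, small_map, ROHParams(10, 50_000, 0, 0))
    assert [s.interval.start_bp for s in strict] == [
        small_map[20].position_bp,
        small_map[51].position_bp,
    ]
    lenient = detect_roh(g, small_map, ROHParams(10, 50_000, 1, 0))
    assert len(lenient) == 1
    # boundaries still trimmed to homozygous SNPs
    assert lenient[0].interval.start_bp == small_map[20].position_bp
    assert lenient[0].interval.end_bp == small_map[79].position_bp


def test_missing_budget_and_trimming(small_map):
    g = plant_block(len(small_map), 20, 59)
    g[20] = [-1, -1]  # missing at the nominal left edge
    segs = detect_roh(g, small_map, ROHParams(10, 50_000, 0, 2))
    assert len(segs) == 1
    # boundary trimmed to the first homozygous SNP
    assert segs[0].interval.start_bp == small_map[21].position_bp


def test_boundary_error_at_most_one_gap_over_seeds(small_map):
    """Planted homozygous blocks in heterozygous backgrounds are recovered
    with zero boundary error (<= 1 inter-marker gap) for every seed."""
    gap = 10_000
    for seed in range(20):
        rng = np.random.default_rng(seed)
        start = int(rng.integers(5, 40))
        end = start + int(rng.integers(30, 50))
        g = plant_block(len(small_map), start, end)
        segs = detect_roh(g, small_map, ROHParams(25, 100_000, 0, 0))
        assert len(segs) == 1
        assert abs(segs[0].interval.start_bp - small_map[start].position_bp) <= gap
        assert abs(segs[0].interval.end_bp - small_map[end].position_bp) <= gap


def test_no_false_segments_on_heterozygous_data(small_map):
    assert detect_roh(het(len(small_map)), small_map, ROHParams()) == []


def test_genotype_map_length_mismatch(small_map):
    with pytest.raises(ValueError):
        detect_roh(het(5), small_map)


def test_shared_autozygous_interval():
    roh = {
        "A": [_seg("chr1", 100, 500)],
        "B": [_seg("chr1", 300, 800)],
        "C": [_seg("chr1", 200, 600), _seg("chr1", 900, 950)],
    }
    assert shared_autozygous_interval(roh) == [GenomicInterval("chr1", 300, 500)]
    union = shared_autozygous_interval(roh, require_all=False)
    assert union == [
        GenomicInterval("chr1", 100, 800),
        GenomicInterval("chr1", 900, 950),
    ]


def _seg(chrom, start, end):
    from clccmap.roh import ROHSegment

    return ROHSegment(GenomicInterval(chrom, start, end), snp_count=1)


def test_refine_by_haplotype_trims_to_concordant_run(small_map):
    """All affecteds homozygous inside [40, 59] for the same allele; one
    individual switches to the other homozygote outside."""
    a = hom(len(small_map), 0)
    b = hom(len(small_map), 1)
    b[40:60] = 0
    interval = GenomicInterval("chr1", small_map[0].position_bp,
                               small_map[len(small_map) - 1].position_bp)
    refined = refine_by_haplotype(interval, {"A": a, "B": b}, small_map)
    assert refined is not None
    assert refined.start_bp == small_map[40].position_bp
    assert refined.end_bp == small_map[59].position_bp


def test_refine_none_when_no_concordant_site(small_map):
    refined = refine_by_haplotype(
        GenomicInterval("chr1", 1, 10**9),
        {"A": hom(len(small_map), 0), "B": hom(len(small_map), 1)},
        small_map,
    )
    assert refined is None


def test_refine_tie_goes_leftmost():
    m = make_map(n=9)
    a = hom(9, 0)
    b = np.array([[0, 0]] * 3 + [[0, 1]] + [[0, 0]] * 3 + [[0, 1], [0, 0]])
    interval = GenomicInterval("chr1", 1, 10**9)
    refined = refine_by_haplotype(interval, {"A": a, "B": b}, m)
    # runs of length 3 at [0..2] and [4..6]; leftmost wins
    assert refined.start_bp == m[0].position_bp
    assert refined.end_bp == m[2].position_bp
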