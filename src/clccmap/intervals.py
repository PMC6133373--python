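"""Genomic intervals and interval algebra for autozygosity mapping.

Coordinates are 1-based inclusive throughout the library, matching the way
physical positions are printed in the human genetics literature
(e.g. ``chr1:108,820,610-109,142,651``).  BED files on disk use the
conventional 0-based half-open coordinates; :func:`read_bed` and
:func:`write_bed` convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, inclusive physical interval on a chromosome."""

    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError(
                f"start_bp {self.start_bp} > end_bp {self.end_bp} on {self.chromosome}"
            )
        if self.start_bp < 1:
            raise ValueError("1-based coordinates must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, chromosome: str, position_bp: int) -> bool:
        return (
            chromosome == self.chromosome
            and self.start_bp <= position_bp <= self.end_bp
        )

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            other.chromosome == self.chromosome
            and self.start_bp <= other.start_bp
            and other.end_bp <= self.end_bp
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            other.chromosome == self.chromosome
            and self.start_bp <= other.end_bp
            and other.start_bp <= self.end_bp
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chromosome,
            max(self.start_bp, other.start_bp),
            min(self.end_bp, other.end_bp),
        )


def interval_length_kb(interval: GenomicInterval) -> int:
    """Interval length in kb, rounded to the nearest integer.

    A single-bp interval rounds to 0 kb; the printed critical region
    chr1:108,820,610-109,142,651 rounds to 322 kb.
    """
    return round(interval.length_bp / 1000)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: merge overlapping/adjacent ones, sorted."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and iv.chromosome == out[-1].chromosome and iv.start_bp <= out[-1].end_bp + 1:
            out[-1] = GenomicInterval(
                iv.chromosome, out[-1].start_bp, max(out[-1].end_bp, iv.end_bp)
            )
        else:
            out.append(iv)
    return out


def intersect_segment_sets(
    segment_sets: Sequence[Sequence[GenomicInterval]],
) -> list[GenomicInterval]:
    """Maximal intervals covered by at least one segment of *every* set.

    This is the interval-algebra core of cross-individual autozygosity
    intersection.  Each input set is first unioned (an individual may carry
    several runs of homozygosity); the result is the n-way intersection of
    those unions, sorted, possibly empty.
    """
    if not segment_sets:
        return []
    current = merge_intervals(segment_sets[0])
    for segs in segment_sets[1:]:
        merged = merge_intervals(segs)
        nxt: list[GenomicInterval] = []
        for a in current:
            for b in merged:
                got = a.intersect(b)
                if got is not None:
                    nxt.append(got)
        current = sorted(nxt)
        if not current:
            return []
    return current


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into 1-based inclusive intervals."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        out.append(GenomicInterval(chrom, start + 1, end))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open)."""
    lines = [
        f"{iv.chromosome}\t{iv.start_bp - 1}\t{iv.end_bp}" for iv in intervals
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
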