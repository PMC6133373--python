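"""Marker maps: ordered SNP/microsatellite positions with allele frequencies.

MAP file dialect (tab-separated): ``chromosome  marker_id  position_bp
[allele_freqs comma-separated]``.  Positions must be strictly increasing
within a chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class Marker:
    marker_id: str
    chromosome: str
    position_bp: int
    allele_freqs: tuple[float, ...] = (0.5, 0.5)

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError(f"{self.marker_id}: position must be >= 1")
        if len(self.allele_freqs) < 2:
            raise ValueError(f"{self.marker_id}: need >= 2 alleles")
        if abs(sum(self.allele_freqs) - 1.0) > 1e-9:
            raise ValueError(f"{self.marker_id}: allele freqs must sum to 1")

    @property
    def allele_count(self) -> int:
        return len(self.allele_freqs)


@dataclass
class MarkerMap:
    markers: list[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: dict[str, int] = {}
        for m in self.markers:
            prev = seen.get(m.chromosome)
            if prev is not None and m.position_bp <= prev:
                raise ValueError(
                    f"positions not strictly increasing on {m.chromosome}"
                )
            seen[m.chromosome] = m.position_bp

    def __len__(self) -> int:
        return len(self.markers)

    def __getitem__(self, i: int) -> Marker:
        return self.markers[i]

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([m.position_bp for m in self.markers])

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def index_of(self, marker_id: str) -> int:
        for i, m in enumerate(self.markers):
            if m.marker_id == marker_id:
                return i
        raise KeyError(marker_id)

    def nearest_index(self, chromosome: str, position_bp: int) -> int:
        best, best_d = -1, None
        for i, m in enumerate(self.markers):
            if m.chromosome != chromosome:
                continue
            d = abs(m.position_bp - position_bp)
            if best_d is None or d < best_d:
                best, best_d = i, d
        if best < 0:
            raise KeyError(f"no markers on {chromosome}")
        return best


def haldane_recomb_fraction(distance_bp: float, cm_per_mb: float = 1.0) -> float:
    """Recombination fraction from physical distance via the Haldane map
    function at a fixed cM/Mb rate (default 1 cM/Mb, the genome-average
    convention)."""
    morgans = distance_bp / 1e6 * cm_per_mb / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * morgans))


def adjacent_recomb_fractions(
    marker_map: MarkerMap, cm_per_mb: float = 1.0
) -> np.ndarray:
    """theta between consecutive markers (0.5 across chromosome breaks)."""
    thetas = np.empty(max(len(marker_map) - 1, 0))
    for i in range(len(marker_map) - 1):
        a, b = marker_map[i], marker_map[i + 1]
        if a.chromosome != b.chromosome:
            thetas[i] = 0.5
        else:
            thetas[i] = haldane_recomb_fraction(
                b.position_bp - a.position_bp, cm_per_mb
            )
    return thetas


def write_map(marker_map: MarkerMap, path: str | Path) -> None:
    lines = [
        "\t".join(
            [
                m.chromosome,
                m.marker_id,
                str(m.position_bp),
                ",".join(f"{f:.6g}" for f in m.allele_freqs),
            ]
        )
        for m in marker_map.markers
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_map(path: str | Path) -> MarkerMap:
    markers = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        chrom, mid, pos = f[0], f[1], int(f[2])
        freqs: Sequence[float]
        if len(f) > 3 and f[3]:
            freqs = tuple(float(x) for x in f[3].split(","))
        else:
            freqs = (0.5, 0.5)
        markers.append(Marker(mid, chrom, pos, tuple(freqs)))
    return MarkerMap(markers)
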