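"""Shared fixtures: small pedigrees, marker maps and genotype helpers."""

from __future__ import annotations

import numpy as np
import pytest

from clccmap.markers import Marker, MarkerMap
from clccmap.pedigree import Individual, Pedigree


@pytest.fixture(scope="session")
def bundled_report(tmp_path_factory):
    """The bundled 8-family study, run once per session: (report, out_dir)."""
    from clccmap.pipeline import bundled_config_path, load_config, run_pipeline

    cfg = load_config(bundled_config_path())
    out = tmp_path_factory.mktemp("study")
    cfg = cfg.model_copy(update={"out_dir": str(out)})
    return run_pipeline(cfg), out


@pytest.fixture
def nuclear_ped() -> Pedigree:
    return Pedigree(
        "NUC",
        [
            Individual("F", sex="male", affection="unaffected"),
            Individual("M", sex="female", affection="unaffected"),
            Individual("A1", "F", "M", "male", "affected"),
            Individual("U1", "F", "M", "female", "unaffected"),
        ],
    )


@pytest.fixture
def first_cousin_ped() -> Pedigree:
    from clccmap.simulate import build_pedigree

    return build_pedigree("first_cousin", 2, 1, seed=0, family_id="FC")


def make_map(
    n: int = 100,
    spacing_bp: int = 10_000,
    start_bp: int = 1_000_000,
    chromosome: str = "chr1",
    freqs: tuple[float, float] = (0.5, 0.5),
) -> MarkerMap:
    return MarkerMap(
        [
            Marker(f"m{i + 1}", chromosome, start_bp + i * spacing_bp, freqs)
            for i in range(n)
        ]
    )


@pytest.fixture
def small_map() -> MarkerMap:
    return make_map()


def het(n: int) -> np.ndarray:
    """n heterozygous biallelic genotypes."""
    return np.tile([0, 1], (n, 1))


def hom(n: int, allele: int = 0) -> np.ndarray:
    return np.full((n, 2), allele)
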