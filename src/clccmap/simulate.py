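"""Synthetic-data generators for the whole mapping pipeline.

These generators emulate the inputs of a consanguineous recessive-disease
mapping study and of a larval-zebrafish photopic ERG experiment:

* pedigrees from templates (nuclear, first-cousin, double-first-cousin);
* gene-dropped SNP genotypes with a planted founder haplotype carrying the
  disease allele, conditioned by rejection sampling so the designated
  individuals are affected, with the true identity-by-descent segments
  recorded;
* ERG amplitude grids generated from the four-cone spectral model with
  additive Gaussian noise;
* two-group morphometry tables.

Everything is driven by explicit seeds and is bit-reproducible.
Physical distance converts to recombination fraction through the Haldane map
function at a fixed 1 cM/Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .erg import (
    CONE_CLASSES,
    DEFAULT_IRRADIANCES,
    DEFAULT_WAVELENGTHS,
    ConeParams,
    PigmentTemplate,
    default_templates,
    forward_model,
)
from .intervals import GenomicInterval
from .linkage import GeneticModel
from .markers import Marker, MarkerMap, haldane_recomb_fraction
from .pedigree import Individual, Pedigree

# ---------------------------------------------------------------------------
# pedigree templates

TEMPLATES = ("nuclear", "first_cousin", "double_first_cousin", "custom")


def build_pedigree(
    template: str,
    n_affected: int,
    n_unaffected: int,
    seed: int = 0,
    family_id: str = "FAM1",
    custom_individuals: Sequence[Individual] | None = None,
) -> Pedigree:
    """Construct a pedigree from a named template.

    Affected and unaffected individuals are always children of the final
    mating; under a recessive model an affected founder has no within-pedigree
    explanation, so templates never place affection on founders.  The seed
    only randomises child sexes; the structure is deterministic.
    """
    if n_affected < 0 or n_unaffected < 0:
        raise ValueError("counts must be >= 0")
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}")
    if template == "custom":
        if custom_individuals is None:
            raise ValueError("custom template needs custom_individuals")
        ped = Pedigree(family_id, list(custom_individuals))
        for ind in ped.individuals:
            if ind.affection == "affected" and ind.is_founder:
                raise ValueError(
                    f"{ind.id}: affected founder is impossible under the"
                    " recessive templates"
                )
        return ped
    rng = np.random.default_rng(seed)
    inds: list[Individual] = []
    if template == "nuclear":
        father, mother = "F", "M"
        inds += [
            Individual("F", sex="male", affection="unaffected"),
            Individual("M", sex="female", affection="unaffected"),
        ]
    elif template == "first_cousin":
        inds += [
            Individual("GP1", sex="male", affection="unaffected"),
            Individual("GP2", sex="female", affection="unaffected"),
            Individual("P1", "GP1", "GP2", "male", "unaffected"),
            Individual("P2", "GP1", "GP2", "female", "unaffected"),
            Individual("S1", sex="female", affection="unaffected"),
            Individual("S2", sex="male", affection="unaffected"),
            Individual("C1", "P1", "S1", "male", "unaffected"),
            Individual("C2", "S2", "P2", "female", "unaffected"),
        ]
        father, mother = "C1", "C2"
    else:  # double_first_cousin
        inds += [
            Individual("GA1", sex="male", affection="unaffected"),
            Individual("GA2", sex="female", affection="unaffected"),
            Individual("GB1", sex="male", affection="unaffected"),
            Individual("GB2", sex="female", affection="unaffected"),
            Individual("A1", "GA1", "GA2", "male", "unaffected"),
            Individual("A2", "GA1", "GA2", "female", "unaffected"),
            Individual("B1", "GB1", "GB2", "female", "unaffected"),
            Individual("B2", "GB1", "GB2", "male", "unaffected"),
            Individual("C1", "A1", "B1", "male", "unaffected"),
            Individual("C2", "B2", "A2", "female", "unaffected"),
        ]
        father, mother = "C1", "C2"
    for i in range(n_affected + n_unaffected):
        aff = "affected" if i < n_affected else "unaffected"
        sex = "male" if rng.integers(2) == 0 else "female"
        inds.append(Individual(f"K{i + 1}", father, mother, sex, aff))
    return Pedigree(family_id, inds)


# ---------------------------------------------------------------------------
# marker maps


def default_marker_map(
    chromosome: str = "chr1",
    start_bp: int = 106_500_000,
    spacing_bp: int = 5_000,
    n_markers: int = 1_000,
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    anchor_positions: Sequence[int] = (),
) -> MarkerMap:
    """Array-density biallelic SNP map: default 5 kb spacing over 5 Mb
    (about 1,000 SNPs), MAF ~ Uniform(0.1, 0.5).

    `anchor_positions` forces markers at exact physical positions (each
    replaces the nearest regular position) so that simulated intervals can be
    bounded by real printed coordinates.
    """
    rng = np.random.default_rng(seed)
    positions = start_bp + spacing_bp * np.arange(n_markers)
    positions = positions.astype(np.int64)
    for p in sorted(anchor_positions):
        i = int(np.argmin(np.abs(positions - p)))
        positions[i] = p
    positions = np.sort(positions)
    if len(np.unique(positions)) != len(positions):
        raise ValueError("anchor positions collide with the regular grid")
    markers = []
    for i, pos in enumerate(positions):
        maf = rng.uniform(*maf_range)
        markers.append(
            Marker(f"snp{i + 1:05d}", chromosome, int(pos), (1.0 - maf, maf))
        )
    return MarkerMap(markers)


# ---------------------------------------------------------------------------
# gene dropping

FOUNDER_HAPLOTYPE_LABEL = -1  # shared-ancestry label for planted chromosomes


@dataclass
class GeneDropTruth:
    """Truth container for a gene-dropped family."""

    genotypes: dict[str, np.ndarray]  # id -> (n_markers, 2) ordered (pat, mat)
    disease_genotypes: dict[str, np.ndarray]  # id -> (2,) at the disease locus
    disease_locus: tuple[str, int]
    true_ibd_segments: dict[str, list[GenomicInterval]]
    founder_haplotype: np.ndarray  # alleles over markers inside the region
    region_marker_indices: np.ndarray
    origin_labels: dict[str, np.ndarray] = field(default_factory=dict)
    attempts: int = 1


def auto_carrier_founders(ped: Pedigree) -> dict[str, int]:
    """Choose which founders carry one copy of the planted disease haplotype.

    If a single founder is an ancestor of *both* parents of every affected
    individual (consanguineous templates), one copy in that founder suffices.
    Otherwise one copy is planted in each parent-side founder lineage
    (nuclear families: both parents), modelling descent of both copies from
    an unrepresented common ancestor.
    """
    affected = [ped.by_id[a] for a in ped.affected_ids]
    if not affected:
        raise ValueError("pedigree has no affected individuals")
    for a in affected:
        if a.is_founder:
            raise ValueError(f"affected founder {a.id} cannot be gene-dropped")
    shared: set[str] | None = None
    for a in affected:
        both = (ped.ancestors(a.father_id) | {a.father_id}) & (
            ped.ancestors(a.mother_id) | {a.mother_id}
        )
        both = {i for i in both if ped.by_id[i].is_founder}
        shared = both if shared is None else shared & both
    if shared:
        chosen = sorted(shared)[0]
        return {chosen: 1}
    carriers: dict[str, int] = {}
    for a in affected:
        for pid in (a.father_id, a.mother_id):
            lineage = {pid} | ped.ancestors(pid)
            fnd = sorted(i for i in lineage if ped.by_id[i].is_founder)
            if not fnd:
                raise ValueError("no founder available on a parental lineage")
            carriers[fnd[0]] = 1
    return carriers


def gene_drop(
    ped: Pedigree,
    marker_map: MarkerMap,
    disease_model: GeneticModel,
    founder_haplotype_region: GenomicInterval,
    seed: int = 0,
    disease_position_bp: int | None = None,
    founder_haplotype: np.ndarray | None = None,
    carrier_founders: Mapping[str, int] | None = None,
    cm_per_mb: float = 1.0,
    max_attempts: int = 1_000_000,
    require_full_region: bool = True,
) -> GeneDropTruth:
    """Drop alleles through the pedigree and condition on the affection
    pattern by rejection sampling.

    The planted founder haplotype spans the markers inside
    `founder_haplotype_region` and carries the disease allele at the disease
    locus (default: the region midpoint).  Non-carrier founder chromosomes
    draw the disease allele at the model's population frequency, so under the
    default q = 1e-5 essentially every disease allele in the family descends
    from the plant.  An attempt is accepted when every affected individual is
    disease-homozygous, no unaffected individual is, and (by default) each
    affected individual's autozygous truth segment covers the whole planted
    region.
    """
    chrom = founder_haplotype_region.chromosome
    region_idx = np.array(
        [
            i
            for i, m in enumerate(marker_map.markers)
            if founder_haplotype_region.contains(m.chromosome, m.position_bp)
        ]
    )
    if region_idx.size == 0:
        raise ValueError("no markers inside the founder haplotype region")
    if disease_position_bp is None:
        disease_position_bp = (
            founder_haplotype_region.start_bp + founder_haplotype_region.end_bp
        ) // 2
    if not founder_haplotype_region.contains(chrom, disease_position_bp):
        raise ValueError("disease locus must lie inside the planted region")
    span = GenomicInterval(
        chrom,
        marker_map[0].position_bp,
        marker_map[len(marker_map) - 1].position_bp,
    )
    if not span.contains(chrom, disease_position_bp):
        raise ValueError("disease locus outside the marker map span")

    rng = np.random.default_rng(seed)
    n_markers = len(marker_map)
    # insert the disease locus into the locus sequence
    marker_pos = marker_map.positions_bp
    d_insert = int(np.searchsorted(marker_pos, disease_position_bp))
    loci_pos = np.insert(marker_pos.astype(float), d_insert, disease_position_bp)
    n_loci = n_markers + 1
    d_idx = d_insert  # index of the disease locus within loci
    marker_loci = np.array([i for i in range(n_loci) if i != d_idx])
    region_loci = np.isin(marker_loci, marker_loci[region_idx])

    thetas = np.array(
        [
            haldane_recomb_fraction(loci_pos[i + 1] - loci_pos[i], cm_per_mb)
            for i in range(n_loci - 1)
        ]
    )
    freqs = np.array([m.allele_freqs[1] for m in marker_map.markers])

    if founder_haplotype is None:
        founder_haplotype = (
            rng.random(region_idx.size) < freqs[region_idx]
        ).astype(int)
    founder_haplotype = np.asarray(founder_haplotype, dtype=int)
    if founder_haplotype.size != region_idx.size:
        raise ValueError("founder haplotype length != markers in region")

    carriers = (
        dict(carrier_founders)
        if carrier_founders is not None
        else auto_carrier_founders(ped)
    )
    for fid, copies in carriers.items():
        if not ped.by_id[fid].is_founder:
            raise ValueError(f"carrier {fid} is not a founder")
        if copies not in (1, 2):
            raise ValueError("carrier copies must be 1 or 2")

    q = disease_model.disease_allele_freq
    order = ped.topological_order()
    founders = [i for i in order if i.is_founder]
    affected = set(ped.affected_ids)
    unaffected = set(ped.unaffected_ids)
    label_counter = 0

    for attempt in range(1, max_attempts + 1):
        alleles: dict[str, np.ndarray] = {}  # id -> (2, n_loci)
        labels: dict[str, np.ndarray] = {}  # id -> (2, n_loci) int labels
        label_counter = 0
        for f in founders:
            hap_a = np.empty((2, n_loci), dtype=int)
            hap_l = np.empty((2, n_loci), dtype=int)
            n_plant = carriers.get(f.id, 0)
            for h in range(2):
                label_counter += 1
                marker_alleles = (rng.random(n_markers) < freqs).astype(int)
                d_allele = int(rng.random() < q)
                row = np.empty(n_loci, dtype=int)
                row[marker_loci] = marker_alleles
                row[d_idx] = d_allele
                lab = np.full(n_loci, label_counter, dtype=int)
                if h < n_plant:
                    row[marker_loci[region_loci]] = founder_haplotype
                    row[d_idx] = 1
                    lab[marker_loci[region_loci]] = FOUNDER_HAPLOTYPE_LABEL
                    lab[d_idx] = FOUNDER_HAPLOTYPE_LABEL
                hap_a[h] = row
                hap_l[h] = lab
            alleles[f.id] = hap_a
            labels[f.id] = hap_l
        ok = True
        for ind in order:
            if ind.is_founder:
                continue
            hap_a = np.empty((2, n_loci), dtype=int)
            hap_l = np.empty((2, n_loci), dtype=int)
            for h, pid in enumerate((ind.father_id, ind.mother_id)):
                start = rng.integers(2)
                switches = rng.random(n_loci - 1) < thetas
                chain = np.empty(n_loci, dtype=int)
                chain[0] = start
                chain[1:] = (start + np.cumsum(switches)) % 2
                hap_a[h] = alleles[pid][chain, np.arange(n_loci)]
                hap_l[h] = labels[pid][chain, np.arange(n_loci)]
            alleles[ind.id] = hap_a
            labels[ind.id] = hap_l
        # affection pattern conditioning
        for ind in order:
            dd = alleles[ind.id][0, d_idx] + alleles[ind.id][1, d_idx] == 2
            if ind.id in affected and not dd:
                ok = False
                break
            if ind.id in unaffected and dd:
                ok = False
                break
        if ok and require_full_region:
            for a in affected:
                lab = labels[a]
                full = np.all(
                    lab[0, marker_loci[region_loci]] == FOUNDER_HAPLOTYPE_LABEL
                ) and np.all(
                    lab[1, marker_loci[region_loci]] == FOUNDER_HAPLOTYPE_LABEL
                )
                if not full:
                    ok = False
                    break
        if ok:
            genotypes = {
                i.id: alleles[i.id][:, marker_loci].T.copy() for i in order
            }
            disease_genotypes = {
                i.id: alleles[i.id][:, d_idx].copy() for i in order
            }
            ibd: dict[str, list[GenomicInterval]] = {}
            for a in sorted(affected):
                lab = labels[a]
                same = lab[0] == lab[1]
                # maximal run of locus-wise shared ancestry containing the
                # disease locus
                lo = d_idx
                while lo > 0 and same[lo - 1]:
                    lo -= 1
                hi = d_idx
                while hi < n_loci - 1 and same[hi + 1]:
                    hi += 1
                ibd[a] = [
                    GenomicInterval(chrom, int(loci_pos[lo]), int(loci_pos[hi]))
                ]
            origin_labels = {
                i.id: labels[i.id][:, marker_loci].T.copy() for i in order
            }
            return GeneDropTruth(
                genotypes,
                disease_genotypes,
                (chrom, disease_position_bp),
                ibd,
                founder_haplotype,
                region_idx,
                origin_labels=origin_labels,
                attempts=attempt,
            )
    raise RuntimeError(
        f"rejection budget of {max_attempts} attempts exceeded for family"
        f" {ped.family_id}: the pedigree cannot realise the affection pattern"
    )


def simulate_cohort_chromosomes(
    marker_map: MarkerMap,
    snp_indices: Sequence[int],
    founder_haplotype: np.ndarray,
    founder_frequency: float,
    n_individuals: int,
    seed: int = 0,
) -> list[np.ndarray]:
    """Unphased control-cohort genotypes at a SNP subset, with the founder
    haplotype segregating at exactly the given population frequency (for EM
    recovery studies).

    Background chromosomes are drawn at linkage equilibrium conditioned on
    differing from the founder haplotype in at least one SNP, so the true
    population frequency of the founder haplotype equals ``founder_frequency``
    rather than being inflated by chance matches.
    """
    rng = np.random.default_rng(seed)
    idx = np.asarray(snp_indices)
    freqs = np.array([marker_map[int(i)].allele_freqs[1] for i in idx])
    fh = np.asarray(founder_haplotype, dtype=int)
    if fh.size != idx.size:
        raise ValueError("founder haplotype length mismatch")

    def background_chrom() -> np.ndarray:
        for _ in range(10_000):
            chrom = (rng.random(idx.size) < freqs).astype(int)
            if np.any(chrom != fh):
                return chrom
        raise RuntimeError(
            "could not draw a background chromosome distinct from the "
            "founder haplotype (allele frequencies too extreme)"
        )

    out = []
    for _ in range(n_individuals):
        chroms = []
        for _ in range(2):
            if rng.random() < founder_frequency:
                chroms.append(fh.copy())
            else:
                chroms.append(background_chrom())
        out.append(np.stack(chroms, axis=1))  # (n_snps, 2)
    return out


# ---------------------------------------------------------------------------
# ERG simulation


@dataclass(frozen=True)
class ERGSimConfig:
    """Amplitude-grid simulation settings: by default the 9-wavelength x
    7-irradiance x 4-replicate design with additive Gaussian noise whose SD
    is a floor (uV) plus a fraction of the model amplitude."""

    wavelengths_nm: tuple[float, ...] = DEFAULT_WAVELENGTHS
    irradiances: tuple[float, ...] = DEFAULT_IRRADIANCES
    replicates: int = 4
    noise_sd_floor: float = 0.5
    noise_sd_frac: float = 0.05
    response_type: str = "PIII"
    seed: int = 0

    def __post_init__(self) -> None:
        if any(i <= 0 for i in self.irradiances):
            raise ValueError("irradiances must be > 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def simulate_erg(
    cfg: ERGSimConfig,
    params_by_group: Mapping[str, ConeParams],
    templates: Mapping[str, PigmentTemplate] | None = None,
) -> pd.DataFrame:
    """Forward-model ERG amplitude table, one row per (group, wavelength,
    irradiance, replicate); replicates are treated as eyes."""
    templates = templates or default_templates()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for group in params_by_group:
        params = params_by_group[group]
        for lam in cfg.wavelengths_nm:
            for irr in cfg.irradiances:
                mu = float(forward_model(params, templates, irr, lam))
                sd = cfg.noise_sd_floor + cfg.noise_sd_frac * abs(mu)
                for rep in range(1, cfg.replicates + 1):
                    amp = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    rows.append(
                        (group, cfg.response_type, rep, lam, irr, rep, amp)
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "group",
            "response_type",
            "eye_id",
            "wavelength_nm",
            "irradiance",
            "replicate",
            "amplitude_uv",
        ],
    )


def default_wt_cone_params() -> ConeParams:
    """Wild-type simulation preset: amplitude maxima of order 100 uV and
    half-saturations above the 2500 hv.um^-2.s^-1 constant-quanta level, so
    that level sits below semi-saturation for every cone type."""
    return ConeParams(
        {"UV": 60.0, "blue": 80.0, "green": 100.0, "red": 120.0},
        {"UV": 3500.0, "blue": 4000.0, "green": 5000.0, "red": 6000.0},
    )


# ---------------------------------------------------------------------------
# morphometry simulation


@dataclass(frozen=True)
class GroupSpec:
    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


@dataclass(frozen=True)
class MorphoSimConfig:
    measures: Mapping[str, tuple[GroupSpec, GroupSpec]]
    seed: int = 0


def fig7_morphometry_config(seed: int = 0) -> MorphoSimConfig:
    """Morpholino-knockdown vs mismatch-control morphometry preset.

    Group means and sample sizes follow the published knockdown comparison
    (eye and lens areas in mm^2, layer thicknesses in um, rod counts per
    section); the SDs, which were not published, are set so that the
    two-sample t statistics land near the published p-values.
    """
    mo, mm = "clcc1-MO", "MM-MO"
    m = {
        "eye_area_mm2": (GroupSpec(mo, 0.13, 0.030, 40), GroupSpec(mm, 0.178, 0.030, 41)),
        "lens_area_mm2": (GroupSpec(mo, 0.019, 0.005, 40), GroupSpec(mm, 0.026, 0.005, 41)),
        "ipl_thickness_um": (GroupSpec(mo, 7.82, 4.7, 40), GroupSpec(mm, 12.30, 4.7, 41)),
        "onl_thickness_um": (GroupSpec(mo, 9.1, 3.0, 40), GroupSpec(mm, 12.9, 3.0, 41)),
        "inl_thickness_um": (GroupSpec(mo, 36.78, 2.4, 40), GroupSpec(mm, 36.12, 2.4, 41)),
        "gcl_thickness_um": (GroupSpec(mo, 40.0, 19.0, 40), GroupSpec(mm, 25.48, 19.0, 41)),
        "rod_count": (GroupSpec(mo, 22.5, 9.5, 8), GroupSpec(mm, 63.3, 9.5, 10)),
    }
    return MorphoSimConfig(m, seed=seed)


def simulate_morphometry(cfg: MorphoSimConfig) -> pd.DataFrame:
    """Normal draws per group per measure; columns group, measure, value."""
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for measure, groups in cfg.measures.items():
        for spec in groups:
            values = rng.normal(spec.mean, spec.sd, spec.n)
            if spec.sd == 0:
                values = np.full(spec.n, spec.mean)
            for v in values:
                rows.append((spec.label, measure, float(v)))
    return pd.DataFrame(rows, columns=["group", "measure", "value"])


def simulate_rescue_outcomes(
    p_normal: float = 0.87, n_embryos: int = 100, seed: int = 0
) -> list[str]:
    """Per-embryo normal/abnormal labels for a rescue experiment."""
    if not 0.0 <= p_normal <= 1.0:
        raise ValueError("p_normal must be in [0, 1]")
    if n_embryos < 1:
        raise ValueError("need at least one embryo")
    rng = np.random.default_rng(seed)
    return [
        "normal" if rng.random() < p_normal else "abnormal"
        for _ in range(n_embryos)
    ]
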