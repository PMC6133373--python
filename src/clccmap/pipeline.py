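"""End-to-end synthetic study: simulate -> map -> link -> founder -> filter
-> ERG -> stats, from one YAML configuration.

The pipeline reproduces, on synthetic data, the analysis arc of a
consanguineous recessive-disease mapping study: gene-dropped families sharing
a planted founder haplotype are mapped by runs of homozygosity, the shared
autozygous interval is refined by haplotype concordance, two-point LOD scores
are pooled over families, the founder haplotype's population frequency is
re-estimated by EM in a simulated control cohort and converted to a
founder-sharing probability, candidate variants are filtered in the critical
interval, and the functional arm simulates and refits ERG cone spectral
sensitivities plus morphometry statistics.

The single global seed fans out to per-stage streams through
``numpy.random.SeedSequence((seed, stage_index))``, so any stage can be
re-run in isolation reproducibly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import sys
import time
from importlib import resources
from pathlib import Path
from typing import Any, Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .erg import default_templates, fit_cone_components, group_depression, sensitivity_spectrum
from .haplotypes import em_haplotype_frequencies, founder_sharing_probability
from .intervals import GenomicInterval, interval_length_kb, write_bed
from .linkage import GeneticModel, two_point_lod
from .markers import write_map
from .pedigree import read_ped, write_ped
from .roh import ROHParams, detect_roh, refine_by_haplotype, shared_autozygous_interval
from .simulate import (
    ERGSimConfig,
    build_pedigree,
    default_marker_map,
    default_wt_cone_params,
    fig7_morphometry_config,
    gene_drop,
    simulate_cohort_chromosomes,
    simulate_erg,
    simulate_morphometry,
    simulate_rescue_outcomes,
)
from .stats import ratio_of_means, rescue_fraction, unpaired_t_test
from .variants import FilterRules, filter_candidate_variants

logger = logging.getLogger("clccmap.pipeline")

_STAGE_INDEX = {
    "simulate": 0,
    "roh": 1,
    "lod": 2,
    "founder": 3,
    "variants": 4,
    "erg": 5,
    "stats": 6,
}


def stage_seed(master_seed: int, stage: str, extra: int = 0) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence((master_seed, _STAGE_INDEX[stage], extra))
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# configuration schema


class StageToggles(BaseModel):
    model_config = ConfigDict(extra="forbid")
    simulate: bool = True
    roh: bool = True
    lod: bool = True
    founder: bool = True
    variants: bool = True
    erg: bool = True
    stats: bool = True


class FamilySpec(BaseModel):
    model_config = ConfigDict(extra="forbid")
    template: Literal["nuclear", "first_cousin", "double_first_cousin"]
    n_affected: int = Field(ge=0)
    n_unaffected: int = Field(ge=0)


class RegionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    chromosome: str = "chr1"
    start_bp: int = Field(default=108_820_610, ge=1)
    end_bp: int = Field(default=109_142_651, ge=1)


class MarkerMapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    start_bp: int = Field(default=106_500_000, ge=1)
    spacing_bp: int = Field(default=5_000, ge=1)
    n_markers: int = Field(default=1_000, ge=2)
    maf_low: float = Field(default=0.1, gt=0, lt=0.5)
    maf_high: float = Field(default=0.5, gt=0, le=0.5)


class GeneticModelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    disease_allele_freq: float = Field(default=0.00001, gt=0, lt=1)
    penetrance: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def build(self) -> GeneticModel:
        return GeneticModel(self.disease_allele_freq, tuple(self.penetrance))


class ROHConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_snps: int = Field(default=25, ge=0)
    min_length_bp: int = Field(default=500_000, ge=0)
    max_het: int = Field(default=0, ge=0)
    max_missing: int = Field(default=2, ge=0)

    def build(self) -> ROHParams:
        return ROHParams(self.min_snps, self.min_length_bp, self.max_het, self.max_missing)


class FounderConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_em_snps: int = Field(default=8, ge=1)
    n_controls: int = Field(default=200, ge=10)
    founder_frequency: float = Field(default=0.03, gt=0, lt=1)
    k_founder_chromosomes: int = Field(default=7, ge=0)


class ERGConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    replicates: int = Field(default=4, ge=1)
    noise_sd_floor: float = Field(default=0.5, ge=0)
    noise_sd_frac: float = Field(default=0.05, ge=0)
    depression_factor: float = Field(default=0.4, gt=0, le=1)
    n_starts: int = Field(default=16, ge=1)


class RescueConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_normal: float = Field(default=0.87, ge=0, le=1)
    n_embryos: int = Field(default=100, ge=1)


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    seed: int = 1
    out_dir: str = "study_out"
    stages: StageToggles = StageToggles()
    families: list[FamilySpec] = Field(
        default_factory=lambda: [
            FamilySpec(template="first_cousin", n_affected=2, n_unaffected=1),
            FamilySpec(template="first_cousin", n_affected=1, n_unaffected=1),
            FamilySpec(template="nuclear", n_affected=2, n_unaffected=1),
            FamilySpec(template="nuclear", n_affected=1, n_unaffected=1),
            FamilySpec(template="nuclear", n_affected=1, n_unaffected=1),
            FamilySpec(template="nuclear", n_affected=1, n_unaffected=1),
            FamilySpec(template="nuclear", n_affected=1, n_unaffected=1),
            FamilySpec(template="nuclear", n_affected=1, n_unaffected=1),
        ]
    )
    region: RegionConfig = RegionConfig()
    marker_map: MarkerMapConfig = MarkerMapConfig()
    genetic_model: GeneticModelConfig = GeneticModelConfig()
    roh_params: ROHConfig = ROHConfig()
    founder: FounderConfig = FounderConfig()
    erg: ERGConfig = ERGConfig()
    rescue: RescueConfig = RescueConfig()


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    return PipelineConfig.model_validate(raw)


def validate_config(path: str | Path) -> list[str]:
    """Exhaustive schema validation; returns a list of error strings
    (empty when the config is valid)."""
    try:
        text = Path(path).read_text()
    except OSError as exc:
        return [f"unreadable config file: {exc}"]
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        return [f"invalid YAML: {exc}"]
    try:
        PipelineConfig.model_validate(raw or {})
    except ValidationError as exc:
        return [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
            for e in exc.errors()
        ]
    return []


def bundled_config_path() -> Path:
    return Path(str(resources.files("clccmap") / "data" / "toy_study.yaml"))


# ---------------------------------------------------------------------------
# study report


class StudyReport:
    """Per-stage outputs plus provenance; serialisable as JSON and text."""

    def __init__(self, config: PipelineConfig):
        cfg_json = config.model_dump_json()
        self.data: dict[str, Any] = {
            "provenance": {
                "version": __version__,
                "seed": config.seed,
                "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            },
            "stages": {},
        }

    def add(self, stage: str, payload: dict[str, Any]) -> None:
        self.data["stages"][stage] = payload

    def to_json(self) -> str:
        def default(o: Any) -> Any:
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, float) and math.isinf(o):
                return "-inf" if o < 0 else "inf"
            raise TypeError(type(o))

        def sanitize(x: Any) -> Any:
            if isinstance(x, dict):
                return {k: sanitize(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [sanitize(v) for v in x]
            if isinstance(x, float) and math.isinf(x):
                return "-inf" if x < 0 else "inf"
            return x

        return json.dumps(sanitize(self.data), indent=2, default=default)

    def summary_text(self) -> str:
        lines = [f"clccmap study report (seed {self.data['provenance']['seed']})"]
        for stage, payload in self.data["stages"].items():
            lines.append(f"[{stage}]")
            for k, v in payload.items():
                if isinstance(v, (int, float, str)):
                    lines.append(f"  {k}: {v}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# the pipeline


def run_pipeline(config: PipelineConfig) -> StudyReport:
    """Run all enabled stages; deterministic given (config, seed).

    Stage outputs are written under ``config.out_dir``; the consolidated
    report is returned and also written as report.json / report.txt.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = StudyReport(config)
    t_all = time.time()

    region = GenomicInterval(
        config.region.chromosome, config.region.start_bp, config.region.end_bp
    )
    model = config.genetic_model.build()

    marker_map = None
    families = None
    truths = None
    refined = None
    founder_hap = None

    if config.stages.simulate:
        t0 = time.time()
        sim_seed = stage_seed(config.seed, "simulate")
        mcfg = config.marker_map
        marker_map = default_marker_map(
            chromosome=region.chromosome,
            start_bp=mcfg.start_bp,
            spacing_bp=mcfg.spacing_bp,
            n_markers=mcfg.n_markers,
            maf_range=(mcfg.maf_low, mcfg.maf_high),
            seed=sim_seed,
            anchor_positions=(region.start_bp, region.end_bp),
        )
        region_idx = [
            i
            for i, m in enumerate(marker_map.markers)
            if region.contains(m.chromosome, m.position_bp)
        ]
        rng = np.random.default_rng(stage_seed(config.seed, "simulate", 1))
        founder_hap = (
            rng.random(len(region_idx))
            < np.array([marker_map[i].allele_freqs[1] for i in region_idx])
        ).astype(int)
        families = []
        truths = {}
        for i, spec in enumerate(config.families):
            fam_id = f"FAM{i + 1}"
            ped = build_pedigree(
                spec.template,
                spec.n_affected,
                spec.n_unaffected,
                seed=stage_seed(config.seed, "simulate", 10 + i),
                family_id=fam_id,
            )
            truth = gene_drop(
                ped,
                marker_map,
                model,
                region,
                seed=stage_seed(config.seed, "simulate", 100 + i),
                founder_haplotype=founder_hap,
            )
            families.append(ped)
            truths[fam_id] = truth
        write_ped(
            families,
            out / "study.ped",
            {f.family_id: truths[f.family_id].genotypes for f in families},
        )
        write_map(marker_map, out / "study.map")
        ibd = [
            seg
            for t in truths.values()
            for segs in t.true_ibd_segments.values()
            for seg in segs
        ]
        write_bed(ibd, out / "truth_ibd.bed")
        report.add(
            "simulate",
            {
                "n_families": len(families),
                "n_markers": len(marker_map),
                "n_affected_total": sum(len(f.affected_ids) for f in families),
                "rejection_attempts": {
                    f.family_id: truths[f.family_id].attempts for f in families
                },
                "planted_region": f"{region.chromosome}:{region.start_bp}-{region.end_bp}",
                "elapsed_s": round(time.time() - t0, 2),
            },
        )
        logger.info("simulate stage done in %.1fs", time.time() - t0)

    if config.stages.roh:
        if families is None:
            raise RuntimeError("roh stage requires the simulate stage")
        t0 = time.time()
        params = config.roh_params.build()
        # homozygosity mapping is informative in consanguineous families,
        # where autozygous runs are long; outbred affecteds carry only the
        # short shared block and would fail the ROH length threshold
        mapping_families = [p for p in families if p.is_consanguineous()]
        if not mapping_families:
            mapping_families = list(families)
        roh_all = {}
        geno_affected = {}
        for ped in mapping_families:
            truth = truths[ped.family_id]
            for a in ped.affected_ids:
                key = f"{ped.family_id}:{a}"
                roh_all[key] = detect_roh(truth.genotypes[a], marker_map, params)
                geno_affected[key] = truth.genotypes[a]
        shared = shared_autozygous_interval(roh_all)
        refined = None
        if shared:
            # refine within the largest shared interval
            widest = max(shared, key=lambda iv: iv.length_bp)
            refined = refine_by_haplotype(widest, geno_affected, marker_map)
        report.add(
            "roh",
            {
                "n_roh_individuals": len(roh_all),
                "shared_intervals": [
                    f"{iv.chromosome}:{iv.start_bp}-{iv.end_bp}" for iv in shared
                ],
                "refined_interval": (
                    f"{refined.chromosome}:{refined.start_bp}-{refined.end_bp}"
                    if refined
                    else None
                ),
                "refined_length_kb": interval_length_kb(refined) if refined else None,
                "elapsed_s": round(time.time() - t0, 2),
            },
        )
        logger.info("roh stage done in %.1fs", time.time() - t0)

    if config.stages.lod:
        if families is None:
            raise RuntimeError("lod stage requires the simulate stage")
        t0 = time.time()
        # two-point analysis "with the variant": the disease variant itself is
        # the marker, the most informative single locus available
        fam_geno = []
        for ped in families:
            truth = truths[ped.family_id]
            fam_geno.append(
                (ped, {iid: tuple(g) for iid, g in truth.disease_genotypes.items()})
            )
        lod = two_point_lod(fam_geno, model)
        rows = ["family\ttheta\tlod"]
        for fam, curve in lod.per_family.items():
            for th, l in zip(lod.theta_grid, curve):
                rows.append(f"{fam}\t{th}\t{l}")
        for th, l in zip(lod.theta_grid, lod.lod):
            rows.append(f"POOLED\t{th}\t{l}")
        (out / "lod.tsv").write_text("\n".join(rows) + "\n")
        report.add(
            "lod",
            {
                "marker": "disease_variant",
                "theta_grid": list(lod.theta_grid),
                "pooled_lod": list(lod.lod),
                "pooled_max_lod": lod.max_lod,
                "argmax_theta": lod.argmax_theta,
                "per_family_max": {
                    fam: max(curve) for fam, curve in lod.per_family.items()
                },
                "elapsed_s": round(time.time() - t0, 2),
            },
        )
        logger.info("lod stage done in %.1fs", time.time() - t0)

    if config.stages.founder:
        if marker_map is None or founder_hap is None:
            raise RuntimeError("founder stage requires the simulate stage")
        t0 = time.time()
        fc = config.founder
        region_idx = [
            i
            for i, m in enumerate(marker_map.markers)
            if region.contains(m.chromosome, m.position_bp)
        ]
        take = np.linspace(0, len(region_idx) - 1, fc.n_em_snps).round().astype(int)
        take = sorted(set(int(t) for t in take))
        snp_idx = [region_idx[t] for t in take]
        sub_hap = np.array([founder_hap[t] for t in take])
        cohort = simulate_cohort_chromosomes(
            marker_map,
            snp_idx,
            sub_hap,
            fc.founder_frequency,
            fc.n_controls,
            seed=stage_seed(config.seed, "founder"),
        )
        em = em_haplotype_frequencies(
            cohort, [marker_map[i].marker_id for i in snp_idx]
        )
        f_hat = em.table.frequency_of(tuple(int(a) for a in sub_hap))
        p_sharing = founder_sharing_probability(f_hat, fc.k_founder_chromosomes)
        report.add(
            "founder",
            {
                "em_snp_ids": em.table.snp_ids,
                "em_iterations": em.iterations,
                "em_converged": em.converged,
                "founder_haplotype_frequency": f_hat,
                "configured_frequency": fc.founder_frequency,
                "k_founder_chromosomes": fc.k_founder_chromosomes,
                "founder_sharing_probability": p_sharing,
                "elapsed_s": round(time.time() - t0, 2),
            },
        )
        logger.info("founder stage done in %.1fs", time.time() - t0)

    if config.stages.variants:
        t0 = time.time()
        data = resources.files("clccmap") / "data"
        peds, _ = read_ped(str(data / "toy_family.ped"))
        filt = filter_candidate_variants(
            str(data / "toy_variants.vcf"),
            region,
            peds,
            FilterRules(probands=("IND12",)),
        )
        report.add(
            "variants",
            {
                "n_records": filt.n_records,
                "n_skipped_malformed": filt.n_skipped_malformed,
                "n_surviving": len(filt.surviving),
                "n_cosegregating": filt.n_cosegregating,
                "surviving": [
                    {
                        "gene": v.gene,
                        "position": v.position_bp,
                        "cosegregates": v.cosegregates,
                        "failing": v.failing_individuals,
                    }
                    for v in filt.surviving
                ],
                "elapsed_s": round(time.time() - t0, 2),
            },
        )
        logger.info("variants stage done in %.1fs", time.time() - t0)

    if config.stages.erg:
        t0 = time.time()
        ecfg = config.erg
        wt = default_wt_cone_params()
        mut = wt.scaled(ecfg.depression_factor)
        sim_cfg = ERGSimConfig(
            replicates=ecfg.replicates,
            noise_sd_floor=ecfg.noise_sd_floor,
            noise_sd_frac=ecfg.noise_sd_frac,
            seed=stage_seed(config.seed, "erg"),
        )
        data = simulate_erg(sim_cfg, {"WT": wt, "KO": mut})
        data.to_csv(out / "erg_amplitudes.tsv", sep="\t", index=False)
        templates = default_templates()
        fits = {}
        for g, sub_seed in (("WT", 1), ("KO", 2)):
            fits[g] = fit_cone_components(
                data[data.group == g],
                templates,
                n_starts=ecfg.n_starts,
                seed=stage_seed(config.seed, "erg", sub_seed),
            )
        s_wt = sensitivity_spectrum(fits["WT"].params, templates)
        s_ko = sensitivity_spectrum(fits["KO"].params, templates)
        dep = group_depression(s_wt, s_ko)
        params_out = {
            g: {
                "V_uv": fits[g].params.amplitude_max,
                "K_irradiance": fits[g].params.half_saturation,
                "sse": fits[g].sse,
            }
            for g in fits
        }
        (out / "erg_fits.json").write_text(json.dumps(params_out, indent=2, default=dict))
        report.add(
            "erg",
            {
                "depression_percent_at_peak": dep["percent_at_peak"],
                "depression_mean_percent": dep["mean_percent"],
                "simulated_depression_percent": 100.0 * (1 - ecfg.depression_factor),
                "wt_sse": fits["WT"].sse,
                "ko_sse": fits["KO"].sse,
                "elapsed_s": round(time.time() - t0, 2),
            },
        )
        logger.info("erg stage done in %.1fs", time.time() - t0)

    if config.stages.stats:
        t0 = time.time()
        morpho = simulate_morphometry(
            fig7_morphometry_config(seed=stage_seed(config.seed, "stats"))
        )
        morpho.to_csv(out / "morphometry.tsv", sep="\t", index=False)
        tests = {}
        for measure, sub in morpho.groupby("measure"):
            groups = sorted(sub.group.unique())
            x = sub[sub.group == groups[0]].value.to_numpy()
            y = sub[sub.group == groups[1]].value.to_numpy()
            r = unpaired_t_test(x, y)
            tests[measure] = {"t": r.statistic, "p": r.p_value, "df": r.df}
        mo_eye = morpho[(morpho.group == "clcc1-MO") & (morpho.measure == "eye_area_mm2")].value.mean()
        mo_lens = morpho[(morpho.group == "clcc1-MO") & (morpho.measure == "lens_area_mm2")].value.mean()
        mm_eye = morpho[(morpho.group == "MM-MO") & (morpho.measure == "eye_area_mm2")].value.mean()
        mm_lens = morpho[(morpho.group == "MM-MO") & (morpho.measure == "lens_area_mm2")].value.mean()
        outcomes = simulate_rescue_outcomes(
            config.rescue.p_normal,
            config.rescue.n_embryos,
            seed=stage_seed(config.seed, "stats", 1),
        )
        report.add(
            "stats",
            {
                "t_tests": tests,
                "lens_eye_ratio_morphant": ratio_of_means(mo_lens, mo_eye),
                "lens_eye_ratio_control": ratio_of_means(mm_lens, mm_eye),
                "rescue_percent": rescue_fraction(outcomes),
                "elapsed_s": round(time.time() - t0, 2),
            },
        )
        logger.info("stats stage done in %.1fs", time.time() - t0)

    (out / "report.json").write_text(report.to_json())
    (out / "report.txt").write_text(report.summary_text())
    logger.info("pipeline done in %.1fs", time.time() - t_all)
    return report


def _configure_logging() -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
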