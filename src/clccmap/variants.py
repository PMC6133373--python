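"""Candidate-variant filtering for a recessive disease inside a mapped interval.

Mirrors the standard homozygosity-mapping endgame: of all annotated variants
in the critical interval, keep rare, protein-altering changes homozygous in
the proband(s), then test cosegregation across the whole pedigree (every
affected homozygous, no unaffected homozygous).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from cyvcf2 import VCF

from .intervals import GenomicInterval
from .pedigree import Pedigree

logger = logging.getLogger(__name__)

DEFAULT_NONSYNONYMOUS = frozenset(
    {
        "missense_variant",
        "missense",
        "stop_gained",
        "stop_lost",
        "frameshift_variant",
        "frameshift",
        "splice_donor_variant",
        "splice_acceptor_variant",
        "splice_donor",
        "splice_acceptor",
        "inframe_insertion",
        "inframe_deletion",
        "inframe_indel",
    }
)


@dataclass(frozen=True)
class FilterRules:
    """Configuration of the variant filter.

    probands: samples whose zygosity defines the primary filter (homozygous
    alternate required); defaults to every affected pedigree member with a
    genotype.  Cosegregation is always judged over the whole pedigree.
    """

    consequence_classes: frozenset[str] = DEFAULT_NONSYNONYMOUS
    max_population_af: float = 0.01
    consequence_info_key: str = "Consequence"
    af_info_key: str = "AF"
    probands: tuple[str, ...] | None = None


@dataclass
class VariantVerdict:
    chromosome: str
    position_bp: int
    ref: str
    alt: str
    gene: str | None
    consequence: str
    population_af: float | None
    cosegregates: bool
    failing_individuals: list[str] = field(default_factory=list)


@dataclass
class FilterReport:
    surviving: list[VariantVerdict]
    n_records: int
    n_skipped_malformed: int

    @property
    def n_cosegregating(self) -> int:
        return sum(1 for v in self.surviving if v.cosegregates)


def _genotype_class(gt_types_value: int) -> str:
    # cyvcf2 gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
    return {0: "hom_ref", 1: "het", 2: "missing", 3: "hom_alt"}[gt_types_value]


def filter_candidate_variants(
    vcf_path: str,
    interval: GenomicInterval,
    pedigrees: Sequence[Pedigree],
    rules: FilterRules = FilterRules(),
) -> FilterReport:
    """Filter annotated VCF records and attach a cosegregation verdict.

    A record survives when it lies inside the interval (1-based inclusive
    coordinates), its consequence is in the configured non-synonymous set,
    its population AF is <= the threshold (missing AF passes), and every
    proband is homozygous for the alternate allele.  The verdict fails when
    any affected pedigree member is not hom-alt or any unaffected member is
    hom-alt.
    """
    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    sample_idx = {s: i for i, s in enumerate(samples)}
    affected = [
        i.id for ped in pedigrees for i in ped.individuals
        if i.affection == "affected" and i.id in sample_idx
    ]
    unaffected = [
        i.id for ped in pedigrees for i in ped.individuals
        if i.affection == "unaffected" and i.id in sample_idx
    ]
    probands = list(rules.probands) if rules.probands is not None else affected
    missing_probands = [p for p in probands if p not in sample_idx]
    if missing_probands:
        raise ValueError(f"probands absent from VCF: {missing_probands}")

    surviving: list[VariantVerdict] = []
    n_records = 0
    n_skipped = 0
    for rec in vcf:
        n_records += 1
        try:
            if not interval.contains(rec.CHROM, rec.POS):
                continue
            csq = rec.INFO.get(rules.consequence_info_key)
            if csq is None:
                raise ValueError("missing consequence annotation")
            # CSQ-style multi-field annotations: take the consequence terms
            terms = {
                t
                for part in str(csq).split(",")
                for t in part.split("|")[0].split("&")
            }
            if not terms & rules.consequence_classes:
                continue
            af = rec.INFO.get(rules.af_info_key)
            af_value = float(af) if af is not None else None
            if af_value is not None and af_value > rules.max_population_af:
                continue
            gts = rec.gt_types
            if any(
                _genotype_class(gts[sample_idx[p]]) != "hom_alt"
                for p in probands
            ):
                continue
            failing: list[str] = []
            for a in affected:
                if _genotype_class(gts[sample_idx[a]]) != "hom_alt":
                    failing.append(a)
            for u in unaffected:
                if _genotype_class(gts[sample_idx[u]]) == "hom_alt":
                    failing.append(u)
            surviving.append(
                VariantVerdict(
                    chromosome=rec.CHROM,
                    position_bp=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0] if rec.ALT else ".",
                    gene=rec.INFO.get("Gene"),
                    consequence=str(csq),
                    population_af=af_value,
                    cosegregates=not failing,
                    failing_individuals=failing,
                )
            )
        except (ValueError, KeyError, IndexError, TypeError) as exc:
            n_skipped += 1
            logger.warning(
                "skipping malformed record %s:%s (%s)",
                getattr(rec, "CHROM", "?"), getattr(rec, "POS", "?"), exc,
            )
    return FilterReport(surviving, n_records, n_skipped)
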