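"""Pedigree structures and LINKAGE-style PED file I/O.

A pedigree is a list of individuals with parent pointers.  Consanguinity
(marriage between relatives) is expected and legal; what is forbidden is an
individual being its own ancestor through parent links.

PED dialect: whitespace-delimited columns
``family id father mother sex affection [allele1 allele2]...``
with sex coded 1=male, 2=female, 0=unknown; affection coded 2=affected,
1=unaffected, 0=unknown; parent id "0" for founders; allele 0 for missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

UNKNOWN = "0"

SEX_CODES = {"male": "1", "female": "2", "unknown": "0"}
SEX_DECODE = {v: k for k, v in SEX_CODES.items()}
AFFECTION_CODES = {"affected": "2", "unaffected": "1", "unknown": "0"}
AFFECTION_DECODE = {v: k for k, v in AFFECTION_CODES.items()}


@dataclass(frozen=True)
class Individual:
    id: str
    father_id: str = UNKNOWN
    mother_id: str = UNKNOWN
    sex: str = "unknown"  # male / female / unknown
    affection: str = "unknown"  # affected / unaffected / unknown

    @property
    def is_founder(self) -> bool:
        return self.father_id == UNKNOWN and self.mother_id == UNKNOWN


@dataclass
class Pedigree:
    family_id: str
    individuals: list[Individual] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [ind.id for ind in self.individuals]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate individual ids in family {self.family_id}")
        known = set(ids)
        for ind in self.individuals:
            has_f = ind.father_id != UNKNOWN
            has_m = ind.mother_id != UNKNOWN
            if has_f != has_m:
                raise ValueError(
                    f"{ind.id}: parents must be both known or both unknown"
                )
            if has_f and (ind.father_id not in known or ind.mother_id not in known):
                raise ValueError(f"{ind.id}: referenced parent not in pedigree")
            if ind.sex not in SEX_CODES or ind.affection not in AFFECTION_CODES:
                raise ValueError(f"{ind.id}: invalid sex or affection label")
        # cycle-free parentage: DFS through parent links
        by_id = self.by_id
        state: dict[str, int] = {}

        def visit(i: str) -> None:
            if state.get(i) == 1:
                raise ValueError(f"parentage cycle involving {i}")
            if state.get(i) == 2:
                return
            state[i] = 1
            ind = by_id[i]
            for p in (ind.father_id, ind.mother_id):
                if p != UNKNOWN:
                    visit(p)
            state[i] = 2

        for i in ids:
            visit(i)

    @property
    def by_id(self) -> dict[str, Individual]:
        return {ind.id: ind for ind in self.individuals}

    @property
    def founders(self) -> list[Individual]:
        return [ind for ind in self.individuals if ind.is_founder]

    @property
    def nonfounders(self) -> list[Individual]:
        return [ind for ind in self.individuals if not ind.is_founder]

    @property
    def affected_ids(self) -> list[str]:
        return [i.id for i in self.individuals if i.affection == "affected"]

    @property
    def unaffected_ids(self) -> list[str]:
        return [i.id for i in self.individuals if i.affection == "unaffected"]

    def topological_order(self) -> list[Individual]:
        """Individuals ordered so every parent precedes its children."""
        by_id = self.by_id
        done: dict[str, bool] = {}
        order: list[Individual] = []

        def visit(i: str) -> None:
            if done.get(i):
                return
            ind = by_id[i]
            for p in (ind.father_id, ind.mother_id):
                if p != UNKNOWN:
                    visit(p)
            done[i] = True
            order.append(ind)

        for ind in self.individuals:
            visit(ind.id)
        return order

    def ancestors(self, ind_id: str) -> set[str]:
        by_id = self.by_id
        out: set[str] = set()
        stack = [ind_id]
        while stack:
            ind = by_id[stack.pop()]
            for p in (ind.father_id, ind.mother_id):
                if p != UNKNOWN and p not in out:
                    out.add(p)
                    stack.append(p)
        return out

    def is_consanguineous(self) -> bool:
        """True if some mating pair shares a common ancestor (or one is the
        other's ancestor)."""
        pairs = {
            (i.father_id, i.mother_id)
            for i in self.individuals
            if not i.is_founder
        }
        for f, m in pairs:
            anc_f = self.ancestors(f) | {f}
            anc_m = self.ancestors(m) | {m}
            if anc_f & anc_m:
                return True
        return False


# genotype container: id -> (n_markers, 2) int array of 0-based allele
# indices, -1 for missing
GenotypeTable = Mapping[str, np.ndarray]


def mendelian_consistent(
    ped: Pedigree, genotypes: GenotypeTable, n_alleles: Iterable[int] | None = None
) -> bool:
    """Check every non-founder's unordered genotype is explainable by one
    allele from each parent, at every marker; missing alleles match anything.
    """
    by_id = ped.by_id
    for ind in ped.nonfounders:
        g = np.asarray(genotypes[ind.id])
        gf = np.asarray(genotypes[by_id[ind.father_id].id])
        gm = np.asarray(genotypes[by_id[ind.mother_id].id])
        for k in range(g.shape[0]):
            a, b = g[k]
            ok = False
            for x, y in ((a, b), (b, a)):
                from_f = x == -1 or x in gf[k] or -1 in gf[k]
                from_m = y == -1 or y in gm[k] or -1 in gm[k]
                if from_f and from_m:
                    ok = True
                    break
            if not ok:
                return False
    return True


def write_ped(
    pedigrees: Iterable[Pedigree],
    path: str | Path,
    genotypes: Mapping[str, GenotypeTable] | None = None,
) -> None:
    """Write LINKAGE-style PED; genotypes (optional) keyed by family then
    individual, alleles written 1-based with 0 = missing."""
    lines = []
    for ped in pedigrees:
        fam_g = (genotypes or {}).get(ped.family_id, {})
        for ind in ped.individuals:
            row = [
                ped.family_id,
                ind.id,
                ind.father_id,
                ind.mother_id,
                SEX_CODES[ind.sex],
                AFFECTION_CODES[ind.affection],
            ]
            if ind.id in fam_g:
                g = np.asarray(fam_g[ind.id])
                row += [str(int(a) + 1) if a >= 0 else "0" for a in g.ravel()]
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ped(
    path: str | Path,
) -> tuple[list[Pedigree], dict[str, dict[str, np.ndarray]]]:
    """Read LINKAGE-style PED.

    Returns (pedigrees, genotypes) with genotypes keyed family -> individual,
    as (n_markers, 2) arrays of 0-based allele indices (-1 missing).
    """
    rows_by_family: dict[str, list[Individual]] = {}
    geno: dict[str, dict[str, np.ndarray]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        fam, iid, fat, mot, sex, aff = f[:6]
        rows_by_family.setdefault(fam, []).append(
            Individual(
                iid,
                fat,
                mot,
                SEX_DECODE.get(sex, "unknown"),
                AFFECTION_DECODE.get(aff, "unknown"),
            )
        )
        alleles = [int(a) - 1 for a in f[6:]]
        if alleles:
            if len(alleles) % 2:
                raise ValueError(f"odd allele count for {iid} in {fam}")
            geno.setdefault(fam, {})[iid] = np.asarray(alleles).reshape(-1, 2)
    peds = [Pedigree(fam, inds) for fam, inds in rows_by_family.items()]
    return peds, geno
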