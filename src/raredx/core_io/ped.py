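"""6-column PED pedigree reader.

Columns: family_id, individual_id, father_id, mother_id, sex (1=male,
2=female, 0=unknown), phenotype (2=affected, 1=unaffected, 0=unknown).
``0`` or ``.`` in a parent column means no parent. The index of each family
is the first affected individual with both parents in the pedigree, falling
back to the first affected individual, then the first row.
"""

from __future__ import annotations

import gzip
from typing import IO

from raredx.core_io.models import Affection, Individual, Pedigree, Sex
from raredx.errors import FormatError

_SEX = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_PHENO = {"2": Affection.AFFECTED, "1": Affection.UNAFFECTED, "0": Affection.UNKNOWN}


def _open_text(path: str) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path)


def _pick_index(individuals: list[Individual]) -> str:
    affected = [i for i in individuals if i.affected == Affection.AFFECTED]
    for ind in affected:
        if ind.mother_id and ind.father_id:
            return ind.id
    if affected:
        return affected[0].id
    return individuals[0].id


def read_ped(path: str) -> list[Pedigree]:
    families: dict[str, list[Individual]] = {}
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 6:
                raise FormatError(f"{path} line {line_no}: expected 6 PED columns")
            fam, ind_id, father, mother, sex, pheno = fields[:6]
            families.setdefault(fam, []).append(
                Individual(
                    id=ind_id,
                    sex=_SEX.get(sex, Sex.UNKNOWN),
                    affected=_PHENO.get(pheno, Affection.UNKNOWN),
                    mother_id=None if mother in ("0", ".", "") else mother,
                    father_id=None if father in ("0", ".", "") else father,
                )
            )
    pedigrees = []
    for fam, individuals in families.items():
        pedigrees.append(
            Pedigree(family_id=fam, individuals=individuals, index_id=_pick_index(individuals))
        )
    return pedigrees


def write_ped(pedigrees: list[Pedigree], path: str) -> None:
    sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
    pheno_code = {Affection.AFFECTED: "2", Affection.UNAFFECTED: "1", Affection.UNKNOWN: "0"}
    with open(path, "w") as fh:
        for ped in pedigrees:
            for ind in ped.individuals:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            ind.id,
                            ind.father_id or "0",
                            ind.mother_id or "0",
                            sex_code[ind.sex],
                            pheno_code[ind.affected],
                        ]
                    )
                    + "\n"
                )
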