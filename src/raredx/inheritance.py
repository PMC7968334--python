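"""Mendelian inheritance-model deduction and compound-heterozygote pairing.

For each variant and family the deducer returns every model under which the
observed genotypes are consistent with the variant being causal:

* all genotyped affected members carry the model's causal configuration
  (het for AD/XD, hom-alt for AR_hom, hemizygous/hom-alt for XR);
* no genotyped unaffected member carries it (dominant models can relax this
  via the reduced-penetrance option);
* ``*_dn`` sub-models additionally require the alternate allele to be absent
  from both genotyped parents of the index;
* plain (inherited) models require that transmission from the parents is not
  excluded by their genotypes.

Ungenotyped or absent relatives impose no constraint, so singletons return
every model consistent with the index genotype alone, and removing a
genotyped relative can only grow the model set.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from raredx.core_io.models import (
    MT_CONTIGS,
    Affection,
    Individual,
    Pedigree,
    SampleCall,
    Sex,
    VariantRecord,
    is_x_nonpar,
)
from raredx.errors import PairingError


class InheritanceModel(str, Enum):
    AD = "AD"
    AD_DN = "AD_dn"
    AR_HOM = "AR_hom"
    AR_HOM_DN = "AR_hom_dn"
    AR_COMP = "AR_comp"
    AR_COMP_DN = "AR_comp_dn"
    XD = "XD"
    XD_DN = "XD_dn"
    XR = "XR"
    XR_DN = "XR_dn"
    MT = "MT"


@dataclass
class DeduceOptions:
    """Tunables for model deduction."""

    min_parent_depth: int = 10  # reads needed in each parent for a confident de novo
    mosaic_fraction: float = 0.20  # alt-fraction below which a call looks mosaic
    reduced_penetrance: bool = False  # let unaffected carriers keep dominant models


@dataclass
class ModelAssignment:
    variant_key: tuple
    models: set[InheritanceModel] = field(default_factory=set)
    confident_de_novo: bool = False
    mosaic_suspect: bool = False
    mt_origin: Optional[str] = None  # maternal / de_novo / undetermined

    @property
    def tokens(self) -> list[str]:
        return sorted(m.value for m in self.models)


_DN_OF = {
    InheritanceModel.AD: InheritanceModel.AD_DN,
    InheritanceModel.AR_HOM: InheritanceModel.AR_HOM_DN,
    InheritanceModel.XD: InheritanceModel.XD_DN,
    InheritanceModel.XR: InheritanceModel.XR_DN,
}


def _affected_ok(model: InheritanceModel, call: SampleCall, ind: Individual) -> bool:
    """Does this genotyped affected individual carry the causal configuration?"""
    if model == InheritanceModel.AD:
        return bool(call.is_het)
    if model == InheritanceModel.AR_HOM:
        return bool(call.is_hom_alt)
    if model == InheritanceModel.XD:
        if ind.sex == Sex.MALE and len(call.genotype) == 1:
            return call.genotype[0] == 1
        return bool(call.is_het)
    if model == InheritanceModel.XR:
        # males: hemizygous alt (or coerced hom-alt); females: hom-alt
        return bool(call.is_hom_alt)
    raise ValueError(model)


def _unaffected_ok(
    model: InheritanceModel, call: SampleCall, ind: Individual, opts: DeduceOptions
) -> bool:
    """Is this genotyped unaffected individual compatible with the model?"""
    if model in (InheritanceModel.AD, InheritanceModel.XD):
        if opts.reduced_penetrance:
            return True
        if model == InheritanceModel.XD and ind.sex == Sex.FEMALE:
            return not call.carries_alt
        return not call.carries_alt
    if model == InheritanceModel.AR_HOM:
        return not call.is_hom_alt  # het carriers are fine
    if model == InheritanceModel.XR:
        if ind.sex == Sex.MALE:
            return not call.carries_alt  # an unaffected male cannot carry an XR allele
        return not call.is_hom_alt
    raise ValueError(model)


def _base_compatible(
    model: InheritanceModel,
    record: VariantRecord,
    pedigree: Pedigree,
    opts: DeduceOptions,
) -> bool:
    for ind in pedigree.individuals:
        call = record.per_sample.get(ind.id)
        if call is None or call.genotype is None:
            continue
        if ind.affected == Affection.AFFECTED:
            if not _affected_ok(model, call, ind):
                return False
        elif ind.affected == Affection.UNAFFECTED:
            if not _unaffected_ok(model, call, ind, opts):
                return False
        # unknown affection imposes no constraint
    # the index must itself carry the causal configuration
    index_call = record.per_sample.get(pedigree.index_id)
    if index_call is not None and index_call.genotype is not None:
        if not _affected_ok(model, index_call, pedigree.index):
            return False
    return True


def _parent_call(record: VariantRecord, parent: Optional[Individual]) -> Optional[SampleCall]:
    if parent is None:
        return None
    call = record.per_sample.get(parent.id)
    if call is None or call.genotype is None:
        return None
    return call


def _dn_allowed(mother_call, father_call) -> bool:
    """De novo sub-model: allele absent from every genotyped parent."""
    for call in (mother_call, father_call):
        if call is not None and call.carries_alt:
            return False
    return True


def _transmission_possible(
    model: InheritanceModel,
    record: VariantRecord,
    pedigree: Pedigree,
    mother_call: Optional[SampleCall],
    father_call: Optional[SampleCall],
) -> bool:
    """Could the index's causal alleles all have come from its parents?

    A genotyped parent without the allele excludes transmission from that
    side; an ungenotyped or absent parent excludes nothing.
    """

    def may_supply(call: Optional[SampleCall]) -> bool:
        return call is None or bool(call.carries_alt)

    if model in (InheritanceModel.AD, InheritanceModel.XD):
        if model == InheritanceModel.XD and pedigree.index.sex == Sex.MALE:
            return may_supply(mother_call)  # a boy's X comes from his mother
        return may_supply(mother_call) or may_supply(father_call)
    if model == InheritanceModel.AR_HOM:
        return may_supply(mother_call) and may_supply(father_call)
    if model == InheritanceModel.XR:
        if pedigree.index.sex == Sex.MALE:
            return may_supply(mother_call)
        return may_supply(mother_call) and may_supply(father_call)
    raise ValueError(model)


def _mt_origin(record: VariantRecord, pedigree: Pedigree) -> str:
    mother, _ = pedigree.parents_of(pedigree.index_id) if pedigree.index.mother_id else (None, None)
    call = _parent_call(record, mother)
    if call is None:
        return "undetermined"
    return "maternal" if call.carries_alt else "de_novo"


def deduce_models(
    record: VariantRecord,
    pedigree: Pedigree,
    options: Optional[DeduceOptions] = None,
) -> ModelAssignment:
    """Deduce the set of compatible inheritance models for one variant."""
    opts = options or DeduceOptions()
    if record.per_sample and not set(record.per_sample) & set(pedigree.member_ids):
        raise PairingError(
            f"record samples {sorted(record.per_sample)} disjoint from "
            f"pedigree {pedigree.family_id}"
        )
    assignment = ModelAssignment(variant_key=record.key)

    index_call = record.per_sample.get(pedigree.index_id)
    carries = index_call is not None and bool(index_call.carries_alt)

    if record.chrom in MT_CONTIGS:
        if carries:
            assignment.models.add(InheritanceModel.MT)
            assignment.mt_origin = _mt_origin(record, pedigree)
        return assignment
    if not carries:
        return assignment

    on_x = is_x_nonpar(record.chrom, record.pos)
    candidates = (
        (InheritanceModel.XD, InheritanceModel.XR)
        if on_x
        else (InheritanceModel.AD, InheritanceModel.AR_HOM)
    )

    mother, father = (
        pedigree.parents_of(pedigree.index_id)
        if (pedigree.index.mother_id or pedigree.index.father_id)
        else (None, None)
    )
    mother_call = _parent_call(record, mother)
    father_call = _parent_call(record, father)

    for model in candidates:
        if not _base_compatible(model, record, pedigree, opts):
            continue
        if _transmission_possible(model, record, pedigree, mother_call, father_call):
            assignment.models.add(model)
        if _dn_allowed(mother_call, father_call):
            assignment.models.add(_DN_OF[model])

    if any(m in _DN_OF.values() for m in assignment.models):
        assignment.confident_de_novo = (
            mother_call is not None
            and father_call is not None
            and not mother_call.carries_alt
            and not father_call.carries_alt
            and (mother_call.depth or 0) >= opts.min_parent_depth
            and (father_call.depth or 0) >= opts.min_parent_depth
        )

    frac = index_call.alt_fraction if index_call else None
    if frac is not None and 0 < frac < opts.mosaic_fraction:
        assignment.mosaic_suspect = True

    return assignment


# ---------------------------------------------------------------------------
# compound heterozygotes


@dataclass
class CompoundHetPair:
    variant_a: VariantRecord
    variant_b: VariantRecord
    model: InheritanceModel
    phase_known: bool


def _origin(record: VariantRecord, mother_call, father_call) -> Optional[str]:
    """'maternal' / 'paternal' / 'de_novo' when parental genotypes settle it."""
    if mother_call is None or father_call is None:
        return None
    m, f = bool(mother_call.carries_alt), bool(father_call.carries_alt)
    if m and not f:
        return "maternal"
    if f and not m:
        return "paternal"
    if not m and not f:
        return "de_novo"
    return None  # both carry: phase unresolved


def pair_compound_hets(
    records: list[VariantRecord], pedigree: Pedigree
) -> list[CompoundHetPair]:
    """Pair heterozygous variants in one gene into trans candidates.

    With genotyped parents, a pair is kept when the two variants demonstrably
    sit on different haplotypes (one maternal-only + one paternal-only →
    ``AR_comp``; one side de novo → ``AR_comp_dn``), and dropped when both
    are transmitted from the same single parent (cis). Without parental
    information all het pairs are returned with ``phase_known=False``.
    """
    index_id = pedigree.index_id
    hets = [
        r
        for r in records
        if (c := r.per_sample.get(index_id)) is not None and c.is_het
    ]
    mother, father = (
        pedigree.parents_of(index_id)
        if (pedigree.index.mother_id or pedigree.index.father_id)
        else (None, None)
    )
    pairs: list[CompoundHetPair] = []
    for a, b in itertools.combinations(hets, 2):
        origin_a = _origin(a, _parent_call(a, mother), _parent_call(a, father))
        origin_b = _origin(b, _parent_call(b, mother), _parent_call(b, father))
        if origin_a is None or origin_b is None:
            pairs.append(CompoundHetPair(a, b, InheritanceModel.AR_COMP, False))
            continue
        if "de_novo" in (origin_a, origin_b):
            pairs.append(CompoundHetPair(a, b, InheritanceModel.AR_COMP_DN, True))
        elif {origin_a, origin_b} == {"maternal", "paternal"}:
            pairs.append(CompoundHetPair(a, b, InheritanceModel.AR_COMP, True))
        # same single parental origin for both -> cis, not a candidate
    return pairs
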