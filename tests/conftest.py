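from __future__ import annotations

import pytest

from raredx.core_io.models import (
    Affection,
    AnnotationSet,
    Individual,
    Pedigree,
    SampleCall,
    Sex,
    VariantRecord,
)

CHILD, MOTHER, FATHER = "child", "mother", "father"


def make_call(gt, depth=30, gq=99, ad=None, phased=False):
    """Shorthand SampleCall: gt is a tuple of allele ints or None."""
    return SampleCall(
        genotype=gt, depth=depth, genotype_quality=gq, allele_depths=ad, phased=phased
    )


def make_record(chrom="1", pos=1000, ref="A", alt="G", filter_status="PASS",
                per_sample=None, annotations=None):
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        filter_status=filter_status,
        per_sample=per_sample or {},
        annotations=annotations or AnnotationSet(),
    )


def trio_record(child_gt, mother_gt, father_gt, chrom="1", pos=1000, ref="A",
                alt="G", annotations=None, child_dp=30, mother_dp=30, father_dp=30,
                child_ad=None):
    return make_record(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        per_sample={
            CHILD: make_call(child_gt, depth=child_dp, ad=child_ad),
            MOTHER: make_call(mother_gt, depth=mother_dp),
            FATHER: make_call(father_gt, depth=father_dp),
        },
        annotations=annotations,
    )


def make_trio_pedigree(child_sex=Sex.MALE, mother_affected=Affection.UNAFFECTED,
                       father_affected=Affection.UNAFFECTED, family_id="FAM1"):
    return Pedigree(
        family_id=family_id,
        individuals=[
            Individual(CHILD, child_sex, Affection.AFFECTED, MOTHER, FATHER),
            Individual(MOTHER, Sex.FEMALE, mother_affected),
            Individual(FATHER, Sex.MALE, father_affected),
        ],
        index_id=CHILD,
    )


def make_singleton_pedigree(sex=Sex.MALE, individual_id="proband", family_id="FAM1"):
    return Pedigree(
        family_id=family_id,
        individuals=[Individual(individual_id, sex, Affection.AFFECTED)],
        index_id=individual_id,
    )


@pytest.fixture
def trio_pedigree():
    return make_trio_pedigree()


@pytest.fixture
def female_trio_pedigree():
    return make_trio_pedigree(child_sex=Sex.FEMALE)


@pytest.fixture
def singleton_male():
    return make_singleton_pedigree(sex=Sex.MALE)
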