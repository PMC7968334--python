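from __future__ import annotations

import itertools

import pytest

from raredx.core_io.models import Affection, AnnotationSet, Individual, Pedigree, Sex
from raredx.errors import PairingError
from raredx.inheritance import (
    CompoundHetPair,
    DeduceOptions,
    InheritanceModel as M,
    deduce_models,
    pair_compound_hets,
)
from tests.conftest import (
    CHILD,
    FATHER,
    MOTHER,
    make_call,
    make_record,
    make_singleton_pedigree,
    make_trio_pedigree,
    trio_record,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate parental genotype completions

AUTO_GTS = [(0, 0), (0, 1), (1, 1)]
MALE_X_GTS = [(0,), (1,)]


def _carries(gt):
    return any(a == 1 for a in gt)


def _affected_config_ok(model, gt, sex):
    if model in (M.AD,):
        return sorted(gt) == [0, 1]
    if model in (M.AR_HOM,):
        return gt == (1, 1)
    if model in (M.XD,):
        return gt == (1,) if sex == Sex.MALE else sorted(gt) == [0, 1]
    if model in (M.XR,):
        return all(a == 1 for a in gt)
    raise AssertionError(model)


def _unaffected_config_ok(model, gt, sex, reduced):
    if model in (M.AD, M.XD):
        return True if reduced else not _carries(gt)
    if model == M.AR_HOM:
        return gt != (1, 1)
    if model == M.XR:
        if sex == Sex.MALE:
            return not _carries(gt)
        return not all(a == 1 for a in gt)
    raise AssertionError(model)


def _transmit_ok(model, mother_gt, father_gt, child_sex, on_x):
    m, f = _carries(mother_gt), _carries(father_gt)
    if model in (M.AD, M.XD):
        if on_x and child_sex == Sex.MALE:
            return m  # a boy's X is maternal
        return m or f
    if model in (M.AR_HOM, M.XR):
        if on_x and child_sex == Sex.MALE:
            return m
        return m and f
    raise AssertionError(model)


def oracle_models(
    child_gt,
    mother_gt,
    father_gt,
    child_sex=Sex.MALE,
    mother_aff=Affection.UNAFFECTED,
    father_aff=Affection.UNAFFECTED,
    on_x=False,
    reduced=False,
):
    """Enumerate completions of missing parental genotypes; a model is listed
    when some completion satisfies carrier configs, affection constraints on
    genotyped members, and transmission (plain) / parental absence (de novo).
    """
    if child_gt is None or not _carries(child_gt):
        return set()
    dn_map = {M.AD: M.AD_DN, M.AR_HOM: M.AR_HOM_DN, M.XD: M.XD_DN, M.XR: M.XR_DN}
    base_models = (M.XD, M.XR) if on_x else (M.AD, M.AR_HOM)
    mother_opts = [mother_gt] if mother_gt is not None else AUTO_GTS
    father_opts = (
        [father_gt]
        if father_gt is not None
        else (MALE_X_GTS if on_x else AUTO_GTS)
    )
    out = set()
    for model in base_models:
        if not _affected_config_ok(model, child_gt, child_sex):
            continue
        constraints_ok = True
        for gt, aff, sex in (
            (mother_gt, mother_aff, Sex.FEMALE),
            (father_gt, father_aff, Sex.MALE),
        ):
            if gt is None:
                continue  # ungenotyped members impose no constraint
            if aff == Affection.AFFECTED and not _affected_config_ok(model, gt, sex):
                constraints_ok = False
            if aff == Affection.UNAFFECTED and not _unaffected_config_ok(
                model, gt, sex, reduced
            ):
                constraints_ok = False
        if not constraints_ok:
            continue
        if any(
            _transmit_ok(model, m, f, child_sex, on_x)
            for m in mother_opts
            for f in father_opts
        ):
            out.add(model)
        if any(
            not _carries(m) and not _carries(f)
            for m in mother_opts
            for f in father_opts
        ):
            out.add(dn_map[model])
    return out


def _deduce(child_gt, mother_gt, father_gt, child_sex=Sex.MALE,
            mother_aff=Affection.UNAFFECTED, father_aff=Affection.UNAFFECTED,
            on_x=False, reduced=False):
    ped = make_trio_pedigree(
        child_sex=child_sex, mother_affected=mother_aff, father_affected=father_aff
    )
    chrom, pos = ("X", 15_000_000) if on_x else ("1", 1000)
    rec = trio_record(child_gt, mother_gt, father_gt, chrom=chrom, pos=pos)
    opts = DeduceOptions(reduced_penetrance=reduced)
    return deduce_models(rec, ped, opts).models


class TestOracleEquivalence:
    @pytest.mark.parametrize("mother_aff", list(Affection))
    @pytest.mark.parametrize("father_aff", list(Affection))
    def test_exhaustive_autosomal_trio(self, mother_aff, father_aff):
        gts = AUTO_GTS + [None]
        for child, mother, father in itertools.product(gts, repeat=3):
            got = _deduce(child, mother, father,
                          mother_aff=mother_aff, father_aff=father_aff)
            want = oracle_models(child, mother, father,
                                 mother_aff=mother_aff, father_aff=father_aff)
            assert got == want, (child, mother, father, mother_aff, father_aff)

    @pytest.mark.parametrize("child_sex", [Sex.MALE, Sex.FEMALE])
    def test_exhaustive_chrx_trio(self, child_sex):
        child_gts = (MALE_X_GTS if child_sex == Sex.MALE else AUTO_GTS) + [None]
        for child, mother, father in itertools.product(
            child_gts, AUTO_GTS + [None], MALE_X_GTS + [None]
        ):
            got = _deduce(child, mother, father, child_sex=child_sex, on_x=True)
            want = oracle_models(child, mother, father, child_sex=child_sex, on_x=True)
            assert got == want, (child, mother, father, child_sex)

    def test_exhaustive_autosomal_reduced_penetrance(self):
        gts = AUTO_GTS + [None]
        for child, mother, father in itertools.product(gts, repeat=3):
            got = _deduce(child, mother, father, reduced=True)
            want = oracle_models(child, mother, father, reduced=True)
            assert got == want, (child, mother, father)


class TestSpecExamples:
    def test_de_novo_dominant_trio(self, trio_pedigree):
        rec = trio_record((0, 1), (0, 0), (0, 0))
        result = deduce_models(rec, trio_pedigree)
        assert result.models == {M.AD_DN}
        assert result.confident_de_novo  # parents at DP 30 >= 10

    def test_recessive_hom_trio(self, trio_pedigree):
        rec = trio_record((1, 1), (0, 1), (0, 1))
        assert deduce_models(rec, trio_pedigree).models == {M.AR_HOM}

    def test_singleton_male_x_hemizygous(self, singleton_male):
        # brute-force over parental completions: all four X models survive
        rec = make_record(
            chrom="X", pos=15_000_000, per_sample={"proband": make_call((1,))}
        )
        result = deduce_models(rec, singleton_male)
        assert result.models == {M.XR, M.XR_DN, M.XD, M.XD_DN}
        assert oracle_models((1,), None, None, on_x=True) == result.models

    def test_mosaic_suspect_low_alt_fraction(self, trio_pedigree):
        # 4 alt reads out of 33 -> fraction 0.12 < 0.20 default threshold
        rec = trio_record((0, 1), (0, 0), (0, 0), child_ad=(29, 4), child_dp=33)
        result = deduce_models(rec, trio_pedigree)
        assert result.mosaic_suspect
        assert M.AD_DN in result.models  # dominant model retained

    def test_not_mosaic_at_balanced_fraction(self, trio_pedigree):
        rec = trio_record((0, 1), (0, 0), (0, 0), child_ad=(15, 15))
        assert not deduce_models(rec, trio_pedigree).mosaic_suspect


class TestDeNovoConfidence:
    def test_low_parent_depth_not_confident(self, trio_pedigree):
        rec = trio_record((0, 1), (0, 0), (0, 0), mother_dp=5, father_dp=30)
        result = deduce_models(rec, trio_pedigree)
        assert M.AD_DN in result.models
        assert not result.confident_de_novo

    def test_ungenotyped_parent_not_confident(self, trio_pedigree):
        rec = trio_record((0, 1), None, (0, 0))
        result = deduce_models(rec, trio_pedigree)
        assert M.AD_DN in result.models
        assert not result.confident_de_novo

    def test_confident_implies_dn_model(self, trio_pedigree):
        for child, mother, father in itertools.product(AUTO_GTS + [None], repeat=3):
            rec = trio_record(child, mother, father)
            result = deduce_models(rec, trio_pedigree)
            if result.confident_de_novo:
                assert result.models & {M.AD_DN, M.AR_HOM_DN}


class TestMitochondrial:
    def _mt_record(self, child_gt, mother_gt):
        return make_record(
            chrom="MT",
            pos=1000,
            per_sample={
                CHILD: make_call(child_gt),
                MOTHER: make_call(mother_gt),
                FATHER: make_call((0,)),
            },
        )

    def test_maternal(self, trio_pedigree):
        result = deduce_models(self._mt_record((1,), (1,)), trio_pedigree)
        assert result.models == {M.MT}
        assert result.mt_origin == "maternal"

    def test_de_novo(self, trio_pedigree):
        result = deduce_models(self._mt_record((1,), (0,)), trio_pedigree)
        assert result.mt_origin == "de_novo"

    def test_undetermined_without_mother(self, trio_pedigree):
        result = deduce_models(self._mt_record((1,), None), trio_pedigree)
        assert result.mt_origin == "undetermined"


class TestMonotoneRelaxation:
    def test_removing_relative_never_shrinks_models(self):
        full_ped = make_trio_pedigree()
        duo_ped = Pedigree(
            family_id="FAM1",
            individuals=[
                Individual(CHILD, Sex.MALE, Affection.AFFECTED, MOTHER, None),
                Individual(MOTHER, Sex.FEMALE, Affection.UNAFFECTED),
            ],
            index_id=CHILD,
        )
        single_ped = make_singleton_pedigree(individual_id=CHILD)
        for child, mother, father in itertools.product(AUTO_GTS, AUTO_GTS, AUTO_GTS):
            trio = trio_record(child, mother, father)
            duo = make_record(
                per_sample={CHILD: make_call(child), MOTHER: make_call(mother)}
            )
            single = make_record(per_sample={CHILD: make_call(child)})
            trio_models = deduce_models(trio, full_ped).models
            duo_models = deduce_models(duo, duo_ped).models
            single_models = deduce_models(single, single_ped).models
            assert trio_models <= duo_models <= single_models


def test_disjoint_samples_raise_pairing_error(trio_pedigree):
    rec = make_record(per_sample={"stranger": make_call((0, 1))})
    with pytest.raises(PairingError):
        deduce_models(rec, trio_pedigree)


# ---------------------------------------------------------------------------
# compound heterozygotes


def _gene_record(pos, child, mother, father):
    return trio_record(
        child, mother, father, pos=pos,
        annotations=AnnotationSet(gene_symbols=frozenset({"ABCA4"})),
    )


class TestCompoundHets:
    def test_trans_pair_with_parents(self, trio_pedigree):
        a = _gene_record(100, (0, 1), (0, 1), (0, 0))
        b = _gene_record(200, (0, 1), (0, 0), (0, 1))
        pairs = pair_compound_hets([a, b], trio_pedigree)
        assert len(pairs) == 1
        assert pairs[0].model == M.AR_COMP
        assert pairs[0].phase_known

    def test_cis_pair_rejected(self, trio_pedigree):
        a = _gene_record(100, (0, 1), (0, 1), (0, 0))
        b = _gene_record(200, (0, 1), (0, 1), (0, 0))
        assert pair_compound_hets([a, b], trio_pedigree) == []

    def test_de_novo_side(self, trio_pedigree):
        a = _gene_record(100, (0, 1), (0, 1), (0, 0))
        b = _gene_record(200, (0, 1), (0, 0), (0, 0))
        pairs = pair_compound_hets([a, b], trio_pedigree)
        assert len(pairs) == 1
        assert pairs[0].model == M.AR_COMP_DN

    def test_singleton_all_pairs_unphased(self):
        ped = make_singleton_pedigree(individual_id=CHILD)
        records = [
            make_record(
                pos=100 * i,
                per_sample={CHILD: make_call((0, 1))},
                annotations=AnnotationSet(gene_symbols=frozenset({"ABCA4"})),
            )
            for i in range(1, 4)
        ]
        pairs = pair_compound_hets(records, ped)
        assert len(pairs) == 3  # C(3, 2)
        assert all(not p.phase_known for p in pairs)
        assert all(isinstance(p, CompoundHetPair) for p in pairs)

    def test_never_pairs_with_itself(self, trio_pedigree):
        a = _gene_record(100, (0, 1), (0, 1), (0, 0))
        assert pair_compound_hets([a], trio_pedigree) == []

    def test_non_het_index_excluded(self, trio_pedigree):
        a = _gene_record(100, (1, 1), (0, 1), (0, 1))
        b = _gene_record(200, (0, 1), (0, 0), (0, 1))
        assert pair_compound_hets([a, b], trio_pedigree) == []
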