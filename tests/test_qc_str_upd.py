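from __future__ import annotations

import itertools
import random

import pytest

from raredx.errors import RaredxError
from raredx.qc_str_upd import (
    STRCall,
    STRCatalogEntry,
    classify_str,
    detect_upd,
    fingerprint_check,
    trio_concordance,
)
from raredx.synth import SynthConfig, generate_trio
from tests.conftest import (
    CHILD,
    FATHER,
    MOTHER,
    make_call,
    make_record,
    make_trio_pedigree,
    trio_record,
)

CATALOG = {
    "LOC_AD": STRCatalogEntry("LOC_AD", "HTT_LIKE", "CAG", 35, 40, "AD"),
    "LOC_AR": STRCatalogEntry("LOC_AR", "RFC_LIKE", "AAGGG", 35, 40, "AR"),
    "LOC_XR": STRCatalogEntry("LOC_XR", "FMR_LIKE", "CGG", 44, 200, "XR"),
}


class TestClassifyStr:
    def test_normal_allele(self):
        result = classify_str(STRCall("LOC_AD", (30, 20)), CATALOG)
        assert result.allele_statuses == ("normal", "normal")
        assert not result.reportable

    def test_intermediate_band(self):
        result = classify_str(STRCall("LOC_AD", (37, 10)), CATALOG)
        assert result.allele_statuses[0] == "intermediate"
        assert not result.reportable

    def test_biallelic_expansion_reportable_at_ar_locus(self):
        # homozygous-state expansion at a recessive locus
        result = classify_str(STRCall("LOC_AR", (45, 46)), CATALOG)
        assert result.allele_statuses == ("expanded", "expanded")
        assert result.reportable

    def test_monoallelic_expansion_rule_table(self):
        # one expanded allele: not reportable at AR, reportable at AD
        assert not classify_str(STRCall("LOC_AR", (45, 12)), CATALOG).reportable
        assert classify_str(STRCall("LOC_AD", (45, 12)), CATALOG).reportable

    def test_hemizygous_single_allele(self):
        assert classify_str(STRCall("LOC_XR", (250,)), CATALOG).reportable

    def test_unknown_locus_lists_catalog(self):
        with pytest.raises(RaredxError, match="LOC_AD"):
            classify_str(STRCall("NOPE", (10, 10)), CATALOG)

    def test_piecewise_monotone_in_allele_size(self):
        order = {"normal": 0, "intermediate": 1, "expanded": 2}
        statuses = [
            classify_str(STRCall("LOC_AD", (size,)), CATALOG).allele_statuses[0]
            for size in range(0, 60)
        ]
        ranks = [order[s] for s in statuses]
        assert ranks == sorted(ranks)

    def test_boundaries(self):
        assert classify_str(STRCall("LOC_AD", (35,)), CATALOG).allele_statuses[0] == "normal"
        assert classify_str(STRCall("LOC_AD", (36,)), CATALOG).allele_statuses[0] == "intermediate"
        assert classify_str(STRCall("LOC_AD", (40,)), CATALOG).allele_statuses[0] == "expanded"

    def test_catalog_invariant(self):
        with pytest.raises(ValueError):
            STRCatalogEntry("X", "G", "CAG", 40, 40, "AD")


def _consistent_trio_records(n, rng=None, af=0.3):
    rng = rng or random.Random(1)
    records = []
    for i in range(n):
        m = tuple(sorted(int(rng.random() < af) for _ in range(2)))
        f = tuple(sorted(int(rng.random() < af) for _ in range(2)))
        c = tuple(sorted((rng.choice(m), rng.choice(f))))
        records.append(trio_record(c, m, f, chrom=str(i % 22 + 1), pos=1000 + i))
    return records


class TestTrioConcordance:
    def test_consistent_trio_confirmed(self, trio_pedigree):
        result = trio_concordance(_consistent_trio_records(1000), trio_pedigree)
        assert result.mendelian_error_fraction == 0.0
        assert result.relationship_confirmed
        assert result.status == "confirmed"

    def test_unrelated_child_rejected(self, trio_pedigree):
        # Enumerated expectation: with child ~ HWE(af) independent of parents,
        # P(violation) is substantial (e.g. child 1/1 with a 0/0 parent).
        rng = random.Random(2)
        af = 0.5
        records = []
        for i in range(1000):
            m = tuple(sorted(int(rng.random() < af) for _ in range(2)))
            f = tuple(sorted(int(rng.random() < af) for _ in range(2)))
            c = tuple(sorted(int(rng.random() < af) for _ in range(2)))  # unrelated
            records.append(trio_record(c, m, f, chrom="1", pos=1000 + i))
        # exact expected violation rate by enumeration over HWE genotypes
        import itertools as it

        def hwe(gt):
            p = {0: (1 - af) ** 2, 1: 2 * af * (1 - af), 2: af**2}
            return p[sum(gt)]

        gts = [(0, 0), (0, 1), (1, 1)]
        expected = sum(
            hwe(c) * hwe(m) * hwe(f)
            for c, m, f in it.product(gts, repeat=3)
            if not any(
                sorted((a, b)) == sorted(c) for a in set(m) for b in set(f)
            )
        )
        assert expected > 0.1  # sanity: enumeration says unrelated trios violate often
        result = trio_concordance(records, trio_pedigree)
        assert result.status == "rejected"
        assert result.mendelian_error_fraction == pytest.approx(expected, abs=0.05)

    def test_too_few_sites_inconclusive(self, trio_pedigree):
        result = trio_concordance(_consistent_trio_records(100), trio_pedigree)
        assert result.status == "inconclusive"
        assert result.relationship_confirmed is None

    def test_sex_chromosomes_excluded(self, trio_pedigree):
        records = [
            trio_record((1, 1), (0, 0), (0, 0), chrom="X", pos=15_000_000 + i)
            for i in range(300)
        ]
        result = trio_concordance(records, trio_pedigree)
        assert result.n_informative == 0


class TestFingerprint:
    SITES = [f"rs{i}" for i in range(51)]

    def _gts(self, n_match):
        wgs = {s: (0, 1) for s in self.SITES}
        arr = dict(wgs)
        for s in self.SITES[n_match:]:
            arr[s] = (1, 1)
        return wgs, arr

    def test_full_match_passes(self):
        wgs, arr = self._gts(51)
        result = fingerprint_check(wgs, arr, self.SITES)
        assert result.verdict == "pass"
        assert result.n_compared == 51 and result.n_match == 51

    def test_40_of_51_fails(self):
        wgs, arr = self._gts(40)
        result = fingerprint_check(wgs, arr, self.SITES)
        assert result.verdict == "fail"  # 0.784 < 0.95

    def test_identity_passes(self):
        wgs, _ = self._gts(51)
        assert fingerprint_check(wgs, wgs, self.SITES).verdict == "pass"

    def test_missing_sites_excluded_from_denominator(self):
        wgs, arr = self._gts(51)
        for s in self.SITES[45:]:
            del arr[s]
        result = fingerprint_check(wgs, arr, self.SITES)
        assert result.n_compared == 45
        assert result.verdict == "pass"

    def test_under_30_sites_inconclusive(self):
        wgs, arr = self._gts(51)
        result = fingerprint_check(wgs, arr, self.SITES[:20])
        assert result.verdict == "inconclusive"

    def test_unordered_genotype_comparison(self):
        result = fingerprint_check(
            {s: (1, 0) for s in self.SITES},
            {s: (0, 1) for s in self.SITES},
            self.SITES,
        )
        assert result.verdict == "pass"


class TestDetectUpd:
    def _signal_records(self, n_signal=48, n_het=2, n_pad_hom=10):
        """Signal sites toward the mother, plus ROH padding and some hets."""
        records = []
        pos = 1_000
        for _ in range(n_het):  # informative but biparental (child het)
            records.append(trio_record((0, 1), (0, 0), (1, 1), chrom="7", pos=pos))
            pos += 1_000
        pos = 1_000_000
        for _ in range(n_signal):  # child hom for the maternal allele
            records.append(trio_record((0, 0), (0, 0), (1, 1), chrom="7", pos=pos))
            pos += 100_000
        for _ in range(n_pad_hom):  # uninformative hom padding extends the run
            records.append(trio_record((1, 1), (1, 1), (1, 1), chrom="7", pos=pos))
            pos += 100_000
        return records

    def test_maternal_isodisomy_call(self, trio_pedigree):
        call = detect_upd(self._signal_records(), trio_pedigree, "7")
        assert call is not None
        assert call.parent_of_origin == "maternal"
        assert call.subtype == "isodisomy_suggestive"
        assert call.n_signal_sites == 48
        assert call.signal_fraction == pytest.approx(48 / 50)

    def test_no_signal_no_call(self, trio_pedigree):
        records = [
            trio_record((0, 1), (0, 0), (1, 1), chrom="7", pos=1_000_000 + i * 1000)
            for i in range(50)
        ]
        assert detect_upd(records, trio_pedigree, "7") is None

    def test_below_min_signal_sites_no_call(self, trio_pedigree):
        call = detect_upd(
            self._signal_records(n_signal=8, n_het=0), trio_pedigree, "7"
        )
        assert call is None

    def test_missing_parent_not_applicable(self):
        from raredx.core_io.models import Affection, Individual, Pedigree, Sex

        duo = Pedigree(
            family_id="F",
            individuals=[
                Individual(CHILD, Sex.MALE, Affection.AFFECTED, MOTHER, None),
                Individual(MOTHER, Sex.FEMALE),
            ],
            index_id=CHILD,
        )
        assert detect_upd([], duo, "7") is None

    def test_planted_maternal_chr7_upd_recovered(self):
        config = SynthConfig(seed=13, n_sites=400, upd_chrom="7")
        trio = generate_trio(config)
        call = detect_upd(trio.records, trio.pedigree, "7")
        assert call is not None
        assert call.parent_of_origin == "maternal"
        assert call.subtype == "isodisomy_suggestive"

    def test_specificity_on_biparental_trios(self):
        # scaled-down version of the acceptance experiment (full run uses 1000)
        for seed in range(100):
            config = SynthConfig(seed=seed, n_sites=100, focus_chrom="7")
            trio = generate_trio(config)
            assert detect_upd(trio.records, trio.pedigree, "7") is None
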