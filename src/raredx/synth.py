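"""Deterministic synthetic fixtures: trios with planted inheritance models,
verification-triage variant sets with a requested criterion composition, and
cohort-level case-result tables realizing given marginals.

Everything is driven by an integer seed through :class:`random.Random`; the
same seed yields byte-identical files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Iterable, Optional

from raredx.cohort_report import CaseResult, ReportedVariant
from raredx.core_io.models import (
    Affection,
    AnnotationSet,
    GenomeMask,
    Individual,
    InspectionStatus,
    Pedigree,
    SampleCall,
    Sex,
    VariantRecord,
)
from raredx.core_io.ped import write_ped
from raredx.core_io.vcf import write_scored_vcf
from raredx.errors import ConfigError
from raredx.inheritance import InheritanceModel

_BASES = ("A", "C", "G", "T")

CONSEQUENCE_VOCAB = (
    "stop_gained",
    "frameshift_variant",
    "missense_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "inframe_deletion",
    "synonymous_variant",
    "intron_variant",
)

_DEFAULT_AF_SPECTRUM = (0.5, 0.1, 0.01, 0.001)


@dataclass
class PlantSpec:
    model: InheritanceModel
    gene: str
    annotations: dict = field(default_factory=dict)


@dataclass
class SynthConfig:
    seed: int = 0
    n_sites: int = 400
    af_spectrum: tuple[float, ...] = _DEFAULT_AF_SPECTRUM
    planted_variants: list[PlantSpec] = field(default_factory=list)
    artifact_variants: int = 0
    trio_error_rate: float = 0.0
    child_sex: Sex = Sex.MALE
    family_id: str = "FAM1"
    upd_chrom: Optional[str] = None  # maternal-isodisomy chromosome mode
    focus_chrom: Optional[str] = None  # place all background sites on one chromosome


@dataclass
class PlantTruth:
    key: str
    model: InheritanceModel
    gene: str


@dataclass
class TrioData:
    records: list[VariantRecord]
    pedigree: Pedigree
    truth: list[PlantTruth]

    @property
    def sample_ids(self) -> tuple[str, str, str]:
        ped = self.pedigree
        return (ped.index_id, ped.index.mother_id, ped.index.father_id)

    def write(self, vcf_path: str, ped_path: str, truth_path: Optional[str] = None) -> None:
        write_scored_vcf(self.records, vcf_path)
        write_ped([self.pedigree], ped_path)
        if truth_path:
            with open(truth_path, "w") as fh:
                fh.write("key\tmodel\tgene\n")
                for t in self.truth:
                    fh.write(f"{t.key}\t{t.model.value}\t{t.gene}\n")


# recipe per model: (on_x, mt, child_gt, mother_gt, father_gt,
#                    mother_affected, father_affected, required_child_sex)
_RECIPES: dict[InheritanceModel, tuple] = {
    InheritanceModel.AD: (False, False, (0, 1), (0, 1), (0, 0), True, False, None),
    InheritanceModel.AD_DN: (False, False, (0, 1), (0, 0), (0, 0), False, False, None),
    InheritanceModel.AR_HOM: (False, False, (1, 1), (0, 1), (0, 1), False, False, None),
    InheritanceModel.AR_HOM_DN: (False, False, (1, 1), (0, 0), (0, 0), False, False, None),
    InheritanceModel.XD: (True, False, (0, 1), (0, 1), (0,), True, False, Sex.FEMALE),
    InheritanceModel.XD_DN: (True, False, (0, 1), (0, 0), (0,), False, False, Sex.FEMALE),
    InheritanceModel.XR: (True, False, (1,), (0, 1), (0,), False, False, Sex.MALE),
    InheritanceModel.XR_DN: (True, False, (1, 1), (0, 0), (0,), False, False, Sex.FEMALE),
    InheritanceModel.MT: (False, True, (1,), (1,), (0,), False, False, None),
}

_COMP_RECIPES = {
    # two variants in one gene: (child, mother, father) for each
    InheritanceModel.AR_COMP: (
        ((0, 1), (0, 1), (0, 0)),
        ((0, 1), (0, 0), (0, 1)),
    ),
    InheritanceModel.AR_COMP_DN: (
        ((0, 1), (0, 1), (0, 0)),
        ((0, 1), (0, 0), (0, 0)),
    ),
}


def _call(gt: tuple[int, ...], depth: int = 30, gq: int = 99) -> SampleCall:
    n_alt = sum(1 for a in gt if a == 1)
    if len(gt) == 1:
        ad = (0, depth) if n_alt else (depth, 0)
    elif n_alt == 2:
        ad = (0, depth)
    elif n_alt == 1:
        ad = (depth - depth // 2, depth // 2)
    else:
        ad = (depth, 0)
    return SampleCall(genotype=gt, depth=depth, genotype_quality=gq, allele_depths=ad)


def _draw_gt(rng: random.Random, af: float) -> tuple[int, int]:
    a = 1 if rng.random() < af else 0
    b = 1 if rng.random() < af else 0
    return (min(a, b), max(a, b))


def _transmit(rng: random.Random, mother_gt, father_gt, error_rate: float) -> tuple[int, int]:
    a, b = rng.choice(mother_gt), rng.choice(father_gt)
    if error_rate and rng.random() < error_rate:
        a = 1 - a
    return (min(a, b), max(a, b))


def _resolve_sex(config: SynthConfig) -> Sex:
    required = {
        _RECIPES[p.model][7]
        for p in config.planted_variants
        if p.model in _RECIPES and _RECIPES[p.model][7] is not None
    }
    if len(required) > 1:
        raise ConfigError(f"plants require conflicting child sexes: {required}")
    if required:
        needed = required.pop()
        if config.child_sex != needed and config.child_sex != Sex.UNKNOWN:
            raise ConfigError(
                f"planted models need a {needed.value} child but config says "
                f"{config.child_sex.value}"
            )
        return needed
    return config.child_sex if config.child_sex != Sex.UNKNOWN else Sex.MALE


def _resolve_parent_affections(config: SynthConfig) -> tuple[Affection, Affection]:
    mother = father = Affection.UNAFFECTED
    need_mother = {p.model for p in config.planted_variants if p.model in _RECIPES and _RECIPES[p.model][5]}
    need_father = {p.model for p in config.planted_variants if p.model in _RECIPES and _RECIPES[p.model][6]}
    avoid = {
        p.model
        for p in config.planted_variants
        if p.model
        in (
            InheritanceModel.AD_DN,
            InheritanceModel.AR_HOM,
            InheritanceModel.AR_HOM_DN,
            InheritanceModel.XD_DN,
            InheritanceModel.XR,
            InheritanceModel.XR_DN,
        )
    }
    if need_mother and avoid:
        raise ConfigError(
            f"cannot combine dominant-inherited plants {need_mother} with "
            f"{avoid} in one trio (conflicting parental affections)"
        )
    if need_mother:
        mother = Affection.AFFECTED
    if need_father:
        father = Affection.AFFECTED
    return mother, father


def _planted_annotations(spec: PlantSpec, rng: random.Random) -> AnnotationSet:
    defaults = dict(
        gene_symbols=frozenset({spec.gene}),
        consequence=rng.choice(CONSEQUENCE_VOCAB[:5]),
        population_af=None,
        deleteriousness_score=round(rng.uniform(20.0, 35.0), 1),
        conservation_score=round(rng.uniform(0.8, 1.0), 3),
    )
    defaults.update(spec.annotations)
    return AnnotationSet(**defaults)


def generate_trio(config: SynthConfig) -> TrioData:
    """Generate a trio VCF-equivalent record set with planted ground truth."""
    rng = random.Random(config.seed)
    child_sex = _resolve_sex(config)
    mother_aff, father_aff = _resolve_parent_affections(config)
    fam = config.family_id
    child_id, mother_id, father_id = f"{fam}_child", f"{fam}_mother", f"{fam}_father"
    pedigree = Pedigree(
        family_id=fam,
        individuals=[
            Individual(child_id, child_sex, Affection.AFFECTED, mother_id, father_id),
            Individual(mother_id, Sex.FEMALE, mother_aff),
            Individual(father_id, Sex.MALE, father_aff),
        ],
        index_id=child_id,
    )

    records: list[VariantRecord] = []
    # background autosomal sites, evenly spread over chromosomes 1..22
    for i in range(config.n_sites):
        if config.focus_chrom is not None:
            chrom = config.focus_chrom
            pos = 1_000_000 + i * 100_000
        else:
            chrom = str(i % 22 + 1)
            if config.upd_chrom is not None and chrom == config.upd_chrom:
                chrom = "22" if config.upd_chrom != "22" else "21"
            pos = 1_000_000 + (i // 22) * 150_000 + (7919 if chrom == "22" else 0)
        af = config.af_spectrum[i % len(config.af_spectrum)]
        ref = _BASES[i % 4]
        alt = _BASES[(i + 1) % 4]
        mother_gt = _draw_gt(rng, af)
        father_gt = _draw_gt(rng, af)
        child_gt = _transmit(rng, mother_gt, father_gt, config.trio_error_rate)
        records.append(
            VariantRecord(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                per_sample={
                    child_id: _call(child_gt),
                    mother_id: _call(mother_gt),
                    father_id: _call(father_gt),
                },
                annotations=AnnotationSet(
                    gene_symbols=frozenset({f"BG{i % 200:04d}"}),
                    population_af=af,
                    consequence="intron_variant",
                ),
            )
        )
    # maternal-isodisomy chromosome: child homozygous for a maternal allele
    if config.upd_chrom is not None:
        for j in range(200):
            pos = 2_000_000 + j * 300_000
            af = 0.5
            mother_gt = _draw_gt(rng, af)
            father_gt = _draw_gt(rng, af)
            a = rng.choice(mother_gt)
            records.append(
                VariantRecord(
                    chrom=config.upd_chrom,
                    pos=pos,
                    ref="A",
                    alt="G",
                    per_sample={
                        child_id: _call((a, a)),
                        mother_id: _call(mother_gt),
                        father_id: _call(father_gt),
                    },
                    annotations=AnnotationSet(population_af=af),
                )
            )
    # artifact variants at fixed keys, so different families share them
    for j in range(config.artifact_variants):
        records.append(
            VariantRecord(
                chrom="2",
                pos=500_000 + j * 1000,
                ref="C",
                alt="T",
                per_sample={
                    child_id: _call((0, 1)),
                    mother_id: _call((0, 1)),
                    father_id: _call((0, 1)),
                },
                annotations=AnnotationSet(
                    gene_symbols=frozenset({f"ART{j:03d}"}), population_af=None
                ),
            )
        )

    truth: list[PlantTruth] = []
    plant_pos = {"auto": 5_000_000, "x": 10_000_000, "mt": 1000}
    for spec in config.planted_variants:
        if spec.model in _COMP_RECIPES:
            for child_gt, mother_gt, father_gt in _COMP_RECIPES[spec.model]:
                pos = plant_pos["auto"]
                plant_pos["auto"] += 97
                rec = VariantRecord(
                    chrom="11",
                    pos=pos,
                    ref="G",
                    alt="A",
                    per_sample={
                        child_id: _call(child_gt),
                        mother_id: _call(mother_gt),
                        father_id: _call(father_gt),
                    },
                    annotations=_planted_annotations(spec, rng),
                )
                records.append(rec)
                truth.append(PlantTruth(rec.key_str, spec.model, spec.gene))
            continue
        if spec.model not in _RECIPES:
            raise ConfigError(f"cannot plant model {spec.model}")
        on_x, on_mt, child_gt, mother_gt, father_gt, *_ = _RECIPES[spec.model]
        if on_mt:
            chrom, pos = "MT", plant_pos["mt"]
            plant_pos["mt"] += 53
        elif on_x:
            chrom, pos = "X", plant_pos["x"]
            plant_pos["x"] += 101
        else:
            chrom, pos = "7", plant_pos["auto"]
            plant_pos["auto"] += 97
        rec = VariantRecord(
            chrom=chrom,
            pos=pos,
            ref="C",
            alt="T",
            per_sample={
                child_id: _call(child_gt),
                mother_id: _call(mother_gt),
                father_id: _call(father_gt),
            },
            annotations=_planted_annotations(spec, rng),
        )
        records.append(rec)
        truth.append(PlantTruth(rec.key_str, spec.model, spec.gene))

    records.sort(key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
    return TrioData(records=records, pedigree=pedigree, truth=truth)


def generate_families(
    base_config: SynthConfig, n_families: int, artifact_carrier_fraction: float = 0.0
) -> list[TrioData]:
    """Independent trios sharing artifact-variant keys in a controlled fraction.

    The first ``round(fraction * n_families)`` families carry every artifact
    variant; the rest carry none.
    """
    n_carriers = round(artifact_carrier_fraction * n_families)
    out = []
    for i in range(n_families):
        cfg_artifacts = base_config.artifact_variants if i < n_carriers else 0
        cfg = SynthConfig(
            seed=base_config.seed * 100_003 + i,
            n_sites=base_config.n_sites,
            af_spectrum=base_config.af_spectrum,
            planted_variants=list(base_config.planted_variants),
            artifact_variants=cfg_artifacts,
            trio_error_rate=base_config.trio_error_rate,
            child_sex=base_config.child_sex,
            family_id=f"FAM{i + 1}",
            upd_chrom=base_config.upd_chrom,
        )
        out.append(generate_trio(cfg))
    return out


# ---------------------------------------------------------------------------
# verification-triage fixtures


#: which criteria each stratum violates (others are satisfied)
TRIAGE_STRATA = {
    "skip": (),
    "indel": ("is_snv",),
    "low_gq": ("gq_max",),
    "no_pass": ("filter_pass",),
    "low_depth": ("depth_ok",),
    "no_inspection": ("inspection_good",),
    "in_segdup": ("outside_segdup",),
}


def generate_triage_set(
    stage_counts: dict[str, int], sample_id: str = "S1"
) -> tuple[list[VariantRecord], GenomeMask]:
    """Emit one variant per requested stratum occurrence, plus the matching mask.

    ``stage_counts`` maps stratum names from :data:`TRIAGE_STRATA` to counts.
    Records in the ``in_segdup`` stratum are placed inside the returned
    segmental-duplication mask; everything else is outside it.
    """
    unknown = set(stage_counts) - set(TRIAGE_STRATA)
    if unknown:
        raise ConfigError(f"unknown triage strata: {sorted(unknown)}")
    segdup_start = 90_000_000
    mask = GenomeMask([("1", segdup_start, segdup_start + 10_000_000)])
    records = []
    pos = 1_000_000
    for stratum in TRIAGE_STRATA:  # fixed order for determinism
        violations = set(TRIAGE_STRATA[stratum])
        for _ in range(stage_counts.get(stratum, 0)):
            in_segdup = "outside_segdup" in violations
            p = (segdup_start + 1_000_000 + pos % 1_000_000) if in_segdup else pos
            pos += 17
            ref, alt = ("AT", "A") if "is_snv" in violations else ("A", "G")
            records.append(
                VariantRecord(
                    chrom="1",
                    pos=p,
                    ref=ref,
                    alt=alt,
                    filter_status="LowQual" if "filter_pass" in violations else "PASS",
                    per_sample={
                        sample_id: SampleCall(
                            genotype=(0, 1),
                            depth=12 if "depth_ok" in violations else 35,
                            genotype_quality=87 if "gq_max" in violations else 99,
                            allele_depths=(18, 17),
                        )
                    },
                    annotations=AnnotationSet(
                        inspection_status=InspectionStatus.UNSET
                        if "inspection_good" in violations
                        else InspectionStatus.GOOD
                    ),
                )
            )
    return records, mask


# ---------------------------------------------------------------------------
# cohort case-result fixtures


def generate_case_results(
    panel_rows: Iterable[dict],
    analysis_type: str = "singleton",
    id_prefix: str = "CASE",
) -> list[CaseResult]:
    """Case results realizing per-panel analysis/solved marginals.

    Each row is ``{"panel": name, "n_analyses": int, "n_solved": int}``; a
    solved case gets one generic causative reported variant.
    """
    cases = []
    counter = 0
    for row in panel_rows:
        panel, n, k = row["panel"], row["n_analyses"], row["n_solved"]
        if k > n:
            raise ConfigError(f"panel {panel}: n_solved {k} > n_analyses {n}")
        for j in range(n):
            counter += 1
            solved = j < k
            variants = (
                [
                    ReportedVariant(
                        gene=f"GENE{counter:05d}",
                        variant_key=f"1:{counter}:A:G",
                        inheritance_category="assumed_AD",
                        determined=False,
                    )
                ]
                if solved
                else []
            )
            cases.append(
                CaseResult(
                    case_id=f"{id_prefix}{counter:05d}",
                    panels_analyzed=[panel],
                    analysis_type=analysis_type,
                    solved=solved,
                    reported_variants=variants,
                )
            )
    return cases


def generate_inheritance_findings(
    determined_counts: dict[str, int],
    assumed_counts: Optional[dict[str, int]] = None,
    id_prefix: str = "MOI",
) -> list[CaseResult]:
    """One solved case per finding, realizing the per-category counts."""
    cases = []
    counter = 0
    for determined, counts in ((True, determined_counts), (False, assumed_counts or {})):
        for category, n in counts.items():
            for _ in range(n):
                counter += 1
                cases.append(
                    CaseResult(
                        case_id=f"{id_prefix}{counter:05d}",
                        panels_analyzed=["panel"],
                        solved=True,
                        reported_variants=[
                            ReportedVariant(
                                gene=f"GENE{counter:05d}",
                                variant_key=f"1:{counter}:A:G",
                                inheritance_category=category,
                                determined=determined,
                            )
                        ],
                    )
                )
    return cases


def generate_gene_recurrence_cases(
    histogram: dict[int, int], id_prefix: str = "REC"
) -> list[CaseResult]:
    """Cases realizing a gene-recurrence histogram {cases_per_gene: n_genes}."""
    cases = []
    gene_no = 0
    case_no = 0
    for cases_per_gene in sorted(histogram):
        for _ in range(histogram[cases_per_gene]):
            gene_no += 1
            gene = f"GENE{gene_no:05d}"
            for _ in range(cases_per_gene):
                case_no += 1
                cases.append(
                    CaseResult(
                        case_id=f"{id_prefix}{case_no:06d}",
                        panels_analyzed=["panel"],
                        solved=True,
                        reported_variants=[
                            ReportedVariant(
                                gene=gene,
                                variant_key=f"1:{case_no}:A:G",
                                inheritance_category="assumed_AD",
                                determined=False,
                            )
                        ],
                    )
                )
    return cases
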