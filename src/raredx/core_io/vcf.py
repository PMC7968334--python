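"""VCF ingest (via cyvcf2) and emission of scored VCFs.

Reading delegates parsing to cyvcf2; this layer splits multi-allelic sites,
maps per-sample fields into :class:`SampleCall` objects and recovers toolkit
annotations from INFO keys. Writing serializes our biallelic record model
back to VCF v4.2 text, carrying rank scores and inheritance models as INFO
keys (``RankScore``, ``RankResult``, ``GeneticModels``).
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Iterator, Optional

from cyvcf2 import VCF

from raredx.core_io.models import (
    AnnotationSet,
    InspectionStatus,
    Pedigree,
    SampleCall,
    Sex,
    VariantRecord,
    is_x_nonpar,
)
from raredx.errors import FormatError

logger = logging.getLogger(__name__)

# INFO keys used to round-trip annotations through written VCFs
_INFO_DEFS = [
    ("GENE", "String", "Gene symbols (comma separated)"),
    ("CSQ", "String", "Most severe consequence"),
    ("POP_AF", "Float", "Population allele frequency"),
    ("CONS_SCORE", "Float", "Conservation score"),
    ("DEL_SCORE", "Float", "Deleteriousness score"),
    ("CLNSIG", "String", "Clinical significance"),
    ("OBS", "Integer", "Local observation count"),
    ("OBS_FREQ", "Float", "Local observation frequency"),
    ("ARTIFACT", "Flag", "Local artifact flag"),
    ("INSPECT", "String", "Manual inspection status"),
    ("GeneticModels", "String", "Compatible inheritance models"),
    ("RankScore", "String", "family_id:total rank score"),
    ("RankResult", "String", "Per-category rank points, colon separated"),
]


def _maybe(value, cast):
    if value is None:
        return None
    try:
        out = cast(value)
    except (TypeError, ValueError):
        return None
    if cast is float:
        # htslib stores INFO floats as float32; canonicalize to the 6-sig-fig
        # decimal we wrote so round-trips compare equal
        out = float(f"{out:.6g}")
    return out


def _annotations_from_info(variant) -> AnnotationSet:
    info = variant.INFO
    genes = info.get("GENE")
    gene_symbols = frozenset(genes.split(",")) if genes else frozenset()
    inspect = info.get("INSPECT")
    return AnnotationSet(
        gene_symbols=gene_symbols,
        consequence=info.get("CSQ"),
        population_af=_maybe(info.get("POP_AF"), float),
        conservation_score=_maybe(info.get("CONS_SCORE"), float),
        deleteriousness_score=_maybe(info.get("DEL_SCORE"), float),
        clinical_significance=info.get("CLNSIG"),
        local_obs=_maybe(info.get("OBS"), int),
        local_frequency=_maybe(info.get("OBS_FREQ"), float),
        local_artifact=bool(info.get("ARTIFACT")),
        inspection_status=InspectionStatus(inspect) if inspect else InspectionStatus.UNSET,
    )


def _scalar_format(variant, key: str, sample_idx: int) -> Optional[int]:
    arr = variant.format(key)
    if arr is None:
        return None
    v = int(arr[sample_idx][0])
    return v if v >= 0 else None


def _split_genotype(
    alleles: list, alt_index: int
) -> tuple[Optional[tuple[int, ...]], bool]:
    """Map a cyvcf2 genotype entry onto the biallelic split for ``alt_index``.

    Alleles equal to ``alt_index`` become 1, other called alleles become 0.
    Any missing allele makes the whole genotype missing.
    """
    phased = bool(alleles[-1])
    calls = alleles[:-1]
    if any(a < 0 for a in calls):
        return None, phased
    mapped = tuple(1 if a == alt_index else 0 for a in calls)
    return mapped, phased


def _coerce_hemizygous(
    gt: Optional[tuple[int, ...]], chrom: str, pos: int, sample_id: str
) -> Optional[tuple[int, ...]]:
    if gt is None or len(gt) == 1:
        return gt
    if gt[0] == gt[1]:
        return (gt[0],)
    warnings.warn(
        f"heterozygous diploid call for male sample {sample_id} at {chrom}:{pos} "
        "coerced to hemizygous alt",
        stacklevel=3,
    )
    return (1,)


def read_vcf(path: str, pedigree: Optional[Pedigree] = None) -> Iterator[VariantRecord]:
    """Stream biallelic :class:`VariantRecord` objects from a VCF file.

    Multi-allelic sites are split into one record per alternate allele, with
    per-allele AD carried alongside the matching alt. Missing DP/GQ/AD stay
    missing. With a pedigree, diploid chrX non-PAR calls in males are coerced
    to hemizygous single-allele genotypes.
    """
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad headers
        raise FormatError(f"{path}: cannot parse VCF header: {exc}") from exc
    male_ids = set()
    if pedigree is not None:
        male_ids = {ind.id for ind in pedigree.individuals if ind.sex == Sex.MALE}
    samples = vcf.samples
    for line_no, variant in enumerate(vcf, start=1):
        alts = variant.ALT
        if not alts:
            continue
        annotations = _annotations_from_info(variant)
        filter_status = variant.FILTER or "PASS"
        genotypes = variant.genotypes if samples else []
        ad = variant.format("AD") if samples else None
        for k, alt in enumerate(alts, start=1):
            per_sample: dict[str, SampleCall] = {}
            for idx, sample_id in enumerate(samples):
                alleles = genotypes[idx]
                if len(alleles) - 1 > 2:
                    raise FormatError(
                        f"{path} record {line_no}: ploidy > 2 for sample {sample_id}"
                    )
                gt, phased = _split_genotype(alleles, k)
                if sample_id in male_ids and is_x_nonpar(variant.CHROM, variant.POS):
                    gt = _coerce_hemizygous(gt, variant.CHROM, variant.POS, sample_id)
                allele_depths = None
                if ad is not None:
                    row = ad[idx]
                    if len(row) > k and int(row[0]) >= 0 and int(row[k]) >= 0:
                        allele_depths = (int(row[0]), int(row[k]))
                per_sample[sample_id] = SampleCall(
                    genotype=gt,
                    depth=_scalar_format(variant, "DP", idx),
                    genotype_quality=_scalar_format(variant, "GQ", idx),
                    allele_depths=allele_depths,
                    phased=phased,
                )
            try:
                yield VariantRecord(
                    chrom=variant.CHROM,
                    pos=variant.POS,
                    ref=variant.REF,
                    alt=alt,
                    filter_status=filter_status,
                    per_sample=per_sample,
                    annotations=annotations,
                )
            except ValueError as exc:
                raise FormatError(f"{path} record {line_no}: {exc}") from exc


def _fmt_float(x: float) -> str:
    return f"{x:.6g}"


def _info_string(record: VariantRecord) -> str:
    ann = record.annotations
    parts: list[str] = []
    if ann.gene_symbols:
        parts.append("GENE=" + ",".join(sorted(ann.gene_symbols)))
    if ann.consequence is not None:
        parts.append(f"CSQ={ann.consequence}")
    if ann.population_af is not None:
        parts.append(f"POP_AF={_fmt_float(ann.population_af)}")
    if ann.conservation_score is not None:
        parts.append(f"CONS_SCORE={_fmt_float(ann.conservation_score)}")
    if ann.deleteriousness_score is not None:
        parts.append(f"DEL_SCORE={_fmt_float(ann.deleteriousness_score)}")
    if ann.clinical_significance is not None:
        parts.append(f"CLNSIG={ann.clinical_significance}")
    if ann.local_obs is not None:
        parts.append(f"OBS={ann.local_obs}")
    if ann.local_frequency is not None:
        parts.append(f"OBS_FREQ={_fmt_float(ann.local_frequency)}")
    if ann.local_artifact:
        parts.append("ARTIFACT")
    if ann.inspection_status != InspectionStatus.UNSET:
        parts.append(f"INSPECT={ann.inspection_status.value}")
    extra = getattr(record, "info_extra", None)
    if extra:
        for key, value in extra.items():
            parts.append(key if value is True else f"{key}={value}")
    return ";".join(parts) if parts else "."


def _format_call(call: SampleCall) -> str:
    if call.genotype is None:
        gt = "./."
    else:
        sep = "|" if call.phased else "/"
        gt = sep.join(str(a) for a in call.genotype)
    dp = "." if call.depth is None else str(call.depth)
    gq = "." if call.genotype_quality is None else str(call.genotype_quality)
    ad = "." if call.allele_depths is None else f"{call.allele_depths[0]},{call.allele_depths[1]}"
    return f"{gt}:{dp}:{gq}:{ad}"


def write_scored_vcf(records: Iterable[VariantRecord], path: str) -> int:
    """Write records to a VCF v4.2 text file; returns the record count.

    Extra INFO keys attached via ``record.info_extra`` (a dict, e.g. from the
    ranking/inheritance stages) are serialized verbatim.
    """
    records = list(records)
    sample_ids: list[str] = []
    for rec in records:
        for sid in rec.per_sample:
            if sid not in sample_ids:
                sample_ids.append(sid)
    contigs: list[str] = []
    for rec in records:
        if rec.chrom not in contigs:
            contigs.append(rec.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=raredx\n")
        for contig in contigs:
            fh.write(f"##contig=<ID={contig}>\n")
        for status in sorted({r.filter_status for r in records} - {"PASS", "."}):
            fh.write(f'##FILTER=<ID={status},Description="upstream filter">\n')
        for key, typ, desc in _INFO_DEFS:
            number = "0" if typ == "Flag" else "1"
            fh.write(
                f'##INFO=<ID={key},Number={number},Type={typ},Description="{desc}">\n'
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
        if sample_ids:
            header_cols += ["FORMAT"] + sample_ids
        fh.write("\t".join(header_cols) + "\n")
        for rec in records:
            cols = [
                rec.chrom,
                str(rec.pos),
                ".",
                rec.ref,
                rec.alt,
                ".",
                rec.filter_status,
                _info_string(rec),
            ]
            if sample_ids:
                cols.append("GT:DP:GQ:AD")
                for sid in sample_ids:
                    call = rec.per_sample.get(sid)
                    cols.append(_format_call(call) if call else "./.:.:.:.")
            fh.write("\t".join(cols) + "\n")
    logger.info("wrote %d records to %s", len(records), path)
    return len(records)
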