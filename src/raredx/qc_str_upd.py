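"""Family-level QC: trio concordance, SNP-fingerprint checks, STR expansion
classification and trio-based uniparental-disomy screening.

The UPD statistic is this toolkit's own design: at sites where the parents
are opposite homozygotes, a biparental child must be heterozygous; a child
homozygous for one parent's allele is a "signal" site pointing to that
parent. A chromosome-level call requires >= 10 signal sites with >= 90% of
informative sites signalling the same parent. Isodisomy is suggested when
the child's run-of-homozygosity fraction on that chromosome is >= 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from raredx.core_io.models import Pedigree, VariantRecord, normalize_chrom
from raredx.core_io.ped import _open_text
from raredx.errors import FormatError, RaredxError

_SEX_CHROMS = frozenset({"X", "Y", "MT", "M"})

# ---------------------------------------------------------------------------
# STR classification


@dataclass(frozen=True)
class STRCatalogEntry:
    locus_id: str
    gene: str
    repeat_unit: str
    normal_max: int
    pathologic_min: int
    inheritance: str  # AD | AR | XR

    def __post_init__(self) -> None:
        if self.normal_max >= self.pathologic_min:
            raise ValueError(
                f"{self.locus_id}: normal_max must be < pathologic_min"
            )


@dataclass
class STRCall:
    locus_id: str
    allele_sizes: tuple[int, ...]  # pair, or single when hemizygous

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.allele_sizes):
            raise ValueError("repeat sizes must be >= 0")


@dataclass
class STRClassification:
    locus_id: str
    allele_statuses: tuple[str, ...]  # normal | intermediate | expanded
    reportable: bool


def read_str_catalog(path: str) -> dict[str, STRCatalogEntry]:
    """TSV columns: locus_id gene repeat_unit normal_max pathologic_min inheritance."""
    catalog: dict[str, STRCatalogEntry] = {}
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("locus_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path} line {line_no}: expected 6 columns")
            entry = STRCatalogEntry(
                locus_id=fields[0],
                gene=fields[1],
                repeat_unit=fields[2],
                normal_max=int(fields[3]),
                pathologic_min=int(fields[4]),
                inheritance=fields[5],
            )
            catalog[entry.locus_id] = entry
    return catalog


def classify_str(call: STRCall, catalog: dict[str, STRCatalogEntry]) -> STRClassification:
    """Classify each allele against the locus thresholds and flag reportability.

    AD/XR loci are reportable with one expanded allele; AR loci need two.
    """
    entry = catalog.get(call.locus_id)
    if entry is None:
        raise RaredxError(
            f"unknown STR locus {call.locus_id!r}; catalog has {sorted(catalog)}"
        )

    def status(size: int) -> str:
        if size <= entry.normal_max:
            return "normal"
        if size >= entry.pathologic_min:
            return "expanded"
        return "intermediate"

    statuses = tuple(status(s) for s in call.allele_sizes)
    n_expanded = sum(1 for s in statuses if s == "expanded")
    if entry.inheritance == "AR":
        reportable = n_expanded >= 2
    else:  # AD, XR: one expanded allele suffices
        reportable = n_expanded >= 1
    return STRClassification(call.locus_id, statuses, reportable)


# ---------------------------------------------------------------------------
# trio concordance


@dataclass
class ConcordanceResult:
    n_informative: int
    n_errors: int
    mendelian_error_fraction: Optional[float]
    relationship_confirmed: Optional[bool]
    status: str  # confirmed | rejected | inconclusive


def _child_possible(child: tuple[int, ...], mother: tuple[int, ...], father: tuple[int, ...]) -> bool:
    return any(
        sorted((m, f)) == sorted(child) for m in set(mother) for f in set(father)
    )


def trio_concordance(
    records: Iterable[VariantRecord],
    pedigree: Pedigree,
    min_sites: int = 200,
    max_error_fraction: float = 0.02,
) -> ConcordanceResult:
    """Mendelian-error rate over biallelic autosomal sites genotyped in all three.

    chrX/chrY/chrM are excluded. Below ``min_sites`` informative sites the
    verdict is 'inconclusive', never a pass.
    """
    mother, father = pedigree.parents_of(pedigree.index_id)
    if mother is None or father is None:
        raise RaredxError("trio_concordance needs both parents in the pedigree")
    n_informative = 0
    n_errors = 0
    for record in records:
        if normalize_chrom(record.chrom) in _SEX_CHROMS:
            continue
        calls = [
            record.per_sample.get(i)
            for i in (pedigree.index_id, mother.id, father.id)
        ]
        if any(c is None or c.genotype is None or len(c.genotype) != 2 for c in calls):
            continue
        n_informative += 1
        child_gt, mother_gt, father_gt = (c.genotype for c in calls)
        if not _child_possible(child_gt, mother_gt, father_gt):
            n_errors += 1
    if n_informative < min_sites:
        return ConcordanceResult(n_informative, n_errors, None, None, "inconclusive")
    fraction = n_errors / n_informative
    confirmed = fraction <= max_error_fraction
    return ConcordanceResult(
        n_informative,
        n_errors,
        fraction,
        confirmed,
        "confirmed" if confirmed else "rejected",
    )


# ---------------------------------------------------------------------------
# fingerprint check


@dataclass
class FingerprintResult:
    n_compared: int
    n_match: int
    verdict: str  # pass | fail | inconclusive


def fingerprint_check(
    wgs_genotypes: dict[str, tuple[int, ...]],
    array_genotypes: dict[str, tuple[int, ...]],
    site_list: Iterable[str],
    min_sites: int = 30,
    min_match_fraction: float = 0.95,
) -> FingerprintResult:
    """Compare WGS-called genotypes against orthogonal array genotypes.

    Sites missing in either source drop out of the denominator. Genotypes
    compare as unordered allele multisets.
    """
    n_compared = 0
    n_match = 0
    for site in site_list:
        wgs = wgs_genotypes.get(site)
        arr = array_genotypes.get(site)
        if wgs is None or arr is None:
            continue
        n_compared += 1
        if sorted(wgs) == sorted(arr):
            n_match += 1
    if n_compared < min_sites:
        return FingerprintResult(n_compared, n_match, "inconclusive")
    verdict = "pass" if n_match / n_compared >= min_match_fraction else "fail"
    return FingerprintResult(n_compared, n_match, verdict)


# ---------------------------------------------------------------------------
# UPD screening


@dataclass
class UPDCall:
    chrom: str
    parent_of_origin: str  # maternal | paternal
    subtype: str  # isodisomy_suggestive | heterodisomy_suggestive | undetermined
    n_signal_sites: int
    signal_fraction: float


def _roh_fraction(
    sites: list[tuple[int, bool]], min_bases: int = 1_000_000, min_sites: int = 50
) -> float:
    """Fraction of the surveyed span inside child-homozygosity runs.

    A run qualifies when it spans >= 1 Mb over >= 50 consecutive homozygous
    sites. The surveyed span is last site - first site + 1.
    """
    if not sites:
        return 0.0
    span = sites[-1][0] - sites[0][0] + 1
    if span <= 0:
        return 0.0
    roh_bases = 0
    run_start: Optional[int] = None
    run_len = 0
    prev_pos = None
    for pos, hom in sites + [(None, False)]:  # sentinel flushes the last run
        if hom:
            if run_start is None:
                run_start = pos
                run_len = 0
            run_len += 1
            prev_pos = pos
        else:
            if run_start is not None:
                length = prev_pos - run_start + 1
                if length >= min_bases and run_len >= min_sites:
                    roh_bases += length
                run_start = None
    return min(1.0, roh_bases / span)


def detect_upd(
    records: Iterable[VariantRecord],
    pedigree: Pedigree,
    chrom: str,
    min_signal_sites: int = 10,
    min_signal_fraction: float = 0.9,
    roh_threshold: float = 0.8,
) -> Optional[UPDCall]:
    """Screen one chromosome of a trio for uniparental inheritance."""
    mother, father = pedigree.parents_of(pedigree.index_id)
    if mother is None or father is None:
        return None
    chrom = normalize_chrom(chrom)
    maternal_signal = 0
    paternal_signal = 0
    n_informative = 0
    hom_sites: list[tuple[int, bool]] = []
    for record in sorted(
        (r for r in records if r.chrom == chrom), key=lambda r: r.pos
    ):
        child = record.per_sample.get(pedigree.index_id)
        mo = record.per_sample.get(mother.id)
        fa = record.per_sample.get(father.id)
        if child is None or child.genotype is None or len(child.genotype) != 2:
            continue
        child_hom = child.genotype[0] == child.genotype[1]
        hom_sites.append((record.pos, child_hom))
        if mo is None or fa is None or mo.genotype is None or fa.genotype is None:
            continue
        mo_hom = len(mo.genotype) == 2 and mo.genotype[0] == mo.genotype[1]
        fa_hom = len(fa.genotype) == 2 and fa.genotype[0] == fa.genotype[1]
        if not (mo_hom and fa_hom) or mo.genotype[0] == fa.genotype[0]:
            continue  # need opposite-homozygote parents
        n_informative += 1
        if not child_hom:
            continue  # heterozygous child = biparental, as expected
        if child.genotype[0] == mo.genotype[0]:
            maternal_signal += 1
        elif child.genotype[0] == fa.genotype[0]:
            paternal_signal += 1
    if n_informative == 0:
        return None
    for parent, signal in (("maternal", maternal_signal), ("paternal", paternal_signal)):
        fraction = signal / n_informative
        if signal >= min_signal_sites and fraction >= min_signal_fraction:
            roh = _roh_fraction(hom_sites)
            if roh >= roh_threshold:
                subtype = "isodisomy_suggestive"
            elif signal >= min_signal_sites:
                # signal sites are themselves duo-inconsistent with the other
                # parent, which supports heterodisomy when homozygosity is low
                subtype = "heterodisomy_suggestive"
            else:
                subtype = "undetermined"
            return UPDCall(
                chrom=chrom,
                parent_of_origin=parent,
                subtype=subtype,
                n_signal_sites=signal,
                signal_fraction=fraction,
            )
    return None
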