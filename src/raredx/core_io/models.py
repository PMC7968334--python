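"""Core domain types: variants, sample calls, pedigrees and interval masks.

All coordinates follow the conventions of their source formats: variant
positions are 1-based (VCF), mask intervals are 0-based half-open (BED).
Chromosome labels are normalized to the no-``chr`` dialect internally.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

from raredx.errors import StructuralError

MT_CONTIGS = frozenset({"MT", "M"})

#: hg19 pseudoautosomal regions on X, 1-based inclusive
PAR1 = (60001, 2699520)
PAR2 = (154931044, 155260560)


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix and map ``chrM`` to ``MT``."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return "MT" if c in ("M", "m") else c


def is_x_nonpar(chrom: str, pos: int) -> bool:
    """True for chrX positions outside PAR1/PAR2 (treated as truly hemizygous)."""
    if normalize_chrom(chrom) != "X":
        return False
    return not (PAR1[0] <= pos <= PAR1[1] or PAR2[0] <= pos <= PAR2[1])


class VariantClass(str, Enum):
    SNV = "SNV"
    INDEL = "INDEL"
    SV = "SV"
    STR = "STR"
    MT = "MT"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class InspectionStatus(str, Enum):
    GOOD = "good"
    UNCERTAIN = "uncertain"
    BAD = "bad"
    UNSET = "unset"


@dataclass
class SampleCall:
    """Per-sample genotype and quality fields for one variant.

    ``genotype`` is a tuple of allele indices: length 2 for diploid calls,
    length 1 for hemizygous calls, ``None`` when missing. Missing DP/GQ/AD
    stay ``None`` — they never default to zero.
    """

    genotype: Optional[tuple[int, ...]] = None
    depth: Optional[int] = None
    genotype_quality: Optional[int] = None
    allele_depths: Optional[tuple[int, int]] = None
    phased: bool = False

    def __post_init__(self) -> None:
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be >= 0")
        if self.allele_depths is not None and any(d < 0 for d in self.allele_depths):
            raise ValueError("allele depths must be >= 0")

    @property
    def has_genotype(self) -> bool:
        return self.genotype is not None

    @property
    def n_alt(self) -> Optional[int]:
        """Number of alternate alleles in the call, None when ungenotyped."""
        if self.genotype is None:
            return None
        return sum(1 for a in self.genotype if a == 1)

    @property
    def carries_alt(self) -> Optional[bool]:
        n = self.n_alt
        return None if n is None else n > 0

    @property
    def is_hom_alt(self) -> Optional[bool]:
        """Hom-alt diploid or hemizygous-alt call."""
        if self.genotype is None:
            return None
        return all(a == 1 for a in self.genotype)

    @property
    def is_het(self) -> Optional[bool]:
        if self.genotype is None:
            return None
        return len(self.genotype) == 2 and sorted(self.genotype) == [0, 1]

    @property
    def alt_fraction(self) -> Optional[float]:
        if self.allele_depths is None:
            return None
        total = self.allele_depths[0] + self.allele_depths[1]
        return self.allele_depths[1] / total if total else None


@dataclass
class AnnotationSet:
    """Functional and frequency annotations attached to a variant."""

    gene_symbols: frozenset[str] = frozenset()
    consequence: Optional[str] = None
    population_af: Optional[float] = None
    conservation_score: Optional[float] = None
    deleteriousness_score: Optional[float] = None
    clinical_significance: Optional[str] = None
    local_obs: Optional[int] = None
    local_frequency: Optional[float] = None
    local_artifact: bool = False
    inspection_status: InspectionStatus = InspectionStatus.UNSET

    def __post_init__(self) -> None:
        if self.population_af is not None and not 0.0 <= self.population_af <= 1.0:
            raise ValueError("population_af must be in [0, 1]")
        self.gene_symbols = frozenset(g.upper() for g in self.gene_symbols)


def classify_alleles(chrom: str, ref: str, alt: str) -> VariantClass:
    if normalize_chrom(chrom) in MT_CONTIGS:
        return VariantClass.MT
    if alt.startswith("<"):
        return VariantClass.STR if alt.startswith("<STR") else VariantClass.SV
    if "[" in alt or "]" in alt:  # breakend notation
        return VariantClass.SV
    if len(ref) == 1 and len(alt) == 1:
        return VariantClass.SNV
    return VariantClass.INDEL


@dataclass
class VariantRecord:
    """One normalized biallelic call (multi-allelic sites are split on ingest)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    filter_status: str = "PASS"
    per_sample: dict[str, SampleCall] = field(default_factory=dict)
    annotations: AnnotationSet = field(default_factory=AnnotationSet)
    variant_class: VariantClass = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.chrom = normalize_chrom(self.chrom)
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.variant_class is None:
            self.variant_class = classify_alleles(self.chrom, self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the reference allele."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))

    def call(self, sample_id: str) -> SampleCall:
        return self.per_sample[sample_id]

    def with_annotations(self, **updates) -> "VariantRecord":
        return replace(self, annotations=replace(self.annotations, **updates))


@dataclass
class Individual:
    id: str
    sex: Sex = Sex.UNKNOWN
    affected: Affection = Affection.UNKNOWN
    mother_id: Optional[str] = None
    father_id: Optional[str] = None


@dataclass
class Pedigree:
    """A family: individuals with parental links plus a designated index."""

    family_id: str
    individuals: list[Individual]
    index_id: str

    def __post_init__(self) -> None:
        ids = {ind.id for ind in self.individuals}
        if self.index_id not in ids:
            raise StructuralError(
                f"family {self.family_id}: index {self.index_id!r} not in pedigree"
            )
        for ind in self.individuals:
            for pid in (ind.mother_id, ind.father_id):
                if pid is not None and pid not in ids:
                    raise StructuralError(
                        f"family {self.family_id}: unknown parent id {pid!r}"
                    )
        self._check_no_ancestry_cycle()

    def _check_no_ancestry_cycle(self) -> None:
        by_id = {ind.id: ind for ind in self.individuals}
        for start in by_id:
            seen = set()
            stack = [start]
            while stack:
                cur = stack.pop()
                ind = by_id[cur]
                for pid in (ind.mother_id, ind.father_id):
                    if pid is None:
                        continue
                    if pid == start:
                        raise StructuralError(
                            f"family {self.family_id}: {start!r} is its own ancestor"
                        )
                    if pid not in seen:
                        seen.add(pid)
                        stack.append(pid)

    def __getitem__(self, ind_id: str) -> Individual:
        for ind in self.individuals:
            if ind.id == ind_id:
                return ind
        raise KeyError(ind_id)

    def __contains__(self, ind_id: str) -> bool:
        return any(ind.id == ind_id for ind in self.individuals)

    @property
    def index(self) -> Individual:
        return self[self.index_id]

    @property
    def member_ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def parents_of(self, ind_id: str) -> tuple[Optional[Individual], Optional[Individual]]:
        """(mother, father) of ``ind_id``; entries are None when absent."""
        ind = self[ind_id]
        mother = self[ind.mother_id] if ind.mother_id else None
        father = self[ind.father_id] if ind.father_id else None
        return mother, father

    def is_trio(self) -> bool:
        ind = self.index
        return ind.mother_id is not None and ind.father_id is not None


class GenomeMask:
    """Set of genomic intervals, 0-based half-open, with merged overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        raw: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            if start >= end:
                raise ValueError(f"interval start must be < end: {(chrom, start, end)}")
            raw.setdefault(normalize_chrom(chrom), []).append((start, end))
        self._merged: dict[str, tuple[list[int], list[int]]] = {}
        for chrom, ivals in raw.items():
            ivals.sort()
            merged: list[tuple[int, int]] = []
            for s, e in ivals:
                if merged and s <= merged[-1][1]:
                    merged[-1] = (merged[-1][0], max(merged[-1][1], e))
                else:
                    merged.append((s, e))
            self._merged[chrom] = ([s for s, _ in merged], [e for _, e in merged])

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True when [start, end) intersects any mask interval on ``chrom``."""
        entry = self._merged.get(normalize_chrom(chrom))
        if entry is None:
            return False
        starts, ends = entry
        i = bisect.bisect_right(starts, start)
        if i > 0 and ends[i - 1] > start:
            return True
        return i < len(starts) and starts[i] < end

    def covers_position(self, chrom: str, pos: int) -> bool:
        """True when the 1-based position ``pos`` falls in the mask."""
        return self.overlaps(chrom, pos - 1, pos)

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._merged.values())
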