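"""Cohort-level aggregation: diagnostic yield, inheritance distribution and
gene recurrence across case results.

Every emitted percentage travels with its numerator and denominator so
reports stay recomputable. Integer percentages round half away from zero.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from raredx.errors import RaredxError
from raredx.triage import round_half_away

DETERMINED_CATEGORIES = ("AR", "de_novo", "AD_inherited", "XL_inherited", "MT")
ASSUMED_CATEGORIES = ("assumed_AD", "assumed_AR", "assumed_XL")
INHERITANCE_CATEGORIES = DETERMINED_CATEGORIES + ASSUMED_CATEGORIES


@dataclass
class ReportedVariant:
    gene: str
    variant_key: str
    inheritance_category: str
    determined: bool
    causative: bool = True

    def __post_init__(self) -> None:
        if self.inheritance_category not in INHERITANCE_CATEGORIES:
            raise ValueError(
                f"unknown inheritance category {self.inheritance_category!r}"
            )
        self.gene = self.gene.upper()


@dataclass
class CaseResult:
    case_id: str
    panels_analyzed: list[str] = field(default_factory=list)
    analysis_type: str = "singleton"  # singleton | trio_family
    solved: bool = False
    reported_variants: list[ReportedVariant] = field(default_factory=list)

    def __post_init__(self) -> None:
        has_causative = any(v.causative for v in self.reported_variants)
        if self.solved != has_causative:
            raise ValueError(
                f"case {self.case_id}: solved flag inconsistent with reported variants"
            )


def pct(numerator: int, denominator: int) -> int:
    return round_half_away(100.0 * numerator / denominator)


@dataclass
class YieldRow:
    group: str
    n_cases: int
    n_solved: int
    pct_solved: int


def yield_summary(
    case_results: Iterable[CaseResult], group_by: Optional[str] = None
) -> list[YieldRow]:
    """Per-group case and solved counts with integer percent solved.

    ``group_by`` is ``None`` (one 'all' row), ``"panel"`` (a case with
    multiple panels counts once per panel group) or ``"analysis_type"``.
    The 'all' row also appears first when grouping.
    """
    cases = list(case_results)
    if not cases:
        raise RaredxError("yield_summary requires at least one case")
    rows = [
        YieldRow(
            "all",
            len(cases),
            sum(c.solved for c in cases),
            pct(sum(c.solved for c in cases), len(cases)),
        )
    ]
    if group_by is None:
        return rows
    groups: dict[str, list[CaseResult]] = {}
    if group_by == "panel":
        for case in cases:
            for panel in case.panels_analyzed:
                groups.setdefault(panel, []).append(case)
    elif group_by == "analysis_type":
        for case in cases:
            groups.setdefault(case.analysis_type, []).append(case)
    else:
        raise RaredxError(f"unknown group_by {group_by!r}")
    for name in sorted(groups):
        members = groups[name]
        n_solved = sum(c.solved for c in members)
        rows.append(YieldRow(name, len(members), n_solved, pct(n_solved, len(members))))
    return rows


def panels_per_case(case_results: Iterable[CaseResult]) -> float:
    """Panel analyses divided by cases, to two decimals."""
    cases = list(case_results)
    if not cases:
        raise RaredxError("panels_per_case requires at least one case")
    return round(sum(len(c.panels_analyzed) for c in cases) / len(cases), 2)


@dataclass
class InheritanceDistribution:
    n_findings: int
    n_determined: int
    pct_determined: int
    determined_counts: dict[str, int]
    determined_pct: dict[str, int]  # over the determined-only denominator
    assumed_counts: dict[str, int]
    combined_counts: dict[str, int]


def inheritance_distribution(
    case_results: Iterable[CaseResult],
) -> InheritanceDistribution:
    """Count reported causative variants per inheritance category.

    Determined-category percentages use the determined-only denominator;
    combined counts cover all findings.
    """
    variants = [
        v for c in case_results for v in c.reported_variants if v.causative
    ]
    if not variants:
        raise RaredxError("no reported variants")
    determined = [v for v in variants if v.determined]
    assumed = [v for v in variants if not v.determined]
    det_counts = Counter(v.inheritance_category for v in determined)
    asm_counts = Counter(v.inheritance_category for v in assumed)
    n_det = len(determined)
    return InheritanceDistribution(
        n_findings=len(variants),
        n_determined=n_det,
        pct_determined=pct(n_det, len(variants)),
        determined_counts={c: det_counts.get(c, 0) for c in DETERMINED_CATEGORIES},
        determined_pct={
            c: pct(det_counts.get(c, 0), n_det) if n_det else 0
            for c in DETERMINED_CATEGORIES
        },
        assumed_counts={c: asm_counts.get(c, 0) for c in ASSUMED_CATEGORIES},
        combined_counts=dict(Counter(v.inheritance_category for v in variants)),
    )


@dataclass
class GeneRecurrence:
    table: list[tuple[str, int]]  # gene -> n_cases, descending, ties alphabetical
    n_genes: int
    n_single_case: int
    pct_single_case: int


def gene_recurrence(case_results: Iterable[CaseResult]) -> GeneRecurrence:
    """Cases per reported gene plus the single-case gene fraction."""
    per_gene: dict[str, set[str]] = {}
    for case in case_results:
        for variant in case.reported_variants:
            if variant.causative:
                per_gene.setdefault(variant.gene, set()).add(case.case_id)
    table = sorted(
        ((gene, len(cases)) for gene, cases in per_gene.items()),
        key=lambda gc: (-gc[1], gc[0]),
    )
    n_genes = len(table)
    n_single = sum(1 for _, n in table if n == 1)
    return GeneRecurrence(
        table=table,
        n_genes=n_genes,
        n_single_case=n_single,
        pct_single_case=pct(n_single, n_genes) if n_genes else 0,
    )


@dataclass
class CohortOverview:
    n_cases: int
    n_relatives: int
    n_individuals: int
    n_solved: int
    pct_solved: int


def cohort_overview(
    case_results: Iterable[CaseResult], n_relatives: int = 0
) -> CohortOverview:
    """Headline cohort numbers; individuals = index cases + sequenced relatives."""
    cases = list(case_results)
    if not cases:
        raise RaredxError("cohort_overview requires at least one case")
    n_solved = sum(c.solved for c in cases)
    return CohortOverview(
        n_cases=len(cases),
        n_relatives=n_relatives,
        n_individuals=len(cases) + n_relatives,
        n_solved=n_solved,
        pct_solved=pct(n_solved, len(cases)),
    )
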