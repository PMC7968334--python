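"""Secondary-verification triage: decide when orthogonal confirmation can be skipped.

A reported variant may skip confirmation only when ALL six criteria hold:

* single base pair substitution (all other variant classes always confirm);
* sequence depth >= 20 at the position (missing depth fails);
* genotype quality equal to the caller maximum, 99 (missing fails);
* caller filter status ``PASS``;
* reference span not overlapping the segmental-duplication mask;
* good quality on manual visual inspection (unset status fails → review).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

from raredx.core_io.models import GenomeMask, VariantClass, VariantRecord
from raredx.errors import PairingError, RaredxError

DEPTH_THRESHOLD = 20  # inclusive
GQ_MAX = 99

CRITERIA = ("is_snv", "depth_ok", "gq_max", "filter_pass", "outside_segdup", "inspection_good")


@dataclass
class TriageDecision:
    variant_key: tuple
    criteria: dict[str, bool]

    @property
    def skip_verification(self) -> bool:
        return all(self.criteria.values())

    @property
    def reasons(self) -> list[str]:
        return [name for name in CRITERIA if not self.criteria[name]]


def triage_variant(
    record: VariantRecord,
    sample_id: str,
    mask: Optional[GenomeMask] = None,
    gq_max: int = GQ_MAX,
    depth_threshold: int = DEPTH_THRESHOLD,
) -> TriageDecision:
    """Evaluate the six confirmation-waiver criteria for one reported variant."""
    if sample_id not in record.per_sample:
        raise PairingError(f"sample {sample_id!r} not in record {record.key_str}")
    call = record.per_sample[sample_id]
    start, end = record.ref_span
    criteria = {
        "is_snv": record.variant_class == VariantClass.SNV,
        "depth_ok": call.depth is not None and call.depth >= depth_threshold,
        "gq_max": call.genotype_quality is not None and call.genotype_quality == gq_max,
        "filter_pass": record.filter_status == "PASS",
        "outside_segdup": mask is None or not mask.overlaps(record.chrom, start, end),
        "inspection_good": record.annotations.inspection_status.value == "good",
    }
    return TriageDecision(variant_key=record.key, criteria=criteria)


@dataclass
class TriageSummary:
    n_total: int
    n_skip: int
    n_confirm: int
    pct_skip: int
    per_criterion_failures: dict[str, int]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def triage_summary(decisions: Iterable[TriageDecision]) -> TriageSummary:
    decisions = list(decisions)
    if not decisions:
        raise RaredxError("triage_summary requires at least one decision")
    n_skip = sum(1 for d in decisions if d.skip_verification)
    failures: Counter[str] = Counter()
    for d in decisions:
        if not d.skip_verification:
            failures.update(d.reasons)
    n_total = len(decisions)
    return TriageSummary(
        n_total=n_total,
        n_skip=n_skip,
        n_confirm=n_total - n_skip,
        pct_skip=round_half_away(100.0 * n_skip / n_total),
        per_criterion_failures={c: failures.get(c, 0) for c in CRITERIA},
    )
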