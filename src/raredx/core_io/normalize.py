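"""Allele normalization: shared suffix then shared prefix trimming.

This is parsimony-style trimming without a reference genome; reference-guided
left-alignment is a documented limitation. Symbolic (``<...>``) and breakend
alleles pass through unchanged.
"""

from __future__ import annotations

from dataclasses import replace

from raredx.core_io.models import VariantRecord


def trim_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix, keeping >= 1 base of each allele.

    Prefix trimming advances ``pos`` by the number of bases removed.
    """
    # suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize_variant(record: VariantRecord) -> VariantRecord:
    """Return the record with trimmed alleles; idempotent; no-op for symbolic alts."""
    if record.alt.startswith("<") or "[" in record.alt or "]" in record.alt:
        return record
    pos, ref, alt = trim_alleles(record.pos, record.ref, record.alt)
    if (pos, ref, alt) == (record.pos, record.ref, record.alt):
        return record
    return replace(record, pos=pos, ref=ref, alt=alt, variant_class=None)
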