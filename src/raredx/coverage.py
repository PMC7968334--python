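"""Transcript coverage completeness from interval depth tracks.

Depth tracks are BED4-style (chrom, start, end, depth), 0-based half-open,
non-overlapping per chromosome. Bases absent from the track count as depth 0.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from raredx.core_io.models import normalize_chrom
from raredx.errors import RaredxError

DEFAULT_CUTOFFS = (10, 20, 30)
DEFAULT_REPORT_CUTOFF = 10


class DepthTrack:
    """Sorted, non-overlapping depth intervals with overlap queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int, int]]):
        per_chrom: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, start, end, depth in intervals:
            if depth < 0:
                raise ValueError("depth must be >= 0")
            if start >= end:
                raise ValueError(f"empty interval ({chrom}, {start}, {end})")
            per_chrom.setdefault(normalize_chrom(chrom), []).append((start, end, depth))
        self._track: dict[str, list[tuple[int, int, int]]] = {}
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            for (s1, e1, _), (s2, _, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping depth intervals on {chrom}")
            self._track[chrom] = ivals

    def segments(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """(length, depth) pieces tiling [start, end); gaps appear as depth 0."""
        ivals = self._track.get(normalize_chrom(chrom), [])
        out: list[tuple[int, int]] = []
        cursor = start
        idx = bisect.bisect_right([s for s, _, _ in ivals], start) - 1
        idx = max(idx, 0)
        for s, e, depth in ivals[idx:]:
            if e <= cursor:
                continue
            if s >= end:
                break
            lo, hi = max(s, cursor), min(e, end)
            if lo > cursor:
                out.append((lo - cursor, 0))
            out.append((hi - lo, depth))
            cursor = hi
        if cursor < end:
            out.append((end - cursor, 0))
        return out


@dataclass
class TranscriptModel:
    transcript_id: str
    gene: str
    exons: list[tuple[str, int, int]]  # 0-based half-open

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.exons:
            by_chrom.setdefault(normalize_chrom(chrom), []).append((start, end))
        for chrom, ivals in by_chrom.items():
            ivals.sort()
            for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 < e1:
                    raise ValueError(
                        f"{self.transcript_id}: overlapping exons on {chrom}"
                    )

    @property
    def length(self) -> int:
        return sum(end - start for _, start, end in self.exons)


@dataclass
class CompletenessResult:
    transcript_id: str
    gene: str
    length: int
    mean_coverage: float
    completeness: dict[int, float]  # cutoff -> fraction of bases >= cutoff

    def fully_covered(self, cutoff: int) -> bool:
        return self.completeness[cutoff] == 1.0


def completeness(
    track: DepthTrack,
    transcript: TranscriptModel,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> CompletenessResult:
    """Mean coverage and per-cutoff completeness over a transcript's exons."""
    length = transcript.length
    if length == 0:
        raise RaredxError(f"{transcript.transcript_id}: zero-length transcript")
    depth_sum = 0
    above: dict[int, int] = {c: 0 for c in cutoffs}
    for chrom, start, end in transcript.exons:
        for seg_len, depth in track.segments(chrom, start, end):
            depth_sum += seg_len * depth
            for c in cutoffs:
                if depth >= c:
                    above[c] += seg_len
    return CompletenessResult(
        transcript_id=transcript.transcript_id,
        gene=transcript.gene,
        length=length,
        mean_coverage=depth_sum / length,
        completeness={c: above[c] / length for c in cutoffs},
    )


@dataclass
class PanelCoverageReport:
    cutoff: int
    rows: list[CompletenessResult]
    n_transcripts: int = 0
    n_fully_covered: int = 0
    panel_mean_coverage: float = 0.0
    per_gene_mean: dict[str, float] = field(default_factory=dict)


def panel_coverage_report(
    track: DepthTrack,
    transcripts: Iterable[TranscriptModel],
    panel: Optional[frozenset[str]] = None,
    cutoff: int = DEFAULT_REPORT_CUTOFF,
    cutoffs: Sequence[int] = DEFAULT_CUTOFFS,
) -> PanelCoverageReport:
    """Per-transcript completeness for a panel plus fully-covered counts.

    ``panel`` is a set of gene symbols; ``None`` keeps every transcript. The
    panel-wide mean is length-weighted across the selected transcripts.
    """
    selected = [
        t
        for t in transcripts
        if panel is None or t.gene.upper() in panel
    ]
    if not selected:
        raise RaredxError("no transcripts selected for the coverage report")
    if cutoff not in cutoffs:
        cutoffs = tuple(cutoffs) + (cutoff,)
    rows = [completeness(track, t, cutoffs) for t in selected]
    total_len = sum(r.length for r in rows)
    panel_mean = sum(r.mean_coverage * r.length for r in rows) / total_len
    per_gene: dict[str, list[CompletenessResult]] = {}
    for r in rows:
        per_gene.setdefault(r.gene.upper(), []).append(r)
    per_gene_mean = {
        g: sum(r.mean_coverage * r.length for r in rs) / sum(r.length for r in rs)
        for g, rs in per_gene.items()
    }
    return PanelCoverageReport(
        cutoff=cutoff,
        rows=rows,
        n_transcripts=len(rows),
        n_fully_covered=sum(1 for r in rows if r.fully_covered(cutoff)),
        panel_mean_coverage=panel_mean,
        per_gene_mean=per_gene_mean,
    )


def read_exon_tsv(path: str) -> list[TranscriptModel]:
    """Exon TSV: transcript_id gene chrom start end (0-based half-open)."""
    from raredx.core_io.ped import _open_text

    grouped: dict[str, tuple[str, list[tuple[str, int, int]]]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "transcript_id\t")):
                continue
            tid, gene, chrom, start, end = line.split("\t")[:5]
            grouped.setdefault(tid, (gene, []))[1].append((chrom, int(start), int(end)))
    return [
        TranscriptModel(transcript_id=tid, gene=gene, exons=exons)
        for tid, (gene, exons) in grouped.items()
    ]
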