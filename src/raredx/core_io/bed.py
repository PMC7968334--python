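"""BED readers: interval masks (BED3+) and depth tracks (BED4)."""

from __future__ import annotations

from raredx.core_io.models import GenomeMask, normalize_chrom
from raredx.core_io.ped import _open_text
from raredx.errors import FormatError


def _bed_rows(path: str, min_cols: int):
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < min_cols:
                raise FormatError(
                    f"{path} line {line_no}: expected >= {min_cols} BED columns"
                )
            yield line_no, fields


def read_bed_mask(path: str) -> GenomeMask:
    """Read a BED3+ file into a :class:`GenomeMask` (0-based half-open)."""
    intervals = []
    for line_no, fields in _bed_rows(path, 3):
        try:
            intervals.append((fields[0], int(fields[1]), int(fields[2])))
        except ValueError as exc:
            raise FormatError(f"{path} line {line_no}: {exc}") from exc
    return GenomeMask(intervals)


def read_depth_bed(path: str) -> list[tuple[str, int, int, int]]:
    """Read a BED4 depth track: (chrom, start, end, depth) rows."""
    rows = []
    for line_no, fields in _bed_rows(path, 4):
        try:
            rows.append(
                (normalize_chrom(fields[0]), int(fields[1]), int(fields[2]), int(fields[3]))
            )
        except ValueError as exc:
            raise FormatError(f"{path} line {line_no}: {exc}") from exc
    return rows


def write_bed(intervals, path: str) -> None:
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
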