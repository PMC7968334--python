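"""In-silico gene panels: loading, HPO-driven construction, merging, filtering."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from raredx.core_io.models import VariantRecord
from raredx.core_io.ped import _open_text
from raredx.errors import FormatError

logger = logging.getLogger(__name__)


@dataclass
class GenePanel:
    name: str
    genes: frozenset[str]
    version: str = "0"
    source: str = "precompiled"  # precompiled | hpo_generated | merged
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("panel name must be non-empty")
        self.genes = frozenset(g.upper() for g in self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in self.genes


def load_panel(path: str, name: Optional[str] = None, version: str = "0") -> GenePanel:
    """Load a panel TSV (columns: gene_symbol[, inheritance, comment]).

    A header row starting with ``gene_symbol`` is skipped; duplicate symbols
    are deduplicated and logged.
    """
    genes: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            symbol = line.split("\t")[0].strip()
            if symbol.lower() == "gene_symbol":
                continue
            if symbol:
                genes.append(symbol.upper())
    if not genes:
        raise FormatError(f"{path}: empty gene panel")
    dupes = [g for g, n in Counter(genes).items() if n > 1]
    if dupes:
        logger.warning("%s: %d duplicate gene row(s): %s", path, len(dupes), dupes[:5])
    panel_name = name or str(path)
    return GenePanel(name=panel_name, genes=frozenset(genes), version=version)


def read_hpo_gene_map(path: str) -> dict[str, frozenset[str]]:
    """Read a term->gene TSV (``term_id<TAB>gene_symbol``) into a map."""
    mapping: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path} line {line_no}: expected term_id<TAB>gene")
            if fields[0].lower() in ("term_id", "hpo_id"):
                continue
            mapping.setdefault(fields[0], set()).add(fields[1].upper())
    return {term: frozenset(genes) for term, genes in mapping.items()}


def build_hpo_panel(
    hpo_terms: Iterable[str],
    hpo_gene_map: dict[str, frozenset[str]],
    min_terms: int = 1,
    name: str = "hpo_panel",
) -> GenePanel:
    """Panel of genes linked to >= ``min_terms`` of the given HPO terms.

    ``min_terms=1`` is the pure union. Terms absent from the map warn and
    contribute nothing. No ontology-descendant closure is applied.
    """
    terms = list(hpo_terms)
    if not terms:
        logger.warning("empty HPO term list; returning empty panel")
        return GenePanel(name=name, genes=frozenset(), source="hpo_generated")
    counts: Counter[str] = Counter()
    for term in terms:
        genes = hpo_gene_map.get(term)
        if genes is None:
            logger.warning("HPO term %s absent from the gene map", term)
            continue
        counts.update(genes)
    genes = frozenset(g for g, n in counts.items() if n >= min_terms)
    return GenePanel(name=name, genes=genes, source="hpo_generated")


def merge_panels(panels: Iterable[GenePanel], name: str = "merged") -> GenePanel:
    """Union of panels with per-gene provenance (which panels contributed it)."""
    panels = list(panels)
    genes: set[str] = set()
    provenance: dict[str, set[str]] = {}
    for panel in panels:
        genes |= panel.genes
        for g in panel.genes:
            provenance.setdefault(g, set()).add(panel.name)
    return GenePanel(
        name=name,
        genes=frozenset(genes),
        source="merged",
        provenance={g: frozenset(p) for g, p in provenance.items()},
    )


def filter_to_panel(
    records: Iterable[VariantRecord], panel: GenePanel
) -> tuple[list[VariantRecord], int]:
    """Keep records annotated with >= 1 panel gene; returns (kept, n_dropped)."""
    kept: list[VariantRecord] = []
    dropped = 0
    for record in records:
        if record.annotations.gene_symbols & panel.genes:
            kept.append(record)
        else:
            dropped += 1
    logger.info("panel %s: kept %d, dropped %d", panel.name, len(kept), dropped)
    return kept, dropped
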