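"""End-to-end annotate-and-rank flow plus reanalysis diffing.

Stage order: normalize → local-observation annotation → panel filter →
inheritance deduction → rank scoring → ordering. Record counts are logged
after every stage, and each run emits a manifest sufficient to reproduce it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata
from typing import Optional

from raredx.core_io.models import Pedigree, VariantRecord
from raredx.core_io.normalize import normalize_variant
from raredx.errors import RaredxError
from raredx.inheritance import DeduceOptions, ModelAssignment, deduce_models
from raredx.obsdb import ObsStore, annotate_local_obs
from raredx.panels import GenePanel, filter_to_panel
from raredx.ranking import RankModelConfig, RankScore, rank_case, score_variant

logger = logging.getLogger(__name__)


@dataclass
class RankedVariant:
    rank: int
    record: VariantRecord
    score: RankScore
    assignment: ModelAssignment


@dataclass
class RunResult:
    ranked: list[RankedVariant]
    stage_counts: dict[str, int]
    manifest: dict


def _tool_version() -> str:
    try:
        return metadata.version("raredx")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


@dataclass
class RunManifest:
    inputs: dict = field(default_factory=dict)
    panel: Optional[str] = None
    panel_version: Optional[str] = None
    rank_config: Optional[str] = None
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "tool": "raredx",
            "tool_version": _tool_version(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "inputs": self.inputs,
            "panel": self.panel,
            "panel_version": self.panel_version,
            "rank_config": self.rank_config,
            "options": self.options,
        }


def annotate_and_rank(
    records: list[VariantRecord],
    pedigree: Pedigree,
    panel: GenePanel,
    rank_config: RankModelConfig,
    obs_store: Optional[ObsStore] = None,
    deduce_options: Optional[DeduceOptions] = None,
    cutoff: Optional[int] = None,
    manifest: Optional[RunManifest] = None,
) -> RunResult:
    """Run the full interpretation flow over one case's records."""
    if len(panel) == 0:
        raise RaredxError(f"panel {panel.name!r} is empty; refusing to filter")
    counts = {"input": len(records)}

    records = [normalize_variant(r) for r in records]
    counts["normalized"] = len(records)

    if obs_store is not None and obs_store.loaded_cases > 0:
        records = [annotate_local_obs(r, obs_store) for r in records]
    counts["obs_annotated"] = len(records)

    records, dropped = filter_to_panel(records, panel)
    counts["in_panel"] = len(records)
    counts["panel_dropped"] = dropped

    assignments = {r.key: deduce_models(r, pedigree, deduce_options) for r in records}
    scored = [(r, score_variant(r, assignments[r.key], rank_config)) for r in records]
    ranked = [
        RankedVariant(rank=i, record=r, score=s, assignment=assignments[r.key])
        for i, r, s in rank_case(scored, cutoff=cutoff)
    ]
    counts["ranked"] = len(ranked)
    for stage, n in counts.items():
        logger.info("stage %-14s %d records", stage, n)

    mf = manifest or RunManifest()
    mf.panel = panel.name
    mf.panel_version = panel.version
    mf.rank_config = rank_config.name
    return RunResult(ranked=ranked, stage_counts=counts, manifest=mf.to_dict())


@dataclass
class ReanalysisDiff:
    newly_in_panel: list[str]  # variant keys present only in the new run
    no_longer_in_panel: list[str]
    newly_top_ranked: list[str]  # entered the top-N in the new run
    dropped_from_top: list[str]


def diff_runs(old: RunResult, new: RunResult, top_n: int = 10) -> ReanalysisDiff:
    """Compare two runs of the same case (e.g. after panel/model updates)."""
    old_keys = {rv.record.key_str for rv in old.ranked}
    new_keys = {rv.record.key_str for rv in new.ranked}
    old_top = {rv.record.key_str for rv in old.ranked if rv.rank <= top_n}
    new_top = {rv.record.key_str for rv in new.ranked if rv.rank <= top_n}
    return ReanalysisDiff(
        newly_in_panel=sorted(new_keys - old_keys),
        no_longer_in_panel=sorted(old_keys - new_keys),
        newly_top_ranked=sorted(new_top - old_top),
        dropped_from_top=sorted(old_top - new_top),
    )


def write_manifest(manifest: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
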