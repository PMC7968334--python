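"""Local observation database: per-variant counts of observing families.

One individual per family — the index — contributes to the counts, so the
store measures families, not samples. Counts expose cohort-specific rarity
and let systematic artifacts (variants seen in a large fraction of all
loaded families) be flagged and down-prioritized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable

from raredx.core_io.models import Pedigree, VariantRecord
from raredx.core_io.normalize import normalize_variant
from raredx.core_io.ped import _open_text
from raredx.errors import EmptyStoreError, FormatError

logger = logging.getLogger(__name__)

DEFAULT_ARTIFACT_THRESHOLD = 0.05


@dataclass
class ObsEntry:
    obs_count: int = 0  # families in which the index carries the variant
    hom_count: int = 0  # families in which the index is hom-alt / hemizygous-alt


@dataclass
class ObsStore:
    entries: dict[str, ObsEntry] = field(default_factory=dict)
    case_registry: set[str] = field(default_factory=set)

    @property
    def loaded_cases(self) -> int:
        return len(self.case_registry)

    def load_case(
        self, records: Iterable[VariantRecord], pedigree: Pedigree
    ) -> "ObsStore":
        """Count the index individual's carried variants; idempotent per family."""
        if pedigree.family_id in self.case_registry:
            logger.warning(
                "family %s already loaded; ignoring duplicate load", pedigree.family_id
            )
            return self
        index_id = pedigree.index_id
        seen: set[str] = set()
        for record in records:
            record = normalize_variant(record)
            call = record.per_sample.get(index_id)
            if call is None or not call.carries_alt:
                continue
            key = record.key_str
            if key in seen:  # a family counts at most once per variant
                continue
            seen.add(key)
            entry = self.entries.setdefault(key, ObsEntry())
            entry.obs_count += 1
            if call.is_hom_alt:
                entry.hom_count += 1
        self.case_registry.add(pedigree.family_id)
        return self

    def lookup(self, record: VariantRecord) -> ObsEntry:
        return self.entries.get(normalize_variant(record).key_str, ObsEntry())


def load_case(records, pedigree: Pedigree, store: ObsStore) -> ObsStore:
    return store.load_case(records, pedigree)


def annotate_local_obs(
    record: VariantRecord,
    store: ObsStore,
    artifact_threshold: float = DEFAULT_ARTIFACT_THRESHOLD,
) -> VariantRecord:
    """Attach local_obs / local_frequency / artifact-flag annotations."""
    if store.loaded_cases == 0:
        raise EmptyStoreError("observation store has no loaded cases")
    entry = store.lookup(record)
    freq = entry.obs_count / store.loaded_cases
    return replace(
        record,
        annotations=replace(
            record.annotations,
            local_obs=entry.obs_count,
            local_frequency=freq,
            local_artifact=freq >= artifact_threshold,
        ),
    )


def dump_store(store: ObsStore, path: str) -> None:
    """Persist to a flat TSV: header carries the case registry, one line per key."""
    with open(path, "w") as fh:
        fh.write(f"##loaded_cases={store.loaded_cases}\n")
        fh.write("##case_ids=" + ",".join(sorted(store.case_registry)) + "\n")
        fh.write("key\tobs_count\thom_count\n")
        for key in sorted(store.entries):
            entry = store.entries[key]
            fh.write(f"{key}\t{entry.obs_count}\t{entry.hom_count}\n")


def read_store(path: str) -> ObsStore:
    store = ObsStore()
    declared_cases = None
    with _open_text(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##loaded_cases="):
                declared_cases = int(line.split("=", 1)[1])
                continue
            if line.startswith("##case_ids="):
                ids = line.split("=", 1)[1]
                store.case_registry = set(ids.split(",")) if ids else set()
                continue
            if not line or line.startswith("key\t"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise FormatError(f"{path} line {line_no}: expected 3 columns")
            store.entries[fields[0]] = ObsEntry(int(fields[1]), int(fields[2]))
    if declared_cases is not None and declared_cases != store.loaded_cases:
        raise FormatError(
            f"{path}: declared loaded_cases={declared_cases} but "
            f"{store.loaded_cases} case ids listed"
        )
    return store
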