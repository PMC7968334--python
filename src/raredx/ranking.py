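"""Weighted-sum rank model: config parsing, validation, scoring and ordering.

Config format (INI-like)::

    [category.frequency]
    default = 2
    rule.1 = population_af missing => 2
    rule.2 = population_af in [0.0, 0.0001) => 2
    rule.3 = population_af in [0.0001, 0.005) => 1
    rule.4 = population_af in [0.005, inf) => -6

    [category.consequence]
    default = 0
    rule.1 = consequence is {stop_gained, frameshift_variant} => 5

Per category, the first matching rule (in declared order) supplies the
points; with no match the category default applies. The total score is the
plain integer sum over categories. Rule predicates are numeric half-open
intervals ``[lo, hi)``, value-set membership ``is {a, b}``, or ``missing``.
The frequency category is validated for monotonicity: points must not
increase as the interval lower bound increases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Union

from raredx.core_io.models import VariantRecord
from raredx.errors import ConfigError
from raredx.inheritance import ModelAssignment

# annotation schema: field_key -> extractor over (record, assignment)
_FIELD_EXTRACTORS = {
    "population_af": lambda r, a: r.annotations.population_af,
    "consequence": lambda r, a: r.annotations.consequence,
    "conservation_score": lambda r, a: r.annotations.conservation_score,
    "deleteriousness_score": lambda r, a: r.annotations.deleteriousness_score,
    "clinical_significance": lambda r, a: r.annotations.clinical_significance,
    "local_obs": lambda r, a: r.annotations.local_obs,
    "local_frequency": lambda r, a: r.annotations.local_frequency,
    "inspection_status": lambda r, a: r.annotations.inspection_status.value,
    "models": lambda r, a: set(a.tokens) if a is not None else set(),
    "filter_status": lambda r, a: r.filter_status,
    "variant_class": lambda r, a: r.variant_class.value,
}

FIELD_KEYS = frozenset(_FIELD_EXTRACTORS)


@dataclass(frozen=True)
class Rule:
    field_key: str
    kind: str  # "interval" | "set" | "missing"
    lo: float = 0.0
    hi: float = 0.0
    values: frozenset[str] = frozenset()
    points: int = 0

    def matches(self, value) -> bool:
        if self.kind == "missing":
            return value is None or value == set()
        if value is None:
            return False
        if self.kind == "interval":
            try:
                return self.lo <= float(value) < self.hi
            except (TypeError, ValueError):
                return False
        if isinstance(value, set):
            return bool(value & self.values)
        return str(value) in self.values


@dataclass
class Category:
    name: str
    default_points: int = 0
    rules: list[Rule] = field(default_factory=list)

    def score(self, record: VariantRecord, assignment: Optional[ModelAssignment]) -> int:
        for rule in self.rules:
            value = _FIELD_EXTRACTORS[rule.field_key](record, assignment)
            if rule.matches(value):
                return rule.points
        return self.default_points


@dataclass
class RankModelConfig:
    categories: list[Category]
    name: str = "rank_model"

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise ConfigError(f"duplicate category name(s): {sorted(dup)}")
        self._validate_frequency_monotonic()

    def _validate_frequency_monotonic(self) -> None:
        for cat in self.categories:
            if cat.name != "frequency":
                continue
            interval_rules = [r for r in cat.rules if r.kind == "interval"]
            ordered = sorted(interval_rules, key=lambda r: r.lo)
            for prev, cur in zip(ordered, ordered[1:]):
                if cur.points > prev.points:
                    raise ConfigError(
                        "frequency category not monotone: points increase from "
                        f"[{prev.lo},{prev.hi}) -> [{cur.lo},{cur.hi})"
                    )

    @property
    def category_names(self) -> list[str]:
        return [c.name for c in self.categories]


@dataclass
class RankScore:
    per_category: dict[str, int]
    config_name: str = "rank_model"

    @property
    def total(self) -> int:
        return sum(self.per_category.values())

    @property
    def rank_result_token(self) -> str:
        return ":".join(str(v) for v in self.per_category.values())


_RULE_RE = re.compile(
    r"""^(?P<field>\w+)\s+
        (?:
            (?P<missing>missing)
          | in\s+\[\s*(?P<lo>[^,\]]+)\s*,\s*(?P<hi>[^)\]]+)\s*\)
          | is\s+\{(?P<values>[^}]*)\}
        )
        \s*=>\s*(?P<points>-?\d+)$""",
    re.VERBOSE,
)


def _parse_rule(text: str, location: str) -> Rule:
    m = _RULE_RE.match(text.strip())
    if not m:
        raise ConfigError(f"{location}: cannot parse rule {text!r}")
    field_key = m.group("field")
    if field_key not in FIELD_KEYS:
        raise ConfigError(
            f"{location}: unknown field_key {field_key!r}; known: {sorted(FIELD_KEYS)}"
        )
    points = int(m.group("points"))
    if m.group("missing"):
        return Rule(field_key, "missing", points=points)
    if m.group("values") is not None:
        values = frozenset(v.strip() for v in m.group("values").split(",") if v.strip())
        return Rule(field_key, "set", values=values, points=points)
    try:
        lo, hi = float(m.group("lo")), float(m.group("hi"))
    except ValueError as exc:
        raise ConfigError(f"{location}: bad interval bounds in {text!r}") from exc
    if not lo < hi:
        raise ConfigError(f"{location}: empty interval [{lo}, {hi})")
    return Rule(field_key, "interval", lo=lo, hi=hi, points=points)


def parse_rank_model(text: str, name: str = "rank_model") -> RankModelConfig:
    categories: list[Category] = []
    current: Optional[Category] = None
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        loc = f"{name} line {line_no}"
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip()
            if not section.startswith("category."):
                raise ConfigError(f"{loc}: expected [category.<name>] section")
            current = Category(name=section[len("category."):])
            categories.append(current)
            continue
        if current is None:
            raise ConfigError(f"{loc}: directive outside any [category.*] section")
        if "=" not in line:
            raise ConfigError(f"{loc}: expected 'key = value'")
        key, _, value = line.partition("=")
        key = key.strip()
        if key == "default":
            current.default_points = int(value.strip())
        elif key.startswith("rule."):
            current.rules.append(_parse_rule(value, loc))
        else:
            raise ConfigError(f"{loc}: unknown key {key!r}")
    if not categories:
        raise ConfigError(f"{name}: no categories defined")
    return RankModelConfig(categories=categories, name=name)


def load_rank_model(path: str) -> RankModelConfig:
    with open(path) as fh:
        return parse_rank_model(fh.read(), name=str(path))


def default_rank_model() -> RankModelConfig:
    """The shipped default SNV/INDEL rank model (implementer-chosen weights)."""
    text = resources.files("raredx.data").joinpath("rank_model_default.ini").read_text()
    return parse_rank_model(text, name="default")


def score_variant(
    record: VariantRecord,
    model_assignment: Optional[ModelAssignment],
    config: RankModelConfig,
) -> RankScore:
    """Score one variant: per-category first-match points, summed into a total."""
    per_category = {
        cat.name: cat.score(record, model_assignment) for cat in config.categories
    }
    return RankScore(per_category=per_category, config_name=config.name)


_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25}


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    return (_CHROM_ORDER.get(chrom, 99), chrom)


def rank_case(
    scored: list[tuple[VariantRecord, RankScore]],
    cutoff: Optional[int] = None,
) -> list[tuple[int, VariantRecord, RankScore]]:
    """Order scored records by descending total, ties by genomic coordinate.

    Returns (rank_position, record, score) triples, rank starting at 1.
    Equal totals share ordering by (chrom, pos, ref, alt) so output is a
    deterministic function of the input set. ``cutoff`` keeps the top N.
    """
    configs = {s.config_name for _, s in scored}
    if len(configs) > 1:
        raise ConfigError(f"records scored with mixed configs: {sorted(configs)}")
    ordered = sorted(
        scored,
        key=lambda rs: (-rs[1].total, chrom_sort_key(rs[0].chrom), rs[0].pos, rs[0].ref, rs[0].alt),
    )
    out = [(i + 1, rec, score) for i, (rec, score) in enumerate(ordered)]
    return out[:cutoff] if cutoff is not None else out
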