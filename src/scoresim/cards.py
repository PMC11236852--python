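"""Declarative scorecard model: categories, indicators, cards.

A scorecard is a named set of indicators, each offering an ordered list of
categorical scores (which may be negative). The best possible selection on
every indicator sums exactly to the card's nominal maximum (100 or 500);
the sum of the worst negative scores is the card's potential point loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "GROUPS",
    "ScoreCategory",
    "Indicator",
    "Scorecard",
    "SchemaError",
    "CardValidationError",
    "load_scorecard",
    "group_weights",
    "eclipsing_report",
]

#: The three general indicator categories every indicator belongs to.
GROUPS = ("vegetation", "hydrology", "site_management")

#: Tolerance for floating-point identities on point sums.
_TOL = 1e-9


class SchemaError(ValueError):
    """A configuration document does not match the scorecard schema."""


class CardValidationError(ValueError):
    """A structurally well-formed card violates a scorecard invariant."""


@dataclass(frozen=True)
class ScoreCategory:
    """One selectable categorical score of an indicator."""

    label: str
    description: str = ""
    points: float = 0.0
    provenance: str | None = None

    def to_dict(self) -> dict:
        d = {"label": self.label, "description": self.description,
             "points": self.points}
        if self.provenance is not None:
            d["provenance"] = self.provenance
        return d


@dataclass(frozen=True)
class Indicator:
    """A proxy indicator with its ordered category list."""

    id: str
    name: str
    group: str
    categories: tuple[ScoreCategory, ...]
    method: str = ""
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise SchemaError(
                f"indicator {self.id!r}: group must be one of {GROUPS}, "
                f"got {self.group!r}")
        if len(self.categories) < 2:
            raise CardValidationError(
                f"indicator {self.id!r} needs at least 2 categories")
        labels = [c.label for c in self.categories]
        if len(set(labels)) != len(labels):
            raise CardValidationError(
                f"indicator {self.id!r} has duplicate category labels")

    @property
    def max_points(self) -> float:
        return max(c.points for c in self.categories)

    @property
    def min_points(self) -> float:
        return min(c.points for c in self.categories)

    @property
    def span(self) -> float:
        """Combined positive + negative reach: max_points - min_points."""
        return self.max_points - self.min_points

    def category(self, label: str) -> ScoreCategory:
        for c in self.categories:
            if c.label == label:
                return c
        raise KeyError(
            f"indicator {self.id!r} has no category labelled {label!r}")

    def to_dict(self) -> dict:
        d = {"id": self.id, "name": self.name, "group": self.group,
             "method": self.method,
             "categories": [c.to_dict() for c in self.categories]}
        if self.provenance is not None:
            d["provenance"] = self.provenance
        return d


@dataclass(frozen=True)
class Scorecard:
    """A complete card: indicators plus the nominal maximum they sum to."""

    id: str
    name: str
    nominal_max: float
    indicators: tuple[Indicator, ...]
    declared_point_loss: float | None = None
    aliases: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nominal_max <= 0:
            raise CardValidationError(
                f"card {self.id!r}: nominal_max must be positive")
        ids = [i.id for i in self.indicators]
        if len(set(ids)) != len(ids):
            raise CardValidationError(
                f"card {self.id!r} has duplicate indicator ids")
        total = sum(i.max_points for i in self.indicators)
        if abs(total - self.nominal_max) > _TOL:
            raise CardValidationError(
                f"card {self.id!r}: indicator maxima sum to {total}, "
                f"expected nominal_max {self.nominal_max}")
        if self.declared_point_loss is not None:
            computed = self.potential_point_loss
            if abs(computed - self.declared_point_loss) > _TOL:
                raise CardValidationError(
                    f"card {self.id!r}: computed potential point loss "
                    f"{computed} != declared {self.declared_point_loss}")
        for canonical, local in self.aliases.items():
            if local not in ids:
                raise CardValidationError(
                    f"card {self.id!r}: alias {canonical!r} points to "
                    f"unknown indicator {local!r}")

    @property
    def potential_point_loss(self) -> float:
        """Total of the negative scores the card can hand out."""
        return sum(abs(min(0.0, i.min_points)) for i in self.indicators)

    def indicator(self, indicator_id: str) -> Indicator:
        for i in self.indicators:
            if i.id == indicator_id:
                return i
        raise KeyError(f"card {self.id!r} has no indicator {indicator_id!r}")

    def to_dict(self) -> dict:
        d: dict = {"id": self.id, "name": self.name,
                   "nominal_max": self.nominal_max}
        if self.declared_point_loss is not None:
            d["declared_point_loss"] = self.declared_point_loss
        d["indicators"] = [i.to_dict() for i in self.indicators]
        if self.aliases:
            d["aliases"] = dict(self.aliases)
        return d

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False,
                              allow_unicode=True)


def _require(doc: Mapping, key: str, types, where: str):
    if key not in doc:
        raise SchemaError(f"{where}: missing required field {key!r}")
    value = doc[key]
    if not isinstance(value, types):
        raise SchemaError(
            f"{where}: field {key!r} has wrong type "
            f"{type(value).__name__}")
    return value


def load_scorecard(doc) -> Scorecard:
    """Build a validated :class:`Scorecard` from a configuration document.

    ``doc`` may be a mapping already parsed from YAML/JSON, a path to a
    YAML/JSON file, or a YAML string. Schema problems raise
    :class:`SchemaError` naming the offending field; invariant violations
    raise :class:`CardValidationError` listing computed vs declared values.
    """
    if isinstance(doc, (str, Path)):
        p = Path(doc)
        if p.exists():
            doc = yaml.safe_load(p.read_text())
        elif isinstance(doc, str):
            doc = yaml.safe_load(doc)
        else:
            raise FileNotFoundError(p)
    if not isinstance(doc, Mapping):
        raise SchemaError("scorecard document must be a mapping")

    card_id = _require(doc, "id", str, "scorecard")
    name = _require(doc, "name", str, f"card {card_id!r}")
    nominal_max = _require(doc, "nominal_max", (int, float),
                           f"card {card_id!r}")
    raw_inds = _require(doc, "indicators", list, f"card {card_id!r}")

    indicators = []
    for n, raw in enumerate(raw_inds):
        where = f"card {card_id!r} indicators[{n}]"
        if not isinstance(raw, Mapping):
            raise SchemaError(f"{where}: indicator must be a mapping")
        iid = _require(raw, "id", str, where)
        categories = []
        for m, rc in enumerate(_require(raw, "categories", list, where)):
            cwhere = f"{where} ({iid!r}) categories[{m}]"
            if not isinstance(rc, Mapping):
                raise SchemaError(f"{cwhere}: category must be a mapping")
            categories.append(ScoreCategory(
                label=_require(rc, "label", str, cwhere),
                description=str(rc.get("description", "")),
                points=float(_require(rc, "points", (int, float), cwhere)),
                provenance=rc.get("provenance")))
        indicators.append(Indicator(
            id=iid,
            name=str(raw.get("name", iid)),
            group=_require(raw, "group", str, where),
            method=str(raw.get("method", "")),
            categories=tuple(categories),
            provenance=raw.get("provenance")))

    declared = doc.get("declared_point_loss")
    aliases = doc.get("aliases") or {}
    if not isinstance(aliases, Mapping):
        raise SchemaError(f"card {card_id!r}: 'aliases' must be a mapping")
    return Scorecard(id=card_id, name=name, nominal_max=float(nominal_max),
                     indicators=tuple(indicators),
                     declared_point_loss=(None if declared is None
                                          else float(declared)),
                     aliases=dict(aliases))


def group_weights(card: Scorecard) -> dict[str, float]:
    """Maximum score contribution of each indicator group, as % of the
    nominal maximum. The three percentages always sum to 100."""
    out = {g: 0.0 for g in GROUPS}
    for ind in card.indicators:
        out[ind.group] += ind.max_points
    return {g: 100.0 * v / card.nominal_max for g, v in out.items()}


def eclipsing_report(card: Scorecard, threshold: float = 0.4,
                     ) -> list[tuple[str, float, bool]]:
    """Per-indicator combined span (|max|+|negative reach|) as % of the
    nominal maximum, sorted descending, flagged when above ``threshold``.

    A single indicator spanning a large share of the total score can
    overshadow all others ("attribute eclipsing").
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be a fraction in (0, 1]")
    rows = [(i.id, 100.0 * i.span / card.nominal_max) for i in card.indicators]
    rows.sort(key=lambda r: -r[1])
    return [(iid, pct, pct > 100.0 * threshold) for iid, pct in rows]


def schema_path() -> Path:
    """Path of the machine-readable scorecard document schema."""
    return Path(__file__).parent / "fixtures" / "scorecard.schema.json"


def schema() -> dict:
    return json.loads(schema_path().read_text())
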