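"""Score a site from an observation; standardise onto the 0-10 scale."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .cards import CardValidationError, Scorecard

__all__ = ["Observation", "SiteScore", "ObservationError",
           "score_site", "standardise",
           "read_observations", "write_observations", "write_scores"]


class ObservationError(CardValidationError):
    """An observation does not match its card."""


@dataclass(frozen=True)
class Observation:
    """One site's selected category label per indicator of one card."""

    site_id: str
    card_id: str
    selections: Mapping[str, str]

    def validate(self, card: Scorecard) -> None:
        """Raise :class:`ObservationError` naming the offending indicator."""
        if self.card_id != card.id:
            raise ObservationError(
                f"observation for card {self.card_id!r} scored against "
                f"card {card.id!r}")
        for ind in card.indicators:
            if ind.id not in self.selections:
                raise ObservationError(
                    f"site {self.site_id!r}: no selection for indicator "
                    f"{ind.id!r}")
            label = self.selections[ind.id]
            try:
                ind.category(label)
            except KeyError:
                raise ObservationError(
                    f"site {self.site_id!r}: indicator {ind.id!r} has no "
                    f"category labelled {label!r}") from None
        extra = set(self.selections) - {i.id for i in card.indicators}
        if extra:
            raise ObservationError(
                f"site {self.site_id!r}: selections for unknown "
                f"indicators {sorted(extra)}")


@dataclass(frozen=True)
class SiteScore:
    site_id: str
    card_id: str
    raw: float
    standardised: float


def standardise(raw: float, nominal_max: float) -> float:
    """Present a raw score on the common 0-10 scale (may go negative)."""
    if nominal_max <= 0:
        raise ValueError("nominal_max must be positive")
    return 10.0 * raw / nominal_max


def score_site(card: Scorecard, obs: Observation) -> SiteScore:
    """Sum the selected category points and standardise.

    Raw scores are exact sums; no per-site re-normalisation is performed,
    so an indicator scored below its maximum simply caps the achievable
    total.
    """
    obs.validate(card)
    raw = sum(card.indicator(iid).category(label).points
              for iid, label in obs.selections.items())
    return SiteScore(site_id=obs.site_id, card_id=card.id, raw=raw,
                     standardised=standardise(raw, card.nominal_max))


def read_observations(path: str | Path) -> list[Observation]:
    """Read observations from CSV with columns
    site_id, card_id, indicator_id, category_label (one row per selection)."""
    rows = list(csv.DictReader(Path(path).open(newline="")))
    required = {"site_id", "card_id", "indicator_id", "category_label"}
    if rows and not required <= set(rows[0]):
        raise ObservationError(
            f"observation CSV must have columns {sorted(required)}")
    grouped: dict[tuple[str, str], dict[str, str]] = {}
    order: list[tuple[str, str]] = []
    for row in rows:
        key = (row["site_id"], row["card_id"])
        if key not in grouped:
            grouped[key] = {}
            order.append(key)
        sel = grouped[key]
        if row["indicator_id"] in sel:
            raise ObservationError(
                f"site {key[0]!r}, card {key[1]!r}: duplicate selection "
                f"for indicator {row['indicator_id']!r}")
        sel[row["indicator_id"]] = row["category_label"]
    return [Observation(site_id=s, card_id=c, selections=grouped[(s, c)])
            for s, c in order]


def write_observations(observations: Iterable[Observation],
                       path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "card_id", "indicator_id", "category_label"])
        for obs in observations:
            for iid, label in obs.selections.items():
                w.writerow([obs.site_id, obs.card_id, iid, label])


def write_scores(scores: Iterable[SiteScore], path: str | Path) -> None:
    """Write site scores; standardised values at Table-3 (1 dp) precision."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["site_id", "card_id", "raw", "standardised"])
        for s in scores:
            w.writerow([s.site_id, s.card_id, repr(s.raw),
                        f"{s.standardised:.1f}"])
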