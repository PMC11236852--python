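"""Cross-card comparison analytics.

Works on a complete sites x cards matrix of standardised scores: per-card
averages, per-site ranges, the overall variation percentage, per-indicator
contribution tables, and the cross-card spread of contributions for
indicators shared (via aliases) between cards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cards import Scorecard
from .scoring import Observation

__all__ = ["ScoreMatrix", "ContributionTable", "card_averages",
           "site_ranges", "overall_variation_pct", "contribution_table",
           "metric_variation"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoreMatrix:
    """Sites x cards grid of standardised scores (no missing cells)."""

    values: pd.DataFrame  # index: site ids, columns: card ids

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("score matrix has missing cells")

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.values.index]

    @property
    def cards(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(values=df.astype(float))

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index_label="site")


def card_averages(m: ScoreMatrix) -> dict[str, float]:
    """Arithmetic mean standardised score per card (matrix column)."""
    if m.values.empty:
        raise ValueError("empty score matrix")
    return {str(c): float(v) for c, v in m.values.mean(axis=0).items()}


def site_ranges(m: ScoreMatrix) -> tuple[dict[str, float], float]:
    """Per-site score range (max - min across cards) and the mean range."""
    if len(m.cards) < 2:
        raise ValueError("site ranges need at least 2 cards")
    if m.values.empty:
        raise ValueError("empty score matrix")
    ranges = m.values.max(axis=1) - m.values.min(axis=1)
    return ({str(s): float(r) for s, r in ranges.items()},
            float(ranges.mean()))


def overall_variation_pct(m: ScoreMatrix) -> float:
    """Mean per-site range as a percentage of the 10-point scale.

    The mean range is taken at its 1-decimal presentation precision before
    conversion, so a mean range of 3.74 reports as 37%.
    """
    _, mean_range = site_ranges(m)
    return 100.0 * round(mean_range, 1) / 10.0


@dataclass(frozen=True)
class ContributionTable:
    """Per-indicator share of the score actually achieved across sites.

    ``contribution_pct`` is the total achieved by an indicator over all
    sites against its potential maximum contribution
    (n_sites x max_points); negative totals give negative percentages
    (points lost).
    """

    card_id: str
    n_sites: int
    rows: pd.DataFrame  # index: indicator id; columns: achieved_total,
    #                     potential_max, contribution_pct, omitted


def contribution_table(card: Scorecard,
                       observations: Sequence[Observation],
                       ) -> ContributionTable:
    if not observations:
        raise ValueError("contribution table needs at least one observation")
    for obs in observations:
        obs.validate(card)
    n = len(observations)
    records = []
    for ind in card.indicators:
        if ind.max_points == 0:
            log.info("card %s: indicator %s excluded from contribution "
                     "table (max_points == 0)", card.id, ind.id)
            continue
        achieved = sum(ind.category(obs.selections[ind.id]).points
                       for obs in observations)
        pct = 100.0 * achieved / (n * ind.max_points)
        records.append({"indicator": ind.id, "achieved_total": achieved,
                        "potential_max": ind.max_points,
                        "contribution_pct": pct,
                        "omitted": achieved == 0})
    rows = pd.DataFrame.from_records(records).set_index("indicator")
    return ContributionTable(card_id=card.id, n_sites=n, rows=rows)


def metric_variation(tables: Iterable[ContributionTable],
                     aliases: Mapping[str, Mapping[str, str]],
                     ) -> pd.DataFrame:
    """Cross-card spread of contribution percentages per canonical
    indicator.

    ``aliases`` maps card id -> {canonical indicator -> local indicator id}.
    Returns min/max/median contribution and the number of cards using each
    canonical indicator, sorted by descending median.
    """
    values: dict[str, list[float]] = {}
    for table in tables:
        local_to_canonical = {local: canonical for canonical, local
                              in aliases.get(table.card_id, {}).items()}
        for local, row in table.rows.iterrows():
            canonical = local_to_canonical.get(str(local))
            if canonical is None:
                continue
            values.setdefault(canonical, []).append(
                float(row["contribution_pct"]))
    if not values:
        log.warning("no shared indicators between the supplied cards")
        return pd.DataFrame(
            columns=["min", "max", "median", "n_cards"]).rename_axis(
                "indicator")
    df = pd.DataFrame(
        [{"indicator": k, "min": min(v), "max": max(v),
          "median": float(pd.Series(v).median()), "n_cards": len(v)}
         for k, v in values.items()]).set_index("indicator")
    return df.sort_values("median", ascending=False)
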