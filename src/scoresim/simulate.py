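"""Monte-Carlo scenario engine for categorical scorecards.

Each replicate draws one category per indicator — uniformly, from weighted
probabilities, or with conditional rules that reweight a child indicator
when its parent indicators land in designated categories — and sums the
drawn points into a raw site score. Replicated scenarios are summarised and
compared with a one-way ANOVA.
"""

from __future__ import annotations

import graphlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

from .cards import Scorecard

__all__ = ["ScenarioSpec", "ConditionalRule", "SimulationResult",
           "AnovaResult", "ScenarioError", "load_scenario", "simulate",
           "analytic_mean", "compare_scenarios"]

log = logging.getLogger(__name__)

#: Histogram bin width (points) for report plots.
HIST_BIN_WIDTH = 5.0


class ScenarioError(ValueError):
    """A scenario specification is invalid or does not fit the card."""


@dataclass(frozen=True)
class ConditionalRule:
    """Reweight ``child`` when every parent selection hits its label set.

    Rules are applied in declaration order and at most one rule fires per
    child per replicate (first match wins).
    """

    parents: tuple[tuple[str, frozenset[str]], ...]
    child: str
    weights_when_triggered: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(self.child == iid for iid, _ in self.parents):
            raise ScenarioError(
                f"rule child {self.child!r} appears among its own parents")


@dataclass(frozen=True)
class ScenarioSpec:
    """Category probability weights plus optional conditional rules.

    Indicators absent from ``weights`` draw uniformly over their
    categories.
    """

    name: str
    weights: Mapping[str, tuple[float, ...]] = field(default_factory=dict)
    rules: tuple[ConditionalRule, ...] = ()

    def __post_init__(self) -> None:
        for iid, w in self.weights.items():
            arr = np.asarray(w, dtype=float)
            if (arr < 0).any():
                raise ScenarioError(
                    f"indicator {iid!r}: negative probability weight")
            if not np.isclose(arr.sum(), 1.0):
                raise ScenarioError(
                    f"indicator {iid!r}: weights sum to {arr.sum()}, not 1")

    def validate_for(self, card: Scorecard) -> None:
        """Check weight-vector lengths, rule labels and rule acyclicity."""
        for iid, w in self.weights.items():
            ind = card.indicator(iid)  # KeyError -> unknown indicator
            if len(w) != len(ind.categories):
                raise ScenarioError(
                    f"indicator {iid!r}: {len(w)} weights for "
                    f"{len(ind.categories)} categories")
        children = [r.child for r in self.rules]
        for rule in self.rules:
            child = card.indicator(rule.child)
            if len(rule.weights_when_triggered) != len(child.categories):
                raise ScenarioError(
                    f"rule for {rule.child!r}: "
                    f"{len(rule.weights_when_triggered)} weights for "
                    f"{len(child.categories)} categories")
            w = np.asarray(rule.weights_when_triggered, dtype=float)
            if (w < 0).any() or not np.isclose(w.sum(), 1.0):
                raise ScenarioError(
                    f"rule for {rule.child!r}: triggered weights must be "
                    "a probability vector")
            for iid, labels in rule.parents:
                parent = card.indicator(iid)
                known = {c.label for c in parent.categories}
                unknown = set(labels) - known
                if unknown:
                    raise ScenarioError(
                        f"rule for {rule.child!r}: parent {iid!r} has no "
                        f"categories {sorted(unknown)}")
        # parent->child edges must be acyclic so parents can be drawn first
        graph: dict[str, set[str]] = {}
        for rule in self.rules:
            graph.setdefault(rule.child, set()).update(
                iid for iid, _ in rule.parents)
        try:
            tuple(graphlib.TopologicalSorter(graph).static_order())
        except graphlib.CycleError as err:
            raise ScenarioError(f"cyclic conditional rules: {err}") from err


def load_scenario(doc) -> ScenarioSpec:
    """Parse a scenario document (mapping, YAML string, or file path)."""
    if isinstance(doc, (str, Path)):
        p = Path(doc)
        doc = yaml.safe_load(p.read_text() if p.exists() else str(doc))
    if not isinstance(doc, Mapping):
        raise ScenarioError("scenario document must be a mapping")
    rules = []
    for raw in doc.get("rules") or ():
        rules.append(ConditionalRule(
            parents=tuple((p["indicator"], frozenset(p["labels"]))
                          for p in raw["parents"]),
            child=raw["child"],
            weights_when_triggered=tuple(float(x) for x in raw["weights"])))
    return ScenarioSpec(
        name=str(doc.get("name", "custom")),
        weights={iid: tuple(float(x) for x in w)
                 for iid, w in (doc.get("weights") or {}).items()},
        rules=tuple(rules))


@dataclass(frozen=True)
class SimulationResult:
    card_id: str
    scenario: str
    n_reps: int
    seed: int
    raw_scores: np.ndarray
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.raw_scores.mean())

    @property
    def sd(self) -> float:
        return float(self.raw_scores.std(ddof=1))

    def summary(self) -> dict:
        return {"card": self.card_id, "scenario": self.scenario,
                "n_reps": self.n_reps, "seed": self.seed,
                "mean": self.mean, "sd": self.sd,
                "min": float(self.raw_scores.min()),
                "max": float(self.raw_scores.max())}


def _draw_order(card: Scorecard, scenario: ScenarioSpec) -> list[str]:
    """Card order, adjusted so rule parents are drawn before children."""
    graph = {i.id: set() for i in card.indicators}
    for rule in scenario.rules:
        graph[rule.child].update(iid for iid, _ in rule.parents)
    sorter = graphlib.TopologicalSorter(graph)
    topo = list(sorter.static_order())
    # stable: keep card order among indicators at the same depth
    card_pos = {i.id: n for n, i in enumerate(card.indicators)}
    depth: dict[str, int] = {}
    for iid in topo:
        depth[iid] = 1 + max((depth[p] for p in graph[iid]), default=-1)
    return sorted(graph, key=lambda iid: (depth[iid], card_pos[iid]))


def draw_selections(card: Scorecard, scenario: ScenarioSpec, n: int,
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Draw ``n`` replicate category indices per indicator.

    One uniform variate per (replicate, indicator), mapped through the
    inverse CDF of the applicable weight vector; rule-triggered replicates
    use the rule's CDF instead of the base one.
    """
    scenario.validate_for(card)
    selections: dict[str, np.ndarray] = {}
    rules_by_child: dict[str, list[ConditionalRule]] = {}
    for rule in scenario.rules:
        rules_by_child.setdefault(rule.child, []).append(rule)
    label_index = {i.id: {c.label: k for k, c in enumerate(i.categories)}
                   for i in card.indicators}

    for iid in _draw_order(card, scenario):
        ind = card.indicator(iid)
        k = len(ind.categories)
        base = np.asarray(scenario.weights.get(iid, np.full(k, 1.0 / k)),
                          dtype=float)
        u = rng.random(n)
        idx = np.searchsorted(np.cumsum(base), u, side="right")
        idx = np.minimum(idx, k - 1)  # guard u landing on cumsum rounding
        assigned = np.zeros(n, dtype=bool)  # first matching rule wins
        for rule in rules_by_child.get(iid, ()):
            mask = ~assigned
            for parent_id, labels in rule.parents:
                in_set = np.isin(
                    selections[parent_id],
                    [label_index[parent_id][l] for l in labels])
                mask &= in_set
            if mask.any():
                cdf = np.cumsum(rule.weights_when_triggered)
                tidx = np.searchsorted(cdf, u[mask], side="right")
                idx[mask] = np.minimum(tidx, k - 1)
            assigned |= mask
        selections[iid] = idx
    return selections


def simulate(card: Scorecard, scenario: ScenarioSpec, n_reps: int,
             seed: int) -> SimulationResult:
    """Run ``n_reps`` replicates of ``scenario`` on ``card``.

    Deterministic for a given (card, scenario, n_reps, seed); every
    replicate score lies in [-potential_point_loss, nominal_max].
    """
    if n_reps < 1:
        raise ValueError("n_reps must be a positive integer")
    rng = np.random.default_rng(seed)
    selections = draw_selections(card, scenario, n_reps, rng)
    scores = np.zeros(n_reps)
    for ind in card.indicators:
        points = np.array([c.points for c in ind.categories])
        scores += points[selections[ind.id]]
    lo = -card.potential_point_loss
    edges = np.arange(np.floor(lo / HIST_BIN_WIDTH) * HIST_BIN_WIDTH,
                      card.nominal_max + HIST_BIN_WIDTH, HIST_BIN_WIDTH)
    counts, edges = np.histogram(scores, bins=edges)
    return SimulationResult(card_id=card.id, scenario=scenario.name,
                            n_reps=n_reps, seed=seed, raw_scores=scores,
                            histogram_counts=counts, histogram_edges=edges)


def analytic_mean(card: Scorecard, scenario: ScenarioSpec) -> float:
    """Closed-form expected score for a rule-free scenario:
    sum over indicators of sum_c p_c * points_c."""
    if scenario.rules:
        raise ScenarioError(
            "analytic_mean is defined for rule-free scenarios only; "
            "use simulate()")
    scenario.validate_for(card)
    total = 0.0
    for ind in card.indicators:
        k = len(ind.categories)
        w = np.asarray(scenario.weights.get(ind.id, np.full(k, 1.0 / k)))
        total += float(w @ np.array([c.points for c in ind.categories]))
    return total


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    group_means: dict[str, float]
    df_between: int
    df_within: int


def compare_scenarios(results: Sequence[SimulationResult]) -> AnovaResult:
    """One-way fixed-effects ANOVA on the replicate raw-score vectors.

    Sums of squares are assembled from per-group size/mean/variance (one
    pass over each vector), which stays exact at millions of replicates.
    """
    if len(results) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(r.n_reps < 2 for r in results):
        raise ValueError("every group needs at least 2 replicates")
    ns = np.array([r.n_reps for r in results], dtype=float)
    means = np.array([r.mean for r in results])
    variances = np.array([float(r.raw_scores.var(ddof=1)) for r in results])
    if variances.min() > 0 and variances.max() / variances.min() > 4:
        log.warning("group variances differ by more than 4x; the ANOVA "
                    "F-test assumes homogeneous variances")
    grand = float((ns * means).sum() / ns.sum())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * variances).sum())
    df_between = len(results) - 1
    df_within = int(ns.sum()) - len(results)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    f = ms_between / ms_within if ms_within > 0 else float("inf")
    p = float(stats.f.sf(f, df_between, df_within))
    labels = [f"{r.card_id}:{r.scenario}" for r in results]
    return AnovaResult(F=f, p=p,
                       group_means=dict(zip(labels, means.tolist())),
                       df_between=df_between, df_within=df_within)
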