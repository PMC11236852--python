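"""Built-in fixtures and synthetic site-observation generation.

Ships the five card encodings, the printed 9-site score matrix, the three
scenario specifications and a generic simulation card, and draws complete
synthetic observations from any scenario so every pipeline stage can be
exercised without field data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cards import Scorecard, load_scorecard
from .compare import ScoreMatrix
from .scoring import Observation
from .simulate import ScenarioSpec, draw_selections, load_scenario

__all__ = ["FIXTURE_REGISTRY", "builtin_fixture", "fixture_path",
           "ObservationGeneratorConfig", "generate_observations"]

_FIXTURE_DIR = Path(__file__).parent / "fixtures"

#: name -> (kind, file name)
FIXTURE_REGISTRY: dict[str, tuple[str, str]] = {
    "bff": ("scorecard", "bff.yaml"),
    "hhp": ("scorecard", "hhp.yaml"),
    "pmp": ("scorecard", "pmp.yaml"),
    "rbaps_draft": ("scorecard", "rbaps_draft.yaml"),
    "test_card": ("scorecard", "test_card.yaml"),
    "generic_sim_card": ("scorecard", "generic_sim_card.yaml"),
    "table3_matrix": ("score_matrix", "table3_matrix.csv"),
    "scenario_random": ("scenario", "scenario_random.yaml"),
    "scenario_biased": ("scenario", "scenario_biased.yaml"),
    "scenario_correlated": ("scenario", "scenario_correlated.yaml"),
}


def fixture_path(name: str) -> Path:
    try:
        _, filename = FIXTURE_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: "
            f"{sorted(FIXTURE_REGISTRY)}") from None
    return _FIXTURE_DIR / filename


def builtin_fixture(name: str):
    """Return a validated built-in fixture object by registry name."""
    kind, _ = FIXTURE_REGISTRY.get(name, (None, None))
    path = fixture_path(name)
    if kind == "scorecard":
        return load_scorecard(path)
    if kind == "score_matrix":
        return ScoreMatrix.from_csv(path)
    return load_scenario(path)


@dataclass(frozen=True)
class ObservationGeneratorConfig:
    """Configuration for drawing synthetic site observations."""

    card_id: str
    n_sites: int
    scenario: ScenarioSpec
    seed: int


def generate_observations(cfg: ObservationGeneratorConfig,
                          card: Scorecard | None = None,
                          ) -> list[Observation]:
    """Draw ``n_sites`` complete observations under ``cfg.scenario``.

    Site ids are consecutive integers from 1, matching the anonymised
    field-site naming. Deterministic for a given seed, and consistent with
    :func:`scoresim.simulate.simulate`: scoring the generated observations
    reproduces the simulator's score distribution for the same scenario.
    """
    if cfg.n_sites < 1:
        raise ValueError("n_sites must be a positive integer")
    if card is None:
        card = builtin_fixture(cfg.card_id)
    if card.id != cfg.card_id:
        raise ValueError(
            f"config names card {cfg.card_id!r} but got {card.id!r}")
    rng = np.random.default_rng(cfg.seed)
    selections = draw_selections(card, cfg.scenario, cfg.n_sites, rng)
    observations = []
    for n in range(cfg.n_sites):
        chosen = {ind.id: ind.categories[selections[ind.id][n]].label
                  for ind in card.indicators}
        observations.append(Observation(site_id=str(n + 1),
                                        card_id=card.id, selections=chosen))
    return observations
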