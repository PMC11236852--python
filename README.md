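# scoresim

Ecological condition scorecards as data: a declarative model for rapid
habitat-assessment scorecards (categorical proxy indicators with signed
point values), a site-scoring engine, cross-card comparison analytics, and
a Monte-Carlo scenario simulator for asking whether the *design* of a card
— rather than the condition of a site — drives the score it produces.

The package ships validated encodings of five Irish peatland/heathland
scorecards (`bff`, `hhp`, `pmp`, `rbaps_draft`, `test_card`), a generic
12-indicator simulation card, a printed 9-site × 5-card score matrix, and
three simulation scenarios (`random`, `biased`, `correlated`).

## Concepts

- **Scorecard** — named indicators, each with an ordered list of
  categories carrying positive, zero or negative points. The best
  selection on every indicator sums exactly to the card's nominal maximum
  (100 or 500); the sum of worst negative scores is its *potential point
  loss*. Cards are YAML documents (`scoresim fixtures export bff --out
  bff.yaml`; schema in `src/scoresim/fixtures/scorecard.schema.json`).
- **Observation** — one selected category label per indicator for one
  site; scored raw and standardised to the common 0–10 scale
  (`10 × raw / nominal_max`, possibly negative).
- **ScoreMatrix** — complete sites × cards grid of standardised scores,
  supporting per-card averages, per-site ranges and the overall variation
  percentage.
- **ScenarioSpec** — per-indicator category probability weights (uniform
  when absent) plus optional conditional rules that reweight a child
  indicator when parent indicators land in designated categories
  (first matching rule wins). Rule-free scenarios have a closed-form
  expected score (`analytic_mean`) used as an oracle for the simulator.

## CLI

```sh
# analytics on the shipped printed score matrix
scoresim compare --matrix table3_matrix --out out/

# score observed sites (CSV: site_id,card_id,indicator_id,category_label)
scoresim score --card bff --observations obs.csv --out out/

# Monte-Carlo scenario simulation (1e6 replicates by default)
scoresim simulate --card generic_sim_card --scenario scenario_biased \
    --reps 100000 --seed 1 --out out/ --plot

scoresim fixtures list
```

Every artifact embeds a provenance header (package version, seed, SHA-256
digests of the inputs); reruns with the same seed are bit-identical.

## Library

```python
import scoresim as ss

card = ss.builtin_fixture("pmp")
ss.group_weights(card)              # {'vegetation': 55.0, ...}
ss.eclipsing_report(card, 0.40)     # drainage spans 45% -> flagged

result = ss.simulate(card, ss.builtin_fixture("scenario_random"),
                     n_reps=1_000_000, seed=1)
result.mean, result.sd
ss.compare_scenarios([result, ...]) # one-way ANOVA across score vectors

matrix = ss.builtin_fixture("table3_matrix")
ss.card_averages(matrix); ss.site_ranges(matrix)
ss.overall_variation_pct(matrix)    # 37.0
```

Synthetic site observations with field-motivated biases (elevated negative
burning/bracken probabilities, burning × bare-soil → vegetation-structure
correlation) come from `scoresim.synth.generate_observations`, which is
distribution-consistent with the simulator.

## Notes on fixture provenance

Category point values not printed in the source tables are marked
`provenance: reconstructed` in the fixture YAML; they are chosen to satisfy
the printed structural constraints (group weightings, indicator counts,
nominal maxima, potential point loss, known category endpoints) exactly,
and to reproduce the published simulation means analytically.
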