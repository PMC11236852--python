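import numpy as np
import pytest
from scipy import stats

from scoresim import builtin_fixture
from scoresim.simulate import (ConditionalRule, ScenarioError, ScenarioSpec,
                               analytic_mean, compare_scenarios,
                               load_scenario, simulate)

from conftest import make_card

UNIFORM = ScenarioSpec(name="random")


@pytest.fixture(scope="module")
def symmetric_card():
    return make_card({"x": [10, 0, -10]}, card_id="sym")


# --- simulate --------------------------------------------------------------

def test_symmetric_uniform_mean_near_zero(symmetric_card):
    result = simulate(symmetric_card, UNIFORM, n_reps=100_000, seed=0)
    se = result.sd / np.sqrt(result.n_reps)
    assert abs(result.mean) < 4 * se


def test_deterministic_given_seed(generic_card):
    a = simulate(generic_card, UNIFORM, n_reps=5_000, seed=42)
    b = simulate(generic_card, UNIFORM, n_reps=5_000, seed=42)
    np.testing.assert_array_equal(a.raw_scores, b.raw_scores)
    c = simulate(generic_card, UNIFORM, n_reps=5_000, seed=43)
    assert not np.array_equal(a.raw_scores, c.raw_scores)


# biased/correlated weight vectors are generic-card specific, so only the
# uniform scenario applies to every card
BOUND_COMBOS = ([(c, "scenario_random") for c in
                 ("bff", "hhp", "pmp", "rbaps_draft", "test_card",
                  "generic_sim_card")]
                + [("generic_sim_card", s) for s in
                   ("scenario_biased", "scenario_correlated")])


@pytest.mark.parametrize("card_name,scenario_name", BOUND_COMBOS)
def test_replicates_within_card_bounds(card_name, scenario_name):
    card = builtin_fixture(card_name)
    scenario = builtin_fixture(scenario_name)
    result = simulate(card, scenario, n_reps=2_000, seed=5)
    assert result.raw_scores.min() >= -card.potential_point_loss - 1e-9
    assert result.raw_scores.max() <= card.nominal_max + 1e-9
    assert len(result.raw_scores) == result.n_reps
    assert result.histogram_counts.sum() == result.n_reps


def test_histogram_bins_are_5_points_wide(generic_card):
    result = simulate(generic_card, UNIFORM, n_reps=1_000, seed=1)
    widths = np.diff(result.histogram_edges)
    assert np.allclose(widths, 5.0)
    assert result.histogram_edges[0] <= -generic_card.potential_point_loss
    assert result.histogram_edges[-1] >= generic_card.nominal_max


def test_reps_must_be_positive(generic_card):
    with pytest.raises(ValueError):
        simulate(generic_card, UNIFORM, n_reps=0, seed=1)


# --- analytic mean and the Monte-Carlo oracle ------------------------------

def test_analytic_mean_uniform_symmetric(symmetric_card):
    assert analytic_mean(symmetric_card, UNIFORM) == pytest.approx(0.0)


def test_analytic_mean_degenerate_weights_gives_nominal_max(generic_card):
    weights = {}
    for ind in generic_card.indicators:
        best = int(np.argmax([c.points for c in ind.categories]))
        w = [0.0] * len(ind.categories)
        w[best] = 1.0
        weights[ind.id] = tuple(w)
    scenario = ScenarioSpec(name="degenerate", weights=weights)
    assert analytic_mean(generic_card, scenario) == pytest.approx(
        generic_card.nominal_max)
    result = simulate(generic_card, scenario, n_reps=100, seed=0)
    assert np.all(result.raw_scores == generic_card.nominal_max)


@pytest.mark.parametrize("card_name,region", [
    ("bff", (-20, 0)), ("pmp", (-50, -30))])
def test_analytic_mean_uniform_regions(card_name, region):
    mean = analytic_mean(builtin_fixture(card_name), UNIFORM)
    assert region[0] < mean < region[1]


def test_analytic_mean_rejects_rules(generic_card):
    scenario = builtin_fixture("scenario_correlated")
    with pytest.raises(ScenarioError):
        analytic_mean(generic_card, scenario)


@pytest.mark.parametrize("seed", range(5))
@pytest.mark.parametrize("scenario_name", ["scenario_random",
                                           "scenario_biased"])
def test_mc_mean_within_4se_of_analytic(generic_card, scenario_name, seed):
    scenario = builtin_fixture(scenario_name)
    result = simulate(generic_card, scenario, n_reps=10_000, seed=seed)
    expected = analytic_mean(generic_card, scenario)
    se = result.sd / np.sqrt(result.n_reps)
    assert abs(result.mean - expected) <= 4 * se


def test_uniform_means_reproduce_field_ordering():
    means = {name: analytic_mean(builtin_fixture(name), UNIFORM)
             for name in ("bff", "hhp", "pmp")}
    assert means["bff"] > means["pmp"] > means["hhp"]
    for name in ("bff", "hhp", "pmp"):
        mc = simulate(builtin_fixture(name), UNIFORM, n_reps=20_000, seed=11)
        assert mc.mean == pytest.approx(means[name], abs=4 * mc.sd / 140)


# --- scenario validation ---------------------------------------------------

def test_weight_length_mismatch_rejected(generic_card):
    scenario = ScenarioSpec(name="bad",
                            weights={"burning": (0.5, 0.5)})
    with pytest.raises(ScenarioError, match="burning"):
        simulate(generic_card, scenario, n_reps=10, seed=0)


def test_weights_must_sum_to_one():
    with pytest.raises(ScenarioError, match="sum"):
        ScenarioSpec(name="bad", weights={"x": (0.5, 0.1)})


def test_negative_weights_rejected():
    with pytest.raises(ScenarioError, match="negative"):
        ScenarioSpec(name="bad", weights={"x": (1.5, -0.5)})


def test_unknown_indicator_in_weights_rejected(generic_card):
    scenario = ScenarioSpec(name="bad", weights={"ghost": (0.5, 0.5)})
    with pytest.raises(KeyError):
        simulate(generic_card, scenario, n_reps=10, seed=0)


def test_child_among_parents_rejected():
    with pytest.raises(ScenarioError, match="parents"):
        ConditionalRule(parents=(("x", frozenset({"c0"})),), child="x",
                        weights_when_triggered=(1.0, 0.0))


def test_cyclic_rules_rejected():
    card = make_card({"x": [5, 0], "y": [5, 0]})
    rules = (
        ConditionalRule(parents=(("x", frozenset({"c1"})),), child="y",
                        weights_when_triggered=(0.0, 1.0)),
        ConditionalRule(parents=(("y", frozenset({"c1"})),), child="x",
                        weights_when_triggered=(0.0, 1.0)),
    )
    scenario = ScenarioSpec(name="cyclic", rules=rules)
    with pytest.raises(ScenarioError, match="cyclic"):
        simulate(card, scenario, n_reps=10, seed=0)


def test_rule_unknown_parent_label_rejected(generic_card):
    rule = ConditionalRule(parents=(("burning", frozenset({"nope"})),),
                           child="veg_structure",
                           weights_when_triggered=(1.0, 0.0, 0.0, 0.0))
    scenario = ScenarioSpec(name="bad", rules=(rule,))
    with pytest.raises(ScenarioError, match="nope"):
        simulate(generic_card, scenario, n_reps=10, seed=0)


# --- conditional rules -----------------------------------------------------

def test_rule_triggers_exactly_on_parent_categories():
    # parent x: c0=+5, c1=0; child y: c0=+5, c1=0
    card = make_card({"x": [5, 0], "y": [5, 0]})
    rule = ConditionalRule(parents=(("x", frozenset({"c1"})),), child="y",
                           weights_when_triggered=(0.0, 1.0))
    scenario = ScenarioSpec(name="forced", rules=(rule,))
    result = simulate(card, scenario, n_reps=50_000, seed=3)
    # whenever x drew c1 (score 0 from x), y is forced to 0 -> total 0
    # whenever x drew c0 (+5), y is uniform -> totals 10 or 5
    assert set(np.unique(result.raw_scores)) <= {0.0, 5.0, 10.0}
    assert np.isclose((result.raw_scores == 0.0).mean(), 0.5, atol=0.02)


def test_first_matching_rule_wins():
    card = make_card({"x": [5, 0], "y": [9, 0]})
    r1 = ConditionalRule(parents=(("x", frozenset({"c0", "c1"})),),
                         child="y", weights_when_triggered=(1.0, 0.0))
    r2 = ConditionalRule(parents=(("x", frozenset({"c0", "c1"})),),
                         child="y", weights_when_triggered=(0.0, 1.0))
    result = simulate(card, ScenarioSpec(name="order", rules=(r1, r2)),
                      n_reps=1_000, seed=0)
    # r1 always matches first, so y is always at its maximum of 9
    assert set(np.unique(result.raw_scores)) <= {9.0, 14.0}


def test_downweighting_rule_never_increases_mean():
    card = make_card({"x": [0, -10], "y": [20, 0]})
    rule = ConditionalRule(parents=(("x", frozenset({"c1"})),), child="y",
                           weights_when_triggered=(0.1, 0.9))
    with_rule = ScenarioSpec(name="down", rules=(rule,))
    for seed in range(5):
        ruled = simulate(card, with_rule, n_reps=5_000, seed=seed)
        free = simulate(card, ScenarioSpec(name="free"), n_reps=5_000,
                        seed=seed)
        assert ruled.mean <= free.mean + 0.5  # rule shifts mean down ~4.5


def test_correlated_fixture_mean_below_biased():
    card = builtin_fixture("generic_sim_card")
    biased = simulate(card, builtin_fixture("scenario_biased"),
                      n_reps=50_000, seed=2)
    correlated = simulate(card, builtin_fixture("scenario_correlated"),
                          n_reps=50_000, seed=2)
    assert correlated.mean < biased.mean


# --- ANOVA -----------------------------------------------------------------

def _fake_result(arr, card_id, scenario):
    from scoresim.simulate import SimulationResult
    return SimulationResult(card_id=card_id, scenario=scenario,
                            n_reps=len(arr), seed=0, raw_scores=arr,
                            histogram_counts=np.array([len(arr)]),
                            histogram_edges=np.array([arr.min(),
                                                      arr.max() + 1]))


def test_identical_groups_give_zero_f():
    v = [1.0, 2.0, 3.0]
    res = compare_scenarios([_fake_result(np.array(v), "a", "s"),
                             _fake_result(np.array(v), "b", "s")])
    assert res.F == pytest.approx(0.0)


def test_anova_matches_hand_worked_sums_of_squares():
    # groups {1,2,3} and {2,3,4}: means 2 and 3, grand mean 2.5
    # SSB = 3*(0.5^2)*2 = 1.5 (df 1); SSW = 2+2 = 4 (df 4)
    # F = (1.5/1) / (4/4) = 1.5
    g1, g2 = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
    res = compare_scenarios([_fake_result(g1, "a", "s"),
                             _fake_result(g2, "b", "s")])
    assert res.F == pytest.approx(1.5)
    assert res.df_between == 1 and res.df_within == 4
    assert res.group_means == {"a:s": pytest.approx(2.0),
                               "b:s": pytest.approx(3.0)}


@pytest.mark.parametrize("seed", [0, 1])
def test_anova_matches_scipy_f_oneway(seed):
    rng = np.random.default_rng(seed)
    groups = [rng.normal(loc, 10, size=500) for loc in (0, 1, 3)]
    res = compare_scenarios([_fake_result(g, f"g{n}", "s")
                             for n, g in enumerate(groups)])
    f_ref, p_ref = stats.f_oneway(*groups)
    assert res.F == pytest.approx(float(f_ref), rel=1e-10)
    assert res.p == pytest.approx(float(p_ref), rel=1e-8)


def test_anova_needs_two_groups():
    with pytest.raises(ValueError):
        compare_scenarios([_fake_result(np.array([1.0, 2.0]), "a", "s")])


def test_anova_unequal_variances_warn(caplog):
    rng = np.random.default_rng(0)
    a = _fake_result(rng.normal(0, 1, 200), "a", "s")
    b = _fake_result(rng.normal(0, 10, 200), "b", "s")
    with caplog.at_level("WARNING", logger="scoresim.simulate"):
        compare_scenarios([a, b])
    assert any("variance" in r.message for r in caplog.records)


def test_three_card_anova_is_extreme():
    results = [simulate(builtin_fixture(name), UNIFORM, n_reps=20_000,
                        seed=9) for name in ("bff", "hhp", "pmp")]
    res = compare_scenarios(results)
    assert res.F > 5_000
    assert res.p < 1e-10


# --- scenario loading ------------------------------------------------------

def test_load_scenario_round_trip_fixture():
    scenario = load_scenario({"name": "biased",
                              "weights": {"x": [0.25, 0.75]},
                              "rules": []})
    assert scenario.name == "biased"
    assert scenario.weights["x"] == (0.25, 0.75)


def test_builtin_correlated_scenario_parses():
    scenario = builtin_fixture("scenario_correlated")
    assert scenario.name == "correlated"
    assert len(scenario.rules) == 1
    assert scenario.rules[0].child == "veg_structure"
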