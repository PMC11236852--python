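import pytest

from scoresim import builtin_fixture
from scoresim.cards import Indicator, ScoreCategory, Scorecard


@pytest.fixture(scope="session")
def bff():
    return builtin_fixture("bff")


@pytest.fixture(scope="session")
def hhp():
    return builtin_fixture("hhp")


@pytest.fixture(scope="session")
def pmp():
    return builtin_fixture("pmp")


@pytest.fixture(scope="session")
def generic_card():
    return builtin_fixture("generic_sim_card")


@pytest.fixture(scope="session")
def table3():
    return builtin_fixture("table3_matrix")


@pytest.fixture(scope="session")
def all_cards():
    return [builtin_fixture(n) for n in
            ("bff", "hhp", "pmp", "rbaps_draft", "test_card")]


def make_indicator(iid, points, group="vegetation"):
    """Indicator with one category per point value, labelled c0, c1, ..."""
    cats = tuple(ScoreCategory(label=f"c{n}", description="", points=p)
                 for n, p in enumerate(points))
    return Indicator(id=iid, name=iid, group=group, categories=cats)


def make_card(indicator_points, card_id="toy", groups=None):
    """Card whose nominal max is the sum of per-indicator maxima.

    ``indicator_points``: mapping indicator id -> list of point values.
    """
    groups = groups or {}
    inds = tuple(make_indicator(iid, pts, groups.get(iid, "vegetation"))
                 for iid, pts in indicator_points.items())
    return Scorecard(id=card_id, name=card_id,
                     nominal_max=sum(i.max_points for i in inds),
                     indicators=inds)


@pytest.fixture
def toy_card():
    return make_card({"a": [4, 2, 0], "b": [6, 0, -6]})
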