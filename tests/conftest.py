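import datetime as dt

import pytest
from hypothesis import settings

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

from pittaforage.core import FeedingVisit, PreyItem
from pittaforage.synthetic import SyntheticConfig, generate


def make_item(taxon="earthworm", length_bu=3.0, item_id="i", pieces=1):
    return PreyItem(
        item_id=item_id, taxon=taxon, length_beak_units=length_bu,
        n_sundered_pieces=pieces,
    )


def make_visit(
    items,
    visit_id="v1",
    nest_id="nest1",
    date=dt.date(2021, 6, 1),
    clock=dt.time(9, 0),
    age=5,
    brood=5,
    rain=0.0,
    interval=20.0,
    order=2,
):
    return FeedingVisit(
        visit_id=visit_id,
        nest_id=nest_id,
        session_id=f"{nest_id}:{date.isoformat()}",
        date=date,
        clock_time=clock,
        items=tuple(items),
        nestling_age_days=age,
        brood_size=brood,
        rainfall_mm=rain,
        inter_visit_interval_min=interval,
        visit_order=order,
    )


def printed_counts_visits():
    """A visit list realising the study's printed marginal counts exactly:
    233 visits (11 NoE / 151 OnlyE / 71 MIX) holding 647 identified items
    of which 547 are earthworms and 34 centipedes."""
    visits = []
    i = 0

    def add(taxa):
        nonlocal i
        items = [make_item(taxon=t, item_id=f"{i}:{j}") for j, t in enumerate(taxa)]
        visits.append(make_visit(items, visit_id=f"v{i}", order=i + 2))
        i += 1

    # 100 non-earthworm items: 34 centipedes then 66 beetles
    others = ["centipede"] * 34 + ["beetle"] * 66
    for _ in range(11):  # NoE: one item each
        add([others.pop()])
    for k in range(71):  # MIX: 1 worm + 1-2 others (89 others in total)
        n_other = 2 if k < 18 else 1
        add(["earthworm"] + [others.pop() for _ in range(n_other)])
    assert not others
    # OnlyE: 476 worms over 151 visits (23 visits of 4, 128 of 3)
    for k in range(151):
        add(["earthworm"] * (4 if k < 23 else 3))
    assert len(visits) == 233
    return visits


@pytest.fixture(scope="session")
def default_dataset():
    """A study-sized synthetic dataset (4 nests, ~8 sessions each)."""
    cfg = SyntheticConfig()
    visits, nests, frame = generate(cfg, seed=11)
    return cfg, visits, nests, frame


@pytest.fixture(scope="session")
def large_dataset():
    """A 200-session dataset for Monte-Carlo parameter-recovery checks."""
    cfg = SyntheticConfig(n_nests=20, sessions_per_nest=10)
    visits, nests, frame = generate(cfg, seed=7)
    return cfg, visits, nests, frame
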