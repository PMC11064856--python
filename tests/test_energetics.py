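"""Bioenergetic chain: allometry, DEE, and the consumption extrapolation."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pittaforage.core import DayRecord, NestObservation
from pittaforage.energetics import (
    EnergeticsParams,
    afdm_from_length,
    brood_consumption,
    daily_rates,
    dee,
    family_consumption,
    fresh_from_afdm,
    pair_dee,
    parent_consumption,
    round_half_up,
)

from conftest import make_item, make_visit

P = EnergeticsParams()


class TestAllometry:
    @pytest.mark.parametrize(
        "length_mm, expected_g",
        [(63.4, 0.0733), (100.0, 0.3136)],
    )
    def test_afdm_values(self, length_mm, expected_g):
        """Direct evaluation of exp(3.19 ln L - 15.85)."""
        assert afdm_from_length(length_mm) == pytest.approx(
            math.exp(3.19 * math.log(length_mm) - 15.85), rel=1e-12
        )
        assert afdm_from_length(length_mm) == pytest.approx(expected_g, abs=5e-4)

    @given(st.floats(1.0, 200.0), st.floats(1.0, 200.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, l1, l2):
        if l1 == l2:
            return
        lo, hi = sorted([l1, l2])
        assert afdm_from_length(lo) < afdm_from_length(hi)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            afdm_from_length(0.0)

    @pytest.mark.parametrize("afdm, fresh", [(0.0, 0.0), (1.0, 5.7904)])
    def test_fresh_mass_ratio(self, afdm, fresh):
        assert fresh_from_afdm(afdm) == pytest.approx(fresh)
        with pytest.raises(ValueError):
            fresh_from_afdm(-0.1)


class TestDEE:
    def test_unit_mass(self):
        assert dee(1.0) == pytest.approx(1092.0)

    def test_sex_specific_values(self):
        assert dee(P.male_mass_kg) == pytest.approx(217.0, abs=0.1)
        assert dee(P.female_mass_kg) == pytest.approx(159.6, abs=0.1)

    def test_pair_dee_rounds_to_printed_value(self):
        """Unrounded pair DEE is ~376.6 kJ/day and reports as 377 (kg-units
        regression guard)."""
        raw = dee(P.male_mass_kg) + dee(P.female_mass_kg)
        assert 376.0 <= raw <= 377.5
        assert pair_dee() == 377

    def test_symmetry_and_power_law_scaling(self):
        p_eq = EnergeticsParams(male_mass_kg=0.1, female_mass_kg=0.1)
        assert dee(0.1) * 2 == pytest.approx(
            dee(p_eq.male_mass_kg) + dee(p_eq.female_mass_kg)
        )
        assert dee(0.05) / dee(0.1) == pytest.approx(0.5**0.729)

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError):
            dee(0.0)


def _one_day_nest(worm_lengths_bu, hours, date=dt.date(2021, 6, 1), nest="nest1"):
    items = [
        make_item(length_bu=b, item_id=str(k)) for k, b in enumerate(worm_lengths_bu)
    ]
    visits = (
        [make_visit(items, nest_id=nest, date=date, interval=None, order=1)]
        if items
        else []
    )
    obs = NestObservation(
        nest_id=nest,
        brood_size=5,
        days=(DayRecord(date=date, nestling_age_days=5, recorded_hours=hours, rainfall_mm=0.0),),
    )
    return visits, [obs]


class TestDailyRates:
    def test_simple_rate(self):
        visits, nests = _one_day_nest([2.5] * 10, hours=2.0)
        rates = daily_rates(visits, nests)
        assert rates.loc[0, "worms_per_hour"] == pytest.approx(5.0)

    def test_day_without_visits_is_zero_rate(self):
        visits, nests = _one_day_nest([], hours=2.0)
        rates = daily_rates(visits, nests)
        assert rates.loc[0, "worms_per_hour"] == 0.0

    def test_afdm_rate_sums_evaluations(self):
        visits, nests = _one_day_nest([2.5, 4.0], hours=1.0)  # 50 mm and 80 mm
        rates = daily_rates(visits, nests)
        expected = afdm_from_length(50.0) + afdm_from_length(80.0)
        assert rates.loc[0, "afdm_g_per_hour"] == pytest.approx(expected)


def _rates_frame(nest_rates: dict) -> pd.DataFrame:
    rows = []
    for nest, day_rates in nest_rates.items():
        for k, r in enumerate(day_rates):
            rows.append(
                {
                    "nest_id": nest,
                    "date": dt.date(2021, 6, 1) + dt.timedelta(days=k),
                    "recorded_hours": 1.0,
                    "worms": r,
                    "afdm_g": r * 0.1,
                    "worms_per_hour": r,
                    "afdm_g_per_hour": r * 0.1,
                }
            )
    return pd.DataFrame(rows)


def _nest_obs(nest_ids, brood=5):
    return [
        NestObservation(
            nest_id=n,
            brood_size=brood,
            days=(
                DayRecord(
                    date=dt.date(2021, 6, 1),
                    nestling_age_days=5,
                    recorded_hours=1.0,
                    rainfall_mm=0.0,
                ),
            ),
        )
        for n in nest_ids
    ]


class TestBroodConsumption:
    def test_constant_rate_arithmetic_chain(self):
        """5 worms/h -> 903.75 per brood, 180.75 per nestling, 903.75
        standardized (brood of five)."""
        rates = _rates_frame({"nest1": [5.0, 5.0, 5.0]})
        out = brood_consumption(rates, _nest_obs(["nest1"]), nest_selection="all")
        assert out.per_nest["nest1"].worms == pytest.approx(5 * 15 * 12.05)
        assert out.per_nestling["nest1"].worms == pytest.approx(903.75 / 5)
        assert out.standardized.worms == pytest.approx(903.75)

    def test_mean_of_daily_rates(self):
        """Two days at 4 and 6 worms/h equal a constant 5 worms/h."""
        r1 = _rates_frame({"nest1": [4.0, 6.0]})
        r2 = _rates_frame({"nest1": [5.0, 5.0]})
        obs = _nest_obs(["nest1"])
        a = brood_consumption(r1, obs, nest_selection="all").standardized.worms
        b = brood_consumption(r2, obs, nest_selection="all").standardized.worms
        assert a == pytest.approx(b)

    def test_subset_drops_least_sampled_nest(self):
        rates = _rates_frame(
            {"nest1": [5.0, 5.0, 5.0], "nest2": [9.0], "nest3": [5.0, 5.0]}
        )
        obs = _nest_obs(["nest1", "nest2", "nest3"])
        out = brood_consumption(rates, obs, nest_selection="subset")
        assert out.nests_used == ("nest1", "nest3")
        out_all = brood_consumption(rates, obs, nest_selection="all")
        assert set(out_all.nests_used) == {"nest1", "nest2", "nest3"}

    def test_empty_rates_rejected(self):
        with pytest.raises(ValueError):
            brood_consumption(pd.DataFrame(), _nest_obs(["nest1"]))


class TestParentAndFamily:
    def test_zero_proportion(self):
        assert parent_consumption(0.0).worms == 0.0

    @pytest.mark.parametrize("p, worms", [(0.3, 1989), (0.7, 4642)])
    def test_parent_consumption_scenarios(self, p, worms):
        est = parent_consumption(p)
        assert est.worms == pytest.approx(
            p * 377 * 36.05 / (0.12258 * 16.72), rel=1e-12
        )
        assert est.worms_rounded == worms

    @pytest.mark.parametrize("p, total", [(0.3, 2844), (0.7, 5497), (0.0, 855)])
    def test_family_consumption_printed_values(self, p, total):
        assert family_consumption(p, 855.0).worms_rounded == total

    def test_invalid_proportion_rejected(self):
        for bad in (-0.1, 1.3):
            with pytest.raises(ValueError):
                parent_consumption(bad)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_linearity_in_p(self, p1, p2):
        """family(p2) - family(p1) = parents(p2 - p1) (before rounding)."""
        lo, hi = sorted([p1, p2])
        diff = family_consumption(hi, 855.0).worms - family_consumption(lo, 855.0).worms
        assert diff == pytest.approx(parent_consumption(hi - lo).worms, abs=1e-8)

    def test_worms_biomass_consistency(self):
        """Counts and biomass agree through the mean-worm AFDM constant."""
        est = parent_consumption(0.5)
        assert est.fresh_biomass_g == pytest.approx(
            est.worms * P.mean_worm_afdm_g * P.fresh_to_afdm_ratio
        )


@pytest.mark.parametrize("x, expected", [(0.5, 1), (1.49, 1), (2.5, 3), (-0.5, -1)])
def test_round_half_up(x, expected):
    assert round_half_up(x) == expected
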