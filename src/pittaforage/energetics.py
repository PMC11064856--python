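"""Bioenergetic chain: worm biomass, parental energy budget, and the
consumption extrapolation from observed provisioning rates to a whole
breeding event.

The chain has three stages:

1. **Allometry.**  Earthworm ash-free dry mass (AFDM, g) from length L (mm),
   ``AFDM = exp(3.19 ln L - 15.85)`` (Megascolecidae allometry), and fresh
   mass as ``5.7904 x AFDM``.

2. **Brood consumption.**  For each nest-day, observed worms (and summed
   AFDM) per recorded hour; per-nest day-means are scaled by 15 provisioning
   hours/day and a 12.05-day nestling stage, giving per-brood totals; per
   nestling = total / brood size; the cross-nest mean per-nestling value
   times a standard brood of five gives the standardized brood consumption.

3. **Parent and family consumption.**  Adult daily energy expenditure obeys
   the power law ``DEE = 1092 x BM^0.729`` (BM in kg, DEE in kJ/day).  With
   the pair DEE rounded to 377 kJ/day, a fraction ``p`` of it supplied by
   earthworms, a 36.05-day breeding event (12.05 nestling + 14 incubation +
   10 nest building days), a mean worm of 0.12258 g AFDM and an energy
   density of 16.72 kJ/g AFDM, the parents' worm count is
   ``p * 377 * 36.05 / (0.12258 * 16.72)``; family = standardized brood +
   parents.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .core import FeedingVisit, NestObservation

__all__ = [
    "EnergeticsParams",
    "ConsumptionEstimate",
    "afdm_from_length",
    "fresh_from_afdm",
    "dee",
    "pair_dee",
    "daily_rates",
    "brood_consumption",
    "BroodConsumption",
    "parent_consumption",
    "family_consumption",
    "round_half_up",
]


@dataclass(frozen=True)
class EnergeticsParams:
    """Constants of the bioenergetic chain (defaults are the study values)."""

    allometry_slope: float = 3.19  # AFDM allometry exponent on ln(length mm)
    allometry_intercept: float = -15.85
    fresh_to_afdm_ratio: float = 5.7904  # fresh g per g AFDM
    dee_coefficient: float = 1092.0  # kJ/day at 1 kg
    dee_exponent: float = 0.729
    male_mass_kg: float = 0.109
    female_mass_kg: float = 0.0715
    pair_dee_printed: float = 377.0  # kJ/day, rounded pair total used downstream
    worm_energy_density: float = 16.72  # kJ per g AFDM
    mean_worm_afdm_g: float = 0.12258
    provisioning_hours_per_day: float = 15.0
    nestling_period_days: float = 12.05
    incubation_days: float = 14.0
    nest_building_days: float = 10.0
    standard_brood_size: int = 5

    @property
    def breeding_event_days(self) -> float:
        return self.nestling_period_days + self.incubation_days + self.nest_building_days

    def __post_init__(self) -> None:
        for f in (
            "fresh_to_afdm_ratio",
            "dee_coefficient",
            "male_mass_kg",
            "female_mass_kg",
            "pair_dee_printed",
            "worm_energy_density",
            "mean_worm_afdm_g",
            "provisioning_hours_per_day",
            "nestling_period_days",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero (reporting rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def afdm_from_length(length_mm: float, params: EnergeticsParams = EnergeticsParams()) -> float:
    """Ash-free dry mass (g) of an earthworm from its length in mm."""
    if length_mm <= 0:
        raise ValueError("length must be positive (mm)")
    return math.exp(
        params.allometry_slope * math.log(length_mm) + params.allometry_intercept
    )


def fresh_from_afdm(afdm_g: float, params: EnergeticsParams = EnergeticsParams()) -> float:
    """Fresh mass (g) from AFDM (g)."""
    if afdm_g < 0:
        raise ValueError("AFDM must be non-negative")
    return afdm_g * params.fresh_to_afdm_ratio


def dee(body_mass_kg: float, params: EnergeticsParams = EnergeticsParams()) -> float:
    """Daily energy expenditure (kJ/day) from body mass in kilograms."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be positive (kg)")
    return params.dee_coefficient * body_mass_kg**params.dee_exponent


def pair_dee(params: EnergeticsParams = EnergeticsParams()) -> int:
    """DEE of a breeding pair (male + female), rounded to integer kJ/day."""
    return round_half_up(dee(params.male_mass_kg, params) + dee(params.female_mass_kg, params))


def daily_rates(
    visits: Sequence[FeedingVisit],
    nests: Sequence[NestObservation],
) -> pd.DataFrame:
    """Per nest-day provisioning rates: worms/hour and AFDM g/hour.

    Worm counts include earthworms delivered in mixed loads.  AFDM sums use
    measured worms only (unmeasured lengths carry no biomass); days with
    recorded effort but no visits are valid zero-rate days.  Days recorded
    with non-positive hours are excluded with a warning.
    """
    per_day: dict[tuple[str, object], dict] = {}
    for nest in nests:
        for d in nest.days:
            if d.recorded_hours <= 0:
                warnings.warn(f"nest {nest.nest_id} day {d.date}: zero recorded hours, excluded")
                continue
            per_day[(nest.nest_id, d.date)] = {
                "nest_id": nest.nest_id,
                "date": d.date,
                "recorded_hours": d.recorded_hours,
                "worms": 0,
                "afdm_g": 0.0,
            }
    for v in visits:
        key = (v.nest_id, v.date)
        if key not in per_day:
            raise ValueError(f"visit {v.visit_id} has no matching nest-day record")
        rec = per_day[key]
        for it in v.items:
            if not it.is_earthworm:
                continue
            rec["worms"] += 1
            if it.length_mm is not None:
                rec["afdm_g"] += afdm_from_length(it.length_mm)
    frame = pd.DataFrame(per_day.values())
    frame["worms_per_hour"] = frame["worms"] / frame["recorded_hours"]
    frame["afdm_g_per_hour"] = frame["afdm_g"] / frame["recorded_hours"]
    return frame


@dataclass(frozen=True)
class ConsumptionEstimate:
    """Worm count and fresh biomass for one scope of the consumption budget."""

    scope: str  # brood:<nest>, per-nestling:<nest>, standardized-brood, parents, family
    worms: float
    fresh_biomass_g: float
    diet_proportion: Optional[float] = None  # parents / family scopes only

    @property
    def worms_rounded(self) -> int:
        return round_half_up(self.worms)


@dataclass(frozen=True)
class BroodConsumption:
    """Brood-level consumption estimates derived from observed daily rates."""

    per_nest: dict  # nest_id -> ConsumptionEstimate (scope "brood:<nest>")
    per_nestling: dict  # nest_id -> ConsumptionEstimate
    standardized: ConsumptionEstimate  # mean per-nestling x standard brood
    nests_used: tuple[str, ...]


def brood_consumption(
    rates: pd.DataFrame,
    nests: Sequence[NestObservation],
    params: EnergeticsParams = EnergeticsParams(),
    nest_selection: Literal["all", "subset"] = "subset",
) -> BroodConsumption:
    """Extrapolate observed rates to whole-nestling-stage brood consumption.

    Per nest: mean daily worms/hour x 15 h/day x 12.05 days = brood total;
    divided by brood size = per-nestling total.  The standardized brood
    estimate is the cross-nest mean per-nestling value scaled to a brood of
    five.  ``nest_selection="subset"`` drops the nest with the fewest
    recorded days (ties broken by nest id) before averaging, mirroring the
    use of the three best-sampled nests; ``"all"`` keeps every nest.
    """
    if rates.empty:
        raise ValueError("no nest-day rates supplied")
    brood_sizes = {n.nest_id: n.brood_size for n in nests}
    scale = params.provisioning_hours_per_day * params.nestling_period_days

    per_nest: dict[str, ConsumptionEstimate] = {}
    per_nestling: dict[str, ConsumptionEstimate] = {}
    for nest_id, g in rates.groupby("nest_id"):
        worms = float(g["worms_per_hour"].mean()) * scale
        afdm = float(g["afdm_g_per_hour"].mean()) * scale
        fresh = fresh_from_afdm(afdm, params)
        per_nest[nest_id] = ConsumptionEstimate(f"brood:{nest_id}", worms, fresh)
        b = brood_sizes[nest_id]
        per_nestling[nest_id] = ConsumptionEstimate(
            f"per-nestling:{nest_id}", worms / b, fresh / b
        )

    used = sorted(per_nest)
    if nest_selection == "subset" and len(used) > 1:
        days = rates.groupby("nest_id").size()
        drop = min(used, key=lambda n: (days[n], n))
        used = [n for n in used if n != drop]

    mean_worms = float(np.mean([per_nestling[n].worms for n in used]))
    mean_fresh = float(np.mean([per_nestling[n].fresh_biomass_g for n in used]))
    standardized = ConsumptionEstimate(
        "standardized-brood",
        mean_worms * params.standard_brood_size,
        mean_fresh * params.standard_brood_size,
    )
    return BroodConsumption(
        per_nest=per_nest,
        per_nestling=per_nestling,
        standardized=standardized,
        nests_used=tuple(used),
    )


def parent_consumption(
    p: float, params: EnergeticsParams = EnergeticsParams()
) -> ConsumptionEstimate:
    """Worms consumed by the parent pair over a breeding event.

    ``p`` is the proportion of the adult energy budget supplied by
    earthworms.  Uses the printed (rounded) pair DEE constant, matching the
    published consumption equation.
    """
    if not (0 <= p <= 1):
        raise ValueError(f"diet proportion p={p} outside [0, 1]")
    worms = (
        p
        * params.pair_dee_printed
        * params.breeding_event_days
        / (params.mean_worm_afdm_g * params.worm_energy_density)
    )
    fresh = fresh_from_afdm(worms * params.mean_worm_afdm_g, params)
    return ConsumptionEstimate("parents", worms, fresh, diet_proportion=p)


def family_consumption(
    p: float,
    standardized_brood_worms: float,
    params: EnergeticsParams = EnergeticsParams(),
    standardized_brood_fresh_g: Optional[float] = None,
) -> ConsumptionEstimate:
    """Family total: standardized brood plus parental consumption at ``p``."""
    parents = parent_consumption(p, params)
    worms = standardized_brood_worms + parents.worms
    if standardized_brood_fresh_g is None:
        standardized_brood_fresh_g = fresh_from_afdm(
            standardized_brood_worms * params.mean_worm_afdm_g, params
        )
    fresh = standardized_brood_fresh_g + parents.fresh_biomass_g
    return ConsumptionEstimate("family", worms, fresh, diet_proportion=p)
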