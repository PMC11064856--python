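"""Core domain types and categorisation rules for feeding-visit data.

The observational unit is a parental *feeding visit*: one trip of a parent
bird to the nest carrying a beak-load of prey items.  Items are identified
to one of twelve taxonomic categories (earthworm, centipede, caterpillar,
...) or flagged as unidentifiable/unknown, and their lengths are estimated
in units of the adult beak length (2 cm), quantised to the nearest quarter
beak (0.5 cm).

Visits are classified by food-load content into three mutually exclusive
types:

* ``NoE``   -- no earthworms in the load,
* ``OnlyE`` -- the load consists exclusively of earthworms,
* ``MIX``   -- earthworms plus at least one other prey item.

``YesE`` (any earthworms) is the union of ``OnlyE`` and ``MIX``.
"""

from __future__ import annotations

import datetime as _dt
import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

__all__ = [
    "TAXA",
    "SPECIAL_TAXA",
    "BEAK_LENGTH_CM",
    "VisitType",
    "TimeOfDay",
    "RainCategory",
    "AgeClass",
    "PreyItem",
    "FeedingVisit",
    "DayRecord",
    "NestObservation",
    "classify_visit",
    "categorize_time",
    "categorize_rain",
    "categorize_age",
    "beak_units_to_cm",
    "exclude_first_visits",
]

#: The twelve taxonomic categories used for identified prey.
TAXA = (
    "earthworm",
    "centipede",
    "caterpillar",
    "beetle",
    "insect pupa",
    "dragonfly",
    "arrowhead flatworm",
    "mole cricket",
    "moth",
    "grasshopper",
    "stick insect",
    "snake",
)

#: Labels for items that could not be fully identified.  "unknown" items are
#: retained in the table but excluded from diet-composition denominators.
SPECIAL_TAXA = ("unidentifiable arthropod", "unidentifiable non-earthworm", "unknown")

#: Adult beak length assumed when converting photographic length estimates
#: from beak units to centimetres.
BEAK_LENGTH_CM = 2.0

#: Heaviest rain still counted as "light" (daily cumulative, mm); heavy rain
#: must strictly exceed this.
RAIN_THRESHOLD_MM = 4.0

#: Oldest nestling age (days) in the "young" class.
YOUNG_MAX_AGE = 7

#: Valid nestling age range (days), hatching day = 1.
AGE_RANGE = (1, 13)

#: Observation window (hours of day) for visit clock times.
OBSERVATION_WINDOW = (8, 18)


class VisitType(str, enum.Enum):
    """Food-load classification of a feeding visit."""

    NOE = "NoE"
    ONLYE = "OnlyE"
    MIX = "MIX"


class TimeOfDay(str, enum.Enum):
    MORNING = "morning"
    NOON = "noon"
    AFTERNOON = "afternoon"


class RainCategory(str, enum.Enum):
    LIGHT = "light"
    HEAVY = "heavy"


class AgeClass(str, enum.Enum):
    YOUNG = "young"
    OLD = "old"


def beak_units_to_cm(length_beak_units: float) -> float:
    """Convert a prey length measured in beak units to centimetres.

    Lengths are estimated to the nearest 0.25 beak length and the beak is
    taken to be 2 cm, so valid inputs are positive multiples of 0.25 and the
    result is quantised to 0.5 cm steps.
    """
    if length_beak_units <= 0:
        raise ValueError(f"length must be positive, got {length_beak_units}")
    quarter = length_beak_units * 4
    if not math.isclose(quarter, round(quarter), abs_tol=1e-9):
        raise ValueError(
            f"length {length_beak_units} is not quantised to 0.25 beak units"
        )
    return length_beak_units * BEAK_LENGTH_CM


@dataclass(frozen=True)
class PreyItem:
    """One prey item delivered during one feeding visit.

    ``length_beak_units`` is the primary length datum (quantised to 0.25);
    ``length_cm`` is derived.  ``None`` means the item could not be measured
    (poor light, position in the beak) -- such items are retained but
    excluded from length summaries.  ``n_sundered_pieces`` records how many
    pieces a parent cut the item (practically always an earthworm) into
    before transport; the length is the reconstructed pre-sundering length.
    """

    item_id: str
    taxon: str
    length_beak_units: Optional[float] = None
    n_sundered_pieces: int = 1

    def __post_init__(self) -> None:
        if self.taxon not in TAXA and self.taxon not in SPECIAL_TAXA:
            raise ValueError(f"unrecognised taxon {self.taxon!r}")
        if self.n_sundered_pieces < 1:
            raise ValueError("n_sundered_pieces must be >= 1")
        if self.length_beak_units is not None:
            beak_units_to_cm(self.length_beak_units)  # validates quantisation

    @property
    def is_earthworm(self) -> bool:
        return self.taxon == "earthworm"

    @property
    def length_cm(self) -> Optional[float]:
        if self.length_beak_units is None:
            return None
        return beak_units_to_cm(self.length_beak_units)

    @property
    def length_mm(self) -> Optional[float]:
        cm = self.length_cm
        return None if cm is None else cm * 10.0

    @property
    def is_identified(self) -> bool:
        """True for items that enter diet-composition denominators."""
        return self.taxon != "unknown"


def classify_visit(items: Sequence[PreyItem]) -> VisitType:
    """Classify a food-load by earthworm content.

    ``NoE`` if the load contains no earthworms, ``OnlyE`` if every item is
    an earthworm, ``MIX`` otherwise.  An empty load is malformed.
    """
    if len(items) == 0:
        raise ValueError("a feeding visit must contain at least one prey item")
    worms = sum(1 for it in items if it.is_earthworm)
    if worms == 0:
        return VisitType.NOE
    if worms == len(items):
        return VisitType.ONLYE
    return VisitType.MIX


def categorize_time(clock_time: _dt.time) -> TimeOfDay:
    """Assign a clock time to morning [8,10), noon [10,14) or afternoon [14,18].

    The field protocol only observed nests between 08:00 and 18:00; times
    outside that window are rejected.  Boundaries are half-open on the
    earlier category (10:00 is noon, 14:00 is afternoon) except for the
    closing 18:00, which belongs to the afternoon.
    """
    h = clock_time.hour + clock_time.minute / 60.0
    lo, hi = OBSERVATION_WINDOW
    if not (lo <= h <= hi):
        raise ValueError(
            f"{clock_time} is out of the {lo:02d}:00-{hi:02d}:00 observation window"
        )
    if h < 10:
        return TimeOfDay.MORNING
    if h < 14:
        return TimeOfDay.NOON
    return TimeOfDay.AFTERNOON


def categorize_rain(rainfall_mm: float) -> RainCategory:
    """Categorise daily cumulative precipitation as light (<= 4 mm) or heavy.

    Heavy rain is defined as precipitation *exceeding* 4 mm/day, so exactly
    4 mm is light.
    """
    if rainfall_mm < 0:
        raise ValueError(f"rainfall must be non-negative, got {rainfall_mm}")
    return RainCategory.LIGHT if rainfall_mm <= RAIN_THRESHOLD_MM else RainCategory.HEAVY


def categorize_age(nestling_age_days: int) -> AgeClass:
    """Classify brood age as young (1-7 days) or old (8-13 days)."""
    lo, hi = AGE_RANGE
    if not (lo <= nestling_age_days <= hi):
        raise ValueError(f"nestling age {nestling_age_days} outside {lo}-{hi} days")
    return AgeClass.YOUNG if nestling_age_days <= YOUNG_MAX_AGE else AgeClass.OLD


@dataclass(frozen=True)
class FeedingVisit:
    """One parental visit to the nest with a beak-load of prey.

    ``session_id`` identifies the observation session (nest x observation
    day); the first visit of each session has no preceding inter-visit
    interval and is excluded from interval-based analyses.
    """

    visit_id: str
    nest_id: str
    session_id: str
    date: _dt.date
    clock_time: _dt.time
    items: tuple[PreyItem, ...]
    nestling_age_days: int
    brood_size: int
    rainfall_mm: float
    inter_visit_interval_min: Optional[float] = None
    visit_order: int = field(default=0)

    def __post_init__(self) -> None:
        if len(self.items) == 0:
            raise ValueError(f"visit {self.visit_id}: empty food-load")
        if self.inter_visit_interval_min is not None and self.inter_visit_interval_min <= 0:
            raise ValueError(f"visit {self.visit_id}: interval must be positive")
        if not (3 <= self.brood_size <= 6):
            raise ValueError(f"visit {self.visit_id}: brood size {self.brood_size} outside 3-6")
        categorize_age(self.nestling_age_days)
        categorize_rain(self.rainfall_mm)

    @property
    def visit_type(self) -> VisitType:
        return classify_visit(self.items)

    @property
    def time_of_day(self) -> TimeOfDay:
        return categorize_time(self.clock_time)

    @property
    def rain_category(self) -> RainCategory:
        return categorize_rain(self.rainfall_mm)

    @property
    def age_class(self) -> AgeClass:
        return categorize_age(self.nestling_age_days)

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_earthworms(self) -> int:
        return sum(1 for it in self.items if it.is_earthworm)


@dataclass(frozen=True)
class DayRecord:
    """One nest-day of observation effort and conditions."""

    date: _dt.date
    nestling_age_days: int
    recorded_hours: float
    rainfall_mm: float

    def __post_init__(self) -> None:
        if self.recorded_hours <= 0:
            raise ValueError("recorded_hours must be positive")
        categorize_rain(self.rainfall_mm)


@dataclass(frozen=True)
class NestObservation:
    """Per-nest observation metadata: brood size and per-day effort."""

    nest_id: str
    brood_size: int
    days: tuple[DayRecord, ...]

    def __post_init__(self) -> None:
        if not (3 <= self.brood_size <= 6):
            raise ValueError(f"nest {self.nest_id}: brood size outside 3-6")
        by_date = sorted(self.days, key=lambda d: d.date)
        for a, b in zip(by_date, by_date[1:]):
            if (b.date - a.date).days != b.nestling_age_days - a.nestling_age_days:
                raise ValueError(
                    f"nest {self.nest_id}: nestling age must advance one day per calendar day"
                )

    @property
    def recorded_hours_total(self) -> float:
        return sum(d.recorded_hours for d in self.days)


def exclude_first_visits(visits: Iterable[FeedingVisit]) -> list[FeedingVisit]:
    """Drop the first visit of every observation session.

    The preceding inter-visit interval is undefined for a session's first
    visit, so interval-based analyses use this subset.  Exactly one visit is
    removed per session; the returned visits are in the input order.
    """
    visits = list(visits)
    order: dict[str, list[FeedingVisit]] = {}
    for v in visits:
        order.setdefault(v.session_id, []).append(v)
    firsts = {
        min(vs, key=lambda v: (v.visit_order, v.clock_time)).visit_id
        for vs in order.values()
    }
    return [v for v in visits if v.visit_id not in firsts]
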