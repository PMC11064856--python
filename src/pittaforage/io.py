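"""Delimited-text readers and writers for feeding-visit tables.

The interchange format is a UTF-8 CSV with one row per prey item; visit- and
day-level fields are repeated on every item row.  Columns::

    nest_id, date (ISO-8601), session_order, visit_order, clock_time (HH:MM),
    inter_visit_interval_min (blank for the first visit of a session),
    taxon, is_earthworm (0/1), length_beak_units (blank if unmeasured),
    n_sundered_pieces, nestling_age_days, brood_size, rainfall_mm,
    recorded_hours_day

Reading returns typed, validated records plus a validation report listing
rows that were flagged (unknown taxon, unmeasured length) or dropped.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import pandas as pd

from .core import (
    DayRecord,
    FeedingVisit,
    NestObservation,
    PreyItem,
)

__all__ = [
    "COLUMNS",
    "ValidationReport",
    "read_visits",
    "visits_from_frame",
    "visits_to_frame",
    "write_visits",
]

COLUMNS = [
    "nest_id",
    "date",
    "session_order",
    "visit_order",
    "clock_time",
    "inter_visit_interval_min",
    "taxon",
    "is_earthworm",
    "length_beak_units",
    "n_sundered_pieces",
    "nestling_age_days",
    "brood_size",
    "rainfall_mm",
    "recorded_hours_day",
]


@dataclass
class ValidationReport:
    """Summary of data-quality flags raised while reading a visit table."""

    n_rows: int = 0
    n_visits: int = 0
    n_items: int = 0
    unknown_taxon_rows: list[int] = field(default_factory=list)
    unmeasured_length_rows: list[int] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_visits": self.n_visits,
            "n_items": self.n_items,
            "n_unknown_taxon": len(self.unknown_taxon_rows),
            "unknown_taxon_rows": self.unknown_taxon_rows,
            "n_unmeasured_length": len(self.unmeasured_length_rows),
            "unmeasured_length_rows": self.unmeasured_length_rows,
            "dropped": self.dropped,
        }

    def write_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def summary(self) -> str:
        return (
            f"{self.n_rows} rows -> {self.n_visits} visits / {self.n_items} items; "
            f"{len(self.unknown_taxon_rows)} unknown-taxon items flagged, "
            f"{len(self.unmeasured_length_rows)} unmeasured lengths flagged, "
            f"{len(self.dropped)} rows dropped"
        )


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    return float(value)


def visits_from_frame(
    frame: pd.DataFrame,
) -> tuple[list[FeedingVisit], list[NestObservation], ValidationReport]:
    """Build typed visit and nest-observation records from an item-row table."""
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"visit table missing mandatory columns: {missing}")

    report = ValidationReport(n_rows=len(frame))
    visits: list[FeedingVisit] = []

    key_cols = ["nest_id", "date", "session_order", "visit_order"]
    for (nest_id, date_s, session_order, visit_order), g in frame.groupby(
        key_cols, sort=True
    ):
        first = g.iloc[0]
        try:
            date = _dt.date.fromisoformat(str(date_s))
            hh, mm = str(first["clock_time"]).split(":")
            clock = _dt.time(int(hh), int(mm))
            items = []
            for ridx, row in g.iterrows():
                length = _parse_optional_float(row["length_beak_units"])
                item = PreyItem(
                    item_id=f"{nest_id}:{date_s}:{visit_order}:{len(items) + 1}",
                    taxon=str(row["taxon"]),
                    length_beak_units=length,
                    n_sundered_pieces=int(row["n_sundered_pieces"]),
                )
                if bool(item.is_earthworm) != bool(int(row["is_earthworm"])):
                    raise ValueError(
                        f"row {ridx}: is_earthworm flag inconsistent with taxon "
                        f"{item.taxon!r}"
                    )
                if item.taxon == "unknown":
                    report.unknown_taxon_rows.append(int(ridx))
                if length is None:
                    report.unmeasured_length_rows.append(int(ridx))
                items.append(item)
            visit = FeedingVisit(
                visit_id=f"{nest_id}:{date_s}:{int(visit_order)}",
                nest_id=str(nest_id),
                session_id=f"{nest_id}:{date_s}",
                date=date,
                clock_time=clock,
                items=tuple(items),
                nestling_age_days=int(first["nestling_age_days"]),
                brood_size=int(first["brood_size"]),
                rainfall_mm=float(first["rainfall_mm"]),
                inter_visit_interval_min=_parse_optional_float(
                    first["inter_visit_interval_min"]
                ),
                visit_order=int(visit_order),
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"malformed visit (nest {nest_id}, date {date_s}, "
                f"visit {visit_order}): {exc}"
            ) from exc
        visits.append(visit)

    report.n_visits = len(visits)
    report.n_items = sum(v.n_items for v in visits)

    nests = _nest_observations(frame)
    return visits, nests, report


def _nest_observations(frame: pd.DataFrame) -> list[NestObservation]:
    nests = []
    for nest_id, g in frame.groupby("nest_id", sort=True):
        days = []
        for date_s, d in g.groupby("date", sort=True):
            row = d.iloc[0]
            days.append(
                DayRecord(
                    date=_dt.date.fromisoformat(str(date_s)),
                    nestling_age_days=int(row["nestling_age_days"]),
                    recorded_hours=float(row["recorded_hours_day"]),
                    rainfall_mm=float(row["rainfall_mm"]),
                )
            )
        nests.append(
            NestObservation(
                nest_id=str(nest_id),
                brood_size=int(g.iloc[0]["brood_size"]),
                days=tuple(days),
            )
        )
    return nests


def read_visits(
    path: Union[str, Path],
) -> tuple[list[FeedingVisit], list[NestObservation], ValidationReport]:
    """Read a visit-table CSV into typed records plus a validation report."""
    frame = pd.read_csv(path, dtype={"nest_id": str, "clock_time": str, "date": str})
    return visits_from_frame(frame)


def visits_to_frame(
    visits: list[FeedingVisit], nests: list[NestObservation] | None = None
) -> pd.DataFrame:
    """Serialise typed visits back to the one-row-per-item CSV schema."""
    hours = {}
    if nests:
        for n in nests:
            for d in n.days:
                hours[(n.nest_id, d.date)] = d.recorded_hours
    session_order = {}
    for v in visits:
        dates = session_order.setdefault(v.nest_id, {})
        dates.setdefault(v.date, len(dates) + 1)

    rows = []
    for v in visits:
        for item in v.items:
            rows.append(
                {
                    "nest_id": v.nest_id,
                    "date": v.date.isoformat(),
                    "session_order": session_order[v.nest_id][v.date],
                    "visit_order": v.visit_order,
                    "clock_time": v.clock_time.strftime("%H:%M"),
                    "inter_visit_interval_min": v.inter_visit_interval_min,
                    "taxon": item.taxon,
                    "is_earthworm": int(item.is_earthworm),
                    "length_beak_units": item.length_beak_units,
                    "n_sundered_pieces": item.n_sundered_pieces,
                    "nestling_age_days": v.nestling_age_days,
                    "brood_size": v.brood_size,
                    "rainfall_mm": v.rainfall_mm,
                    "recorded_hours_day": hours.get((v.nest_id, v.date)),
                }
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_visits(
    visits: list[FeedingVisit],
    nests: list[NestObservation],
    path: Union[str, Path],
) -> None:
    visits_to_frame(visits, nests).to_csv(path, index=False)
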