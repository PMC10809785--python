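"""Surveillance calendar: due dates, notifications, pauses, stops, overdue.

A :class:`Schedule` materializes a surveillance plan into dated entries:
for each plan item, due dates are anchor + start_offset + k * interval up to
a horizon or the item's end-age bound.  Follow-up breaks (pregnancy,
intercurrent health events, long trips) use shift-then-respace semantics: a
due date falling inside a pause is delayed to the first day after the pause
and later dates are re-spaced by the interval — a missed examination is
delayed, never dropped.  A permanent stop cancels all pending entries and is
irreversible on the schedule object.

The schedule is a pure function of (plan items, anchors, pauses, stop):
every mutating operation re-materializes the entries, carrying done/notified
marks by (endpoint, occurrence index).
"""

from __future__ import annotations

import copy
import datetime as dt
import json
from dataclasses import dataclass, field
from typing import Optional, Union

from dateutil.relativedelta import relativedelta

from .engine import SurveillancePlan
from .rulebase import Duration

PAUSE_REASONS = ("pregnancy", "intercurrent_health_event", "long_trip", "other")
RECIPIENTS = ("patient", "attending_physician")

DEFAULT_HORIZON_YEARS = 5
DEFAULT_GRACE = Duration(months=3)
DEFAULT_LEAD_TIME_DAYS = 30


class ScheduleError(ValueError):
    pass


@dataclass(frozen=True)
class Pause:
    """Half-open break [start, end); end=None means open-ended (suspended)."""

    start: dt.date
    end: Optional[dt.date]
    reason: str = "other"

    def __post_init__(self) -> None:
        if self.end is not None and not self.start < self.end:
            raise ScheduleError("pause start must precede end")
        if self.reason not in PAUSE_REASONS:
            raise ScheduleError(f"unknown pause reason {self.reason!r}")

    def contains(self, day: dt.date) -> bool:
        return self.start <= day and (self.end is None or day < self.end)

    def overlaps(self, other: "Pause") -> bool:
        a_end = self.end or dt.date.max
        b_end = other.end or dt.date.max
        return self.start < b_end and other.start < a_end


@dataclass(frozen=True)
class ItemSpec:
    """Everything needed to enumerate one item's due dates."""

    endpoint_id: str
    interval: Duration
    first_due: dt.date
    end_bound: Optional[dt.date] = None  # last admissible due date (age bound)


@dataclass
class ScheduleEntry:
    endpoint_id: str
    seq: int
    due_date: dt.date
    recipients: tuple[str, ...] = RECIPIENTS
    status: str = "pending"  # pending | notified | done | cancelled


@dataclass
class Schedule:
    plan_id: str
    horizon: dt.date
    item_specs: list[ItemSpec] = field(default_factory=list)
    pauses: list[Pause] = field(default_factory=list)
    stopped: bool = False
    stop_reason: str = ""
    marks: dict[tuple[str, int], str] = field(default_factory=dict)  # done/notified
    entries: list[ScheduleEntry] = field(default_factory=list)

    def entries_for(self, endpoint_id: str) -> list[ScheduleEntry]:
        return [e for e in self.entries if e.endpoint_id == endpoint_id]

    def due_dates(self, endpoint_id: str) -> list[dt.date]:
        return [e.due_date for e in self.entries_for(endpoint_id)]


def _shift_out_of_pauses(day: dt.date, pauses: list[Pause]) -> Optional[dt.date]:
    """First admissible date >= day outside every pause; None if suspended
    by an open-ended pause."""
    moved = True
    while moved:
        moved = False
        for p in pauses:
            if p.contains(day):
                if p.end is None:
                    return None
                day = p.end
                moved = True
    return day


def _materialize(schedule: Schedule) -> None:
    """Recompute entries from (item_specs, pauses, stopped), keeping marks."""
    entries: list[ScheduleEntry] = []
    for spec in schedule.item_specs:
        limit = schedule.horizon
        if spec.end_bound is not None and spec.end_bound < limit:
            limit = spec.end_bound
        step = spec.interval.as_relativedelta()
        due = spec.first_due
        seq = 0
        while True:
            shifted = _shift_out_of_pauses(due, schedule.pauses)
            if shifted is None or shifted > limit:
                break
            status = schedule.marks.get((spec.endpoint_id, seq), "pending")
            if schedule.stopped and status in ("pending", "notified"):
                status = "cancelled"
            entries.append(
                ScheduleEntry(endpoint_id=spec.endpoint_id, seq=seq, due_date=shifted, status=status)
            )
            due = shifted + step
            seq += 1
    schedule.entries = entries


def build_schedule(
    plan: SurveillancePlan,
    anchors: dict[str, dt.date],
    horizon: Optional[dt.date] = None,
) -> Schedule:
    """Materialize a plan into a schedule.

    ``anchors`` must supply the dates the plan's frequency specs reference:
    ``end_of_treatment`` and/or ``diagnosis``, plus ``birth_date`` whenever a
    fixed-age anchor or an end-age bound is used.  Items a physician removed
    (status ``removed``) are not scheduled.  Raises ScheduleError naming the
    item whose anchor is missing.
    """
    if horizon is None:
        base = anchors.get("end_of_treatment") or anchors.get("diagnosis") or plan.generated_at
        horizon = base + relativedelta(years=DEFAULT_HORIZON_YEARS)
    specs: list[ItemSpec] = []
    for item in plan.items:
        if item.status == "removed":
            continue
        freq = item.frequency
        if freq.anchor == "fixed_age":
            birth = anchors.get("birth_date")
            if birth is None:
                raise ScheduleError(
                    f"item {item.endpoint_id}: fixed_age anchor requires a birth_date anchor"
                )
            anchor_date = birth + relativedelta(days=round(freq.anchor_age * 365.25))
        else:
            anchor_date = anchors.get(freq.anchor)
            if anchor_date is None:
                raise ScheduleError(
                    f"item {item.endpoint_id}: missing required anchor {freq.anchor!r}"
                )
        end_bound: Optional[dt.date] = None
        if freq.end_age is not None:
            birth = anchors.get("birth_date")
            if birth is None:
                raise ScheduleError(
                    f"item {item.endpoint_id}: end-age bound requires a birth_date anchor"
                )
            end_bound = birth + relativedelta(days=round(freq.end_age * 365.25))
        specs.append(
            ItemSpec(
                endpoint_id=item.endpoint_id,
                interval=freq.interval,
                first_due=anchor_date + freq.start_offset.as_relativedelta(),
                end_bound=end_bound,
            )
        )
    schedule = Schedule(plan_id=plan.patient_id, horizon=horizon, item_specs=specs)
    _materialize(schedule)
    return schedule


def apply_pause(
    schedule: Schedule,
    start: dt.date,
    end: Optional[dt.date],
    reason: str = "other",
) -> Schedule:
    """Register a follow-up break and re-space due dates around it.

    Overlapping pauses are rejected.  Returns a new schedule.  On a stopped
    schedule a pause changes nothing (there are no future entries to shift).
    """
    if schedule.stopped:
        return copy.deepcopy(schedule)
    pause = Pause(start=start, end=end, reason=reason)
    for existing in schedule.pauses:
        if pause.overlaps(existing):
            raise ScheduleError(
                f"pause [{start}, {end or 'open'}) overlaps existing "
                f"[{existing.start}, {existing.end or 'open'})"
            )
    new = copy.deepcopy(schedule)
    new.pauses.append(pause)
    _materialize(new)
    return new


def stop_schedule(schedule: Schedule, reason: str) -> Schedule:
    """Permanently stop the planning (e.g. replanning from initial follow-up
    to long-term follow-up).  Cancels every pending entry; irreversible."""
    if schedule.stopped:
        raise ScheduleError("schedule already stopped")
    new = copy.deepcopy(schedule)
    new.stopped = True
    new.stop_reason = reason
    _materialize(new)
    return new


def next_notifications(
    schedule: Schedule,
    window: tuple[dt.date, dt.date],
    mark: bool = True,
) -> list[ScheduleEntry]:
    """Entries due within [window start, window end] that still need a
    notification to the patient and the attending physician.

    With ``mark=True`` the returned entries are marked ``notified``, making
    the operation idempotent: a repeated call returns nothing new.
    """
    if schedule.stopped:
        return []
    start, end = window
    due = [
        e
        for e in schedule.entries
        if e.status == "pending" and start <= e.due_date <= end
    ]
    if mark:
        for e in due:
            e.status = "notified"
            schedule.marks[(e.endpoint_id, e.seq)] = "notified"
    return due


def mark_done(schedule: Schedule, endpoint_id: str, seq: int) -> None:
    """Record that an examination took place."""
    for e in schedule.entries:
        if e.endpoint_id == endpoint_id and e.seq == seq:
            e.status = "done"
            schedule.marks[(endpoint_id, seq)] = "done"
            return
    raise ScheduleError(f"no entry {endpoint_id!r} #{seq}")


def flag_overdue(
    schedule: Schedule,
    as_of: dt.date,
    grace: Duration = DEFAULT_GRACE,
) -> list[ScheduleEntry]:
    """Entries whose due date plus grace period has passed without being
    done — the patients becoming less responsive to follow-up."""
    out = []
    for e in schedule.entries:
        if e.status in ("done", "cancelled"):
            continue
        if e.due_date + grace.as_relativedelta() < as_of:
            out.append(e)
    return out


def schedule_to_dict(schedule: Schedule) -> dict:
    return {
        "plan_id": schedule.plan_id,
        "horizon": schedule.horizon.isoformat(),
        "stopped": schedule.stopped,
        "stop_reason": schedule.stop_reason,
        "item_specs": [
            {
                "endpoint_id": s.endpoint_id,
                "interval": str(s.interval),
                "first_due": s.first_due.isoformat(),
                "end_bound": s.end_bound.isoformat() if s.end_bound else None,
            }
            for s in schedule.item_specs
        ],
        "marks": [
            {"endpoint_id": k[0], "seq": k[1], "status": v}
            for k, v in sorted(schedule.marks.items())
        ],
        "pauses": [
            {
                "start": p.start.isoformat(),
                "end": p.end.isoformat() if p.end else None,
                "reason": p.reason,
            }
            for p in schedule.pauses
        ],
        "entries": [
            {
                "endpoint_id": e.endpoint_id,
                "seq": e.seq,
                "due_date": e.due_date.isoformat(),
                "recipients": list(e.recipients),
                "status": e.status,
            }
            for e in schedule.entries
        ],
    }


def schedule_to_json(schedule: Schedule, **kwargs) -> str:
    return json.dumps(schedule_to_dict(schedule), **kwargs)


def schedule_from_dict(doc: dict) -> Schedule:
    """Inverse of :func:`schedule_to_dict`; entries are re-materialized."""
    schedule = Schedule(
        plan_id=doc["plan_id"],
        horizon=dt.date.fromisoformat(doc["horizon"]),
        item_specs=[
            ItemSpec(
                endpoint_id=s["endpoint_id"],
                interval=Duration.parse(s["interval"]),
                first_due=dt.date.fromisoformat(s["first_due"]),
                end_bound=dt.date.fromisoformat(s["end_bound"]) if s.get("end_bound") else None,
            )
            for s in doc.get("item_specs", ())
        ],
        pauses=[
            Pause(
                start=dt.date.fromisoformat(p["start"]),
                end=dt.date.fromisoformat(p["end"]) if p.get("end") else None,
                reason=p.get("reason", "other"),
            )
            for p in doc.get("pauses", ())
        ],
        stopped=doc.get("stopped", False),
        stop_reason=doc.get("stop_reason", ""),
        marks={(m["endpoint_id"], m["seq"]): m["status"] for m in doc.get("marks", ())},
    )
    _materialize(schedule)
    return schedule
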