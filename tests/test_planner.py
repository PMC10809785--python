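import datetime as dt

import pytest

from survplan.engine import PlanItem, SurveillancePlan
from survplan.planner import (
    ScheduleError,
    apply_pause,
    build_schedule,
    flag_overdue,
    mark_done,
    next_notifications,
    schedule_from_dict,
    schedule_to_dict,
    stop_schedule,
)
from survplan.rulebase import Duration, FrequencySpec


def item(endpoint_id="echo", interval="P2Y", anchor="end_of_treatment",
         offset="P1Y", end_age=None, anchor_age=None, status="proposed"):
    return PlanItem(
        endpoint_id=endpoint_id,
        label=endpoint_id,
        kind="complementary_examination",
        matched_conditions=(("c1", "TRUE"),),
        frequency=FrequencySpec(
            interval=Duration.parse(interval),
            anchor=anchor,
            anchor_age=anchor_age,
            start_offset=Duration.parse(offset) if offset else Duration(),
            end_age=end_age,
        ),
        evidence_level="high",
        data_quality="precise",
        status=status,
    )


def plan_with(*items):
    return SurveillancePlan(
        patient_id="P1",
        generated_at=dt.date(2020, 6, 1),
        rulebase_version="t",
        items=list(items),
    )


ANCHORS = {
    "end_of_treatment": dt.date(2020, 6, 1),
    "diagnosis": dt.date(2019, 10, 1),
    "birth_date": dt.date(2005, 1, 1),
}


class TestBuildSchedule:
    def test_due_dates_arithmetic(self):
        sched = build_schedule(plan_with(item()), ANCHORS, horizon=dt.date(2027, 1, 1))
        assert sched.due_dates("echo") == [
            dt.date(2021, 6, 1), dt.date(2023, 6, 1), dt.date(2025, 6, 1)]

    def test_empty_plan_empty_schedule(self):
        sched = build_schedule(plan_with(), ANCHORS, horizon=dt.date(2027, 1, 1))
        assert sched.entries == []

    def test_end_age_bound_stops_before_birthday(self):
        # annual exam until age 25; patient born 2005 turns 25 on 2030-01-01
        sched = build_schedule(
            plan_with(item(interval="P1Y", end_age=25)),
            ANCHORS, horizon=dt.date(2040, 1, 1))
        birthday_25 = dt.date(2005, 1, 1) + dt.timedelta(days=round(25 * 365.25))
        assert sched.due_dates("echo")  # non-empty
        assert all(d <= birthday_25 for d in sched.due_dates("echo"))

    def test_missing_anchor_names_item(self):
        with pytest.raises(ScheduleError, match="echo"):
            build_schedule(plan_with(item()), {"diagnosis": dt.date(2019, 10, 1)},
                           horizon=dt.date(2027, 1, 1))

    def test_removed_items_not_scheduled(self):
        sched = build_schedule(plan_with(item(status="removed")), ANCHORS,
                               horizon=dt.date(2027, 1, 1))
        assert sched.entries == []

    def test_fixed_age_anchor(self):
        sched = build_schedule(
            plan_with(item(interval="P5Y", anchor="fixed_age", anchor_age=35, offset=None)),
            ANCHORS, horizon=dt.date(2050, 1, 1))
        first = sched.due_dates("echo")[0]
        assert first == dt.date(2005, 1, 1) + dt.timedelta(days=round(35 * 365.25))

    def test_gaps_equal_interval_without_pauses(self):
        sched = build_schedule(plan_with(item(interval="P6M")), ANCHORS,
                               horizon=dt.date(2024, 1, 1))
        dates = sched.due_dates("echo")
        assert all(b > a for a, b in zip(dates, dates[1:]))
        for a, b in zip(dates, dates[1:]):
            assert b == a + Duration.parse("P6M").as_relativedelta()


class TestPauses:
    def make(self):
        return build_schedule(plan_with(item()), ANCHORS, horizon=dt.date(2027, 1, 1))

    def test_shift_then_respace(self):
        sched = apply_pause(self.make(), dt.date(2023, 1, 1), dt.date(2024, 1, 1),
                            reason="pregnancy")
        assert sched.due_dates("echo") == [
            dt.date(2021, 6, 1), dt.date(2024, 1, 1), dt.date(2026, 1, 1)]

    def test_pause_outside_due_dates_is_noop(self):
        base = self.make()
        sched = apply_pause(base, dt.date(2022, 1, 1), dt.date(2022, 3, 1))
        assert sched.due_dates("echo") == base.due_dates("echo")

    def test_open_ended_pause_suspends_future_entries(self):
        sched = apply_pause(self.make(), dt.date(2023, 1, 1), None, reason="other")
        assert sched.due_dates("echo") == [dt.date(2021, 6, 1)]

    def test_overlapping_pause_rejected(self):
        sched = apply_pause(self.make(), dt.date(2023, 1, 1), dt.date(2024, 1, 1))
        with pytest.raises(ScheduleError, match="overlap"):
            apply_pause(sched, dt.date(2023, 6, 1), dt.date(2023, 9, 1))

    def test_no_due_date_inside_any_pause(self):
        sched = apply_pause(self.make(), dt.date(2023, 1, 1), dt.date(2024, 1, 1))
        for e in sched.entries:
            for p in sched.pauses:
                assert not p.contains(e.due_date)


class TestStop:
    def make(self):
        return build_schedule(plan_with(item()), ANCHORS, horizon=dt.date(2027, 1, 1))

    def test_stop_cancels_pending(self):
        sched = stop_schedule(self.make(), "replanning initial -> LTFU")
        assert sched.stopped
        assert all(e.status == "cancelled" for e in sched.entries)

    def test_stop_twice_fails(self):
        sched = stop_schedule(self.make(), "x")
        with pytest.raises(ScheduleError, match="already stopped"):
            stop_schedule(sched, "y")

    def test_notifications_after_stop_empty(self):
        sched = stop_schedule(self.make(), "x")
        assert next_notifications(sched, (dt.date(2020, 1, 1), dt.date(2030, 1, 1))) == []

    def test_pause_after_stop_changes_nothing(self):
        stopped = stop_schedule(self.make(), "x")
        # pause covering a former due date (2023-06-01) still has no effect
        paused = apply_pause(stopped, dt.date(2023, 1, 1), dt.date(2024, 1, 1))
        assert schedule_to_dict(paused) == schedule_to_dict(stopped)

    def test_done_entries_survive_stop(self):
        sched = self.make()
        mark_done(sched, "echo", 0)
        stopped = stop_schedule(sched, "x")
        assert stopped.entries_for("echo")[0].status == "done"


class TestNotifications:
    def make(self):
        return build_schedule(plan_with(item()), ANCHORS, horizon=dt.date(2027, 1, 1))

    def test_window_containing_one_due_date(self):
        sched = self.make()
        due = next_notifications(sched, (dt.date(2021, 1, 1), dt.date(2021, 12, 31)))
        assert len(due) == 1
        assert set(due[0].recipients) == {"patient", "attending_physician"}

    def test_idempotent_marking(self):
        sched = self.make()
        window = (dt.date(2021, 1, 1), dt.date(2021, 12, 31))
        assert len(next_notifications(sched, window)) == 1
        assert next_notifications(sched, window) == []

    def test_window_inside_pause_empty(self):
        sched = apply_pause(self.make(), dt.date(2023, 1, 1), dt.date(2024, 1, 1))
        # original 2023-06-01 due date was shifted out of the pause window
        assert next_notifications(sched, (dt.date(2023, 2, 1), dt.date(2023, 12, 31))) == []


class TestOverdue:
    def make(self):
        return build_schedule(plan_with(item()), ANCHORS, horizon=dt.date(2027, 1, 1))

    def test_grace_arithmetic(self):
        sched = build_schedule(
            plan_with(item(interval="P2Y", offset="P1Y6M")),
            {**ANCHORS, "end_of_treatment": dt.date(2020, 7, 1)},
            horizon=dt.date(2027, 1, 1))
        # first due 2022-01-01; grace 6 months -> overdue from 2022-07-02
        overdue = flag_overdue(sched, dt.date(2023, 1, 1), Duration.parse("P6M"))
        assert [e.due_date for e in overdue] == [dt.date(2022, 1, 1)]

    def test_done_never_overdue(self):
        sched = self.make()
        mark_done(sched, "echo", 0)
        overdue = flag_overdue(sched, dt.date(2030, 1, 1), Duration.parse("P3M"))
        assert all(e.seq != 0 for e in overdue)

    def test_before_first_due_date_empty(self):
        assert flag_overdue(self.make(), dt.date(2021, 1, 1), Duration.parse("P3M")) == []


class TestPurity:
    def test_serialization_round_trip_rematerializes_identically(self):
        sched = apply_pause(
            build_schedule(plan_with(item(), item(endpoint_id="tsh", interval="P1Y")),
                           ANCHORS, horizon=dt.date(2027, 1, 1)),
            dt.date(2023, 1, 1), dt.date(2024, 1, 1))
        mark_done(sched, "tsh", 1)
        again = schedule_from_dict(schedule_to_dict(sched))
        assert schedule_to_dict(again) == schedule_to_dict(sched)

    def test_entry_conservation_through_operations(self):
        sched = build_schedule(plan_with(item(interval="P1Y")), ANCHORS,
                               horizon=dt.date(2026, 1, 1))
        n0 = len(sched.entries)
        mark_done(sched, "echo", 0)
        next_notifications(sched, (dt.date(2022, 1, 1), dt.date(2022, 12, 31)))
        sched = stop_schedule(sched, "x")
        statuses = [e.status for e in sched.entries]
        assert len(statuses) == n0
        assert statuses.count("done") + statuses.count("cancelled") == n0
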