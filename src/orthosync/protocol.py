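"""Assessment protocol: ordered, labelled events on the assessment clock.

The default protocol is a combined orthostatic / neuromuscular session:
10 min supine rest, a 3 min active (self-induced) stand, a short break,
another 10 min supine rest, and a 10 min 70-degree head-up tilt. Four 10 s
maximum prompted thigh contractions ("squeezes") are programmed halfway into
each rest period and shortly after both stands, for six labelled events in
total over roughly 37 minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ScheduleError

ACTIVE_STAND = "ACTIVE_STAND"
HEAD_UP_TILT = "HEAD_UP_TILT"
SQUEEZE_LABELS = ("SQUEEZE_1", "SQUEEZE_2", "SQUEEZE_3", "SQUEEZE_4")
EVENT_LABELS = (ACTIVE_STAND, HEAD_UP_TILT) + SQUEEZE_LABELS

SQUEEZE_DURATION_S = 10.0


@dataclass(frozen=True)
class ProtocolEvent:
    label: str
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def overlaps(self, other: "ProtocolEvent") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s


@dataclass(frozen=True)
class ProtocolSchedule:
    """Ordered events plus the phase boundaries they live in.

    ``phases`` maps phase name (rest1, active_stand, break, rest2, tilt) to
    ``(start_s, end_s)`` on the assessment clock.
    """

    events: tuple[ProtocolEvent, ...]
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)
    total_duration_s: float = 0.0

    def event(self, label: str) -> ProtocolEvent:
        for e in self.events:
            if e.label == label:
                return e
        raise ScheduleError(f"no event labelled {label!r} in schedule")

    @property
    def squeezes(self) -> list[ProtocolEvent]:
        return [e for e in self.events if e.label.startswith("SQUEEZE")]

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "events": [
                {"label": e.label, "start_s": e.start_s, "duration_s": e.duration_s}
                for e in self.events
            ],
            "phases": {k: list(v) for k, v in self.phases.items()},
            "total_duration_s": self.total_duration_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSchedule":
        events = tuple(
            ProtocolEvent(e["label"], float(e["start_s"]), float(e["duration_s"]))
            for e in d["events"]
        )
        phases = {k: (float(v[0]), float(v[1])) for k, v in d.get("phases", {}).items()}
        return cls(events, phases, float(d.get("total_duration_s", 0.0)))

    def to_yaml(self, path: str) -> str:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    @classmethod
    def from_yaml(cls, path: str) -> "ProtocolSchedule":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def build_default_schedule(
    rest1_s: float = 600.0,
    active_stand_s: float = 180.0,
    break_s: float = 180.0,
    rest2_s: float = 600.0,
    tilt_s: float = 600.0,
    squeeze_s: float = SQUEEZE_DURATION_S,
    post_stand_gap_s: float = 30.0,
    tail_s: float = 20.0,
) -> ProtocolSchedule:
    """Construct the six-event assessment schedule.

    Defaults give the canonical session: squeezes 1 and 3 at the midpoints of
    the two rest phases, squeezes 2 and 4 thirty seconds after the active
    stand and the tilt respectively. All phase lengths are overridable;
    overlapping phases or a non-positive squeeze duration raise
    :class:`ScheduleError`.

    The ~10 s tilt-table travel time from 0 to 70 degrees is modelled inside
    the tilt event, not as a separate event.
    """
    if squeeze_s <= 0:
        raise ScheduleError(f"squeeze duration must be positive, got {squeeze_s}")
    for name, v in [
        ("rest1_s", rest1_s),
        ("active_stand_s", active_stand_s),
        ("break_s", break_s),
        ("rest2_s", rest2_s),
        ("tilt_s", tilt_s),
    ]:
        if v <= 0:
            raise ScheduleError(f"{name} must be positive, got {v}")

    rest1 = (0.0, rest1_s)
    as_phase = (rest1[1], rest1[1] + active_stand_s)
    brk = (as_phase[1], as_phase[1] + break_s)
    rest2 = (brk[1], brk[1] + rest2_s)
    tilt = (rest2[1], rest2[1] + tilt_s)

    events = (
        ProtocolEvent("SQUEEZE_1", rest1_s / 2.0, squeeze_s),
        ProtocolEvent(ACTIVE_STAND, as_phase[0], active_stand_s),
        ProtocolEvent("SQUEEZE_2", as_phase[1] + post_stand_gap_s, squeeze_s),
        ProtocolEvent("SQUEEZE_3", rest2[0] + rest2_s / 2.0, squeeze_s),
        ProtocolEvent(HEAD_UP_TILT, tilt[0], tilt_s),
        ProtocolEvent("SQUEEZE_4", tilt[1] + post_stand_gap_s, squeeze_s),
    )
    events = tuple(sorted(events, key=lambda e: e.start_s))
    for a, b in zip(events, events[1:]):
        if a.overlaps(b):
            raise ScheduleError(f"events {a.label} and {b.label} overlap")

    total = events[-1].end_s + tail_s
    schedule = ProtocolSchedule(
        events=events,
        phases={
            "rest1": rest1,
            "active_stand": as_phase,
            "break": brk,
            "rest2": rest2,
            "tilt": tilt,
        },
        total_duration_s=total,
    )
    return schedule


def validate_schedule(schedule: ProtocolSchedule) -> list[str]:
    """Return a list of invariant violations (empty iff the schedule is valid).

    Violations are returned, never raised, so the function can be used both as
    a gate and as a report.
    """
    v: list[str] = []
    events = schedule.events
    if len(events) != 6:
        v.append(f"expected 6 events, found {len(events)}")
    for e in events:
        if e.duration_s <= 0:
            v.append(f"event {e.label} has non-positive duration {e.duration_s}")
        if e.label.startswith("SQUEEZE") and abs(e.duration_s - SQUEEZE_DURATION_S) > 1e-9:
            v.append(
                f"squeeze {e.label} lasts {e.duration_s} s, expected "
                f"{SQUEEZE_DURATION_S} s"
            )
    starts = [e.start_s for e in events]
    if starts != sorted(starts):
        v.append("events are not time-ordered")
    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            if a.overlaps(b):
                v.append(f"overlap between {a.label} and {b.label}")
    if not 35 * 60 <= schedule.total_duration_s <= 40 * 60:
        v.append(
            f"total duration {schedule.total_duration_s / 60:.1f} min outside "
            f"the 35-40 min window"
        )
    return v
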