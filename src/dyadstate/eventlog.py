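"""Data model, validation and CSV I/O for pair-session state-transition event logs.

The joint behavioural state of a dyad is coded 1-4:

    1  both fish under cover
    2  focal fish out of cover, partner under cover
    3  partner out of cover, focal fish under cover
    4  both fish out of cover

Only one fish moves per event, so the permitted transitions form the
4-cycle 1<->2, 1<->3, 2<->4, 3<->4; the diagonals 1<->4 and 2<->3 are
structural zeros.

Event logs are stored as two CSV files at different grains: one row per
transition event (``pair_id,session,time_s,from_state,to_state``) and one
row per pair-session (``pair_id,session,duration_s,initial_state,
focal_boldness,partner_boldness,focal_satiated,category``).  The initial
state and the session duration live in the session file only, so a session
with zero events is representable.  Sessions are half-open intervals
``[0, duration)``: the final sojourn is right-censored and an event at
exactly ``time == duration`` is invalid.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "STATES",
    "PERMITTED_EDGES",
    "FORBIDDEN_EDGES",
    "FOCAL_EDGES",
    "PARTNER_EDGES",
    "EventLogError",
    "TransitionEvent",
    "PairTrajectory",
    "SessionMeta",
    "focal_is_out",
    "partner_is_out",
    "moving_fish",
    "validate_trajectory",
    "read_event_log",
    "read_sessions",
    "write_event_log",
    "write_sessions",
]

STATES: tuple[int, ...] = (1, 2, 3, 4)

#: the 8 permitted directed edges, canonical order (row-major in the Q matrix)
PERMITTED_EDGES: tuple[tuple[int, int], ...] = (
    (1, 2), (1, 3), (2, 1), (2, 4), (3, 1), (3, 4), (4, 2), (4, 3),
)

FORBIDDEN_EDGES: frozenset[tuple[int, int]] = frozenset(
    {(1, 4), (4, 1), (2, 3), (3, 2)}
)

#: edges on which the focal fish is the one that moves
FOCAL_EDGES: frozenset[tuple[int, int]] = frozenset({(1, 2), (2, 1), (3, 4), (4, 3)})
#: edges on which the partner is the one that moves
PARTNER_EDGES: frozenset[tuple[int, int]] = frozenset({(1, 3), (3, 1), (2, 4), (4, 2)})

#: time column write precision (decimal places)
TIME_DECIMALS = 6

CATEGORIES = ("SM", "SL", "BM", "BL", "none")
SESSION_LABELS = ("control", "satiated")


def focal_is_out(state: int) -> bool:
    """True iff the focal fish is out of cover in joint state ``state``."""
    return state in (2, 4)


def partner_is_out(state: int) -> bool:
    """True iff the partner fish is out of cover in joint state ``state``."""
    return state in (3, 4)


def moving_fish(edge: tuple[int, int]) -> str:
    """Which fish moves on a permitted edge: ``"focal"`` or ``"partner"``."""
    if edge in FOCAL_EDGES:
        return "focal"
    if edge in PARTNER_EDGES:
        return "partner"
    raise ValueError(f"not a permitted edge: {edge}")


class EventLogError(ValueError):
    """Raised for malformed or inconsistent event-log input.

    ``row`` is the 1-based row number in the offending CSV file (header = row 1)
    when applicable.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class TransitionEvent:
    """A single state-transition event at ``time`` seconds from session start."""

    time: float
    from_state: int
    to_state: int

    @property
    def edge(self) -> tuple[int, int]:
        return (self.from_state, self.to_state)


@dataclass
class PairTrajectory:
    """Ordered, validated transition-event list for one pair-session."""

    pair_id: str
    session: str
    duration: float
    initial_state: int
    events: list[TransitionEvent] = field(default_factory=list)

    @property
    def final_state(self) -> int:
        return self.events[-1].to_state if self.events else self.initial_state

    def state_at(self, t: float) -> int:
        """State occupied at time ``t`` (events take effect at their timestamp)."""
        state = self.initial_state
        for ev in self.events:
            if ev.time > t:
                break
            state = ev.to_state
        return state


@dataclass
class SessionMeta:
    """Per-session metadata: duration, initial state, boldness, satiation arm."""

    pair_id: str
    session: str
    duration: float
    initial_state: int = 1
    focal_boldness: float = float("nan")
    partner_boldness: float = float("nan")
    focal_satiated: int = 0
    category: str = "none"


def validate_trajectory(t: PairTrajectory) -> list[str]:
    """Check every trajectory invariant; return a list of violation messages.

    Returns an empty list iff the trajectory is valid.  Never raises; each
    message names the violated invariant and the offending event index.
    """
    violations: list[str] = []
    if t.duration <= 0:
        violations.append(f"non-positive duration {t.duration}")
    if t.initial_state not in STATES:
        violations.append(f"invalid initial state {t.initial_state}")
    prev_time = 0.0
    state = t.initial_state
    for k, ev in enumerate(t.events):
        if ev.from_state not in STATES or ev.to_state not in STATES:
            violations.append(f"invalid state label at index {k}")
            continue
        if ev.from_state == ev.to_state:
            violations.append(f"self-transition at index {k}")
        elif ev.edge in FORBIDDEN_EDGES:
            violations.append(
                f"forbidden edge {ev.from_state}->{ev.to_state} at index {k}"
            )
        if ev.time <= prev_time:  # prev_time starts at 0, so t=0 is invalid too
            violations.append(f"non-increasing time at index {k}")
        if ev.time >= t.duration:
            violations.append(f"event at index {k} at/after session end")
        if ev.from_state != state:
            violations.append(
                f"chain inconsistency at index {k}: "
                f"from_state {ev.from_state}, expected {state}"
            )
        prev_time = ev.time
        state = ev.to_state
    return violations


def _parse_state(text: str, row: int, column: str) -> int:
    try:
        value = int(text)
    except ValueError:
        raise EventLogError(f"non-integer {column} {text!r}", row) from None
    if value not in STATES:
        raise EventLogError(f"{column} {value} not in 1..4", row)
    return value


def read_sessions(path: str | Path) -> list[SessionMeta]:
    """Read the per-session metadata CSV."""
    metas: list[SessionMeta] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"pair_id", "session", "duration_s", "initial_state"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise EventLogError(f"sessions file missing columns {sorted(missing)}", 1)
        for rownum, rec in enumerate(reader, start=2):
            try:
                duration = float(rec["duration_s"])
            except ValueError:
                raise EventLogError(
                    f"non-numeric duration {rec['duration_s']!r}", rownum
                ) from None
            if duration <= 0:
                raise EventLogError(f"non-positive duration {duration}", rownum)
            meta = SessionMeta(
                pair_id=rec["pair_id"],
                session=rec["session"],
                duration=duration,
                initial_state=_parse_state(rec["initial_state"], rownum, "initial_state"),
                focal_boldness=float(rec.get("focal_boldness") or "nan"),
                partner_boldness=float(rec.get("partner_boldness") or "nan"),
                focal_satiated=int(rec.get("focal_satiated") or 0),
                category=rec.get("category") or "none",
            )
            if meta.focal_satiated not in (0, 1):
                raise EventLogError(f"focal_satiated must be 0/1", rownum)
            if meta.focal_satiated == 1 and meta.session == "control":
                raise EventLogError("focal_satiated=1 on a control session", rownum)
            metas.append(meta)
    keys = [(m.pair_id, m.session) for m in metas]
    if len(set(keys)) != len(keys):
        raise EventLogError("duplicate (pair_id, session) in sessions file")
    return metas


def read_event_log(
    events_path: str | Path, sessions_path: str | Path
) -> list[PairTrajectory]:
    """Read and validate trajectories from the events + sessions CSV pair.

    Every (pair_id, session) listed in the sessions file yields one
    trajectory, in session-file order; a session with no event rows becomes a
    zero-event trajectory held at its initial state.  Any invariant violation
    raises :class:`EventLogError` carrying the offending row number of the
    events file.
    """
    metas = read_sessions(sessions_path)
    by_key: dict[tuple[str, str], list[tuple[int, TransitionEvent]]] = {
        (m.pair_id, m.session): [] for m in metas
    }
    with open(events_path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"pair_id", "session", "time_s", "from_state", "to_state"}
        missing = required - set(reader.fieldnames or ())
        if missing:
            raise EventLogError(f"events file missing columns {sorted(missing)}", 1)
        for rownum, rec in enumerate(reader, start=2):
            key = (rec["pair_id"], rec["session"])
            if key not in by_key:
                raise EventLogError(
                    f"event for unknown session {key}", rownum
                )
            try:
                time = float(rec["time_s"])
            except ValueError:
                raise EventLogError(
                    f"non-numeric time {rec['time_s']!r}", rownum
                ) from None
            ev = TransitionEvent(
                time=time,
                from_state=_parse_state(rec["from_state"], rownum, "from_state"),
                to_state=_parse_state(rec["to_state"], rownum, "to_state"),
            )
            if ev.edge in FORBIDDEN_EDGES or ev.from_state == ev.to_state:
                raise EventLogError(
                    f"forbidden edge {ev.from_state}->{ev.to_state}", rownum
                )
            by_key[key].append((rownum, ev))

    trajectories: list[PairTrajectory] = []
    for meta in metas:
        rows = by_key[(meta.pair_id, meta.session)]
        traj = PairTrajectory(
            pair_id=meta.pair_id,
            session=meta.session,
            duration=meta.duration,
            initial_state=meta.initial_state,
            events=[ev for _, ev in rows],
        )
        # re-run the full validator so the error names the offending CSV row
        violations = validate_trajectory(traj)
        if violations:
            # find the event index named in the first violation, map to row
            msg = violations[0]
            row = None
            if "index" in msg:
                idx = int(msg.rsplit("index", 1)[1].split(":")[0])
                row = rows[idx][0]
            raise EventLogError(
                f"{meta.pair_id}/{meta.session}: {msg}", row
            )
        trajectories.append(traj)
    return trajectories


def write_event_log(
    trajectories: Iterable[PairTrajectory], events_path: str | Path
) -> None:
    """Write the events CSV; times are recorded to 6 decimal places."""
    with open(events_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair_id", "session", "time_s", "from_state", "to_state"])
        for traj in trajectories:
            for ev in traj.events:
                writer.writerow(
                    [
                        traj.pair_id,
                        traj.session,
                        f"{ev.time:.{TIME_DECIMALS}f}",
                        ev.from_state,
                        ev.to_state,
                    ]
                )


def write_sessions(metas: Iterable[SessionMeta], sessions_path: str | Path) -> None:
    """Write the per-session metadata CSV."""
    with open(sessions_path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "pair_id",
                "session",
                "duration_s",
                "initial_state",
                "focal_boldness",
                "partner_boldness",
                "focal_satiated",
                "category",
            ]
        )
        for m in metas:
            writer.writerow(
                [
                    m.pair_id,
                    m.session,
                    f"{m.duration:.{TIME_DECIMALS}f}",
                    m.initial_state,
                    f"{m.focal_boldness:.6f}",
                    f"{m.partner_boldness:.6f}",
                    m.focal_satiated,
                    m.category,
                ]
            )
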