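"""Behavioural summaries derived from pair trajectories.

Covers boldness scoring, merging per-fish leave/return streams into joint
states, sufficient statistics of the transition process, the trip taxonomy
(attempted initiations, joint-trip initiations, follows) and per-fish
session summaries, plus the boldness-ratio pair categories.

Trip taxonomy
-------------
Every leave event opens an out-of-cover bout for the mover; the bout closes
at the mover's next return (or is censored at session end).  Records:

* a leave from state 1 that the partner does not join before the leaver
  returns (i.e. the next event is the leaver's return, or the session ends)
  is a failed attempted initiation;
* every entry into state 4 is one joint trip: the mover is credited a
  *follow* and the fish already out is credited a *joint-trip initiation*
  whose start time is that fish's current bout start.  This bout-local rule
  counts each re-entry of the partner (e.g. state path 2-4-2-4) as a fresh
  follow, with a matching initiation credit, so the ledger identities

      n_joint_initiations(fish)  == n_follows(other fish)
      n_attempted_initiations    == n_joint_initiations + n_failed

  hold exactly on every trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .eventlog import (
    PERMITTED_EDGES,
    STATES,
    PairTrajectory,
    TransitionEvent,
    focal_is_out,
    moving_fish,
    partner_is_out,
)

__all__ = [
    "BoldnessScore",
    "SufficientStats",
    "TripRecord",
    "FishSummary",
    "SessionSummary",
    "boldness_score",
    "derive_states",
    "sufficient_statistics",
    "classify_trips",
    "session_summary",
    "categorize_pair",
]

#: edges whose mover leaves cover / returns to cover
LEAVE_EDGES = frozenset({(1, 2), (1, 3), (2, 4), (3, 4)})
RETURN_EDGES = frozenset({(2, 1), (3, 1), (4, 2), (4, 3)})

#: entries into the both-out state, keyed by mover
JOIN_EDGES = {(2, 4): "partner", (3, 4): "focal"}


@dataclass(frozen=True)
class BoldnessScore:
    """Proportion of time spent out of cover during a solo observation."""

    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"boldness score {self.value} outside [0, 1]")


def boldness_score(
    out_intervals: Sequence[tuple[float, float]], duration: float
) -> BoldnessScore:
    """Score boldness as total out-of-cover time divided by ``duration``.

    ``out_intervals`` must be disjoint, ordered (start, end) pairs within
    ``[0, duration)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    total = 0.0
    prev_end = 0.0
    for k, (start, end) in enumerate(out_intervals):
        if start < prev_end:
            raise ValueError(f"overlapping or unordered interval at index {k}")
        if end <= start:
            raise ValueError(f"empty or inverted interval at index {k}")
        if end > duration:
            raise ValueError(f"interval at index {k} extends beyond duration")
        total += end - start
        prev_end = end
    return BoldnessScore(total / duration)


def derive_states(
    focal_leave_return_times: Sequence[float],
    partner_leave_return_times: Sequence[float],
    duration: float,
    pair_id: str = "pair",
    session: str = "control",
    break_ties: str = "error",
    tie_shift: float = 0.01,
) -> PairTrajectory:
    """Merge two per-fish leave/return streams into a joint-state trajectory.

    Each stream alternates leave, return, leave, ... and the pair starts with
    both fish under cover (state 1).  Equal timestamps across the two fish are
    rejected (``break_ties="error"``) or resolved by shifting the second
    fish's event ``tie_shift`` seconds later (``break_ties="shift"``).
    """
    if break_ties not in ("error", "shift"):
        raise ValueError("break_ties must be 'error' or 'shift'")

    def check_stream(times: Sequence[float], who: str) -> list[float]:
        out = list(times)
        prev = 0.0
        for k, t in enumerate(out):
            if t <= prev:
                raise ValueError(f"{who} stream not strictly increasing at index {k}")
            if t >= duration:
                raise ValueError(f"{who} event at index {k} at/after session end")
            prev = t
        return out

    focal = check_stream(focal_leave_return_times, "focal")
    partner = check_stream(partner_leave_return_times, "partner")

    merged: list[tuple[float, str]] = [(t, "focal") for t in focal]
    merged += [(t, "partner") for t in partner]
    merged.sort(key=lambda item: item[0])
    for k in range(1, len(merged)):
        if merged[k][0] == merged[k - 1][0]:
            if break_ties == "error":
                raise ValueError(
                    f"simultaneous events at t={merged[k][0]} across fish"
                )
            merged[k] = (merged[k][0] + tie_shift, merged[k][1])
            merged.sort(key=lambda item: item[0])

    state = 1
    f_out = False
    p_out = False
    events: list[TransitionEvent] = []
    for t, who in merged:
        if who == "focal":
            f_out = not f_out
        else:
            p_out = not p_out
        new_state = 1 + (1 if f_out else 0) + (2 if p_out else 0)
        events.append(TransitionEvent(time=t, from_state=state, to_state=new_state))
        state = new_state
    return PairTrajectory(
        pair_id=pair_id,
        session=session,
        duration=duration,
        initial_state=1,
        events=events,
    )


@dataclass
class SufficientStats:
    """Transition counts and sojourn totals for one trajectory or pool.

    ``counts[(i, j)]`` is the number of observed i->j events; ``sojourn[i]``
    is the total time spent in state i including the right-censored final
    sojourn, so ``sum(sojourn.values()) == duration``.
    """

    counts: dict[tuple[int, int], int]
    sojourn: dict[int, float]
    duration: float

    @classmethod
    def empty(cls, duration: float = 0.0) -> "SufficientStats":
        return cls(
            counts={e: 0 for e in PERMITTED_EDGES},
            sojourn={s: 0.0 for s in STATES},
            duration=duration,
        )

    def add(self, other: "SufficientStats") -> "SufficientStats":
        for e in PERMITTED_EDGES:
            self.counts[e] += other.counts[e]
        for s in STATES:
            self.sojourn[s] += other.sojourn[s]
        self.duration += other.duration
        return self


def sufficient_statistics(t: PairTrajectory) -> SufficientStats:
    """Count transitions and accumulate sojourn time per state.

    The final sojourn (from the last event to session end) is included, so
    the sojourn totals always sum to the session duration.
    """
    stats = SufficientStats.empty(duration=t.duration)
    state = t.initial_state
    prev_time = 0.0
    for ev in t.events:
        stats.counts[ev.edge] += 1
        stats.sojourn[state] += ev.time - prev_time
        state = ev.to_state
        prev_time = ev.time
    stats.sojourn[state] += t.duration - prev_time
    return stats


@dataclass
class TripRecord:
    """One classified trip (or initiation attempt) by one fish."""

    actor: str  # "focal" | "partner"
    kind: str  # "attempted_initiation_failed" | "joint_trip_initiation" | "follow"
    start_time: float
    end_time: float | None  # None when censored at session end
    censored: bool = False


def classify_trips(t: PairTrajectory) -> list[TripRecord]:
    """Classify every trip in a trajectory per the bout-local taxonomy.

    See the module docstring for the rules.  Records are returned in order of
    creation (event order); a record's end time is the actor's next return to
    cover, or ``None`` (censored) if the actor is still out at session end.
    """
    records: list[TripRecord] = []
    # open records per fish, to be closed at that fish's next return
    open_records: dict[str, list[TripRecord]] = {"focal": [], "partner": []}
    bout_start = {
        "focal": 0.0 if focal_is_out(t.initial_state) else None,
        "partner": 0.0 if partner_is_out(t.initial_state) else None,
    }
    # a solo leave from state 1 awaiting resolution by the next event
    pending: TripRecord | None = None

    for ev in t.events:
        mover = moving_fish(ev.edge)
        other = "partner" if mover == "focal" else "focal"
        upgraded = False
        if pending is not None and ev.edge in JOIN_EDGES and pending.actor == other:
            # the solo leaver was joined immediately: upgrade its attempt
            pending.kind = "joint_trip_initiation"
            upgraded = True
        pending = None

        if ev.edge in LEAVE_EDGES:
            if ev.from_state == 1:
                rec = TripRecord(
                    actor=mover,
                    kind="attempted_initiation_failed",
                    start_time=ev.time,
                    end_time=None,
                )
                records.append(rec)
                open_records[mover].append(rec)
                pending = rec
            else:
                # entry into state 4: the mover follows, and the fish already
                # out is credited one joint-trip initiation for its bout
                # (unless the immediate-upgrade above just did exactly that)
                rec = TripRecord(
                    actor=mover, kind="follow", start_time=ev.time, end_time=None
                )
                records.append(rec)
                open_records[mover].append(rec)
                if not upgraded:
                    start = bout_start[other] if bout_start[other] is not None else 0.0
                    init = TripRecord(
                        actor=other,
                        kind="joint_trip_initiation",
                        start_time=start,
                        end_time=None,
                    )
                    records.append(init)
                    open_records[other].append(init)
            bout_start[mover] = ev.time
        else:
            # mover returns to cover: close all of its open records
            for rec in open_records[mover]:
                rec.end_time = ev.time
            open_records[mover].clear()
            bout_start[mover] = None

    for who in ("focal", "partner"):
        for rec in open_records[who]:
            rec.censored = True
    return records


@dataclass
class FishSummary:
    prop_time_out: float = 0.0
    n_trips: int = 0
    n_attempted_initiations: int = 0
    n_joint_initiations: int = 0
    n_follows: int = 0
    n_failed_initiations: int = 0


@dataclass
class SessionSummary:
    """Per-fish behavioural aggregates for one pair-session."""

    pair_id: str
    session: str
    duration: float
    focal: FishSummary = field(default_factory=FishSummary)
    partner: FishSummary = field(default_factory=FishSummary)

    def fish(self, who: str) -> FishSummary:
        return self.focal if who == "focal" else self.partner


def session_summary(t: PairTrajectory) -> SessionSummary:
    """Aggregate time-out proportions and trip-taxonomy counts per fish."""
    stats = sufficient_statistics(t)
    trips = classify_trips(t)
    summary = SessionSummary(pair_id=t.pair_id, session=t.session, duration=t.duration)
    T = stats.sojourn
    summary.focal.prop_time_out = (T[2] + T[4]) / t.duration
    summary.partner.prop_time_out = (T[3] + T[4]) / t.duration
    N = stats.counts
    summary.focal.n_trips = N[(1, 2)] + N[(3, 4)]
    summary.partner.n_trips = N[(1, 3)] + N[(2, 4)]
    for rec in trips:
        fs = summary.fish(rec.actor)
        if rec.kind == "follow":
            fs.n_follows += 1
        elif rec.kind == "joint_trip_initiation":
            fs.n_joint_initiations += 1
        else:
            fs.n_failed_initiations += 1
    for fs in (summary.focal, summary.partner):
        fs.n_attempted_initiations = fs.n_joint_initiations + fs.n_failed_initiations
    return summary


def categorize_pair(focal_boldness: float, partner_boldness: float) -> str:
    """Assign the boldness-ratio pairing category.

    With r = focal / partner: SM if 0.70 <= r <= 0.85, SL if r < 0.50,
    BM if 1.15 <= r <= 1.40, BL if r > 2.00; otherwise ``"none"``.  Band
    endpoints are inclusive; the 0.50 and 2.00 cutoffs are strict.
    """
    focal = focal_boldness.value if isinstance(focal_boldness, BoldnessScore) else focal_boldness
    partner = (
        partner_boldness.value
        if isinstance(partner_boldness, BoldnessScore)
        else partner_boldness
    )
    if partner <= 0:
        raise ValueError("partner boldness must be positive")
    r = focal / partner
    if r < 0.50:
        return "SL"
    if 0.70 <= r <= 0.85:
        return "SM"
    if 1.15 <= r <= 1.40:
        return "BM"
    if r > 2.00:
        return "BL"
    return "none"


def summaries_records(
    summaries: Iterable[SessionSummary],
) -> list[dict]:
    """Flatten summaries to one record per (pair-session, fish) for CSV output."""
    rows = []
    for s in summaries:
        for who in ("focal", "partner"):
            fs = s.fish(who)
            rows.append(
                {
                    "pair_id": s.pair_id,
                    "session": s.session,
                    "fish": who,
                    "prop_time_out": fs.prop_time_out,
                    "n_trips": fs.n_trips,
                    "n_attempted_initiations": fs.n_attempted_initiations,
                    "n_joint_initiations": fs.n_joint_initiations,
                    "n_follows": fs.n_follows,
                    "n_failed_initiations": fs.n_failed_initiations,
                }
            )
    return rows
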