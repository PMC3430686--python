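"""Independent brute-force references used by the test suite.

These deliberately avoid the package's event-walking implementations:
trajectories are first converted to per-fish out-of-cover intervals, and the
verbal classification rules are applied to the intervals.
"""

from __future__ import annotations

from dyadstate.eventlog import PairTrajectory, focal_is_out, partner_is_out


def out_intervals(trajectory: PairTrajectory, who: str) -> list[tuple[float, float | None]]:
    """Per-fish out-of-cover intervals [start, end); end None if censored."""
    is_out = focal_is_out if who == "focal" else partner_is_out
    intervals: list[tuple[float, float | None]] = []
    open_start: float | None = 0.0 if is_out(trajectory.initial_state) else None
    state = trajectory.initial_state
    for ev in trajectory.events:
        was_out, now_out = is_out(state), is_out(ev.to_state)
        if not was_out and now_out:
            open_start = ev.time
        elif was_out and not now_out:
            intervals.append((open_start, ev.time))
            open_start = None
        state = ev.to_state
    if open_start is not None:
        intervals.append((open_start, None))
    return intervals


def brute_force_trips(trajectory: PairTrajectory) -> list[tuple]:
    """Reference trip classification from per-fish intervals.

    Rules, applied literally to the two interval lists:

    * a fish leaving while the other is under cover makes an attempted
      initiation; it becomes a joint-trip initiation if the other fish
      leaves before the first fish has returned, else it failed;
    * a fish leaving while the other is already out is a follow, and the
      already-out fish is credited one joint-trip initiation (for its
      current interval) per such join.

    Returns an unordered list of (actor, kind, start, end, censored) tuples
    where end is None for censored trips.
    """
    ivals = {w: out_intervals(trajectory, w) for w in ("focal", "partner")}

    def covers(who: str, t: float) -> tuple[float, float | None] | None:
        """The interval of `who` strictly containing time t (start < t)."""
        for s, e in ivals[who]:
            if s < t and (e is None or t < e):
                return (s, e)
        return None

    records: list[tuple] = []
    for who in ("focal", "partner"):
        other = "partner" if who == "focal" else "focal"
        for start, end in ivals[who]:
            censored = end is None
            other_at_start = covers(other, start)
            # events occur at time > 0, so an interval starting at 0 means
            # the fish was out at session start (no leave event happened)
            opened_by_leave = start > 0.0
            # joins of this interval: other-fish leaves strictly inside it
            joins = [
                s
                for s, _ in ivals[other]
                if s > start and (end is None or s < end)
            ]
            if opened_by_leave:
                if other_at_start is not None:
                    records.append((who, "follow", start, end, censored))
                    for _ in joins:
                        records.append(
                            (who, "joint_trip_initiation", start, end, censored)
                        )
                else:
                    if joins:
                        for _ in joins:
                            records.append(
                                (who, "joint_trip_initiation", start, end, censored)
                            )
                    else:
                        records.append(
                            (who, "attempted_initiation_failed", start, end, censored)
                        )
            else:
                # out since session start: joins still credit initiations
                for _ in joins:
                    records.append((who, "joint_trip_initiation", start, end, censored))
    return records


def trips_as_tuples(records) -> list[tuple]:
    """Normalize package TripRecords to comparable tuples."""
    return [
        (r.actor, r.kind, r.start_time, r.end_time, r.censored) for r in records
    ]


def enumerate_chain_sequences(max_events: int):
    """All chain-consistent state paths of <= max_events permitted moves,
    from every initial state.  Yields (initial_state, [states...])."""
    from dyadstate.eventlog import PERMITTED_EDGES

    succ = {s: [j for (i, j) in PERMITTED_EDGES if i == s] for s in (1, 2, 3, 4)}

    def extend(path):
        yield path
        if len(path) - 1 < max_events:
            for nxt in succ[path[-1]]:
                yield from extend(path + [nxt])

    for s0 in (1, 2, 3, 4):
        for path in extend([s0]):
            yield s0, path[1:]
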