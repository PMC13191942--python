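"""Interval reconstruction and queries — the computational core.

Coded button presses are step changes: a press at time t puts its channel
into the pressed state until the next press on that channel.  This module
turns per-channel event streams into half-open ``[start, end)`` intervals
that tile the observed time exactly, aligns the three channels, and answers
the two queries every exposure metric needs: *how many mouthing contacts*
(maximal non-sentinel runs on the OBJECT channel) and *how much time in a
set of states*, optionally intersected with a second channel.

All interval arithmetic is exact; the half-open convention means boundary
instants are never double counted.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

from .mlats import Session, concatenate_session
from .palette import CHANNELS, CONTEXT, LOCATION, OBJECT, PaletteSchema


@dataclass(frozen=True)
class StateInterval:
    channel: str
    state: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError(
                f"degenerate interval [{self.start_s}, {self.end_s}) on {self.channel}"
            )

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class Contact:
    """One mouthing episode: a maximal non-sentinel run on the OBJECT channel."""

    object_state: str
    group: str
    onset_s: float
    end_s: float
    location_at_onset: str
    context_at_onset: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


@dataclass(frozen=True)
class ChildTimeline:
    """Aligned per-channel intervals for one child (campaigns pooled)."""

    child_id: str
    intervals: dict[str, tuple[StateInterval, ...]]
    observed_s: float
    not_in_view_s: float

    def __post_init__(self) -> None:
        for ch, ivs in self.intervals.items():
            total = sum(iv.length_s for iv in ivs)
            if abs(total - self.observed_s) > 1e-6:
                raise ValueError(
                    f"channel {ch} intervals cover {total}s, observed {self.observed_s}s"
                )
        if self.not_in_view_s > self.observed_s + 1e-9:
            raise ValueError("NotInView time exceeds observed time")

    def channel(self, ch: str) -> tuple[StateInterval, ...]:
        return self.intervals[ch]

    @property
    def observable_s(self) -> float:
        """Observed time with NotInView removed."""
        return self.observed_s - self.not_in_view_s


def events_to_intervals(
    events: Sequence[tuple[float, str]], duration_s: float, channel: str = OBJECT
) -> tuple[StateInterval, ...]:
    """Expand a time-ordered event stream into merged tiling intervals.

    Consecutive same-state runs merge; if several presses share a timestamp
    the last one wins (an instantaneous press has zero duration).  The final
    interval closes at ``duration_s``.
    """
    if not events:
        raise ValueError("empty event stream")
    if events[0][0] != 0.0:
        raise ValueError(f"stream must open at t=0, starts at t={events[0][0]}")
    out: list[StateInterval] = []

    def emit(state: str, start: float, end: float) -> None:
        if out and out[-1].state == state and out[-1].end_s == start:
            out[-1] = StateInterval(channel, state, out[-1].start_s, end)
        else:
            out.append(StateInterval(channel, state, start, end))

    cur_state = events[0][1]
    cur_start = 0.0
    for t, state in events[1:]:
        if t < cur_start:
            raise ValueError("events out of order")
        if state == cur_state:
            continue
        if t == cur_start:
            cur_state = state  # same-instant override: last press wins
            continue
        if t >= duration_s:
            break
        emit(cur_state, cur_start, t)
        cur_state, cur_start = state, t
    if cur_start < duration_s:
        emit(cur_state, cur_start, duration_s)
    return tuple(out)


def _merge_adjacent(ivs: Iterable[StateInterval]) -> tuple[StateInterval, ...]:
    out: list[StateInterval] = []
    for iv in ivs:
        if out and out[-1].state == iv.state and out[-1].end_s == iv.start_s:
            out[-1] = StateInterval(iv.channel, iv.state, out[-1].start_s, iv.end_s)
        else:
            out.append(iv)
    return tuple(out)


def timeline_from_sessions(
    sessions: Sequence[Session], schema: PaletteSchema, child_id: str | None = None
) -> ChildTimeline:
    """Build one pooled timeline from a child's sessions (both campaigns).

    Sessions are laid end to end on a cumulative clock; states never carry
    across session boundaries (each clip restates them), but identical states
    meeting at a boundary merge into one interval.
    """
    if not sessions:
        raise ValueError("no sessions given")
    cid = child_id or sessions[0].child_id
    per_channel: dict[str, list[StateInterval]] = {ch: [] for ch in CHANNELS}
    offset = 0.0
    for sess in sessions:
        if sess.child_id != cid:
            raise ValueError(f"session {sess.session_id} is for child {sess.child_id}, not {cid}")
        streams, dur = concatenate_session(sess, schema)
        for ch in CHANNELS:
            for iv in events_to_intervals(streams[ch], dur, ch):
                per_channel[ch].append(
                    StateInterval(
                        ch,
                        iv.state,
                        round(offset + iv.start_s, 3),
                        round(offset + iv.end_s, 3),
                    )
                )
        offset = round(offset + dur, 3)
    merged = {ch: _merge_adjacent(per_channel[ch]) for ch in CHANNELS}
    niv = sum(
        iv.length_s for iv in merged[OBJECT] if iv.state == schema.not_in_view
    )
    return ChildTimeline(
        child_id=cid,
        intervals=merged,
        observed_s=offset,
        not_in_view_s=round(niv, 6),
    )


def timeline_from_clip(clip, schema: PaletteSchema) -> ChildTimeline:
    """Single-clip timeline (used when scoring double-coded clips)."""
    from .mlats import initial_states

    init = initial_states(clip, schema)
    per_channel = {}
    for ch in CHANNELS:
        events = [(0.0, init[ch])] + [
            (e.t, e.state)
            for e in clip.channel_events(ch)
            if 0.0 < e.t < clip.duration_s
        ]
        per_channel[ch] = events_to_intervals(events, clip.duration_s, ch)
    niv = sum(
        iv.length_s for iv in per_channel[OBJECT] if iv.state == schema.not_in_view
    )
    return ChildTimeline(
        child_id=clip.clip_id,
        intervals=per_channel,
        observed_s=clip.duration_s,
        not_in_view_s=round(niv, 6),
    )


def state_at(intervals: Sequence[StateInterval], t: float) -> str:
    """Point lookup: the state whose half-open interval covers ``t``."""
    starts = [iv.start_s for iv in intervals]
    i = bisect_right(starts, t) - 1
    if i < 0 or t >= intervals[i].end_s:
        raise ValueError(f"t={t} outside observed time")
    return intervals[i].state


def extract_contacts(timeline: ChildTimeline, schema: PaletteSchema) -> list[Contact]:
    """One contact per maximal non-sentinel OBJECT interval.

    A change of object without an intervening ``Nothing`` starts a new
    contact (the intervals differ); sentinel intervals yield none.  Location
    and context are attached by point lookup at contact onset.
    """
    loc = timeline.channel(LOCATION)
    ctx = timeline.channel(CONTEXT)
    out: list[Contact] = []
    for iv in timeline.channel(OBJECT):
        if schema.is_sentinel(iv.state):
            continue
        out.append(
            Contact(
                object_state=iv.state,
                group=schema.group_of(iv.state),
                onset_s=iv.start_s,
                end_s=iv.end_s,
                location_at_onset=state_at(loc, iv.start_s),
                context_at_onset=state_at(ctx, iv.start_s),
            )
        )
    return out


def _overlap(a: Sequence[tuple[float, float]], b: Sequence[tuple[float, float]]) -> float:
    """Total overlap length of two sorted disjoint interval lists."""
    total = 0.0
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            total += hi - lo
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _select(timeline: ChildTimeline, channel: str, states: Iterable[str]) -> list[tuple[float, float]]:
    wanted = set(states)
    return [
        (iv.start_s, iv.end_s)
        for iv in timeline.channel(channel)
        if iv.state in wanted
    ]


def time_in(
    timeline: ChildTimeline,
    channel: str,
    states: Iterable[str],
    restrict_to: tuple[str, Iterable[str]] | None = None,
    schema: PaletteSchema | None = None,
) -> float:
    """Seconds spent in ``states`` on ``channel``.

    With ``restrict_to=(other_channel, other_states)`` the time is the exact
    intersection of the two state sets (e.g. high-risk context while
    outdoors).  Passing ``schema`` validates state names.
    """
    states = list(states)
    if schema is not None:
        for s in states:
            schema.validate_state(channel, s)
    sel = _select(timeline, channel, states)
    if restrict_to is None:
        return sum(hi - lo for lo, hi in sel)
    ch2, states2 = restrict_to
    states2 = list(states2)
    if schema is not None:
        for s in states2:
            schema.validate_state(ch2, s)
    return _overlap(sel, _select(timeline, ch2, states2))


def observable_time_in(
    timeline: ChildTimeline,
    channel: str,
    states: Iterable[str],
    schema: PaletteSchema,
) -> float:
    """Like ``time_in`` but with OBJECT-channel NotInView time removed."""
    states = list(states)
    gross = time_in(timeline, channel, states)
    hidden = time_in(timeline, channel, states, restrict_to=(OBJECT, [schema.not_in_view]))
    return gross - hidden


def dump_intervals(timeline: ChildTimeline, dest=None) -> str:
    """Debug dump: tab-separated ``channel  start_s  end_s  state`` lines."""
    lines = [
        f"{iv.channel}\t{iv.start_s:.3f}\t{iv.end_s:.3f}\t{iv.state}"
        for ch in CHANNELS
        for iv in timeline.channel(ch)
    ]
    text = "\n".join(lines) + "\n"
    if dest is not None:
        from pathlib import Path

        Path(dest).write_text(text, encoding="utf-8")
    return text
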