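"""Reading, validating, correcting and concatenating coded event streams.

A coding session produces one *microlevel activity time series* (MLATS) per
video clip: a time-ordered list of button presses, each stamped with seconds
from clip start, a channel and a state.  On disk a session is a directory
holding ``session.yaml`` (child metadata plus the ordered clip list with
durations and coder ids) and ``events.csv`` with header
``clip_id,t_s,channel,state`` (UTF-8, times in seconds with at most three
decimals).

Clips are roughly 20 minutes long; camera pauses appear only as clip
boundaries.  Channel state does not persist across clips — every clip
restates all three channels at t=0 (the OBJECT channel may imply its
``Nothing`` sentinel).
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import yaml

from .palette import CHANNELS, OBJECT, PaletteSchema

MLATS_HEADER = ["clip_id", "t_s", "channel", "state"]
_CHANNEL_ORDER = {ch: i for i, ch in enumerate(CHANNELS)}

AGE_GROUPS = ("6m-<2y", "2-<5y")
MOBILITY_LEVELS = ("cannot crawl", "crawling only", "crawling and walking", "walking only")
SEASONS = ("wet", "dry")


class MlatsError(ValueError):
    """Malformed MLATS input."""


@dataclass(frozen=True, order=True)
class CodedEvent:
    """One button press: at ``t`` seconds from clip start, ``channel`` enters ``state``."""

    t: float
    channel: str
    state: str

    def __post_init__(self) -> None:
        if self.t < 0:
            raise MlatsError(f"negative timestamp: {self.t}")
        if self.channel not in _CHANNEL_ORDER:
            raise MlatsError(f"unknown channel: {self.channel!r}")

    @property
    def sort_key(self) -> tuple[float, int]:
        return (self.t, _CHANNEL_ORDER[self.channel])


@dataclass(frozen=True)
class Correction:
    """A coder's margin note: fix the record at time ``t`` on ``channel``.

    ``kind`` is one of ``substitute`` (wrong_state -> right_state at an
    existing event), ``insert`` (a missed press) or ``delete`` (an accidental
    press).
    """

    t: float
    channel: str
    kind: str
    wrong_state: str | None = None
    right_state: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("substitute", "insert", "delete"):
            raise MlatsError(f"unknown correction kind: {self.kind!r}")
        if self.kind == "substitute" and (self.wrong_state is None or self.right_state is None):
            raise MlatsError("substitute correction needs wrong_state and right_state")
        if self.kind == "insert" and self.right_state is None:
            raise MlatsError("insert correction needs right_state")
        if self.kind == "delete" and self.wrong_state is None:
            raise MlatsError("delete correction needs wrong_state")


@dataclass(frozen=True)
class ClipRecord:
    clip_id: str
    session_id: str
    coder_id: str
    duration_s: float
    events: tuple[CodedEvent, ...]
    corrections: tuple[Correction, ...] = ()

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise MlatsError(f"clip {self.clip_id}: non-positive duration")
        keys = [e.sort_key for e in self.events]
        if keys != sorted(keys):
            raise MlatsError(f"clip {self.clip_id}: events not sorted by (t, channel)")
        for e in self.events:
            if e.t > self.duration_s:
                raise MlatsError(
                    f"clip {self.clip_id}: event at t={e.t} exceeds duration {self.duration_s}"
                )

    def channel_events(self, channel: str) -> list[CodedEvent]:
        return [e for e in self.events if e.channel == channel]


@dataclass(frozen=True)
class Session:
    """One filming visit: child metadata and the ordered clips it produced."""

    session_id: str
    child_id: str
    country: str
    campaign: int
    season: str
    age_group: str
    sex: str
    mobility: str
    clips: tuple[ClipRecord, ...]

    def __post_init__(self) -> None:
        if self.campaign not in (1, 2):
            raise MlatsError(f"campaign must be 1 or 2, got {self.campaign}")
        if self.season not in SEASONS:
            raise MlatsError(f"unknown season: {self.season!r}")
        if self.age_group not in AGE_GROUPS:
            raise MlatsError(f"unknown age group: {self.age_group!r}")
        if self.mobility not in MOBILITY_LEVELS:
            raise MlatsError(f"unknown mobility level: {self.mobility!r}")
        for c in self.clips:
            if c.session_id != self.session_id:
                raise MlatsError(
                    f"clip {c.clip_id} belongs to session {c.session_id}, not {self.session_id}"
                )

    @property
    def total_duration_s(self) -> float:
        return sum(c.duration_s for c in self.clips)


# ---------------------------------------------------------------------------
# CSV dialect


def _format_t(t: float) -> str:
    """Canonical time rendering: fixed three decimals (millisecond grid)."""
    return f"{t:.3f}"


def read_mlats(
    source,
    *,
    duration_s: float | None = None,
    durations: dict[str, float] | None = None,
    session_id: str = "",
    coder_id: str = "",
    coder_ids: dict[str, str] | None = None,
    schema: PaletteSchema | None = None,
) -> list[ClipRecord]:
    """Parse an MLATS CSV into one ``ClipRecord`` per clip.

    ``durations`` maps clip_id -> clip length in seconds (required; a single
    ``duration_s`` may be given instead when the file holds one clip).
    Unknown channels/states and out-of-bound or unsorted timestamps raise
    ``MlatsError`` naming the offending line.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    reader = csv.reader(_io.StringIO(text))
    try:
        header = next(reader)
    except StopIteration:
        raise MlatsError("empty MLATS file") from None
    if header != MLATS_HEADER:
        raise MlatsError(f"bad MLATS header {header!r}, expected {MLATS_HEADER!r}")
    by_clip: dict[str, list[CodedEvent]] = {}
    for lineno, row in enumerate(reader, start=2):
        if not row:
            continue
        if len(row) != 4:
            raise MlatsError(f"line {lineno}: expected 4 fields, got {len(row)}")
        clip_id, t_s, channel, state = row
        try:
            t = float(t_s)
        except ValueError:
            raise MlatsError(f"line {lineno}: bad timestamp {t_s!r}") from None
        if schema is not None:
            try:
                schema.validate_state(channel, state)
            except Exception as exc:
                raise MlatsError(f"line {lineno}: {exc}") from None
        try:
            ev = CodedEvent(t=t, channel=channel, state=state)
        except MlatsError as exc:
            raise MlatsError(f"line {lineno}: {exc}") from None
        by_clip.setdefault(clip_id, []).append(ev)
    clips: list[ClipRecord] = []
    for clip_id, events in by_clip.items():
        if durations is not None:
            if clip_id not in durations:
                raise MlatsError(f"no duration given for clip {clip_id!r}")
            dur = durations[clip_id]
        elif duration_s is not None:
            if len(by_clip) > 1:
                raise MlatsError("duration_s given but file holds multiple clips")
            dur = duration_s
        else:
            raise MlatsError("clip duration(s) required")
        cid = coder_ids.get(clip_id, coder_id) if coder_ids else coder_id
        keys = [e.sort_key for e in events]
        if keys != sorted(keys):
            raise MlatsError(f"clip {clip_id}: events not sorted by (t, channel)")
        clips.append(
            ClipRecord(
                clip_id=clip_id,
                session_id=session_id,
                coder_id=cid,
                duration_s=dur,
                events=tuple(events),
            )
        )
    return clips


def write_mlats(clips: Sequence[ClipRecord] | ClipRecord, dest=None) -> str:
    """Serialize clips to canonical MLATS CSV; returns the text.

    Canonical form: header row, events in (clip order, t, channel-priority)
    order, times fixed to three decimals.  ``write(read(text)) == text`` for
    canonical input.
    """
    if isinstance(clips, ClipRecord):
        clips = [clips]
    buf = _io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(MLATS_HEADER)
    for clip in clips:
        for e in clip.events:
            w.writerow([clip.clip_id, _format_t(e.t), e.channel, e.state])
    text = buf.getvalue()
    if dest is not None:
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            Path(dest).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# Session directories


def write_session(session: Session, directory) -> Path:
    """Write ``session.yaml`` + ``events.csv`` into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    meta = {
        "session_id": session.session_id,
        "child_id": session.child_id,
        "country": session.country,
        "campaign": session.campaign,
        "season": session.season,
        "age_group": session.age_group,
        "sex": session.sex,
        "mobility": session.mobility,
        "clips": [
            {"clip_id": c.clip_id, "duration_s": round(c.duration_s, 3), "coder_id": c.coder_id}
            for c in session.clips
        ],
    }
    (d / "session.yaml").write_text(
        yaml.safe_dump(meta, sort_keys=False), encoding="utf-8"
    )
    write_mlats(list(session.clips), d / "events.csv")
    return d


def read_session(directory, schema: PaletteSchema | None = None) -> Session:
    d = Path(directory)
    meta = yaml.safe_load((d / "session.yaml").read_text(encoding="utf-8"))
    durations = {c["clip_id"]: float(c["duration_s"]) for c in meta["clips"]}
    coder_ids = {c["clip_id"]: str(c.get("coder_id", "")) for c in meta["clips"]}
    clips = read_mlats(
        d / "events.csv",
        durations=durations,
        session_id=meta["session_id"],
        coder_ids=coder_ids,
        schema=schema,
    )
    order = {c["clip_id"]: i for i, c in enumerate(meta["clips"])}
    clips.sort(key=lambda c: order[c.clip_id])
    return Session(
        session_id=meta["session_id"],
        child_id=str(meta["child_id"]),
        country=meta["country"],
        campaign=int(meta["campaign"]),
        season=meta["season"],
        age_group=meta["age_group"],
        sex=meta["sex"],
        mobility=meta["mobility"],
        clips=tuple(clips),
    )


def iter_session_dirs(root) -> Iterator[Path]:
    """Yield every directory under ``root`` holding a ``session.yaml``."""
    root = Path(root)
    for p in sorted(root.rglob("session.yaml")):
        yield p.parent


# ---------------------------------------------------------------------------
# Corrections

@dataclass(frozen=True)
class AppliedEdit:
    correction: Correction
    before: CodedEvent | None
    after: CodedEvent | None


def apply_corrections(clip: ClipRecord) -> tuple[ClipRecord, list[AppliedEdit]]:
    """Apply the clip's correction annotations, returning a new clip + audit log.

    Substitutions and deletions must name an existing (t, channel, state)
    event; a miss raises ``MlatsError``.  The input clip is not mutated.
    """
    events = list(clip.events)
    log: list[AppliedEdit] = []
    for corr in clip.corrections:
        if corr.t > clip.duration_s:
            raise MlatsError(
                f"clip {clip.clip_id}: correction at t={corr.t} beyond duration"
            )
        if corr.kind == "insert":
            ev = CodedEvent(t=corr.t, channel=corr.channel, state=corr.right_state)
            events.append(ev)
            log.append(AppliedEdit(corr, None, ev))
            continue
        matches = [
            i
            for i, e in enumerate(events)
            if e.t == corr.t and e.channel == corr.channel and e.state == corr.wrong_state
        ]
        if not matches:
            raise MlatsError(
                f"clip {clip.clip_id}: correction {corr.kind} at t={corr.t} "
                f"({corr.channel}={corr.wrong_state!r}) matches no event"
            )
        i = matches[0]
        before = events[i]
        if corr.kind == "substitute":
            after = CodedEvent(t=corr.t, channel=corr.channel, state=corr.right_state)
            events[i] = after
            log.append(AppliedEdit(corr, before, after))
        else:  # delete
            del events[i]
            log.append(AppliedEdit(corr, before, None))
    events.sort(key=lambda e: e.sort_key)
    return replace(clip, events=tuple(events), corrections=()), log


# ---------------------------------------------------------------------------
# Concatenation


def initial_states(clip: ClipRecord, schema: PaletteSchema) -> dict[str, str]:
    """State of each channel at the clip's t=0.

    The OBJECT channel may imply the ``Nothing`` sentinel; LOCATION and
    CONTEXT have no sentinel and must be restated explicitly.
    """
    states: dict[str, str] = {}
    for ch in CHANNELS:
        evs = [e for e in clip.events if e.channel == ch and e.t == 0.0]
        if evs:
            states[ch] = evs[0].state
        elif ch == OBJECT:
            states[ch] = schema.nothing
        else:
            raise MlatsError(
                f"clip {clip.clip_id}: channel {ch} has no state at t=0"
            )
    return states


def concatenate_session(
    session: Session, schema: PaletteSchema
) -> tuple[dict[str, list[tuple[float, str]]], float]:
    """Merge a session's clips into per-channel event streams on cumulative time.

    Clip-local times are offset by the summed durations of prior clips, so
    camera pauses contribute zero observed time.  Each clip's t=0 states are
    restated at its offset (state never carries across a boundary).  Returns
    ``(streams, total_duration_s)`` where each stream is a time-sorted list of
    ``(t, state)``.
    """
    streams: dict[str, list[tuple[float, str]]] = {ch: [] for ch in CHANNELS}
    offset = 0.0
    for clip in session.clips:
        init = initial_states(clip, schema)
        for ch in CHANNELS:
            streams[ch].append((round(offset, 3), init[ch]))
            for e in clip.channel_events(ch):
                if e.t == 0.0:
                    continue  # already restated
                if e.t == clip.duration_s:
                    continue  # zero-length tail, outside [0, duration)
                # stay on the millisecond grid despite float accumulation
                streams[ch].append((round(offset + e.t, 3), e.state))
        offset += clip.duration_s
    return streams, round(offset, 3)
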