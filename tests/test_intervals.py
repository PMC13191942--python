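import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import secondwise
from conftest import make_clip, make_session
from mouthing.intervals import (
    StateInterval,
    events_to_intervals,
    extract_contacts,
    observable_time_in,
    state_at,
    time_in,
    timeline_from_clip,
    timeline_from_sessions,
)
from mouthing.palette import CONTEXT, LOCATION, OBJECT, default_palette

SCHEMA = default_palette()


class TestEventsToIntervals:
    def test_basic_tiling(self):
        ivs = events_to_intervals([(0, "Nothing"), (5, "DryFood"), (8, "Nothing")], 10)
        assert [(iv.state, iv.start_s, iv.end_s) for iv in ivs] == [
            ("Nothing", 0, 5),
            ("DryFood", 5, 8),
            ("Nothing", 8, 10),
        ]

    def test_single_event_spans_all(self):
        (iv,) = events_to_intervals([(0, "IndoorHome")], 10, LOCATION)
        assert (iv.start_s, iv.end_s) == (0, 10)

    def test_consecutive_same_state_merged(self):
        ivs = events_to_intervals([(0, "A"), (3, "A"), (6, "B"), (7, "B")], 10)
        assert [(iv.state, iv.start_s, iv.end_s) for iv in ivs] == [("A", 0, 6), ("B", 6, 10)]

    def test_same_instant_last_press_wins(self):
        ivs = events_to_intervals([(0, "A"), (5, "B"), (5, "C")], 10)
        assert [iv.state for iv in ivs] == ["A", "C"]

    def test_must_open_at_zero(self):
        with pytest.raises(ValueError, match="t=0"):
            events_to_intervals([(1, "A")], 10)


class TestExtractContacts:
    def test_contact_with_onset_context(self, simple_timeline):
        (c,) = extract_contacts(simple_timeline, SCHEMA)
        assert (c.object_state, c.group) == ("DryFood", "food")
        assert (c.onset_s, c.end_s) == (5.0, 8.0)
        assert c.location_at_onset == "IndoorHome"
        assert c.context_at_onset == "NoRisk"

    def test_object_change_without_nothing_is_two_contacts(self, schema):
        clip = make_clip(
            [
                (0.0, OBJECT, "Nothing"),
                (0.0, LOCATION, "IndoorHome"),
                (0.0, CONTEXT, "NoRisk"),
                (5.0, OBJECT, "DryFood"),
                (7.0, OBJECT, "PlasticVinylRubber"),
                (9.0, OBJECT, "Nothing"),
            ]
        )
        tl = timeline_from_sessions([make_session([clip])], schema)
        contacts = extract_contacts(tl, schema)
        assert [(c.object_state, c.onset_s, c.end_s) for c in contacts] == [
            ("DryFood", 5.0, 7.0),
            ("PlasticVinylRubber", 7.0, 9.0),
        ]

    def test_not_in_view_yields_no_contact(self, schema):
        clip = make_clip(
            [
                (0.0, OBJECT, "NotInView"),
                (0.0, LOCATION, "IndoorHome"),
                (0.0, CONTEXT, "NoRisk"),
                (5.0, OBJECT, "Nothing"),
            ]
        )
        tl = timeline_from_sessions([make_session([clip])], schema)
        assert extract_contacts(tl, schema) == []
        assert tl.not_in_view_s == 5.0


class TestTimeIn:
    def test_interval_overlap(self, schema):
        clip = make_clip(
            [
                (0.0, OBJECT, "Nothing"),
                (0.0, LOCATION, "OutsideHome"),
                (600.0, LOCATION, "IndoorHome"),
                (0.0, CONTEXT, "NoRisk"),
                (300.0, CONTEXT, "AroundAnimal"),
            ],
            duration_s=900.0,
        )
        tl = timeline_from_sessions([make_session([clip])], schema)
        got = time_in(tl, LOCATION, schema.outdoor_locations, restrict_to=(CONTEXT, ["AroundAnimal"]))
        assert got == 300.0

    def test_empty_state_set(self, simple_timeline):
        assert time_in(simple_timeline, LOCATION, []) == 0.0

    def test_unknown_state_rejected(self, simple_timeline, schema):
        with pytest.raises(Exception, match="unknown state"):
            time_in(simple_timeline, LOCATION, ["Veranda"], schema=schema)

    def test_observable_time_removes_not_in_view(self, schema):
        clip = make_clip(
            [
                (0.0, OBJECT, "NotInView"),
                (4.0, OBJECT, "Nothing"),
                (0.0, LOCATION, "PorchHome"),
                (0.0, CONTEXT, "NoRisk"),
            ]
        )
        tl = timeline_from_sessions([make_session([clip])], schema)
        assert time_in(tl, LOCATION, ["PorchHome"]) == 10.0
        assert observable_time_in(tl, LOCATION, ["PorchHome"], schema) == 6.0


# ---------------------------------------------------------------------------
# property: interval arithmetic equals the per-second oracle

OBJ_STATES = ["Nothing", "NotInView", "DryFood", "Wood", "OwnHand", "AnimalFeces"]
LOC_STATES = ["IndoorHome", "PorchHome", "OutdoorCommunal"]
CTX_STATES = ["NoRisk", "Eating", "AroundAnimal"]


def _stream(draw_times, states, duration, rng):
    ts = sorted({0} | {int(t) for t in rng.integers(0, duration, size=draw_times)})
    return [(t, states[rng.integers(0, len(states))]) for t in ts]


@given(st.integers(0, 2**31 - 1))
def test_interval_queries_match_per_second_oracle(seed):
    rng = np.random.default_rng(seed)
    duration = int(rng.integers(10, 600))
    obj = _stream(rng.integers(0, 40), OBJ_STATES, duration, rng)
    loc = _stream(rng.integers(0, 10), LOC_STATES, duration, rng)
    ctx = _stream(rng.integers(0, 10), CTX_STATES, duration, rng)

    clip_events = [(float(t), OBJECT, s) for t, s in obj]
    clip_events += [(float(t), LOCATION, s) for t, s in loc]
    clip_events += [(float(t), CONTEXT, s) for t, s in ctx]
    tl = timeline_from_sessions(
        [make_session([make_clip(clip_events, duration_s=float(duration))])], SCHEMA
    )

    obj_arr = secondwise.expand(obj, duration)
    loc_arr = secondwise.expand(loc, duration)
    ctx_arr = secondwise.expand(ctx, duration)
    sentinels = SCHEMA.sentinel_states

    contacts = extract_contacts(tl, SCHEMA)
    assert len(contacts) == secondwise.count_contacts(obj_arr, sentinels)
    for s in LOC_STATES:
        assert time_in(tl, LOCATION, [s]) == secondwise.seconds_in(loc_arr, [s])
    assert time_in(
        tl, LOCATION, SCHEMA.outdoor_locations, restrict_to=(CONTEXT, ["AroundAnimal"])
    ) == secondwise.seconds_in_joint(
        loc_arr, SCHEMA.outdoor_locations, ctx_arr, ["AroundAnimal"]
    )
    # conservation: every channel's states tile observed time exactly
    for ch, states in ((OBJECT, OBJ_STATES), (LOCATION, LOC_STATES), (CONTEXT, CTX_STATES)):
        assert time_in(tl, ch, states) == duration


def test_state_at_half_open_boundary():
    ivs = (
        StateInterval(LOCATION, "A", 0.0, 5.0),
        StateInterval(LOCATION, "B", 5.0, 10.0),
    )
    assert state_at(ivs, 4.999) == "A"
    assert state_at(ivs, 5.0) == "B"
    with pytest.raises(ValueError):
        state_at(ivs, 10.0)


def test_timeline_from_clip_matches_session_path(schema):
    clip = make_clip(
        [
            (0.0, OBJECT, "Nothing"),
            (0.0, LOCATION, "IndoorHome"),
            (0.0, CONTEXT, "NoRisk"),
            (2.0, OBJECT, "OwnHand"),
            (4.0, OBJECT, "NotInView"),
            (6.0, OBJECT, "Nothing"),
        ]
    )
    a = timeline_from_clip(clip, schema)
    b = timeline_from_sessions([make_session([clip])], schema)
    assert a.intervals == b.intervals
    assert a.not_in_view_s == b.not_in_view_s == 2.0
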