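import io

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_clip, make_session
from mouthing.mlats import (
    ClipRecord,
    CodedEvent,
    Correction,
    MlatsError,
    apply_corrections,
    concatenate_session,
    read_mlats,
    write_mlats,
)
from mouthing.palette import default_palette

SCHEMA = default_palette()

FIXTURE = """clip_id,t_s,channel,state
clip1,0.000,OBJECT,Nothing
clip1,5.000,OBJECT,DryFood
clip1,8.000,OBJECT,Nothing
"""


class TestReadWrite:
    def test_three_line_fixture(self):
        (clip,) = read_mlats(io.StringIO(FIXTURE), duration_s=10.0, schema=SCHEMA)
        assert len(clip.events) == 3
        assert clip.events[1] == CodedEvent(5.0, "OBJECT", "DryFood")
        assert clip.duration_s == 10.0

    def test_event_beyond_duration_rejected(self):
        bad = FIXTURE.replace("8.000", "12.000")
        with pytest.raises(MlatsError, match="exceeds duration"):
            read_mlats(io.StringIO(bad), duration_s=10.0, schema=SCHEMA)

    def test_unknown_state_reported_with_line_number(self):
        bad = FIXTURE.replace("DryFood", "Spoon")
        with pytest.raises(MlatsError, match="line 3"):
            read_mlats(io.StringIO(bad), duration_s=10.0, schema=SCHEMA)

    def test_unsorted_timestamps_rejected(self):
        lines = FIXTURE.splitlines()
        lines[2], lines[3] = lines[3], lines[2]
        with pytest.raises(MlatsError, match="not sorted"):
            read_mlats(io.StringIO("\n".join(lines)), duration_s=10.0, schema=SCHEMA)

    def test_round_trip_is_canonical(self):
        (clip,) = read_mlats(io.StringIO(FIXTURE), duration_s=10.0, schema=SCHEMA)
        assert write_mlats(clip) == FIXTURE

    @given(
        st.lists(
            st.tuples(
                st.integers(0, 9999),  # milliseconds
                st.sampled_from(["OBJECT", "LOCATION", "CONTEXT"]),
                st.integers(0, 4),
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_write_read_write_identity(self, raw):
        state_for = {
            "OBJECT": ["Nothing", "DryFood", "Wood", "OwnHand", "Animal"],
            "LOCATION": ["IndoorHome", "PorchHome", "OutsideHome", "OutdoorCommunal", "IndoorCommunal"],
            "CONTEXT": ["NoRisk", "Eating", "AroundAnimal", "AroundFeces", "Handwashing"],
        }
        events = [(t / 1000.0, ch, state_for[ch][k]) for t, ch, k in raw]
        clip = make_clip(events, duration_s=10.0)
        text = write_mlats(clip)
        (again,) = read_mlats(
            io.StringIO(text), duration_s=10.0, session_id="s1", coder_id="c1", schema=SCHEMA
        )
        assert write_mlats(again) == text
        assert again.events == clip.events


class TestCorrections:
    def _clip(self):
        return make_clip(
            [
                (0.0, "OBJECT", "Nothing"),
                (5.0, "OBJECT", "DryFood"),
                (8.0, "OBJECT", "Nothing"),
            ]
        )

    def test_substitute(self):
        clip = self._clip()
        clip = ClipRecord(
            **{
                **clip.__dict__,
                "corrections": (
                    Correction(5.0, "OBJECT", "substitute", "DryFood", "PlasticVinylRubber"),
                ),
            }
        )
        fixed, log = apply_corrections(clip)
        assert fixed.events[1].state == "PlasticVinylRubber"
        assert len(log) == 1 and log[0].before.state == "DryFood"
        assert clip.events[1].state == "DryFood"  # original untouched

    def test_delete_missing_event_rejected(self):
        clip = self._clip()
        clip = ClipRecord(
            **{
                **clip.__dict__,
                "corrections": (Correction(4.0, "OBJECT", "delete", wrong_state="DryFood"),),
            }
        )
        with pytest.raises(MlatsError, match="matches no event"):
            apply_corrections(clip)

    def test_insert_then_delete_restores_original(self):
        clip = self._clip()
        ins = Correction(6.0, "OBJECT", "insert", right_state="OwnHand")
        inserted, _ = apply_corrections(
            ClipRecord(**{**clip.__dict__, "corrections": (ins,)})
        )
        assert len(inserted.events) == 4
        deleted, _ = apply_corrections(
            ClipRecord(
                **{
                    **inserted.__dict__,
                    "corrections": (Correction(6.0, "OBJECT", "delete", wrong_state="OwnHand"),),
                }
            )
        )
        assert deleted.events == clip.events

    @given(
        st.lists(
            st.tuples(st.integers(1, 9), st.sampled_from(["DryFood", "Wood", "OwnHand"])),
            min_size=1,
            max_size=6,
            unique_by=lambda x: x[0],
        )
    )
    def test_substitutions_invert(self, subs):
        """Applying an edit script and then its inverse restores the events."""
        base = self._clip()
        events = list(base.events) + [
            CodedEvent(float(t), "OBJECT", s) for t, s in subs if t not in (5, 8)
        ]
        clip = make_clip([(e.t, e.channel, e.state) for e in events])
        forward = tuple(
            Correction(e.t, "OBJECT", "substitute", e.state, "Animal")
            for e in clip.events
            if e.state != "Nothing" and e.state != "Animal"
        )
        edited, _ = apply_corrections(ClipRecord(**{**clip.__dict__, "corrections": forward}))
        backward = tuple(
            Correction(c.t, "OBJECT", "substitute", "Animal", c.wrong_state) for c in forward
        )
        restored, _ = apply_corrections(
            ClipRecord(**{**edited.__dict__, "corrections": backward})
        )
        assert restored.events == clip.events


class TestConcatenate:
    def test_two_clips_offset_and_restated(self):
        clips = [
            make_clip(
                [(0.0, "OBJECT", "Nothing"), (0.0, "LOCATION", "IndoorHome"),
                 (0.0, "CONTEXT", "NoRisk"), (5.0, "OBJECT", "DryFood")],
                duration_s=10.0, clip_id="a",
            ),
            make_clip(
                [(0.0, "OBJECT", "Nothing"), (0.0, "LOCATION", "PorchHome"),
                 (0.0, "CONTEXT", "NoRisk")],
                duration_s=10.0, clip_id="b",
            ),
        ]
        streams, total = concatenate_session(make_session(clips), SCHEMA)
        assert total == 20.0
        assert (10.0, "Nothing") in streams["OBJECT"]  # restatement at boundary
        assert (10.0, "PorchHome") in streams["LOCATION"]
        assert (5.0, "DryFood") in streams["OBJECT"]

    def test_single_clip_identity(self):
        clip = make_clip(
            [(0.0, "OBJECT", "Nothing"), (0.0, "LOCATION", "IndoorHome"), (0.0, "CONTEXT", "NoRisk")]
        )
        streams, total = concatenate_session(make_session([clip]), SCHEMA)
        assert total == clip.duration_s
        assert streams["LOCATION"] == [(0.0, "IndoorHome")]

    def test_missing_initial_location_rejected(self):
        clip = make_clip([(0.0, "OBJECT", "Nothing"), (0.0, "CONTEXT", "NoRisk")])
        with pytest.raises(MlatsError, match="LOCATION"):
            concatenate_session(make_session([clip]), SCHEMA)

    def test_object_channel_implies_nothing_sentinel(self):
        clip = make_clip([(0.0, "LOCATION", "IndoorHome"), (0.0, "CONTEXT", "NoRisk")])
        streams, _ = concatenate_session(make_session([clip]), SCHEMA)
        assert streams["OBJECT"] == [(0.0, "Nothing")]

    @given(st.lists(st.floats(1.0, 1200.0), min_size=1, max_size=6))
    def test_total_duration_is_sum_of_clip_durations(self, durations):
        durations = [round(d, 3) for d in durations]
        clips = [
            make_clip(
                [(0.0, "OBJECT", "Nothing"), (0.0, "LOCATION", "IndoorHome"), (0.0, "CONTEXT", "NoRisk")],
                duration_s=d,
                clip_id=f"c{i}",
            )
            for i, d in enumerate(durations)
        ]
        _, total = concatenate_session(make_session(clips), SCHEMA)
        assert total == pytest.approx(sum(durations), abs=1e-9)
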