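import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mouthing.palette import default_palette

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def schema():
    return default_palette()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_clip(events, duration_s=10.0, clip_id="clip1", session_id="s1", coder_id="c1"):
    """Convenience ClipRecord builder from (t, channel, state) triples."""
    from mouthing.mlats import ClipRecord, CodedEvent

    evs = tuple(sorted((CodedEvent(t, ch, st) for t, ch, st in events), key=lambda e: e.sort_key))
    return ClipRecord(
        clip_id=clip_id,
        session_id=session_id,
        coder_id=coder_id,
        duration_s=duration_s,
        events=evs,
    )


def make_session(clips, child_id="ch1", country="Fiji", campaign=1, season="wet",
                 age_group="2-<5y", sex="M", mobility="walking only", session_id="s1"):
    from mouthing.mlats import Session

    return Session(
        session_id=session_id,
        child_id=child_id,
        country=country,
        campaign=campaign,
        season=season,
        age_group=age_group,
        sex=sex,
        mobility=mobility,
        clips=tuple(clips),
    )


@pytest.fixture()
def simple_timeline(schema):
    """10 s clip: FoodDry-equivalent contact [5, 8) indoors, NoRisk throughout."""
    from mouthing.intervals import timeline_from_sessions

    clip = make_clip(
        [
            (0.0, "OBJECT", "Nothing"),
            (0.0, "LOCATION", "IndoorHome"),
            (0.0, "CONTEXT", "NoRisk"),
            (5.0, "OBJECT", "DryFood"),
            (8.0, "OBJECT", "Nothing"),
        ],
        duration_s=10.0,
    )
    return timeline_from_sessions([make_session([clip])], schema)
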