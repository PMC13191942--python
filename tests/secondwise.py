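"""Brute-force per-second oracle for integer-second event streams.

Deliberately independent of the package's interval arithmetic: each channel
is expanded into one state label per second, and every count or duration is
read off the arrays directly.
"""

import numpy as np


def expand(events, duration):
    """events: [(t, state)] with integer t, first at 0 -> array of length duration."""
    arr = np.empty(duration, dtype=object)
    for i, (t, state) in enumerate(events):
        end = events[i + 1][0] if i + 1 < len(events) else duration
        arr[t:end] = state  # same-t events: later assignment wins
    assert not any(s is None for s in arr)
    return arr


def count_contacts(obj_arr, sentinels):
    n = 0
    prev = None
    for s in obj_arr:
        if s not in sentinels and s != prev:
            n += 1
        prev = s
    return n


def contact_onsets(obj_arr, sentinels):
    """Indices where a contact (maximal non-sentinel run) begins."""
    out = []
    prev = None
    for i, s in enumerate(obj_arr):
        if s not in sentinels and s != prev:
            out.append(i)
        prev = s
    return out


def seconds_in(arr, states):
    states = set(states)
    return int(sum(1 for s in arr if s in states))


def seconds_in_joint(arr_a, states_a, arr_b, states_b):
    sa, sb = set(states_a), set(states_b)
    return int(sum(1 for x, y in zip(arr_a, arr_b) if x in sa and y in sb))


def cell_counts(obj_arr, loc_arr, ctx_arr, sentinels, outdoor, high_risk_ctx):
    """Onset-attributed contact counts per (outdoor/indoor, highrisk/other)."""
    cells = {}
    for i in contact_onsets(obj_arr, sentinels):
        loc = "outdoor" if loc_arr[i] in outdoor else "indoor"
        ctx = "highrisk" if ctx_arr[i] in high_risk_ctx else "other"
        cells[(loc, ctx)] = cells.get((loc, ctx), 0) + 1
    return cells
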