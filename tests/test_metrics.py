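import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_clip, make_session
from mouthing.intervals import extract_contacts, timeline_from_sessions
from mouthing.metrics import (
    cohort_table,
    describe_values,
    eating_related_share,
    intersection_table,
    pooled_mean,
    prevalence,
    summaries_to_frame,
    summarize_child,
)
from mouthing.palette import CONTEXT, LOCATION, OBJECT, default_palette
from mouthing.simulate import fiji_like, simulate_child

SCHEMA = default_palette()


def _timeline_with_contacts(n_contacts, total_s=5400.0, location="IndoorHome"):
    """n short food contacts spread over an observation with no NotInView."""
    events = [(0.0, OBJECT, "Nothing"), (0.0, LOCATION, location), (0.0, CONTEXT, "NoRisk")]
    gap = total_s / (n_contacts + 1)
    for i in range(n_contacts):
        t = round((i + 1) * gap, 3)
        events += [(t, OBJECT, "Rice"), (round(t + 1.0, 3), OBJECT, "Nothing")]
    clip = make_clip(events, duration_s=total_s)
    tl = timeline_from_sessions([make_session([clip])], SCHEMA)
    return tl, extract_contacts(tl, SCHEMA)


class TestSummarizeChild:
    def test_rate_is_count_over_observed_hours(self):
        tl, contacts = _timeline_with_contacts(30, total_s=90 * 60.0)
        s = summarize_child(tl, contacts, SCHEMA)
        assert s["contacts_food"] == 30
        assert s["rate_food"] == pytest.approx(20.0)
        assert s["rate_any"] == pytest.approx(20.0)

    def test_zero_outdoor_stratum_is_missing_not_zero(self):
        tl, contacts = _timeline_with_contacts(5)
        s = summarize_child(tl, contacts, SCHEMA)
        assert s["rate_outdoor"] is None
        assert not s["any_outdoor"]
        assert s["rate_indoor"] == pytest.approx(s["rate_any"])

    def test_zero_observed_time_rejected(self):
        tl, contacts = _timeline_with_contacts(1)
        object.__setattr__(tl, "observed_s", 0.0)
        with pytest.raises(ValueError, match="zero observed"):
            summarize_child(tl, contacts, SCHEMA)

    def test_group_rates_sum_to_any_rate(self):
        truth, _ = simulate_child(fiji_like(1, SCHEMA), 99, "X", SCHEMA)
        s = summarize_child(truth.timeline, list(truth.contacts), SCHEMA)
        total = sum(s[f"rate_{g}"] for g in SCHEMA.groups())
        assert total == pytest.approx(s["rate_any"], rel=1e-9)

    def test_cell_counts_additive_to_total(self):
        truth, _ = simulate_child(fiji_like(1, SCHEMA), 7, "X", SCHEMA)
        s = summarize_child(truth.timeline, list(truth.contacts), SCHEMA)
        cells = sum(
            s[f"contacts_{loc}_{ctx}"]
            for loc in ("outdoor", "indoor")
            for ctx in ("highrisk", "other")
        )
        assert cells == s["contacts_any"]
        assert s["contacts_outdoor"] + s["contacts_indoor"] == s["contacts_any"]

    def test_not_in_view_toggle_moves_rates_up_never_counts(self):
        truth, _ = simulate_child(fiji_like(1, SCHEMA), 11, "X", SCHEMA)
        excl = summarize_child(truth.timeline, list(truth.contacts), SCHEMA, exclude_not_in_view=True)
        incl = summarize_child(truth.timeline, list(truth.contacts), SCHEMA, exclude_not_in_view=False)
        assert truth.timeline.not_in_view_s > 0
        assert excl["contacts_any"] == incl["contacts_any"]
        assert excl["rate_any"] > incl["rate_any"]
        for g in SCHEMA.groups():
            assert excl[f"contacts_{g}"] == incl[f"contacts_{g}"]
            if incl[f"rate_{g}"]:
                assert excl[f"rate_{g}"] >= incl[f"rate_{g}"]

    def test_poisson_rate_recovery_single_child(self):
        cfg = fiji_like(
            1,
            SCHEMA,
            child_rate_cv=0.0,
            group_dispersion={},
            hours_mean=4.0,
            hours_sd=0.0,
            hours_min=4.0,
            hours_max=4.0,
        )
        lam = cfg.any_object_rate_per_h
        truth, _ = simulate_child(cfg, 3, "X", SCHEMA)
        s = summarize_child(truth.timeline, list(truth.contacts), SCHEMA)
        T = s["observable_h"]
        assert abs(s["rate_any"] - lam) <= 3 * np.sqrt(lam / T)


class TestEatingShare:
    def _frame(self, eating, other):
        rows = [
            {
                "contacts_eating_indoor": e,
                "contacts_indoor": e + o,
                "contacts_eating": e,
                "contacts_any": e + o,
            }
            for e, o in zip(eating, other)
        ]
        return pd.DataFrame(rows)

    def test_all_contacts_during_eating(self):
        shares = eating_related_share(self._frame([5, 3], [0, 0]), "indoor")
        assert shares["pooled"] == 1.0 and shares["child_mean"] == 1.0

    def test_no_eating_contacts(self):
        shares = eating_related_share(self._frame([0, 0], [4, 6]), "indoor")
        assert shares["pooled"] == 0.0 and shares["child_mean"] == 0.0

    def test_pooled_vs_child_mean_weighting(self):
        # child A: 9/10 eating; child B: 0/90 -> pooled 9/100, child mean 0.45
        shares = eating_related_share(self._frame([9, 0], [1, 90]), "indoor")
        assert shares["pooled"] == pytest.approx(0.09)
        assert shares["child_mean"] == pytest.approx(0.45)

    def test_zero_contacts_rejected(self):
        with pytest.raises(ValueError):
            eating_related_share(self._frame([0], [0]), "indoor")


class TestCohortTable:
    def test_small_cell_descriptives(self):
        d = describe_values([1, 2, 3])
        assert (d["mean"], d["median"], d["max"]) == (2, 2, 3)
        assert d["iqr"] == pytest.approx(1.0)  # Q3=2.5, Q1=1.5

    def test_prevalence_matches_printed_marginal(self):
        # 58 of 106 children mouthed a high-risk object -> printed 55%
        assert round(prevalence(58, 106)) == 55

    @given(st.lists(st.floats(0, 100), min_size=2, max_size=40))
    def test_quantiles_match_sort_based_oracle(self, values):
        d = describe_values(values)
        arr = np.sort(np.asarray(values))
        # oracle: linear interpolation on sorted order statistics
        def q(p):
            h = (len(arr) - 1) * p
            lo, hi = int(np.floor(h)), int(np.ceil(h))
            return arr[lo] + (h - lo) * (arr[hi] - arr[lo])

        assert d["median"] == pytest.approx(q(0.5), abs=1e-9)
        assert d["iqr"] == pytest.approx(q(0.75) - q(0.25), abs=1e-9)
        assert d["max"] == arr[-1]

    def test_grouped_table_and_empty_cell_error(self):
        df = pd.DataFrame(
            {
                "country": ["A", "A", "B"],
                "rate_any": [1.0, 3.0, 5.0],
                "contacts_any": [1, 3, 5],
            }
        )
        tab = cohort_table(df, "rate_any", observed_col="contacts_any")
        a = tab[tab["country"] == "A"].iloc[0]
        assert a["n"] == 2 and a["mean"] == 2.0 and a["pct_observed"] == 100.0
        with pytest.raises(ValueError):
            cohort_table(df.iloc[0:0], "rate_any")

    def test_conditional_rate_n_counts_stratum_children(self):
        df = pd.DataFrame(
            {
                "country": ["A", "A", "A"],
                "rate_outdoor": [10.0, None, 0.0],
                "contacts_outdoor": [4, 0, 0],
            }
        )
        tab = cohort_table(df, "rate_outdoor", observed_col="contacts_outdoor")
        row = tab.iloc[0]
        assert row["n"] == 2  # child with no outdoor time excluded
        assert row["n_observed"] == 1
        assert row["pct_observed"] == pytest.approx(50.0)


def test_pooled_mean_from_printed_marginals():
    # Fiji 3.4 h (n=106) and Indonesia 5.1 h (n=86) pool to ~4.1-4.2 h
    assert pooled_mean([3.4, 5.1], [106, 86]) == pytest.approx(4.161, abs=5e-3)


def test_intersection_table_consistency():
    cfg = fiji_like(6, SCHEMA)
    rows = []
    for i in range(6):
        truth, _ = simulate_child(cfg, 40 + i, f"X{i}", SCHEMA)
        rows.append(
            summarize_child(truth.timeline, list(truth.contacts), SCHEMA, {"country": "Fiji"})
        )
    df = summaries_to_frame(rows)
    tab = intersection_table(df)
    assert len(tab) == 4
    assert (tab["n_children"] == 6).all()
    total_cells = tab["n_mouthing"].to_numpy()
    assert (total_cells <= 6).all()
    # cross-foot: per-child cell counts sum to the total contact count
    cells = df[
        ["contacts_outdoor_highrisk", "contacts_outdoor_other",
         "contacts_indoor_highrisk", "contacts_indoor_other"]
    ].sum(axis=1)
    assert (cells == df["contacts_any"]).all()
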