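"""Per-child and cohort exposure summaries.

The unit of analysis is the child: counts of mouthing contacts and time in
states are pooled across campaigns first, and each child contributes one
rate (count divided by that child's own observed time), never an average of
per-campaign rates.  Rates are contacts per hour observed; durations are
normalized to minutes per hour observed.  By default "observed" excludes
OBJECT-channel NotInView time (the child was on film but not codable); the
``exclude_not_in_view`` toggle switches to the gross video duration reading.

Stratum-conditional rates (contacts per hour while outdoors, while in a
high-risk context, ...) use the child's time in the stratum as denominator
and are *missing* — not zero — for children never observed in the stratum.
Contacts are attributed to strata by their state at contact onset, which
keeps location x context cell counts additive to the child's total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import ChildTimeline, Contact, observable_time_in, time_in
from .palette import CONTEXT, LOCATION, PaletteSchema


def _rate(count: int, denom_s: float) -> float | None:
    """Contacts/h, or None when the denominator stratum was never observed."""
    if denom_s <= 0:
        return None
    return count / (denom_s / 3600.0)


def _min_per_h(part_s: float, denom_s: float) -> float | None:
    if denom_s <= 0:
        return None
    return 60.0 * part_s / denom_s


@dataclass
class ExposureSummary:
    """One child's exposure metrics (flat mapping ready for a tidy table)."""

    child_id: str
    metadata: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        if key in self.metrics:
            return self.metrics[key]
        return self.metadata[key]

    def to_row(self) -> dict:
        return {"child_id": self.child_id, **self.metadata, **self.metrics}


def _onset_in(contact: Contact, locations: set[str] | None, contexts: set[str] | None) -> bool:
    if locations is not None and contact.location_at_onset not in locations:
        return False
    if contexts is not None and contact.context_at_onset not in contexts:
        return False
    return True


def summarize_child(
    timeline: ChildTimeline,
    contacts: Sequence[Contact],
    schema: PaletteSchema,
    metadata: dict | None = None,
    exclude_not_in_view: bool = True,
) -> ExposureSummary:
    """Compute the full per-child exposure summary.

    ``metadata`` carries the session fields (country, age group, ...) into
    the output row.  Raises ``ValueError`` on zero observed time.
    """
    if timeline.observed_s <= 0:
        raise ValueError(f"child {timeline.child_id}: zero observed time")

    def stratum_s(channel: str, states: Iterable[str]) -> float:
        if exclude_not_in_view:
            return observable_time_in(timeline, channel, states, schema)
        return time_in(timeline, channel, states)

    den_s = timeline.observable_s if exclude_not_in_view else timeline.observed_s
    outdoor = set(schema.outdoor_locations)
    indoor = set(schema.indoor_locations())
    hr_ctx = set(schema.high_risk_contexts)
    other_ctx = set(schema.states[CONTEXT]) - hr_ctx
    eating = {schema.eating_context}
    groups = schema.groups()

    m: dict = {}
    m["observed_h"] = timeline.observed_s / 3600.0
    m["observable_h"] = timeline.observable_s / 3600.0
    m["not_in_view_min_per_h"] = _min_per_h(timeline.not_in_view_s, timeline.observed_s)

    # ---- counts -------------------------------------------------------
    m["contacts_any"] = len(contacts)
    for g in groups:
        m[f"contacts_{g}"] = sum(1 for c in contacts if c.group == g)
    n_out = sum(1 for c in contacts if _onset_in(c, outdoor, None))
    n_in = len(contacts) - n_out
    m["contacts_outdoor"], m["contacts_indoor"] = n_out, n_in
    n_hr = sum(1 for c in contacts if _onset_in(c, None, hr_ctx))
    m["contacts_high_risk_ctx"] = n_hr
    m["contacts_eating"] = sum(1 for c in contacts if _onset_in(c, None, eating))
    for loc_name, loc_set in (("outdoor", outdoor), ("indoor", indoor)):
        for ctx_name, ctx_set in (("highrisk", hr_ctx), ("other", other_ctx)):
            m[f"contacts_{loc_name}_{ctx_name}"] = sum(
                1 for c in contacts if _onset_in(c, loc_set, ctx_set)
            )
        m[f"contacts_eating_{loc_name}"] = sum(
            1 for c in contacts if _onset_in(c, loc_set, eating)
        )
        for g in groups:
            m[f"contacts_{g}_{loc_name}"] = sum(
                1 for c in contacts if c.group == g and _onset_in(c, loc_set, None)
            )

    # ---- whole-observation rates --------------------------------------
    m["rate_any"] = _rate(m["contacts_any"], den_s)
    for g in groups:
        m[f"rate_{g}"] = _rate(m[f"contacts_{g}"], den_s)

    # ---- stratum times and conditional rates --------------------------
    out_s = stratum_s(LOCATION, outdoor)
    in_s = stratum_s(LOCATION, indoor)
    m["outdoor_min_per_h"] = _min_per_h(time_in(timeline, LOCATION, outdoor), timeline.observed_s)
    m["rate_outdoor"] = _rate(n_out, out_s)
    m["rate_indoor"] = _rate(n_in, in_s)
    for g in groups:
        m[f"rate_{g}_outdoor"] = _rate(m[f"contacts_{g}_outdoor"], out_s)
        m[f"rate_{g}_indoor"] = _rate(m[f"contacts_{g}_indoor"], in_s)
    m["rate_eating_outdoor"] = _rate(m["contacts_eating_outdoor"], out_s)
    m["rate_eating_indoor"] = _rate(m["contacts_eating_indoor"], in_s)

    for ctx in sorted(hr_ctx):
        ctx_s = stratum_s(CONTEXT, [ctx])
        m[f"ctx_{ctx}_min_per_h"] = _min_per_h(
            time_in(timeline, CONTEXT, [ctx]), timeline.observed_s
        )
        m[f"rate_ctx_{ctx}"] = _rate(
            sum(1 for c in contacts if c.context_at_onset == ctx), ctx_s
        )
    hr_s = stratum_s(CONTEXT, hr_ctx)
    m["high_risk_ctx_min_per_h"] = _min_per_h(
        time_in(timeline, CONTEXT, hr_ctx), timeline.observed_s
    )
    m["rate_high_risk_ctx"] = _rate(n_hr, hr_s)
    eat_s = stratum_s(CONTEXT, eating)
    m["eating_min_per_h"] = _min_per_h(time_in(timeline, CONTEXT, eating), timeline.observed_s)
    m["rate_eating"] = _rate(m["contacts_eating"], eat_s)

    # ---- location x context cells -------------------------------------
    for loc_name, loc_set in (("outdoor", outdoor), ("indoor", indoor)):
        for ctx_name, ctx_set in (("highrisk", hr_ctx), ("other", other_ctx)):
            cell_gross = time_in(timeline, LOCATION, loc_set, restrict_to=(CONTEXT, ctx_set))
            if exclude_not_in_view:
                hidden = _cell_not_in_view(timeline, loc_set, ctx_set, schema)
                cell_s = cell_gross - hidden
            else:
                cell_s = cell_gross
            m[f"time_{loc_name}_{ctx_name}_min_per_h"] = _min_per_h(
                cell_gross, timeline.observed_s
            )
            m[f"rate_{loc_name}_{ctx_name}"] = _rate(
                m[f"contacts_{loc_name}_{ctx_name}"], cell_s
            )

    # ---- per-location-state durations ---------------------------------
    for loc in schema.states[LOCATION]:
        m[f"loc_{loc}_min_per_h"] = _min_per_h(
            time_in(timeline, LOCATION, [loc]), timeline.observed_s
        )

    # ---- flags ---------------------------------------------------------
    m["any_mouthing"] = m["contacts_any"] > 0
    m["any_high_risk_object"] = m.get("contacts_high_risk", 0) > 0
    m["any_outdoor"] = time_in(timeline, LOCATION, outdoor) > 0
    m["any_high_risk_ctx"] = time_in(timeline, CONTEXT, hr_ctx) > 0
    for ctx in sorted(hr_ctx):
        m[f"any_ctx_{ctx}"] = time_in(timeline, CONTEXT, [ctx]) > 0

    return ExposureSummary(
        child_id=timeline.child_id, metadata=dict(metadata or {}), metrics=m
    )


def _cell_not_in_view(timeline, loc_set, ctx_set, schema) -> float:
    """NotInView seconds inside a location x context cell (3-way overlap)."""
    from .palette import OBJECT

    niv = [
        (iv.start_s, iv.end_s)
        for iv in timeline.channel(OBJECT)
        if iv.state == schema.not_in_view
    ]
    loc = [(iv.start_s, iv.end_s) for iv in timeline.channel(LOCATION) if iv.state in loc_set]
    ctx = [(iv.start_s, iv.end_s) for iv in timeline.channel(CONTEXT) if iv.state in ctx_set]
    # intersect loc and ctx first, then with NotInView
    cell = _intersect(loc, ctx)
    return sum(hi - lo for lo, hi in _intersect(cell, niv))


def _intersect(a, b):
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def summaries_to_frame(summaries: Iterable[ExposureSummary]) -> pd.DataFrame:
    """Tidy per-child table: one row per child, one column per metric."""
    return pd.DataFrame([s.to_row() for s in summaries])


# ---------------------------------------------------------------------------
# Cohort descriptive tables


def describe_values(values: Sequence[float]) -> dict:
    """Mean, SD, median, IQR width (Q3-Q1, linear interpolation) and max."""
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if arr.size == 0:
        return {"n": 0, "mean": np.nan, "sd": np.nan, "median": np.nan, "iqr": np.nan, "max": np.nan}
    q1, q3 = np.percentile(arr, [25, 75])  # linear interpolation convention
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
        "iqr": float(q3 - q1),
        "max": float(arr.max()),
    }


def cohort_table(
    df: pd.DataFrame,
    measure: str,
    groupby: Sequence[str] = ("country",),
    observed_col: str | None = None,
) -> pd.DataFrame:
    """Descriptive cohort table for one per-child measure.

    One output row per cell of ``groupby``.  ``n`` counts children with a
    non-missing value (for conditional rates this is the children observed in
    the stratum); ``n_observed``/``pct_observed`` count children with a
    positive value of ``observed_col`` (default: the measure itself), with
    ``n`` as the percentage denominator.
    """
    if df.empty:
        raise ValueError("no children to tabulate")
    obs = observed_col or measure
    rows = []
    for keys, sub in df.groupby(list(groupby), sort=True, dropna=False):
        if not isinstance(keys, tuple):
            keys = (keys,)
        vals = sub[measure]
        desc = describe_values(vals.tolist())
        if desc["n"] == 0:
            raise ValueError(f"empty cell {dict(zip(groupby, keys))} for {measure}")
        n_obs = int((sub[obs].fillna(0) > 0).sum())
        rows.append(
            {
                **dict(zip(groupby, keys)),
                "measure": measure,
                **desc,
                "n_observed": n_obs,
                "pct_observed": 100.0 * n_obs / desc["n"],
            }
        )
    return pd.DataFrame(rows)


def prevalence(n_observed: int, n_total: int) -> float:
    """Percent of children observed, on the printed 0-100 scale."""
    if n_total <= 0:
        raise ValueError("empty denominator")
    return 100.0 * n_observed / n_total


def pooled_mean(means: Sequence[float], ns: Sequence[int]) -> float:
    """Combine printed per-stratum means into the overall mean."""
    ns = np.asarray(ns, dtype=float)
    return float(np.average(np.asarray(means, dtype=float), weights=ns))


def eating_related_share(
    df: pd.DataFrame, stratum: str = "indoor"
) -> dict[str, float]:
    """Share of mouthing contacts whose onset context is Eating, per stratum.

    Returns both readings: ``pooled`` (total eating-onset contacts over total
    contacts in the stratum, across children) and ``child_mean`` (per-child
    shares averaged over children with >= 1 contact in the stratum).
    """
    num_col = f"contacts_eating_{stratum}" if stratum in ("indoor", "outdoor") else "contacts_eating"
    den_col = f"contacts_{stratum}" if stratum in ("indoor", "outdoor") else "contacts_any"
    den = df[den_col].sum()
    if den == 0:
        raise ValueError(f"no contacts in stratum {stratum!r}")
    with_contacts = df[df[den_col] > 0]
    return {
        "pooled": float(df[num_col].sum() / den),
        "child_mean": float((with_contacts[num_col] / with_contacts[den_col]).mean()),
    }


def intersection_table(df: pd.DataFrame, groupby: Sequence[str] = ("country",)) -> pd.DataFrame:
    """Location x context cells: prevalence and conditional-rate distribution.

    For each (indoor/outdoor) x (high-risk/other context) cell and cohort
    group: number and % of children with >= 1 contact there (denominator: all
    children in the group), plus the distribution of conditional rates among
    children with stratum time > 0.
    """
    rows = []
    for loc in ("outdoor", "indoor"):
        for ctx in ("highrisk", "other"):
            count_col = f"contacts_{loc}_{ctx}"
            rate_col = f"rate_{loc}_{ctx}"
            for keys, sub in df.groupby(list(groupby), sort=True):
                if not isinstance(keys, tuple):
                    keys = (keys,)
                n_all = len(sub)
                n_obs = int((sub[count_col] > 0).sum())
                desc = describe_values(sub[rate_col].tolist())
                rows.append(
                    {
                        **dict(zip(groupby, keys)),
                        "location": loc,
                        "context": ctx,
                        "n_children": n_all,
                        "n_mouthing": n_obs,
                        "pct_mouthing": prevalence(n_obs, n_all),
                        "n_with_stratum_time": desc["n"],
                        **{k: desc[k] for k in ("mean", "sd", "median", "iqr", "max")},
                    }
                )
    return pd.DataFrame(rows)
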