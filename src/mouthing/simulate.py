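"""Synthetic child-behavior cohorts with known ground truth.

No raw videography from the study settings is publicly deposited, so every
upstream module is exercised against simulated children whose generating
parameters are known exactly.  The generator reproduces the *marginal*
statistics of the observed cohorts — overall mouthing around 70 contacts/h
dominated by food, fomites and the child's own hand; rare high-risk-object
contacts (~0.4-1 contacts/h, mouthed by about half of children); location
dwell processes with a large between-arm contrast in outdoor time
(~17 vs ~29 min/h on average); sparse high-risk-context episodes; NotInView
gaps — not the mechanism behind them, which no observational study pins
down.

Model sketch (all times on an integer millisecond grid):

* location: a semi-Markov renewal process over the 8 palette locations with
  exponential dwell times and a rank-1 transition matrix whose outdoor mass
  is calibrated per child to a Beta-distributed target outdoor-time
  fraction;
* context: independent Poisson episode processes per context (animal, feces,
  environmental water, eating, handwashing) painted over a NoRisk baseline
  in ascending palette priority, with per-child Bernoulli exposure
  propensities so that context prevalences are not forced to 100%;
* mouthing: per-object-group Poisson processes in observable time, with a
  per-child gamma rate factor (between-child spread) and an extra
  heavy-tailed gamma factor on the high-risk group (so only about half of
  children ever mouth one); simultaneous onsets resolve by palette priority;
  contact durations are lognormal (median ~2 s, cosmetic — only counts and
  channel times feed the metrics);
* NotInView: Poisson episodes that override the object channel.

Sessions split into ~20-minute clips, each restating all three channels at
t=0, and serialize through the standard MLATS dialect, so generated cohorts
run the full pipeline end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .intervals import ChildTimeline, Contact, extract_contacts, timeline_from_sessions
from .mlats import ClipRecord, CodedEvent, Session, write_session
from .palette import CHANNELS, CONTEXT, LOCATION, OBJECT, PaletteSchema, default_palette

MS = 1000


@dataclass(frozen=True)
class ContextConfig:
    """One context's episode process.

    ``propensity``: probability a child is ever exposed; among exposed
    children episodes arrive at ``rate_per_h`` with exponential mean
    duration ``mean_dur_s``.
    """

    rate_per_h: float
    mean_dur_s: float
    propensity: float = 1.0

    def __post_init__(self) -> None:
        if self.rate_per_h < 0 or self.mean_dur_s <= 0 or not 0 <= self.propensity <= 1:
            raise ValueError("invalid context episode parameters")


@dataclass(frozen=True)
class SimConfig:
    """Study-arm configuration; defaults via :func:`fiji_like` / :func:`indonesia_like`."""

    country: str
    n_children: int
    seed_tag: str = ""
    # observation time (per child, both campaigns pooled), hours
    hours_mean: float = 4.1
    hours_sd: float = 2.5
    hours_min: float = 0.75
    hours_max: float = 10.0
    p_both_campaigns: float = 0.1
    clip_s: float = 1200.0
    # location process
    outdoor_frac_mean: float = 0.29  # of observed time
    outdoor_frac_sd: float = 0.30
    dwell_mean_s: dict[str, float] = field(default_factory=dict)
    location_weights: dict[str, float] = field(default_factory=dict)
    # context processes, keyed by CONTEXT state
    contexts: dict[str, ContextConfig] = field(default_factory=dict)
    # mouthing process
    group_rates_per_h: dict[str, float] = field(default_factory=dict)
    child_rate_cv: float = 0.4
    group_dispersion: dict[str, float] = field(default_factory=dict)  # gamma shape per group
    contact_dur_median_s: float = 2.0
    contact_dur_sigma: float = 0.8
    # rate modifiers (1.0 = homogeneous; marginal rates then match config exactly)
    indoor_multiplier: float = 1.0
    outdoor_multiplier: float = 1.0
    eating_food_multiplier: float = 1.0
    # NotInView episodes
    not_in_view_rate_per_h: float = 2.0
    not_in_view_mean_s: float = 30.0
    # demographics (Bernoulli/categorical probabilities)
    p_age_under2: float = 0.40
    p_male: float = 0.55
    mobility_probs: tuple[float, float, float, float] = (0.03, 0.11, 0.09, 0.77)

    def __post_init__(self) -> None:
        for g, r in self.group_rates_per_h.items():
            if r < 0:
                raise ValueError(f"negative mouthing rate for group {g}")
        if abs(sum(self.mobility_probs) - 1.0) > 1e-6:
            raise ValueError("mobility probabilities must sum to 1")
        for d in self.dwell_mean_s.values():
            if d <= 0:
                raise ValueError("dwell means must be positive")

    @property
    def any_object_rate_per_h(self) -> float:
        return sum(self.group_rates_per_h.values())


def _default_dwell(schema: PaletteSchema) -> dict[str, float]:
    dwell = {}
    for loc in schema.states[LOCATION]:
        dwell[loc] = 900.0 if loc == "IndoorHome" else 300.0
    return dwell


def _default_weights(schema: PaletteSchema) -> dict[str, float]:
    # relative visit propensities within the indoor / outdoor classes
    w = {loc: 1.0 for loc in schema.states[LOCATION]}
    w["IndoorHome"] = 8.0
    w["PorchHome"] = 3.0
    w["OutsideHome"] = 2.0
    return w


def fiji_like(n_children: int = 106, schema: PaletteSchema | None = None, **over) -> SimConfig:
    """Arm calibrated to the Fiji cohort's marginal statistics."""
    schema = schema or default_palette()
    cfg = dict(
        country="Fiji",
        n_children=n_children,
        hours_mean=3.4,
        hours_sd=2.1,
        p_both_campaigns=8 / 106,
        outdoor_frac_mean=17.4 / 60,
        outdoor_frac_sd=19.0 / 60,
        dwell_mean_s=_default_dwell(schema),
        location_weights=_default_weights(schema),
        contexts={
            "AroundFeces": _episode(prevalence=0.07, min_per_h=0.2, mean_dur_s=90.0),
            "AroundAnimal": _episode(prevalence=0.60, min_per_h=2.0, mean_dur_s=120.0),
            "EnvironmentalWater": _episode(prevalence=0.24, min_per_h=0.3, mean_dur_s=60.0),
            "Eating": ContextConfig(rate_per_h=0.5, mean_dur_s=600.0),
            "Handwashing": ContextConfig(rate_per_h=0.5, mean_dur_s=20.0),
        },
        group_rates_per_h={
            "food": 18.9,
            "fomite": 25.6,
            "own_hand_skin": 22.6,
            "other_hand_skin": 3.5,
            "high_risk": 1.0,
        },
        group_dispersion={"high_risk": 0.3},
        p_age_under2=0.36,
        p_male=0.56,
        mobility_probs=(0.04, 0.12, 0.09, 0.75),
    )
    cfg.update(over)
    return SimConfig(**cfg)


def indonesia_like(n_children: int = 86, schema: PaletteSchema | None = None, **over) -> SimConfig:
    """Arm calibrated to the Indonesia cohort's marginal statistics."""
    schema = schema or default_palette()
    cfg = dict(
        country="Indonesia",
        n_children=n_children,
        hours_mean=5.1,
        hours_sd=2.7,
        p_both_campaigns=23 / 86,
        outdoor_frac_mean=28.8 / 60,
        outdoor_frac_sd=18.9 / 60,
        dwell_mean_s=_default_dwell(schema),
        location_weights=_default_weights(schema),
        contexts={
            "AroundFeces": _episode(prevalence=0.26, min_per_h=0.1, mean_dur_s=60.0),
            "AroundAnimal": _episode(prevalence=0.92, min_per_h=3.3, mean_dur_s=120.0),
            "EnvironmentalWater": _episode(prevalence=0.38, min_per_h=0.2, mean_dur_s=60.0),
            "Eating": ContextConfig(rate_per_h=0.6, mean_dur_s=600.0),
            "Handwashing": ContextConfig(rate_per_h=0.5, mean_dur_s=20.0),
        },
        group_rates_per_h={
            "food": 28.4,
            "fomite": 21.1,
            "own_hand_skin": 19.9,
            "other_hand_skin": 3.9,
            "high_risk": 0.4,
        },
        group_dispersion={"high_risk": 0.3},
        p_age_under2=0.45,
        p_male=0.54,
        mobility_probs=(0.01, 0.10, 0.09, 0.80),
    )
    cfg.update(over)
    return SimConfig(**cfg)


def _episode(prevalence: float, min_per_h: float, mean_dur_s: float) -> ContextConfig:
    """Back out the exposed-child episode rate from population-level targets.

    ``min_per_h`` is the cohort-average minutes per observed hour; among the
    exposed fraction the per-hour episode rate is (min_per_h / prevalence)
    * 60 / mean_dur_s.
    """
    rate = (min_per_h / prevalence) * 60.0 / mean_dur_s
    return ContextConfig(rate_per_h=rate, mean_dur_s=mean_dur_s, propensity=prevalence)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated child."""

    child_id: str
    timeline: ChildTimeline
    contacts: tuple[Contact, ...]
    params: dict


# ---------------------------------------------------------------------------
# building blocks (all interval endpoints in integer milliseconds)


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    """Beta(a, b) matching mean/sd, with sd capped below the feasible bound."""
    mean = min(max(mean, 1e-3), 1 - 1e-3)
    var = min(sd**2, 0.95 * mean * (1 - mean))
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


def _outdoor_mass(cfg: SimConfig, schema: PaletteSchema, target_frac: float) -> float:
    """Transition-matrix outdoor mass giving the target outdoor-time fraction.

    With identical rows the embedded chain's stationary law equals the row,
    so the time fraction is p*Mo / (p*Mo + (1-p)*Mi) with Mo/Mi the
    weight-averaged dwell means of the outdoor/indoor classes; invert for p.
    """
    outdoor = schema.outdoor_locations
    w = cfg.location_weights
    mu = cfg.dwell_mean_s

    def class_mean(states):
        tw = sum(w[s] for s in states)
        return sum(w[s] * mu[s] for s in states) / tw

    mo = class_mean([s for s in schema.states[LOCATION] if s in outdoor])
    mi = class_mean([s for s in schema.states[LOCATION] if s not in outdoor])
    f = min(max(target_frac, 0.0), 1.0)
    if f <= 0:
        return 0.0
    if f >= 1:
        return 1.0
    return (f * mi) / (f * mi + (1 - f) * mo)


def _renewal_states(
    rng: np.random.Generator,
    states: Sequence[str],
    probs: np.ndarray,
    dwell_mean_ms: np.ndarray,
    total_ms: int,
) -> list[tuple[int, str]]:
    """Semi-Markov trajectory: iid state draws with exponential dwells."""
    events: list[tuple[int, str]] = []
    t = 0
    while t < total_ms:
        i = rng.choice(len(states), p=probs)
        events.append((t, states[i]))
        dwell = max(1, int(round(rng.exponential(dwell_mean_ms[i]))))
        t += dwell
    return events


def _episodes(
    rng: np.random.Generator, rate_per_h: float, mean_dur_s: float, total_ms: int
) -> list[tuple[int, int]]:
    """Poisson episode starts with exponential durations, clipped to the session."""
    if rate_per_h <= 0:
        return []
    n = rng.poisson(rate_per_h * total_ms / (3600.0 * MS))
    out = []
    for start in sorted(rng.integers(0, total_ms, size=n)):
        dur = max(1, int(round(rng.exponential(mean_dur_s * MS))))
        out.append((int(start), min(int(start) + dur, total_ms)))
    return _merge_spans(out)


def _merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for lo, hi in sorted(spans):
        if out and lo <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], hi))
        else:
            out.append((lo, hi))
    return out


def _paint(base: list[tuple[int, int, str]], spans: list[tuple[int, int]], state: str) -> list[tuple[int, int, str]]:
    """Overlay ``state`` over an interval list (higher priority paints last)."""
    out: list[tuple[int, int, str]] = []
    for lo, hi, s in base:
        cur = lo
        for a, b in spans:
            a, b = max(a, lo), min(b, hi)
            if a >= b:
                continue
            if cur < a:
                out.append((cur, a, s))
            cur = max(cur, b)
        if cur < hi:
            out.append((cur, hi, s))
    merged = out + [(a, b, state) for a, b in spans if a < b]
    merged.sort()
    return merged


def _complement(spans: list[tuple[int, int]], total_ms: int) -> list[tuple[int, int]]:
    out = []
    cur = 0
    for lo, hi in spans:
        if cur < lo:
            out.append((cur, lo))
        cur = max(cur, hi)
    if cur < total_ms:
        out.append((cur, total_ms))
    return out


# ---------------------------------------------------------------------------
# child simulation


def simulate_child(
    cfg: SimConfig,
    child_seed: int,
    child_id: str,
    schema: PaletteSchema | None = None,
) -> tuple[SimTruth, list[Session]]:
    """Generate one child: ground truth plus one session per campaign.

    Deterministic in ``(cfg, child_seed)``.  With all rates zero the child
    still yields a valid (contact-free) session.
    """
    schema = schema or default_palette()
    rng = np.random.default_rng(child_seed)
    if cfg.any_object_rate_per_h == 0:
        warnings.warn(f"child {child_id}: all mouthing rates are zero")

    # --- observation time and campaign structure -----------------------
    hours = float(
        np.clip(rng.normal(cfg.hours_mean, cfg.hours_sd), cfg.hours_min, cfg.hours_max)
    )
    total_ms = int(round(hours * 3600 * MS))
    both = bool(rng.random() < cfg.p_both_campaigns)
    campaigns = (1, 2) if both else (int(rng.integers(1, 3)),)

    # --- location channel ----------------------------------------------
    locs = list(schema.states[LOCATION])
    if cfg.outdoor_frac_sd > 0:
        a, b = _beta_params(cfg.outdoor_frac_mean, cfg.outdoor_frac_sd)
        target_out = float(rng.beta(a, b))
    else:
        target_out = cfg.outdoor_frac_mean
    p_out = _outdoor_mass(cfg, schema, target_out)
    w = np.array([cfg.location_weights[s] for s in locs], dtype=float)
    is_out = np.array([s in schema.outdoor_locations for s in locs])
    probs = np.zeros(len(locs))
    if is_out.any() and p_out > 0:
        probs[is_out] = p_out * w[is_out] / w[is_out].sum()
    if (~is_out).any():
        probs[~is_out] = (1 - p_out) * w[~is_out] / w[~is_out].sum()
    probs = probs / probs.sum()
    dwell_ms = np.array([cfg.dwell_mean_s[s] * MS for s in locs])
    loc_events = _renewal_states(rng, locs, probs, dwell_ms, total_ms)

    # --- context channel: paint episodes in ascending priority ----------
    ctx_states = schema.states[CONTEXT]
    base = [(0, total_ms, "NoRisk" if "NoRisk" in ctx_states else ctx_states[-1])]
    exposure: dict[str, bool] = {}
    for state in reversed(ctx_states):  # lowest priority first, highest paints last
        cc = cfg.contexts.get(state)
        if cc is None:
            continue
        exposed = bool(rng.random() < cc.propensity)
        exposure[state] = exposed
        if not exposed:
            continue
        spans = _episodes(rng, cc.rate_per_h, cc.mean_dur_s, total_ms)
        base = _paint(base, spans, state)
    ctx_intervals = [(lo, hi, s) for lo, hi, s in base if lo < hi]

    # --- NotInView episodes ---------------------------------------------
    niv = _episodes(rng, cfg.not_in_view_rate_per_h, cfg.not_in_view_mean_s, total_ms)
    observable = _complement(niv, total_ms)

    # --- mouthing contacts ----------------------------------------------
    child_factor = 1.0
    if cfg.child_rate_cv > 0:
        k = 1.0 / cfg.child_rate_cv**2
        child_factor = float(rng.gamma(k, 1.0 / k))
    group_factor = {
        g: float(rng.gamma(shape, 1.0 / shape))
        for g, shape in cfg.group_dispersion.items()
    }
    loc_lookup = _segments(loc_events, total_ms)
    onsets = _draw_onsets(
        rng, cfg, schema, observable, loc_lookup, ctx_intervals, child_factor, group_factor
    )
    contacts_ms = _place_contacts(rng, cfg, schema, onsets, observable)

    # --- compose the OBJECT channel --------------------------------------
    obj = [(0, total_ms, schema.nothing)]
    obj = _paint_states(obj, [(lo, hi, s) for lo, hi, s in contacts_ms])
    obj = _paint(obj, niv, schema.not_in_view)
    obj_intervals = sorted(obj)

    # --- split into sessions / clips and build truth ----------------------
    sessions = _make_sessions(
        cfg, rng, child_id, campaigns, total_ms, obj_intervals, loc_lookup, ctx_intervals
    )
    truth_tl = timeline_from_sessions(sessions, schema, child_id)
    truth_contacts = tuple(extract_contacts(truth_tl, schema))
    params = {
        "hours": hours,
        "campaigns": list(campaigns),
        "target_outdoor_fraction": target_out,
        "child_rate_factor": child_factor,
        "group_factors": group_factor,
        "context_exposure": exposure,
        "configured_any_rate": cfg.any_object_rate_per_h,
    }
    return SimTruth(child_id, truth_tl, truth_contacts, params), sessions


def _segments(events: list[tuple[int, str]], total_ms: int) -> list[tuple[int, int, str]]:
    """Event stream -> merged (start, end, state) segments."""
    segs: list[tuple[int, int, str]] = []
    for i, (t, s) in enumerate(events):
        end = events[i + 1][0] if i + 1 < len(events) else total_ms
        if end <= t:
            continue
        if segs and segs[-1][2] == s and segs[-1][1] == t:
            segs[-1] = (segs[-1][0], end, s)
        else:
            segs.append((t, end, s))
    return segs


def _paint_states(base, spans_with_state):
    out = base
    for lo, hi, state in spans_with_state:
        out = _paint(out, [(lo, hi)], state)
    return sorted(out)


def _draw_onsets(rng, cfg, schema, observable, loc_segs, ctx_segs, child_factor, group_factor):
    """Poisson onsets per (observable x location x context) segment and group."""
    outdoor = schema.outdoor_locations
    eating = schema.eating_context
    # refine observable blocks by location and context boundaries
    cuts = sorted(
        {lo for lo, _, _ in loc_segs}
        | {hi for _, hi, _ in loc_segs}
        | {lo for lo, _, _ in ctx_segs}
        | {hi for _, hi, _ in ctx_segs}
    )
    onsets: list[tuple[int, str, str]] = []  # (t_ms, group, object_state)
    groups = [g for g in schema.groups() if cfg.group_rates_per_h.get(g, 0) > 0]
    group_states = {g: schema.states_in_group(g) for g in groups}
    for blo, bhi in observable:
        pts = [blo] + [c for c in cuts if blo < c < bhi] + [bhi]
        for lo, hi in zip(pts[:-1], pts[1:]):
            loc = _state_at_ms(loc_segs, lo)
            ctx = _state_at_ms(ctx_segs, lo)
            loc_mult = cfg.outdoor_multiplier if loc in outdoor else cfg.indoor_multiplier
            dur_h = (hi - lo) / (3600.0 * MS)
            for g in groups:
                lam = cfg.group_rates_per_h[g] * child_factor * group_factor.get(g, 1.0) * loc_mult
                if g == "food" and ctx == eating:
                    lam *= cfg.eating_food_multiplier
                n = rng.poisson(lam * dur_h)
                if n == 0:
                    continue
                ts = rng.integers(lo, hi, size=n)
                for t in ts:
                    state = group_states[g][rng.integers(0, len(group_states[g]))]
                    onsets.append((int(t), g, state))
    # resolve same-millisecond simultaneity by palette priority
    by_t: dict[int, tuple[int, str, str]] = {}
    for t, g, state in onsets:
        r = schema.rank(OBJECT, state)
        if t not in by_t or r < by_t[t][0]:
            by_t[t] = (r, g, state)
    return sorted((t, g, s) for t, (r, g, s) in by_t.items())


def _state_at_ms(segs, t):
    for lo, hi, s in segs:
        if lo <= t < hi:
            return s
    return segs[-1][2]


def _place_contacts(rng, cfg, schema, onsets, observable):
    """Assign durations, truncating at the next onset and the observable block end."""
    placed: list[tuple[int, int, str]] = []
    mu = np.log(cfg.contact_dur_median_s * MS)
    for i, (t, g, state) in enumerate(onsets):
        dur = max(1, int(round(float(rng.lognormal(mu, cfg.contact_dur_sigma)))))
        end = t + dur
        # clip to the observable block holding the onset
        for blo, bhi in observable:
            if blo <= t < bhi:
                end = min(end, bhi)
                break
        if i + 1 < len(onsets):
            end = min(end, onsets[i + 1][0] - 1)
        end = max(end, t + 1)
        placed.append((t, end, state))
    return placed


def _make_sessions(cfg, rng, child_id, campaigns, total_ms, obj, loc_segs, ctx_segs):
    """Cut the continuous truth into campaign sessions and ~20-min clips."""
    age_group = "6m-<2y" if rng.random() < cfg.p_age_under2 else "2-<5y"
    sex = "M" if rng.random() < cfg.p_male else "F"
    from .mlats import MOBILITY_LEVELS

    mobility = MOBILITY_LEVELS[rng.choice(4, p=list(cfg.mobility_probs))]
    seasons = {"Fiji": {1: "wet", 2: "dry"}}.get(cfg.country, {1: "dry", 2: "wet"})

    channels_segs = {OBJECT: obj, LOCATION: loc_segs, CONTEXT: [tuple(x) for x in ctx_segs]}
    if len(campaigns) == 1:
        session_spans = [(0, total_ms, campaigns[0])]
    else:
        half = total_ms // 2
        session_spans = [(0, half, 1), (half, total_ms, 2)]

    clip_ms = int(cfg.clip_s * MS)
    sessions = []
    for s_lo, s_hi, campaign in session_spans:
        sid = f"{child_id}-c{campaign}"
        bounds = list(range(s_lo, s_hi, clip_ms)) + [s_hi]
        # fold a short tail (< 25% of a clip) into the previous clip
        if len(bounds) > 2 and bounds[-1] - bounds[-2] < clip_ms // 4:
            del bounds[-2]
        clips = []
        for k, (c_lo, c_hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
            events = []
            for ch, segs in channels_segs.items():
                first = True
                for lo, hi, state in segs:
                    if hi <= c_lo or lo >= c_hi:
                        continue
                    t = max(lo, c_lo) - c_lo
                    if first and t != 0:
                        raise AssertionError("segments must tile the session")
                    events.append(CodedEvent(t=t / MS, channel=ch, state=state))
                    first = False
            events.sort(key=lambda e: e.sort_key)
            clips.append(
                ClipRecord(
                    clip_id=f"{sid}-k{k:02d}",
                    session_id=sid,
                    coder_id="truth",
                    duration_s=(c_hi - c_lo) / MS,
                    events=tuple(events),
                )
            )
        sessions.append(
            Session(
                session_id=sid,
                child_id=child_id,
                country=cfg.country,
                campaign=campaign,
                season=seasons[campaign],
                age_group=age_group,
                sex=sex,
                mobility=mobility,
                clips=tuple(clips),
            )
        )
    return sessions


# ---------------------------------------------------------------------------
# coder noise


@dataclass(frozen=True)
class CoderNoise:
    """Independent coder imperfections applied to a truth session."""

    lag_sd_s: float = 0.5
    miss_p: float = 0.02
    misclass_p: float = 0.03
    within_group: bool = True  # misclassify to a state of the same group

    def __post_init__(self) -> None:
        if self.lag_sd_s < 0 or not 0 <= self.miss_p <= 1 or not 0 <= self.misclass_p <= 1:
            raise ValueError("noise parameters out of range")


def simulate_coder(
    session: Session,
    noise: CoderNoise,
    coder_seed: int,
    coder_id: str,
    schema: PaletteSchema | None = None,
) -> Session:
    """A noisy coder's rendering of a truth session.

    Event times get a Gaussian reaction lag (clip-initial restatements stay
    at t=0), non-sentinel object presses are missed with ``miss_p`` and
    misclassified with ``misclass_p``.  Zero noise reproduces the input.
    """
    schema = schema or default_palette()
    rng = np.random.default_rng(coder_seed)
    new_clips = []
    for clip in session.clips:
        events = []
        for e in clip.events:
            t, state = e.t, e.state
            is_obj_press = e.channel == OBJECT and not schema.is_sentinel(state)
            if e.t > 0 and noise.lag_sd_s > 0:
                t = float(np.clip(round(e.t + rng.normal(0, noise.lag_sd_s), 3), 0.001, clip.duration_s))
            if is_obj_press and rng.random() < noise.miss_p:
                continue
            if is_obj_press and rng.random() < noise.misclass_p:
                pool = (
                    schema.states_in_group(schema.group_of(state))
                    if noise.within_group
                    else schema.non_sentinel_objects()
                )
                alternatives = [s for s in pool if s != state]
                if alternatives:
                    state = alternatives[rng.integers(0, len(alternatives))]
            events.append(CodedEvent(t=t, channel=e.channel, state=state))
        events.sort(key=lambda e: e.sort_key)
        new_clips.append(
            ClipRecord(
                clip_id=clip.clip_id,
                session_id=clip.session_id,
                coder_id=coder_id,
                duration_s=clip.duration_s,
                events=tuple(events),
            )
        )
    return Session(
        session_id=session.session_id,
        child_id=session.child_id,
        country=session.country,
        campaign=session.campaign,
        season=session.season,
        age_group=session.age_group,
        sex=session.sex,
        mobility=session.mobility,
        clips=tuple(new_clips),
    )


# ---------------------------------------------------------------------------
# cohorts on disk


def generate_cohort(
    configs: Sequence[SimConfig],
    out_dir,
    seed: int = 0,
    schema: PaletteSchema | None = None,
) -> dict:
    """Write a full on-disk dataset (sessions + parallel truth tree).

    Layout: ``<out>/<country>/<child>/<session_id>/{session.yaml,events.csv}``
    and ``<out>/truth/<child>.json``.  Returns a manifest dict.
    """
    schema = schema or default_palette()
    out = Path(out_dir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "arms": [], "children": []}
    for arm_idx, cfg in enumerate(configs):
        manifest["arms"].append({"country": cfg.country, "n_children": cfg.n_children})
        for i in range(cfg.n_children):
            child_seed = int(
                np.random.SeedSequence([seed, arm_idx, i]).generate_state(1)[0] % (2**31)
            )
            child_id = f"{cfg.country[:2].upper()}{i + 1:03d}"
            truth, sessions = simulate_child(cfg, child_seed, child_id, schema)
            for sess in sessions:
                write_session(sess, out / cfg.country / child_id / sess.session_id)
            _write_truth(truth, out / "truth" / f"{child_id}.json")
            manifest["children"].append(
                {"child_id": child_id, "country": cfg.country, "sessions": len(sessions)}
            )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest


def _write_truth(truth: SimTruth, path: Path) -> None:
    doc = {
        "child_id": truth.child_id,
        "params": truth.params,
        "observed_s": truth.timeline.observed_s,
        "not_in_view_s": truth.timeline.not_in_view_s,
        "n_contacts": len(truth.contacts),
        "contacts": [
            {
                "object": c.object_state,
                "group": c.group,
                "onset_s": c.onset_s,
                "end_s": c.end_s,
                "location": c.location_at_onset,
                "context": c.context_at_onset,
            }
            for c in truth.contacts
        ],
        "intervals": {
            ch: [[iv.start_s, iv.end_s, iv.state] for iv in truth.timeline.channel(ch)]
            for ch in CHANNELS
        },
    }
    path.write_text(json.dumps(doc), encoding="utf-8")


def load_truth(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
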