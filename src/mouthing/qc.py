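"""Intercoder reliability QC: ICC(A,1), the proficiency gate, random checks.

Roughly 15% of clips are double coded.  For each assessed parameter (for
example the per-clip mouthing contact count) the two coders' values form an
n-clips x k-coders ratings matrix, scored with the two-way absolute-agreement
single-measure intraclass correlation coefficient ICC(A,1):

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C and MS_E are the between-clip, between-coder and residual
mean squares of the two-way ANOVA decomposition.  Absolute agreement (not
consistency): a coder who is systematically offset is penalised through
MS_C.  Coders must reach ICC >= 0.75 on every assessed parameter before
coding production clips; weekly checks retrain anyone who slips below.

Rare high-risk codes get a separate random-check loop: clips are reviewed
until either coverage (>= 20% of clips or >= 10 clips) is reached with a
clip error rate <= 0.3, or all clips are exhausted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Mapping, Sequence

import numpy as np

from .intervals import ChildTimeline, extract_contacts, time_in
from .palette import CONTEXT, LOCATION, PaletteSchema


@dataclass(frozen=True)
class RatingsMatrix:
    """Per-clip scalar parameter for each coder; no missing cells."""

    values: np.ndarray  # shape (n_clips, k_coders)
    parameter_name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 2:
            raise ValueError("ratings must be a 2-D clips x coders array")
        n, k = v.shape
        if n < 2 or k < 2:
            raise ValueError(f"need >= 2 clips and >= 2 coders, got {n} x {k}")
        if np.isnan(v).any():
            raise ValueError("missing cells; drop incomplete clips before scoring")


def icc_a1(m: RatingsMatrix | np.ndarray) -> float:
    """Two-way absolute-agreement single-measure ICC.

    All-equal matrices have zero total variance; agreement is trivially
    perfect and 1.0 is returned with a warning.
    """
    v = m.values if isinstance(m, RatingsMatrix) else RatingsMatrix(np.asarray(m)).values
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_total = ((v - grand) ** 2).sum()
    if ss_total == 0.0:
        warnings.warn("zero total variance: all ratings identical, ICC defined as 1")
        return 1.0
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    # residual sum of squares computed directly (numerically exact at zero)
    ss_err = ((v - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return float((ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)))


@dataclass(frozen=True)
class GateReport:
    passed: bool
    iccs: dict[str, float]
    threshold: float
    failing: tuple[str, ...]

    def decision(self) -> str:
        return "pass" if self.passed else "retrain"


def proficiency_gate(
    matrices: Mapping[str, RatingsMatrix] | Sequence[RatingsMatrix],
    threshold: float = 0.75,
) -> GateReport:
    """Pass iff ICC(A,1) >= threshold for every assessed parameter."""
    if not isinstance(matrices, Mapping):
        matrices = {m.parameter_name or f"param_{i}": m for i, m in enumerate(matrices)}
    if not matrices:
        raise ValueError("no parameters to assess")
    iccs = {name: icc_a1(m) for name, m in matrices.items()}
    failing = tuple(name for name, v in iccs.items() if v < threshold)
    return GateReport(passed=not failing, iccs=iccs, threshold=threshold, failing=failing)


# ---------------------------------------------------------------------------
# Random-check stopping rule


class CheckDecision(Enum):
    STOP_AND_CORRECT = "stop_and_correct"
    CONTINUE = "continue"
    EXHAUSTED = "exhausted"


@dataclass(frozen=True)
class CheckState:
    clips_checked: int
    clips_total: int
    errors_found: int

    def __post_init__(self) -> None:
        if not 0 <= self.clips_checked <= self.clips_total:
            raise ValueError("clips_checked must be in [0, clips_total]")
        if not 0 <= self.errors_found <= self.clips_checked:
            raise ValueError("errors_found must be in [0, clips_checked]")

    @property
    def error_rate(self) -> float:
        if self.clips_checked == 0:
            return 0.0
        return self.errors_found / self.clips_checked


def random_check(
    state: CheckState,
    coverage: float = 0.20,
    min_clips: int = 10,
    max_rate: float = 0.3,
) -> CheckDecision:
    """Stopping rule for reviewing rare high-risk codes.

    Stop and correct once coverage is sufficient (>= 20% of all clips checked,
    or at least 10 clips) and the clip-level error rate is <= 0.3; if every
    clip has been reviewed the search is exhausted regardless of rate;
    otherwise keep checking.
    """
    if state.clips_checked == state.clips_total:
        covered = True
        if state.error_rate <= max_rate and state.clips_checked > 0:
            return CheckDecision.STOP_AND_CORRECT
        return CheckDecision.EXHAUSTED
    covered = (
        state.clips_checked / state.clips_total >= coverage
        or state.clips_checked >= min_clips
    )
    if covered and state.error_rate <= max_rate:
        return CheckDecision.STOP_AND_CORRECT
    return CheckDecision.CONTINUE


# ---------------------------------------------------------------------------
# Building ratings matrices from double-coded clips

#: Default assessed parameters: callables mapping (timeline, schema) -> scalar.
def _any_contacts(tl: ChildTimeline, schema: PaletteSchema) -> float:
    return float(len(extract_contacts(tl, schema)))


def _food_contacts(tl: ChildTimeline, schema: PaletteSchema) -> float:
    return float(sum(1 for c in extract_contacts(tl, schema) if c.group == "food"))


def _outdoor_seconds(tl: ChildTimeline, schema: PaletteSchema) -> float:
    return time_in(tl, LOCATION, schema.outdoor_locations)


def _high_risk_ctx_seconds(tl: ChildTimeline, schema: PaletteSchema) -> float:
    return time_in(tl, CONTEXT, schema.high_risk_contexts)


DEFAULT_PARAMETERS: dict[str, Callable[[ChildTimeline, PaletteSchema], float]] = {
    "any_contact_count": _any_contacts,
    "food_contact_count": _food_contacts,
    "outdoor_seconds": _outdoor_seconds,
    "high_risk_context_seconds": _high_risk_ctx_seconds,
}


def sample_double_coded(
    clip_ids: Sequence[str], fraction: float = 0.15, seed: int | np.random.Generator = 0
) -> list[str]:
    """Seeded uniform sample of clips for double coding (~15% by default).

    At least one clip is sampled whenever any exist.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(clip_ids)
    if not ids:
        return []
    k = max(1, int(round(fraction * len(ids))))
    picked = rng.choice(len(ids), size=k, replace=False)
    return [ids[i] for i in sorted(picked)]


def ratings_from_timelines(
    coder_a: Sequence[ChildTimeline],
    coder_b: Sequence[ChildTimeline],
    schema: PaletteSchema,
    parameters: Mapping[str, Callable] | None = None,
) -> dict[str, RatingsMatrix]:
    """Score paired per-clip timelines from two coders into ratings matrices."""
    if len(coder_a) != len(coder_b):
        raise ValueError("coders rated different numbers of clips")
    params = dict(parameters or DEFAULT_PARAMETERS)
    out: dict[str, RatingsMatrix] = {}
    for name, fn in params.items():
        values = np.array(
            [[fn(a, schema), fn(b, schema)] for a, b in zip(coder_a, coder_b)]
        )
        out[name] = RatingsMatrix(values=values, parameter_name=name)
    return out
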