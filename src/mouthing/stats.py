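"""Inferential layer: Wilcoxon rank-sum and Yates-corrected chi-square.

The analysis is primarily descriptive; where sample sizes permit,
between-group differences in per-child rates and durations are tested with
the two-sided Wilcoxon rank-sum test (exact enumeration for small untied
samples, tie-corrected normal approximation with continuity correction
otherwise) and associations between binary child factors and binary
exposure indicators with the chi-square test with Yates' continuity
correction, refused when expected cell counts are too small.  No
multiplicity adjustment is applied; the suite reports how many tests it ran.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

EXACT_LIMIT = 12  # pooled sample size up to which untied samples are enumerated


class ApplicabilityError(ValueError):
    """A test's validity conditions are not met for this table."""


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n_per_group: tuple[int, ...]
    comparison: str = ""
    method: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of range: {self.p_value}")


def _clean(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    return arr[~np.isnan(arr)]


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], method: str = "auto", comparison: str = ""
) -> TestResult:
    """Two-sided Wilcoxon rank-sum test on two independent samples.

    The statistic is the rank sum of ``x`` under midranks.  ``method``:
    ``"exact"`` enumerates all assignments of the pooled values (only
    meaningful without ties), ``"normal"`` uses the tie-corrected normal
    approximation with continuity correction, ``"auto"`` picks exact when
    n_x + n_y <= 12 and the pooled values are distinct.
    """
    x, y = _clean(x), _clean(y)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups need at least one value")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    n = n1 + n2
    has_ties = len(np.unique(pooled)) < n

    if method == "auto":
        method = "exact" if (n <= EXACT_LIMIT and not has_ties) else "normal"
    if method == "exact":
        # Enumerate every way to assign n1 of the pooled ranks to group x.
        total = math.comb(n, n1)
        le = ge = 0
        for idx in combinations(range(n), n1):
            s = ranks[list(idx)].sum()
            if s <= w + 1e-9:
                le += 1
            if s >= w - 1e-9:
                ge += 1
        p = min(1.0, 2.0 * min(le, ge) / total)
        return TestResult(
            "wilcoxon_rank_sum", w, p, (n1, n2), comparison, method="exact"
        )
    # Tie-corrected normal approximation with continuity correction.
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:  # all pooled values identical
        return TestResult(
            "wilcoxon_rank_sum", w, 1.0, (n1, n2), comparison, method="normal"
        )
    z = (abs(w - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    p = float(2.0 * norm.sf(z))
    return TestResult(
        "wilcoxon_rank_sum", w, min(p, 1.0), (n1, n2), comparison, method="normal"
    )


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], comparison: str = ""
) -> TestResult:
    """Paired alternative for within-child contrasts (e.g. indoor vs outdoor).

    Provided for sensitivity analysis; the primary location comparison treats
    the per-child conditional rates as independent samples.
    """
    from scipy.stats import wilcoxon as _scipy_wilcoxon

    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    d = x[mask] - y[mask]
    d = d[d != 0]
    if len(d) == 0:
        return TestResult("wilcoxon_signed_rank", 0.0, 1.0, (int(mask.sum()),) * 2, comparison)
    stat, p = _scipy_wilcoxon(d, correction=True)
    return TestResult(
        "wilcoxon_signed_rank", float(stat), float(p), (len(d), len(d)), comparison
    )


def chi_square_yates(table: Sequence[Sequence[float]], comparison: str = "") -> TestResult:
    """Chi-square test of association for a 2x2 table with Yates' correction.

    X^2 = sum over cells of (max(|O - E| - 0.5, 0))^2 / E with 1 df.  Refuses
    (``ApplicabilityError``) when more than 20% of cells — for a 2x2, any
    cell — have expected count below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative cell count")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    n = t.sum()
    if (row == 0).any() or (col == 0).any():
        raise ValueError("zero row/column margin")
    expected = np.outer(row, col) / n
    n_small = int((expected < 5).sum())
    if n_small / expected.size > 0.20:
        raise ApplicabilityError(
            f"{n_small} of 4 cells have expected count < 5 (> 20% of cells); "
            "chi-square with continuity correction is not applicable"
        )
    adj = np.maximum(np.abs(t - expected) - 0.5, 0.0)
    x2 = float((adj**2 / expected).sum())
    p = float(chi2.sf(x2, df=1))
    return TestResult(
        "chi_square_yates",
        x2,
        p,
        tuple(int(v) for v in row),
        comparison,
        method="yates",
        extra={"expected_min": float(expected.min())},
    )


# ---------------------------------------------------------------------------
# The comparison suite


@dataclass(frozen=True)
class Comparison:
    """One planned test: ``outcome`` by ``factor`` within ``stratum``."""

    outcome: str
    factor: str
    stratum: str = "all"  # country name, or "all" for between-country
    test: str = "wilcoxon"  # "wilcoxon" | "chi_square"
    label: str = ""


def _factor_groups(df: pd.DataFrame, factor: str) -> tuple[pd.Series, str]:
    """Dichotomize a child factor; returns boolean series + description."""
    if factor == "age_group":
        return df["age_group"] == "2-<5y", "2-<5y vs 6m-<2y"
    if factor == "mobility":
        # walking vs pre-walking: "walking only" against everything else
        return df["mobility"] == "walking only", "walking only vs pre-walking"
    if factor == "sex":
        return df["sex"] == "F", "F vs M"
    if factor == "country":
        countries = sorted(df["country"].unique())
        if len(countries) != 2:
            raise ValueError(f"country comparison needs 2 countries, found {countries}")
        return df["country"] == countries[0], f"{countries[0]} vs {countries[1]}"
    raise ValueError(f"unknown factor: {factor!r}")


def default_plan(countries: Sequence[str]) -> list[Comparison]:
    """The study's comparison grid.

    Within each country: mouthing frequency and outdoor time by age group,
    mobility (walking vs pre-walking) and sex, plus mouthing frequency by
    location (indoor vs outdoor conditional rates).  Between countries:
    overall mouthing frequency, mouthing frequency within high-risk contexts,
    and outdoor time.  Chi-square: age group and sex against the any-high-
    risk-context indicator, within country.
    """
    plan: list[Comparison] = []
    for ctry in countries:
        for outcome in ("rate_any", "outdoor_min_per_h"):
            for factor in ("age_group", "mobility", "sex"):
                plan.append(Comparison(outcome, factor, ctry, "wilcoxon"))
        plan.append(Comparison("rate_by_location", "location", ctry, "wilcoxon"))
        for factor in ("age_group", "sex"):
            plan.append(Comparison("any_high_risk_ctx", factor, ctry, "chi_square"))
    for outcome in ("rate_any", "rate_high_risk_ctx", "outdoor_min_per_h"):
        plan.append(Comparison(outcome, "country", "all", "wilcoxon"))
    return plan


def run_comparison(df: pd.DataFrame, comp: Comparison, paired_location: bool = False) -> TestResult:
    sub = df if comp.stratum == "all" else df[df["country"] == comp.stratum]
    if sub.empty:
        raise ValueError(f"stratum {comp.stratum!r} has no children")
    label = f"{comp.outcome} | {comp.factor} | {comp.stratum}"
    if comp.outcome == "rate_by_location":
        x = sub["rate_indoor"]
        y = sub["rate_outdoor"]
        if paired_location:
            return wilcoxon_signed_rank(x.tolist(), y.tolist(), comparison=label)
        return wilcoxon_rank_sum(
            x.dropna().tolist(), y.dropna().tolist(), comparison=label + " (indoor vs outdoor)"
        )
    mask, desc = _factor_groups(sub, comp.factor)
    if mask.all() or (~mask).all():
        raise ValueError(f"factor {comp.factor!r} has a single level in {comp.stratum!r}")
    if comp.test == "chi_square":
        flag = sub[comp.outcome].astype(bool)
        table = [
            [int((mask & flag).sum()), int((mask & ~flag).sum())],
            [int((~mask & flag).sum()), int((~mask & ~flag).sum())],
        ]
        return chi_square_yates(table, comparison=f"{label} ({desc})")
    x = sub.loc[mask, comp.outcome].dropna().tolist()
    y = sub.loc[~mask, comp.outcome].dropna().tolist()
    return wilcoxon_rank_sum(x, y, comparison=f"{label} ({desc})")


def run_comparison_suite(
    df: pd.DataFrame,
    plan: Sequence[Comparison] | None = None,
    paired_location: bool = False,
    skip_inapplicable: bool = True,
) -> pd.DataFrame:
    """Execute a comparison plan over the per-child summary table.

    Returns a tidy frame (one row per planned test, in plan order).  Tests
    refused for validity (sparse chi-square cells) or degenerate strata are
    reported with a note rather than a p-value when ``skip_inapplicable``.
    """
    if plan is None:
        plan = default_plan(sorted(df["country"].unique()))
    rows = []
    for comp in plan:
        base = {
            "outcome": comp.outcome,
            "factor": comp.factor,
            "stratum": comp.stratum,
            "test": comp.test,
        }
        try:
            res = run_comparison(df, comp, paired_location=paired_location)
            rows.append(
                {
                    **base,
                    "comparison": res.comparison,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "method": res.method,
                    "n_1": res.n_per_group[0],
                    "n_2": res.n_per_group[1],
                    "note": "",
                }
            )
        except (ApplicabilityError, ValueError) as exc:
            if not skip_inapplicable:
                raise
            rows.append(
                {
                    **base,
                    "comparison": "",
                    "statistic": np.nan,
                    "p_value": np.nan,
                    "method": "",
                    "n_1": 0,
                    "n_2": 0,
                    "note": str(exc),
                }
            )
    out = pd.DataFrame(rows)
    out.attrs["n_tests_run"] = int(out["p_value"].notna().sum())
    out.attrs["n_tests_planned"] = len(plan)
    return out
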