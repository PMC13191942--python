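"""Model/Results facade tying the pipeline stages together.

``ExposureStudy`` is built from coded sessions (on disk or in memory) plus a
palette; ``fit()`` reconstructs every child's timeline, extracts contacts,
computes per-child exposure summaries and returns an ``ExposureResults``
carrying the tidy per-child table, the cohort descriptive tables, the
intersection (location x context) analysis and, when requested, the planned
statistical comparisons.  ``summary()`` renders the headline numbers as
text; everything is also exportable as CSV.

    >>> study = ExposureStudy.from_directory("cohort/", palette)
    >>> res = study.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import metrics as _metrics
from .intervals import extract_contacts, timeline_from_sessions
from .mlats import Session, iter_session_dirs, read_session
from .palette import PaletteSchema, default_palette, palette_to_json
from .stats import Comparison, run_comparison_suite


@dataclass
class ExposureResults:
    """Fitted cohort results; all tables are tidy pandas frames."""

    child_summaries: pd.DataFrame
    group_tables: pd.DataFrame
    duration_tables: pd.DataFrame
    intersection: pd.DataFrame
    comparisons: pd.DataFrame | None
    eating_shares: dict
    manifest: dict = field(default_factory=dict)

    @property
    def n_children(self) -> int:
        return len(self.child_summaries)

    def summary(self) -> str:
        df = self.child_summaries
        lines = [
            "Child mouthing exposure summary",
            "=" * 48,
            f"children: {self.n_children}"
            f"  (observed {df['observed_h'].sum():.1f} h total,"
            f" mean {df['observed_h'].mean():.1f} h/child)",
            "",
        ]
        for ctry, sub in df.groupby("country"):
            lines.append(f"{ctry} (n = {len(sub)})")
            r = sub["rate_any"]
            lines.append(
                f"  any-object mouthing: median {r.median():.1f} contacts/h"
                f" (mean {r.mean():.1f} +/- {r.std():.1f})"
            )
            o = sub["outdoor_min_per_h"]
            pct_out = 100.0 * (sub["any_outdoor"]).mean()
            lines.append(
                f"  time outdoors: median {o.median():.1f} min/h"
                f" (mean {o.mean():.1f}), {pct_out:.0f}% of children observed outdoors"
            )
            pct_hro = 100.0 * (sub["any_high_risk_object"]).mean()
            pct_hrc = 100.0 * (sub["any_high_risk_ctx"]).mean()
            lines.append(
                f"  high-risk objects mouthed by {pct_hro:.0f}% of children;"
                f" {pct_hrc:.0f}% observed in a high-risk context"
            )
            lines.append("")
        if self.comparisons is not None:
            n_run = self.comparisons.attrs.get("n_tests_run", len(self.comparisons))
            lines.append(f"statistical comparisons run: {n_run} (no multiplicity adjustment)")
            sig = self.comparisons.dropna(subset=["p_value"])
            for _, row in sig[sig["p_value"] < 0.05].iterrows():
                lines.append(
                    f"  p={row['p_value']:.4g}  {row['comparison']}"
                )
        return "\n".join(lines)

    def plot_group_rates(self, ax=None):
        """Bar chart of median per-group mouthing rates by cohort group."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        tab = self.group_tables.pivot_table(
            index="measure", columns="country", values="median"
        )
        tab.plot.bar(ax=ax)
        ax.set_ylabel("median contacts/h")
        ax.set_xlabel("object group")
        return ax

    def save(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.child_summaries.to_csv(out / "children.csv", index=False)
        self.group_tables.to_csv(out / "object_group_table.csv", index=False)
        self.duration_tables.to_csv(out / "duration_table.csv", index=False)
        self.intersection.to_csv(out / "intersection_table.csv", index=False)
        if self.comparisons is not None:
            self.comparisons.to_csv(out / "comparisons.csv", index=False)
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2), encoding="utf-8"
        )
        (out / "summary.txt").write_text(self.summary() + "\n", encoding="utf-8")
        return out


class ExposureStudy:
    """Exposure analysis model over a cohort of coded sessions.

    Parameters
    ----------
    sessions : sequence of Session
        Coded sessions; multiple sessions per child are pooled (combined
        across campaigns) before any rate is computed.
    palette : PaletteSchema, optional
        Defaults to the packaged palette.
    exclude_not_in_view : bool
        If True (default) NotInView time is removed from every rate
        denominator; if False denominators are gross video duration.
    """

    def __init__(
        self,
        sessions: Sequence[Session],
        palette: PaletteSchema | None = None,
        exclude_not_in_view: bool = True,
    ):
        if not sessions:
            raise ValueError("no sessions supplied")
        self.palette = palette or default_palette()
        self.exclude_not_in_view = exclude_not_in_view
        by_child: dict[str, list[Session]] = {}
        for s in sessions:
            by_child.setdefault(s.child_id, []).append(s)
        for cid in by_child:
            by_child[cid].sort(key=lambda s: (s.campaign, s.session_id))
        self._by_child = by_child

    @classmethod
    def from_directory(
        cls,
        root,
        palette: PaletteSchema | None = None,
        exclude_not_in_view: bool = True,
    ) -> "ExposureStudy":
        palette = palette or default_palette()
        sessions = [read_session(d, palette) for d in iter_session_dirs(root)]
        return cls(sessions, palette, exclude_not_in_view)

    @property
    def n_children(self) -> int:
        return len(self._by_child)

    def child_summary(self, child_id: str) -> _metrics.ExposureSummary:
        sessions = self._by_child[child_id]
        tl = timeline_from_sessions(sessions, self.palette, child_id)
        contacts = extract_contacts(tl, self.palette)
        first = sessions[0]
        meta = {
            "country": first.country,
            "age_group": first.age_group,
            "sex": first.sex,
            "mobility": first.mobility,
            "n_campaigns": len({s.campaign for s in sessions}),
        }
        return _metrics.summarize_child(
            tl, contacts, self.palette, meta, self.exclude_not_in_view
        )

    def fit(
        self,
        plan: Sequence[Comparison] | None = None,
        run_tests: bool = True,
        paired_location: bool = False,
    ) -> ExposureResults:
        summaries = [self.child_summary(cid) for cid in sorted(self._by_child)]
        df = _metrics.summaries_to_frame(summaries)
        groups = self.palette.groups()
        gt = pd.concat(
            [
                _metrics.cohort_table(df, "rate_any", observed_col="contacts_any").assign(
                    measure="any"
                )
            ]
            + [
                _metrics.cohort_table(
                    df, f"rate_{g}", observed_col=f"contacts_{g}"
                ).assign(measure=g)
                for g in groups
            ],
            ignore_index=True,
        )
        dt_rows = [
            _metrics.cohort_table(df, "outdoor_min_per_h").assign(measure="outdoor"),
            _metrics.cohort_table(df, "high_risk_ctx_min_per_h").assign(
                measure="any_high_risk_context"
            ),
        ]
        for ctx in sorted(self.palette.high_risk_contexts):
            dt_rows.append(
                _metrics.cohort_table(df, f"ctx_{ctx}_min_per_h").assign(measure=ctx)
            )
        dt = pd.concat(dt_rows, ignore_index=True)
        inter = _metrics.intersection_table(df)
        comparisons = None
        if run_tests and df["country"].nunique() >= 1:
            comparisons = run_comparison_suite(df, plan, paired_location=paired_location)
        shares = {}
        for stratum in ("indoor", "outdoor"):
            try:
                shares[stratum] = _metrics.eating_related_share(df, stratum)
            except ValueError:
                shares[stratum] = None
        manifest = {
            "n_children": len(df),
            "exclude_not_in_view": self.exclude_not_in_view,
            "palette_sha256": hashlib.sha256(
                palette_to_json(self.palette).encode()
            ).hexdigest(),
            "attribution": "onset",
        }
        return ExposureResults(
            child_summaries=df,
            group_tables=gt,
            duration_tables=dt,
            intersection=inter,
            comparisons=comparisons,
            eating_shares=shares,
            manifest=manifest,
        )
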