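"""Modified-VIKOR aspiration-level gaps over multi-group performance surveys.

Instead of normalizing against the best and worst *observed* alternatives,
the modified form measures every performance ``f`` against a fixed aspiration
level ``f*`` and worst level ``f-``:

    gap = (f* - f) / (f* - f-)

so a gap of 0 means the aspiration is attained and 1 means the worst level.
Performances aggregate upward by weighted means — criterion scores to
dimension performances with local weights, dimension performances to a total
with dimension weights — and the gap at every level is taken of that level's
own performance.  Weights are renormalized to sum exactly 1 before every
weighted mean, which is what makes rounded published weight tables
reproducible.  All arithmetic is done at full precision; rounding (half-up,
3 decimals) happens only in the report layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._round import round_half_up
from .danp import WeightSet
from .framework import EvaluationFramework

__all__ = [
    "AspirationScale",
    "PerformanceSurvey",
    "GapReport",
    "criterion_performance",
    "criterion_gap",
    "dimension_performance",
    "total_performance",
    "build_gap_report",
    "gap_report_from_performances",
]


@dataclass(frozen=True)
class AspirationScale:
    """Aspiration and worst levels of the rating instrument (default 10/0)."""

    f_star: float = 10.0
    f_worst: float = 0.0

    def __post_init__(self) -> None:
        if not self.f_star > self.f_worst:
            raise ValueError("aspiration level must exceed the worst level")

    @property
    def span(self) -> float:
        return self.f_star - self.f_worst


@dataclass(frozen=True)
class PerformanceSurvey:
    """One respondent group's scores: rows are respondents, columns criteria."""

    group: str
    records: pd.DataFrame
    scale: AspirationScale = AspirationScale()

    def __post_init__(self) -> None:
        if self.records.empty:
            raise ValueError(f"performance survey for {self.group!r} is empty")
        vals = self.records.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(
                f"survey {self.group!r} has missing cells; use from_long(..., "
                "on_missing='drop') to drop incomplete questionnaires"
            )
        if vals.min() < self.scale.f_worst or vals.max() > self.scale.f_star:
            raise ValueError(
                f"survey {self.group!r} has scores outside "
                f"[{self.scale.f_worst}, {self.scale.f_star}]"
            )

    @property
    def n_respondents(self) -> int:
        return len(self.records)

    @classmethod
    def from_long(
        cls,
        table: pd.DataFrame,
        group: str,
        criteria: Sequence[str],
        scale: AspirationScale = AspirationScale(),
        on_missing: str = "error",
    ) -> "PerformanceSurvey":
        """Build from long-format rows (respondent_id, group, criterion_code, score).

        ``on_missing="drop"`` silently discards questionnaires that do not
        cover every criterion (the count is recoverable by comparing
        respondent ids); ``"error"`` (default) rejects them.
        """
        sub = table[table["group"] == group]
        wide = sub.pivot(index="respondent_id", columns="criterion_code", values="score")
        missing_cols = set(criteria) - set(wide.columns)
        if missing_cols:
            raise ValueError(
                f"group {group!r} never scored criteria {sorted(missing_cols)}"
            )
        wide = wide[list(criteria)]
        incomplete = wide.isna().any(axis=1)
        if incomplete.any():
            if on_missing == "drop":
                wide = wide[~incomplete]
                if wide.empty:
                    raise ValueError(f"group {group!r}: every record was incomplete")
            else:
                raise ValueError(
                    f"group {group!r} has {int(incomplete.sum())} incomplete "
                    "questionnaires"
                )
        return cls(group=group, records=wide, scale=scale)

    def to_long(self) -> pd.DataFrame:
        long = self.records.reset_index(names="respondent_id").melt(
            id_vars="respondent_id", var_name="criterion_code", value_name="score"
        )
        long.insert(1, "group", self.group)
        return long


def criterion_performance(survey: PerformanceSurvey) -> pd.Series:
    """Arithmetic mean score per criterion over the group's respondents."""
    return survey.records.mean(axis=0)


def criterion_gap(f, scale: AspirationScale = AspirationScale()):
    """Aspiration gap ``(f* - f) / (f* - f-)`` of a performance (scalar or Series)."""
    arr = np.asarray(f, dtype=float)
    if np.any(arr < scale.f_worst - 1e-12) or np.any(arr > scale.f_star + 1e-12):
        raise ValueError("performance outside the aspiration scale")
    gap = (scale.f_star - arr) / scale.span
    if isinstance(f, pd.Series):
        return pd.Series(gap, index=f.index)
    return float(gap) if arr.ndim == 0 else gap


def _weighted_mean(values: pd.Series, weights: pd.Series) -> float:
    """Weighted mean with weights renormalized to sum exactly 1."""
    w = weights.to_numpy(dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return float(values.to_numpy(dtype=float) @ (w / total))


def dimension_performance(
    f: pd.Series, local_weights: pd.Series, framework: EvaluationFramework
) -> pd.Series:
    """Local-weighted mean of criterion performances, per dimension."""
    out = {}
    for d in framework.dimension_codes:
        codes = framework.codes_of(d)
        missing = [c for c in codes if c not in f.index or c not in local_weights.index]
        if missing:
            raise ValueError(f"missing performance or weight for {missing}")
        out[d] = _weighted_mean(f[codes], local_weights[codes])
    return pd.Series(out)


def total_performance(dim_perf: pd.Series, dim_weights: pd.Series) -> float:
    """Dimension-weighted mean of dimension performances."""
    missing = [d for d in dim_perf.index if d not in dim_weights.index]
    if missing:
        raise ValueError(f"missing dimension weights for {missing}")
    return _weighted_mean(dim_perf, dim_weights[dim_perf.index])


@dataclass(frozen=True)
class GapReport:
    """Performance and aspiration gap per group at every aggregation level.

    ``criterion_tables`` and ``dimension_tables`` map a group label to a
    DataFrame with ``performance`` and ``gap`` columns; ``totals`` maps a
    group to its (performance, gap) pair.  Values are unrounded;
    :meth:`published_layout` renders the half-up 3-decimal view.
    """

    framework: EvaluationFramework
    weights: WeightSet
    scale: AspirationScale
    criterion_tables: dict[str, pd.DataFrame]
    dimension_tables: dict[str, pd.DataFrame]
    totals: dict[str, dict[str, float]]

    @property
    def groups(self) -> list[str]:
        return list(self.criterion_tables)

    def performance(self, group: str, level: str = "criterion") -> pd.Series | float:
        if level == "criterion":
            return self.criterion_tables[group]["performance"]
        if level == "dimension":
            return self.dimension_tables[group]["performance"]
        if level == "total":
            return self.totals[group]["performance"]
        raise ValueError(f"unknown level {level!r}")

    def gap(self, group: str, level: str = "criterion") -> pd.Series | float:
        if level == "criterion":
            return self.criterion_tables[group]["gap"]
        if level == "dimension":
            return self.dimension_tables[group]["gap"]
        if level == "total":
            return self.totals[group]["gap"]
        raise ValueError(f"unknown level {level!r}")

    def published_layout(self, decimals: int = 3) -> pd.DataFrame:
        """Render the familiar published table: dimension rows (in bold
        position) followed by their criteria, then total rows; one
        performance and one gap column per group; half-up rounding."""
        fw = self.framework
        rows = []
        for d in fw.dimension_codes:
            row = {
                "code": d,
                "kind": "dimension",
                "weight": round_half_up(self.weights.dimension[d], decimals),
                "global_weight": np.nan,
            }
            for g in self.groups:
                row[f"{g}_performance"] = round_half_up(
                    self.dimension_tables[g].loc[d, "performance"], decimals
                )
                row[f"{g}_gap"] = round_half_up(
                    self.dimension_tables[g].loc[d, "gap"], decimals
                )
            rows.append(row)
            for c in fw.codes_of(d):
                row = {
                    "code": c,
                    "kind": "criterion",
                    "weight": round_half_up(self.weights.local[c], decimals),
                    "global_weight": round_half_up(self.weights.global_[c], decimals),
                }
                for g in self.groups:
                    row[f"{g}_performance"] = round_half_up(
                        self.criterion_tables[g].loc[c, "performance"], decimals
                    )
                    row[f"{g}_gap"] = round_half_up(
                        self.criterion_tables[g].loc[c, "gap"], decimals
                    )
                rows.append(row)
        total_row = {"code": "TOTAL", "kind": "total", "weight": np.nan,
                     "global_weight": np.nan}
        for g in self.groups:
            total_row[f"{g}_performance"] = round_half_up(
                self.totals[g]["performance"], decimals
            )
            total_row[f"{g}_gap"] = round_half_up(self.totals[g]["gap"], decimals)
        rows.append(total_row)
        return pd.DataFrame(rows).set_index("code")


def gap_report_from_performances(
    performances: Mapping[str, pd.Series],
    weights: WeightSet,
    scale: AspirationScale = AspirationScale(),
    framework: EvaluationFramework | None = None,
) -> GapReport:
    """Build a full gap report from per-group criterion performances.

    This is the entry point when criterion means are already known (e.g. a
    published evaluation table); :func:`build_gap_report` computes them from
    raw surveys first.
    """
    fw = framework or weights.framework
    crit_tables: dict[str, pd.DataFrame] = {}
    dim_tables: dict[str, pd.DataFrame] = {}
    totals: dict[str, dict[str, float]] = {}
    for group, f in performances.items():
        missing = set(fw.criterion_codes) - set(f.index)
        if missing:
            raise ValueError(
                f"group {group!r} does not cover criteria {sorted(missing)}"
            )
        f = f[fw.criterion_codes]
        crit_tables[group] = pd.DataFrame(
            {"performance": f, "gap": criterion_gap(f, scale)}
        )
        dperf = dimension_performance(f, weights.local, fw)
        dim_tables[group] = pd.DataFrame(
            {"performance": dperf, "gap": criterion_gap(dperf, scale)}
        )
        tperf = total_performance(dperf, weights.dimension)
        totals[group] = {
            "performance": tperf,
            "gap": float(criterion_gap(tperf, scale)),
        }
    return GapReport(
        framework=fw,
        weights=weights,
        scale=scale,
        criterion_tables=crit_tables,
        dimension_tables=dim_tables,
        totals=totals,
    )


def build_gap_report(
    surveys: Sequence[PerformanceSurvey],
    weights: WeightSet,
    scale: AspirationScale = AspirationScale(),
    framework: EvaluationFramework | None = None,
) -> GapReport:
    """Score every respondent group: means, then gaps at all three levels."""
    fw = framework or weights.framework
    performances = {}
    for survey in surveys:
        if set(survey.records.columns) != set(fw.criterion_codes):
            raise ValueError(
                f"group {survey.group!r} covers a different criterion set "
                "than the framework"
            )
        performances[survey.group] = criterion_performance(survey)
    return gap_report_from_performances(performances, weights, scale, fw)
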