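"""Improvement-priority synthesis: largest gaps paired with influence sources.

The end product of the pipeline is not a ranking of alternatives but a
root-cause reading of one system: for each dimension, which criterion is
furthest from aspiration (the largest gap) and which criterion is the net
influence *source* within that dimension — the lever to act on.  The overall
section pairs the globally largest-gap criterion with the top source
dimension of the whole map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import pandas as pd
import yaml

from ._round import round_half_up
from .dematel import (
    INRMCoordinates,
    TotalInfluence,
    aggregate_to_dimensions,
    inrm_coordinates,
    influence_order,
)
from .framework import EvaluationFramework
from .vikor import GapReport

__all__ = ["ImprovementReport", "DimensionFinding", "rank_gaps", "build_improvement_report"]

#: Two gaps closer than this are reported as a joint (tied) rank.
GAP_TIE_TOL = 1e-9


def rank_gaps(
    report: GapReport,
    group: str,
    level: str = "dimension",
    scope: str | None = None,
) -> pd.DataFrame:
    """Rank codes by gap, largest first; ties keep display order, flagged joint.

    ``level`` is ``"dimension"`` or ``"criterion"``; a criterion-level ranking
    may be restricted to one dimension via ``scope``.
    """
    if group not in report.groups:
        raise ValueError(f"unknown group {group!r}")
    fw = report.framework
    if level == "dimension":
        if scope is not None:
            raise ValueError("dimension-level ranking takes no scope")
        gaps = report.gap(group, "dimension")
    elif level == "criterion":
        gaps = report.gap(group, "criterion")
        if scope is not None:
            if scope not in fw.dimension_codes:
                raise ValueError(f"unknown scope {scope!r}")
            gaps = gaps[fw.codes_of(scope)]
    else:
        raise ValueError(f"unknown level {level!r}")
    ordered = gaps.sort_values(ascending=False, kind="stable")
    joint = pd.Series(False, index=ordered.index)
    vals = ordered.to_numpy()
    for i in range(len(vals)):
        near = (abs(vals - vals[i]) < GAP_TIE_TOL).sum()
        joint.iloc[i] = near > 1
    return pd.DataFrame({"gap": ordered, "joint": joint})


@dataclass(frozen=True)
class DimensionFinding:
    """Per-dimension reading: its gap, worst criteria, and influence source."""

    dimension: str
    gap: float
    influence_order: tuple[str, ...]
    largest_gap_criteria: tuple[str, ...]  # >1 entry on a joint tie
    largest_gap_value: float
    influence_source: str
    source_is_largest_gap: bool


@dataclass(frozen=True)
class ImprovementReport:
    """Structured improvement priorities for one respondent group."""

    group: str
    dimension_gap_ranking: tuple[tuple[str, float], ...]
    findings: tuple[DimensionFinding, ...]  # ordered by the gap ranking
    overall_largest_gap_criteria: tuple[str, ...]
    overall_largest_gap_value: float
    overall_source_dimension: str
    dimension_influence_order: tuple[str, ...]

    def to_dict(self) -> dict[str, Any]:
        return {
            "group": self.group,
            "dimension_gap_ranking": [
                {"code": c, "gap": round_half_up(g)} for c, g in self.dimension_gap_ranking
            ],
            "dimension_influence_order": list(self.dimension_influence_order),
            "overall": {
                "largest_gap_criteria": list(self.overall_largest_gap_criteria),
                "largest_gap_value": round_half_up(self.overall_largest_gap_value),
                "source_dimension": self.overall_source_dimension,
            },
            "dimensions": [
                {
                    "code": f.dimension,
                    "gap": round_half_up(f.gap),
                    "influence_order": list(f.influence_order),
                    "largest_gap_criteria": list(f.largest_gap_criteria),
                    "largest_gap_value": round_half_up(f.largest_gap_value),
                    "influence_source": f.influence_source,
                    "source_is_largest_gap": f.source_is_largest_gap,
                }
                for f in self.findings
            ],
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    def render_text(self) -> str:
        lines = [f"Improvement priorities — group: {self.group}", ""]
        ranking = ", ".join(
            f"{c} ({round_half_up(g):.3f})" for c, g in self.dimension_gap_ranking
        )
        lines.append(f"Dimension gaps, largest first: {ranking}")
        lines.append(
            "Dimension influence order (net sources first): "
            + ", ".join(self.dimension_influence_order)
        )
        lines.append(
            f"Largest criterion gap overall: "
            + " and ".join(self.overall_largest_gap_criteria)
            + f" ({round_half_up(self.overall_largest_gap_value):.3f}); "
            f"top source dimension: {self.overall_source_dimension}"
        )
        lines.append("")
        for f in self.findings:
            tie = " (joint)" if len(f.largest_gap_criteria) > 1 else ""
            coincide = (
                " — note: the source criterion itself has the largest gap"
                if f.source_is_largest_gap
                else ""
            )
            lines.append(
                f"{f.dimension}: gap {round_half_up(f.gap):.3f}; influence order "
                + ", ".join(f.influence_order)
                + f"; largest gap {' and '.join(f.largest_gap_criteria)}{tie} "
                f"({round_half_up(f.largest_gap_value):.3f}); act on source "
                f"{f.influence_source}{coincide}"
            )
        return "\n".join(lines) + "\n"


def build_improvement_report(
    gaps: GapReport,
    tinf_criterion: TotalInfluence,
    framework: EvaluationFramework,
    group: str,
    sub_map: str = "dimension",
) -> ImprovementReport:
    """Combine a gap report with the influence structure for one group.

    ``sub_map="dimension"`` (default) ranks each dimension's criteria by the
    net relation computed on that dimension's own sub-block of T (a
    self-contained sub-map); ``"whole"`` uses relations from the full map.
    """
    if list(tinf_criterion.T.index) != framework.criterion_codes:
        raise ValueError("influence matrix and gap report use different frameworks")
    if sub_map not in ("dimension", "whole"):
        raise ValueError(f"unknown sub_map mode {sub_map!r}")

    dim_ranking = rank_gaps(gaps, group, level="dimension")
    tinf_dim = aggregate_to_dimensions(tinf_criterion, framework)
    dim_coords = inrm_coordinates(tinf_dim)
    dim_order = influence_order(dim_coords, framework, scope="framework")
    whole_coords = inrm_coordinates(tinf_criterion)

    findings = []
    for d in dim_ranking.index:
        codes = framework.codes_of(d)
        if sub_map == "dimension":
            sub_t = TotalInfluence(
                T=tinf_criterion.T.loc[codes, codes], level="criterion"
            )
            order = influence_order(inrm_coordinates(sub_t), scope="framework")
        else:
            order = influence_order(whole_coords, framework, scope=d)
        crit_ranking = rank_gaps(gaps, group, level="criterion", scope=d)
        top_gap = crit_ranking["gap"].iloc[0]
        top = tuple(
            crit_ranking.index[abs(crit_ranking["gap"] - top_gap) < GAP_TIE_TOL]
        )
        # joint winners keep display order
        top = tuple(c for c in codes if c in top)
        source = order[0]
        findings.append(
            DimensionFinding(
                dimension=d,
                gap=float(dim_ranking.loc[d, "gap"]),
                influence_order=tuple(order),
                largest_gap_criteria=top,
                largest_gap_value=float(top_gap),
                influence_source=source,
                source_is_largest_gap=source in top,
            )
        )

    overall = rank_gaps(gaps, group, level="criterion")
    best = overall["gap"].iloc[0]
    overall_top = tuple(
        c
        for c in framework.criterion_codes
        if c in set(overall.index[abs(overall["gap"] - best) < GAP_TIE_TOL])
    )
    return ImprovementReport(
        group=group,
        dimension_gap_ranking=tuple(
            (c, float(g)) for c, g in dim_ranking["gap"].items()
        ),
        findings=tuple(findings),
        overall_largest_gap_criteria=overall_top,
        overall_largest_gap_value=float(best),
        overall_source_dimension=dim_order[0],
        dimension_influence_order=tuple(dim_order),
    )
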