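"""Packaged study fixture: the published framework and evaluation table.

The published study prints the evaluation framework (5 dimensions, 20
criteria), the local and dimension influential weights, and the mean
criterion performances of two respondent groups ("experts", n=10; "users",
n=315).  The raw influence questionnaires behind the weights live in an
appendix that is not part of the available text, so the weights ship here as
*inputs*: the pipeline can reproduce every downstream aggregate from them
but cannot re-derive the weights themselves.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .danp import WeightSet
from .framework import EvaluationFramework, load_framework

__all__ = [
    "load_study_framework",
    "load_published_table",
    "load_published_weights",
    "load_published_performances",
    "load_published_gaps",
    "GROUPS",
]

#: Respondent groups of the published evaluation, in print order.
GROUPS = ("experts", "users")

#: Rounding slack of the 3-decimal published weight tables.
PUBLISHED_WEIGHT_ATOL = 0.0015


def _data(name: str):
    return files("danpmv").joinpath("data", name)


def load_study_framework() -> EvaluationFramework:
    """The published 5-dimension / 20-criterion evaluation framework."""
    return load_framework(str(_data("framework.yaml")))


def load_published_table() -> pd.DataFrame:
    """The full published evaluation table (weights, performances, gaps).

    Rows are dimensions, criteria, and a TOTAL row, distinguished by the
    ``kind`` column; values carry the print precision (3 decimals).
    """
    with _data("published_evaluation.csv").open("rb") as fh:
        return pd.read_csv(fh).set_index("code")


def load_published_weights(
    framework: EvaluationFramework | None = None,
) -> WeightSet:
    """Published local and dimension weights as a WeightSet.

    Global weights are recomputed as dimension x local (full precision),
    and consistency with the printed values is only required at the
    rounding slack ``PUBLISHED_WEIGHT_ATOL``.
    """
    fw = framework or load_study_framework()
    table = load_published_table()
    crit = table[table["kind"] == "criterion"]
    dims = table[table["kind"] == "dimension"]
    local = crit["weight"].astype(float).reindex(fw.criterion_codes)
    dimension = dims["weight"].astype(float).reindex(fw.dimension_codes)
    dimension = dimension / dimension.sum()
    return WeightSet.from_local_dimension(
        local=local, dimension=dimension, framework=fw, atol=PUBLISHED_WEIGHT_ATOL
    )


def load_published_performances() -> dict[str, pd.Series]:
    """Mean criterion performance per respondent group, from the table."""
    table = load_published_table()
    crit = table[table["kind"] == "criterion"]
    return {g: crit[f"{_col(g)}_performance"].astype(float) for g in GROUPS}


def load_published_gaps() -> dict[str, dict[str, pd.Series | float]]:
    """Printed gaps at all three levels, per group (for cross-checks)."""
    table = load_published_table()
    crit = table[table["kind"] == "criterion"]
    dims = table[table["kind"] == "dimension"]
    total = table[table["kind"] == "total"].iloc[0]
    out: dict[str, dict[str, pd.Series | float]] = {}
    for g in GROUPS:
        col = _col(g)
        out[g] = {
            "criterion": crit[f"{col}_gap"].astype(float),
            "dimension": dims[f"{col}_gap"].astype(float),
            "total": float(total[f"{col}_gap"]),
            "criterion_performance": crit[f"{col}_performance"].astype(float),
            "dimension_performance": dims[f"{col}_performance"].astype(float),
            "total_performance": float(total[f"{col}_performance"]),
        }
    return out


def _col(group: str) -> str:
    return {"experts": "expert", "users": "user"}[group]
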