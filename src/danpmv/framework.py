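"""Evaluation-framework definition, validation, and pre-test criterion screening.

An evaluation framework is a two-level hierarchy: a small set of *dimensions*
(e.g. workforce, funding), each owning at least two *criteria*.  Every
downstream stage — influence aggregation, supermatrix weighting, gap scoring —
is indexed by the criterion codes declared here, in the declared display
order.  Display order is also the tie-break used by all rankings, so a
framework fully determines the layout of every report.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Criterion",
    "Dimension",
    "EvaluationFramework",
    "load_framework",
    "pretest_filter",
    "RETAIN",
    "RESURVEY",
    "DELETE",
]

RETAIN = "retain"
RESURVEY = "resurvey"
DELETE = "delete"

#: Importance screening thresholds on the 0-10 pre-test scale: a mean score of
#: 7.5 or higher retains the criterion outright, below 5 deletes it, and the
#: band in between sends it back to the expert panel for another round.
PRETEST_RETAIN_THRESHOLD = 7.5
PRETEST_DELETE_THRESHOLD = 5.0


class FrameworkError(ValueError):
    """Raised when a framework definition violates a structural invariant."""


@dataclass(frozen=True)
class Dimension:
    """A top-level grouping of criteria."""

    code: str
    name: str
    order: int


@dataclass(frozen=True)
class Criterion:
    """A single evaluated item, owned by exactly one dimension."""

    code: str
    name: str
    dimension_code: str
    order: int


@dataclass(frozen=True)
class EvaluationFramework:
    """Validated two-level hierarchy of dimensions and criteria.

    The constructor checks code uniqueness, dimension references, display-order
    permutations, and that every dimension owns at least two criteria (a
    one-criterion dimension would make the within-dimension block of the
    total-influence matrix impossible to normalize).  :func:`load_framework`
    additionally requires at least two dimensions; single-dimension frameworks
    can still be built directly for degenerate/toy analyses.
    """

    dimensions: tuple[Dimension, ...]
    criteria: tuple[Criterion, ...]

    def __post_init__(self) -> None:
        dim_codes = [d.code for d in self.dimensions]
        crit_codes = [c.code for c in self.criteria]
        if len(set(dim_codes)) != len(dim_codes):
            raise FrameworkError("duplicate dimension codes")
        if len(set(crit_codes) | set(dim_codes)) != len(crit_codes) + len(dim_codes):
            raise FrameworkError("duplicate codes across dimensions/criteria")
        if not self.dimensions:
            raise FrameworkError("framework declares no dimensions")
        for crit in self.criteria:
            if crit.dimension_code not in dim_codes:
                raise FrameworkError(
                    f"criterion {crit.code!r} references unknown dimension "
                    f"{crit.dimension_code!r}"
                )
        for dim in self.dimensions:
            owned = [c for c in self.criteria if c.dimension_code == dim.code]
            if len(owned) < 2:
                raise FrameworkError(
                    f"dimension {dim.code!r} owns {len(owned)} criteria; "
                    "at least 2 are required"
                )
            if sorted(c.order for c in owned) != list(range(1, len(owned) + 1)):
                raise FrameworkError(
                    f"criterion display order within {dim.code!r} is not a "
                    "permutation of 1..n"
                )
        if sorted(d.order for d in self.dimensions) != list(
            range(1, len(self.dimensions) + 1)
        ):
            raise FrameworkError("dimension display order is not a permutation 1..n")

    # -- lookups -----------------------------------------------------------

    @property
    def dimension_codes(self) -> list[str]:
        return [d.code for d in sorted(self.dimensions, key=lambda d: d.order)]

    @property
    def criterion_codes(self) -> list[str]:
        """All criterion codes in display order (dimension-major)."""
        out: list[str] = []
        for dim in sorted(self.dimensions, key=lambda d: d.order):
            out.extend(c.code for c in self.criteria_of(dim.code))
        return out

    def criteria_of(self, dimension_code: str) -> list[Criterion]:
        if dimension_code not in {d.code for d in self.dimensions}:
            raise KeyError(f"unknown dimension {dimension_code!r}")
        owned = [c for c in self.criteria if c.dimension_code == dimension_code]
        return sorted(owned, key=lambda c: c.order)

    def codes_of(self, dimension_code: str) -> list[str]:
        return [c.code for c in self.criteria_of(dimension_code)]

    def dimension_of(self, criterion_code: str) -> str:
        for c in self.criteria:
            if c.code == criterion_code:
                return c.dimension_code
        raise KeyError(f"unknown criterion {criterion_code!r}")

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dimensions": [
                {"code": d.code, "name": d.name}
                for d in sorted(self.dimensions, key=lambda d: d.order)
            ],
            "criteria": [
                {"code": c.code, "name": c.name, "dimension": c.dimension_code}
                for d in sorted(self.dimensions, key=lambda d: d.order)
                for c in self.criteria_of(d.code)
            ],
        }

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False, allow_unicode=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, data: Mapping) -> "EvaluationFramework":
        try:
            raw_dims = list(data["dimensions"])
            raw_crits = list(data["criteria"])
        except (KeyError, TypeError) as exc:
            raise FrameworkError(
                "framework config must declare 'dimensions' and 'criteria'"
            ) from exc
        dims = tuple(
            Dimension(code=str(d["code"]), name=str(d.get("name", d["code"])), order=i)
            for i, d in enumerate(raw_dims, start=1)
        )
        counters: dict[str, int] = {}
        crits = []
        for c in raw_crits:
            dim_code = str(c.get("dimension", ""))
            counters[dim_code] = counters.get(dim_code, 0) + 1
            crits.append(
                Criterion(
                    code=str(c["code"]),
                    name=str(c.get("name", c["code"])),
                    dimension_code=dim_code,
                    order=counters[dim_code],
                )
            )
        return cls(dimensions=dims, criteria=tuple(crits))


def load_framework(source: str | Path | Mapping) -> EvaluationFramework:
    """Load and validate a framework from a YAML document, path, or mapping.

    Parameters
    ----------
    source
        A mapping already parsed, a path to a YAML file, or a YAML string.

    Raises
    ------
    FrameworkError
        On duplicate codes, unknown dimension references, dimensions with
        fewer than two criteria, or fewer than two dimensions.
    """
    if isinstance(source, Mapping):
        data = source
    else:
        path = Path(source)
        if path.exists():
            data = yaml.safe_load(path.read_text(encoding="utf-8"))
        else:
            data = yaml.safe_load(str(source))
    if not isinstance(data, Mapping):
        raise FrameworkError("framework config did not parse to a mapping")
    fw = EvaluationFramework.from_dict(data)
    if len(fw.dimensions) < 2:
        raise FrameworkError("framework must declare at least 2 dimensions")
    return fw


def pretest_filter(scores: Mapping[str, float]) -> dict[str, str]:
    """Classify criteria from pre-test mean importance scores on a 0-10 scale.

    A score of at least 7.5 retains the criterion, a score below 5 deletes it,
    and anything in between is flagged for a further survey round (``5.0``
    itself falls in the resurvey band).

    Returns a mapping of criterion code to ``"retain"``, ``"resurvey"``, or
    ``"delete"``.
    """
    out: dict[str, str] = {}
    for code, score in scores.items():
        s = float(score)
        if not 0.0 <= s <= 10.0:
            raise ValueError(f"score {s} for {code!r} outside [0, 10]")
        if s >= PRETEST_RETAIN_THRESHOLD:
            out[code] = RETAIN
        elif s < PRETEST_DELETE_THRESHOLD:
            out[code] = DELETE
        else:
            out[code] = RESURVEY
    return out
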