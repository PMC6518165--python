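"""DEMATEL: from expert direct-influence questionnaires to total influence.

The Decision-Making Trial and Evaluation Laboratory technique turns a panel's
pairwise direct-influence ratings into a *total-influence* matrix

    T = D (I - D)^{-1} = D + D^2 + D^3 + ...

where ``D`` is the panel-average rating matrix ``A`` normalized so that its
spectral radius is below one.  Row sums ``r`` of ``T`` measure influence
given, column sums ``c`` influence received; the influential network relation
map (INRM) places each node at prominence ``r + c`` and net relation
``r - c``, with positive relation marking net causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .framework import EvaluationFramework

__all__ = [
    "InfluenceSurveySet",
    "AverageInfluenceMatrix",
    "TotalInfluence",
    "INRMCoordinates",
    "average_responses",
    "consensus_gap",
    "normalize_direct",
    "total_influence",
    "aggregate_to_dimensions",
    "inrm_coordinates",
    "influence_order",
]

#: Refuse the Neumann inversion when the spectral radius is this close to 1.
SPECTRAL_RADIUS_GUARD = 1e-9


def _check_square(df: pd.DataFrame, what: str) -> None:
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise ValueError(f"{what} must be square with matching row/column labels")


@dataclass(frozen=True)
class InfluenceSurveySet:
    """Per-expert square direct-influence matrices on a common integer scale.

    Each response is a DataFrame indexed (rows and columns) by criterion code;
    entry ``(i, j)`` is the expert's rating of how strongly criterion *i*
    influences criterion *j*, on ``0..scale_max`` with a zero diagonal.
    """

    responses: tuple[pd.DataFrame, ...]
    scale_max: int = 4

    def __post_init__(self) -> None:
        if not self.responses:
            raise ValueError("survey set contains no responses")
        first = self.responses[0]
        _check_square(first, "influence response")
        for k, resp in enumerate(self.responses):
            if resp.shape != first.shape or list(resp.index) != list(first.index):
                raise ValueError(
                    f"response {k} has inconsistent shape or criterion ordering"
                )
            vals = resp.to_numpy(dtype=float)
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"response {k} contains non-integer ratings")
            if vals.min() < 0 or vals.max() > self.scale_max:
                raise ValueError(
                    f"response {k} has ratings outside [0, {self.scale_max}]"
                )
            if np.any(np.diag(vals) != 0):
                raise ValueError(f"response {k} has a non-zero diagonal")

    @property
    def codes(self) -> list[str]:
        return list(self.responses[0].index)

    @property
    def n_experts(self) -> int:
        return len(self.responses)

    @classmethod
    def from_csvs(
        cls, paths: Iterable[str | Path], scale_max: int = 4
    ) -> "InfluenceSurveySet":
        frames = tuple(pd.read_csv(p, index_col=0) for p in paths)
        return cls(responses=frames, scale_max=scale_max)


@dataclass(frozen=True)
class AverageInfluenceMatrix:
    """Element-wise mean of the panel's direct-influence matrices."""

    A: pd.DataFrame
    n_experts: int

    @property
    def codes(self) -> list[str]:
        return list(self.A.index)


@dataclass(frozen=True)
class TotalInfluence:
    """Total-influence matrix with its row/column sums, at one level.

    ``level`` is ``"criterion"`` for the full matrix or ``"dimension"`` after
    block-mean aggregation.  ``D`` is the normalized direct matrix the total
    influence was derived from (absent at dimension level).
    """

    T: pd.DataFrame
    level: str
    D: pd.DataFrame | None = None

    @property
    def r(self) -> pd.Series:
        """Row sums of T: influence given."""
        return self.T.sum(axis=1)

    @property
    def c(self) -> pd.Series:
        """Column sums of T: influence received."""
        return self.T.sum(axis=0)

    @property
    def codes(self) -> list[str]:
        return list(self.T.index)


@dataclass(frozen=True)
class INRMCoordinates:
    """Influential-network-relation-map coordinates per node.

    ``coords`` has one row per node with columns ``r``, ``c``,
    ``prominence`` (= r + c) and ``relation`` (= r - c).
    """

    coords: pd.DataFrame
    level: str

    @property
    def codes(self) -> list[str]:
        return list(self.coords.index)


def average_responses(surveys: InfluenceSurveySet) -> AverageInfluenceMatrix:
    """Average the panel's direct-influence matrices element-wise."""
    stack = np.stack([r.to_numpy(dtype=float) for r in surveys.responses])
    A = pd.DataFrame(stack.mean(axis=0), index=surveys.codes, columns=surveys.codes)
    return AverageInfluenceMatrix(A=A, n_experts=surveys.n_experts)


def consensus_gap(surveys: InfluenceSurveySet, eps: float = 1e-12) -> float:
    """Mean relative inter-expert deviation from the average matrix, in percent.

    For each off-diagonal cell the absolute deviation of each expert's rating
    from the panel average is divided by the average (guarded by ``eps``),
    averaged over experts, summed over cells, and scaled by ``100 / (n(n-1))``
    for ``n`` criteria.  Identical responses give 0.  Purely advisory: the
    pipeline never gates on it.
    """
    if surveys.n_experts < 2:
        raise ValueError("consensus diagnostic requires at least 2 responses")
    stack = np.stack([r.to_numpy(dtype=float) for r in surveys.responses])
    avg = stack.mean(axis=0)
    rel = np.abs(stack - avg) / np.maximum(avg, eps)
    n = avg.shape[0]
    off = ~np.eye(n, dtype=bool)
    per_cell = rel.mean(axis=0)[off]
    return float(100.0 / (n * (n - 1)) * per_cell.sum())


def normalize_direct(
    A: AverageInfluenceMatrix | pd.DataFrame, variant: str = "max"
) -> pd.DataFrame:
    """Normalize the average direct-influence matrix to spectral radius < 1.

    ``variant="max"`` (default) divides by the larger of the maximum row sum
    and the maximum column sum, which guarantees a sub-unit spectral radius in
    practice.  ``variant="row"`` divides by the maximum row sum only, the
    other normalization seen in this model family.
    """
    df = A.A if isinstance(A, AverageInfluenceMatrix) else A
    _check_square(df, "average influence matrix")
    vals = df.to_numpy(dtype=float)
    if vals.min() < 0:
        raise ValueError("average influence matrix has negative entries")
    row_max = vals.sum(axis=1).max()
    col_max = vals.sum(axis=0).max()
    if variant == "max":
        s = max(row_max, col_max)
    elif variant == "row":
        s = row_max
    else:
        raise ValueError(f"unknown normalization variant {variant!r}")
    if s <= 0:
        raise ValueError("all-zero influence matrix cannot be normalized")
    return df / s


def _spectral_radius(D: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(D))))


def total_influence(D: pd.DataFrame, level: str = "criterion") -> TotalInfluence:
    """Compute the total-influence matrix ``T = D (I - D)^{-1}``.

    Raises ``ValueError`` (reporting the spectral radius) when the Neumann
    series does not converge, i.e. the spectral radius of ``D`` is not safely
    below one.
    """
    _check_square(D, "normalized direct matrix")
    M = D.to_numpy(dtype=float)
    rho = _spectral_radius(M)
    if rho >= 1.0 - SPECTRAL_RADIUS_GUARD:
        raise ValueError(
            f"total influence undefined: spectral radius {rho:.6g} >= 1"
        )
    n = M.shape[0]
    # T = M (I - M)^{-1}, solved as a linear system for numerical stability.
    T = np.linalg.solve((np.eye(n) - M).T, M.T).T
    Tdf = pd.DataFrame(T, index=D.index, columns=D.columns)
    return TotalInfluence(T=Tdf, level=level, D=D)


def aggregate_to_dimensions(
    tinf: TotalInfluence | pd.DataFrame, framework: EvaluationFramework
) -> TotalInfluence:
    """Collapse a criterion-level T to dimension level by block means.

    Entry ``(g, h)`` of the result is the arithmetic mean of the block of
    ``T`` rows in dimension *g* against columns in dimension *h*.
    """
    T = tinf.T if isinstance(tinf, TotalInfluence) else tinf
    if list(T.index) != framework.criterion_codes:
        raise ValueError("total-influence matrix is not indexed like the framework")
    dims = framework.dimension_codes
    out = pd.DataFrame(0.0, index=dims, columns=dims)
    for g in dims:
        rows = framework.codes_of(g)
        for h in dims:
            cols = framework.codes_of(h)
            out.loc[g, h] = T.loc[rows, cols].to_numpy().mean()
    return TotalInfluence(T=out, level="dimension")


def inrm_coordinates(tinf: TotalInfluence) -> INRMCoordinates:
    """Prominence (r + c) and relation (r - c) for every node of ``T``."""
    r, c = tinf.r, tinf.c
    coords = pd.DataFrame(
        {"r": r, "c": c, "prominence": r + c, "relation": r - c},
        index=tinf.codes,
    )
    return INRMCoordinates(coords=coords, level=tinf.level)


def influence_order(
    coords: INRMCoordinates,
    framework: EvaluationFramework | None = None,
    scope: str = "framework",
) -> list[str]:
    """Order nodes by net relation ``r - c``, strongest source first.

    ``scope="framework"`` ranks every node of ``coords``; a dimension code
    restricts criterion-level coordinates to that dimension's criteria.  Ties
    keep the framework display order (the node order of ``coords``).
    """
    if scope == "framework":
        sub = coords.coords
    else:
        if framework is None:
            raise ValueError("a framework is required for a dimension scope")
        if scope not in framework.dimension_codes:
            raise ValueError(f"unknown scope {scope!r}")
        if coords.level != "criterion":
            raise ValueError("dimension scope needs criterion-level coordinates")
        sub = coords.coords.loc[framework.codes_of(scope)]
    # stable sort keeps display order on ties
    order = np.argsort(-sub["relation"].to_numpy(), kind="stable")
    return [sub.index[i] for i in order]
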