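"""DANP influential weights from the DEMATEL total-influence structure.

The DEMATEL-based analytic network process skips pairwise priority
comparisons: the unweighted supermatrix is the block-row-normalized
total-influence matrix transposed, the weighted supermatrix scales each block
by the row-normalized dimension-level total influence, and the influential
weights (IWs) are the common column of the limit of the weighted supermatrix
under matrix powers — the stationary distribution of the implied column-
stochastic chain.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dematel import TotalInfluence
from .framework import EvaluationFramework

__all__ = [
    "Supermatrix",
    "WeightSet",
    "unweighted_supermatrix",
    "weighted_supermatrix",
    "limit_supermatrix",
    "limit_matrix",
    "check_published_weights",
]

COLUMN_STOCHASTIC_TOL = 1e-9


@dataclass(frozen=True)
class Supermatrix:
    """Square criterion-by-criterion matrix at one stage of the DANP chain.

    The weighted and limit stages are column-stochastic (checked at 1e-9);
    the unweighted stage is only block-column-stochastic — each of its
    dimension blocks contributes column sums of 1, so full columns sum to
    the number of dimensions until the dimension weighting is applied.
    """

    W: pd.DataFrame
    stage: str  # "unweighted" | "weighted" | "limit"

    def __post_init__(self) -> None:
        if self.stage not in ("unweighted", "weighted", "limit"):
            raise ValueError(f"unknown supermatrix stage {self.stage!r}")
        if self.stage in ("weighted", "limit"):
            cols = self.W.sum(axis=0).to_numpy()
            if np.any(np.abs(cols - 1.0) > COLUMN_STOCHASTIC_TOL):
                raise ValueError(
                    f"{self.stage} supermatrix is not column-stochastic "
                    f"(max |colsum - 1| = {np.abs(cols - 1.0).max():.3g})"
                )

    @property
    def codes(self) -> list[str]:
        return list(self.W.index)


@dataclass(frozen=True)
class WeightSet:
    """Global, dimension, and within-dimension (local) influential weights.

    Invariants (checked at ``atol``): global and dimension weights each sum
    to 1, local weights sum to 1 within every dimension, and
    ``global = dimension x local`` criterion-wise.  The published, 3-decimal
    weight tables only satisfy these up to rounding, so fixtures relax
    ``atol``.
    """

    global_: pd.Series
    dimension: pd.Series
    local: pd.Series
    framework: EvaluationFramework
    atol: float = 1e-9

    def __post_init__(self) -> None:
        fw = self.framework
        if list(self.global_.index) != fw.criterion_codes:
            raise ValueError("global weights not indexed like the framework")
        if list(self.dimension.index) != fw.dimension_codes:
            raise ValueError("dimension weights not indexed like the framework")
        tol = self.atol
        if abs(self.global_.sum() - 1.0) > tol * len(self.global_):
            raise ValueError("global weights do not sum to 1")
        if abs(self.dimension.sum() - 1.0) > tol * len(self.dimension):
            raise ValueError("dimension weights do not sum to 1")
        for d in fw.dimension_codes:
            codes = fw.codes_of(d)
            if abs(self.local[codes].sum() - 1.0) > tol * len(codes):
                raise ValueError(f"local weights in {d} do not sum to 1")
            for code in codes:
                if abs(self.global_[code] - self.dimension[d] * self.local[code]) > tol:
                    raise ValueError(
                        f"global weight of {code} inconsistent with "
                        "dimension x local"
                    )

    @classmethod
    def from_global(
        cls, global_: pd.Series, framework: EvaluationFramework, atol: float = 1e-9
    ) -> "WeightSet":
        """Derive dimension and local weights from a global weight vector."""
        g = global_ / global_.sum()
        dim = pd.Series(
            {d: g[framework.codes_of(d)].sum() for d in framework.dimension_codes}
        )
        if (dim <= 0).any():
            bad = dim[dim <= 0].index.tolist()
            raise ValueError(f"dimensions with zero total weight: {bad}")
        local = pd.Series(
            {c: g[c] / dim[framework.dimension_of(c)] for c in g.index}
        )
        return cls(
            global_=g, dimension=dim, local=local, framework=framework, atol=atol
        )

    @classmethod
    def from_local_dimension(
        cls,
        local: pd.Series,
        dimension: pd.Series,
        framework: EvaluationFramework,
        atol: float = 1e-9,
    ) -> "WeightSet":
        """Build from local and dimension weights (global = product)."""
        local = local.reindex(framework.criterion_codes)
        dimension = dimension.reindex(framework.dimension_codes)
        global_ = pd.Series(
            {
                c: dimension[framework.dimension_of(c)] * local[c]
                for c in framework.criterion_codes
            }
        )
        return cls(
            global_=global_,
            dimension=dimension,
            local=local,
            framework=framework,
            atol=atol,
        )

    def as_frame(self) -> pd.DataFrame:
        """Criterion table with dimension, local, and global weight columns."""
        fw = self.framework
        return pd.DataFrame(
            {
                "dimension": [fw.dimension_of(c) for c in fw.criterion_codes],
                "local_weight": self.local[fw.criterion_codes].to_numpy(),
                "global_weight": self.global_[fw.criterion_codes].to_numpy(),
            },
            index=pd.Index(fw.criterion_codes, name="code"),
        )


def unweighted_supermatrix(
    tinf: TotalInfluence | pd.DataFrame, framework: EvaluationFramework
) -> Supermatrix:
    """Block-row-normalize the criterion-level T and transpose.

    Within every (row-criterion, column-dimension) block of ``T`` the entries
    are divided by their sum, so each block of the transposed result — and
    hence each full column — sums to one.
    """
    T = tinf.T if isinstance(tinf, TotalInfluence) else tinf
    if list(T.index) != framework.criterion_codes:
        raise ValueError("total-influence matrix is not indexed like the framework")
    norm = T.copy().astype(float)
    for h in framework.dimension_codes:
        cols = framework.codes_of(h)
        block = norm.loc[:, cols]
        sums = block.sum(axis=1)
        if (sums <= 0).any():
            bad = sums[sums <= 0].index[0]
            raise ValueError(
                f"block-row of criterion {bad!r} toward dimension {h!r} sums "
                "to zero; cannot normalize"
            )
        norm.loc[:, cols] = block.div(sums, axis=0)
    return Supermatrix(W=norm.T, stage="unweighted")


def weighted_supermatrix(
    W_unweighted: Supermatrix,
    tinf_dimension: TotalInfluence | pd.DataFrame,
    framework: EvaluationFramework,
) -> Supermatrix:
    """Scale each block of the unweighted supermatrix by dimension influence.

    The dimension-level T is row-normalized; block (rows in dimension *g*,
    columns in dimension *h*) of the unweighted supermatrix is multiplied by
    the normalized entry (h, g) — the transpose convention that keeps the
    result column-stochastic.
    """
    TD = (
        tinf_dimension.T
        if isinstance(tinf_dimension, TotalInfluence)
        else tinf_dimension
    )
    dims = framework.dimension_codes
    if list(TD.index) != dims:
        raise ValueError("dimension-level T is not indexed like the framework")
    sums = TD.sum(axis=1)
    if (sums <= 0).any():
        bad = sums[sums <= 0].index[0]
        raise ValueError(f"dimension row {bad!r} of T sums to zero")
    TDn = TD.div(sums, axis=0)
    W = W_unweighted.W.copy()
    for g in dims:
        rows = framework.codes_of(g)
        for h in dims:
            cols = framework.codes_of(h)
            W.loc[rows, cols] *= TDn.loc[h, g]
    return Supermatrix(W=W, stage="weighted")


def limit_matrix(
    W: Supermatrix,
    tol: float = 1e-9,
    max_iter: int = 10_000,
    cycle_window: int = 12,
) -> Supermatrix:
    """Raise the weighted supermatrix to its limit under matrix powers.

    Successive powers are multiplied out until they differ by less than
    ``tol`` in max norm.  If the powers instead cycle (detected by comparing
    the current power against a short history), the limit is taken as the
    Cesaro average over one detected period, which is the standard limit for
    periodic column-stochastic chains.
    """
    M = W.W.to_numpy(dtype=float)
    history: deque[np.ndarray] = deque(maxlen=cycle_window)
    P = M.copy()
    for _ in range(max_iter):
        P_next = P @ M
        diff = np.max(np.abs(P_next - P))
        if diff < tol:
            out = P_next
            break
        for lag, past in enumerate(reversed(history), start=2):
            if np.max(np.abs(P_next - past)) < tol:
                # period = lag; Cesaro-average one full cycle of powers
                cycle = [P_next, P]
                cycle.extend(list(reversed(history))[: lag - 2])
                out = np.mean(cycle, axis=0)
                break
        else:
            history.append(P)
            P = P_next
            continue
        break
    else:
        raise ValueError(
            f"limit supermatrix did not converge within {max_iter} iterations "
            f"(last residual {diff:.3g})"
        )
    return Supermatrix(
        W=pd.DataFrame(out, index=W.W.index, columns=W.W.columns), stage="limit"
    )


def limit_supermatrix(
    W: Supermatrix,
    framework: EvaluationFramework,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> WeightSet:
    """Influential weights: the common column of the limit supermatrix.

    The global weight vector is read off the (near-identical) columns of the
    limit, dimension weights are per-dimension sums of global weights, and
    local weights are global weights renormalized within their dimension.
    """
    lim = limit_matrix(W, tol=tol, max_iter=max_iter)
    global_ = lim.W.mean(axis=1)
    return WeightSet.from_global(global_, framework)


def check_published_weights(
    computed: WeightSet, published: WeightSet
) -> pd.DataFrame:
    """Per-entry absolute discrepancy between two weight sets (diagnostic).

    Returns a table indexed by criterion code with computed/published local
    and global weights, their absolute differences, and the dimension-weight
    differences broadcast onto the owning criteria.
    """
    fw = computed.framework
    rows = []
    for c in fw.criterion_codes:
        d = fw.dimension_of(c)
        rows.append(
            {
                "dimension": d,
                "local_computed": computed.local[c],
                "local_published": published.local[c],
                "local_abs_diff": abs(computed.local[c] - published.local[c]),
                "global_computed": computed.global_[c],
                "global_published": published.global_[c],
                "global_abs_diff": abs(computed.global_[c] - published.global_[c]),
                "dimension_abs_diff": abs(
                    computed.dimension[d] - published.dimension[d]
                ),
            }
        )
    return pd.DataFrame(rows, index=pd.Index(fw.criterion_codes, name="code"))
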