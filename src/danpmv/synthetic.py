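"""Synthetic questionnaire generator with known ground truth.

No raw questionnaire data is deposited for studies of this kind, so every
pipeline stage is exercised against generated inputs whose parameters are
known exactly: an integer ground-truth direct-influence matrix perturbed by
symmetric ±1 jitter per expert, and per-criterion truncated-normal (clipped)
performance scores per respondent group.  The default instance mirrors the
published study design: a 5-dimension / 20-criterion framework, 10 influence
questionnaires on a 0-4 scale, and performance surveys from an expert group
(n=10) and a user group (n=315) on a 0-10 instrument.

All randomness flows from a single integer seed through one
``numpy.random.default_rng`` stream, so outputs are byte-identical across
runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dematel import InfluenceSurveySet
from .framework import EvaluationFramework
from .vikor import AspirationScale, PerformanceSurvey

__all__ = [
    "PerformanceGroupSpec",
    "GeneratorSpec",
    "InstanceBundle",
    "generate_influence_surveys",
    "generate_performance_surveys",
    "generate_study_instance",
    "random_influence_truth",
]


@dataclass(frozen=True)
class PerformanceGroupSpec:
    """Design of one respondent group's performance survey.

    ``mean`` maps criterion code to the latent mean score; ``sd`` is the
    latent normal standard deviation before clipping to ``bounds``.
    """

    n_respondents: int
    mean: Mapping[str, float]
    sd: float = 1.5
    bounds: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("each group needs at least 1 respondent")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        lo, hi = self.bounds
        for code, m in self.mean.items():
            if not lo <= m <= hi:
                raise ValueError(
                    f"mean {m} for {code!r} outside bounds [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class GeneratorSpec:
    """Full design of a synthetic study instance."""

    framework: EvaluationFramework
    influence_truth: pd.DataFrame
    groups: Mapping[str, PerformanceGroupSpec]
    n_influence_experts: int = 10
    jitter_p: float = 0.25
    scale_max: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.jitter_p <= 1.0:
            raise ValueError("jitter probability must lie in [0, 1]")
        if self.n_influence_experts < 1:
            raise ValueError("need at least one influence questionnaire")
        codes = self.framework.criterion_codes
        if list(self.influence_truth.index) != codes or list(
            self.influence_truth.columns
        ) != codes:
            raise ValueError("influence truth not indexed like the framework")
        vals = self.influence_truth.to_numpy(dtype=float)
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("influence truth must be integer-valued")
        if vals.min() < 0 or vals.max() > self.scale_max:
            raise ValueError(f"influence truth outside [0, {self.scale_max}]")
        for group, gspec in self.groups.items():
            missing = set(codes) - set(gspec.mean)
            if missing:
                raise ValueError(f"group {group!r} lacks means for {sorted(missing)}")


@dataclass(frozen=True)
class InstanceBundle:
    """A generated study: the spec plus its realized questionnaires."""

    spec: GeneratorSpec
    influence: InfluenceSurveySet
    performance: tuple[PerformanceSurvey, ...]


def generate_influence_surveys(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> InfluenceSurveySet:
    """Ground truth plus independent ±1 jitter per off-diagonal cell.

    Each cell is perturbed with probability ``jitter_p`` (direction chosen
    uniformly), then clipped to ``[0, scale_max]``; diagonals stay zero.
    Note that clipping makes the jitter asymmetric for truth values at the
    scale ends, biasing the panel average there.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    truth = spec.influence_truth.to_numpy(dtype=int)
    n = truth.shape[0]
    off = ~np.eye(n, dtype=bool)
    responses = []
    for _ in range(spec.n_influence_experts):
        hit = (rng.random((n, n)) < spec.jitter_p) & off
        sign = rng.choice([-1, 1], size=(n, n))
        resp = np.clip(truth + hit * sign, 0, spec.scale_max)
        np.fill_diagonal(resp, 0)
        responses.append(
            pd.DataFrame(
                resp,
                index=spec.influence_truth.index,
                columns=spec.influence_truth.columns,
            )
        )
    return InfluenceSurveySet(responses=tuple(responses), scale_max=spec.scale_max)


def generate_performance_surveys(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> tuple[PerformanceSurvey, ...]:
    """Clipped-normal scores per group; one row per respondent."""
    rng = np.random.default_rng(spec.seed + 1) if rng is None else rng
    codes = spec.framework.criterion_codes
    surveys = []
    for group, gspec in spec.groups.items():
        lo, hi = gspec.bounds
        mu = np.array([gspec.mean[c] for c in codes])
        raw = rng.normal(loc=mu, scale=gspec.sd, size=(gspec.n_respondents, len(codes)))
        scores = np.clip(raw, lo, hi)
        records = pd.DataFrame(
            scores,
            index=pd.RangeIndex(gspec.n_respondents, name="respondent_id"),
            columns=codes,
        )
        surveys.append(
            PerformanceSurvey(
                group=group,
                records=records,
                scale=AspirationScale(f_star=hi, f_worst=lo),
            )
        )
    return tuple(surveys)


def random_influence_truth(
    framework: EvaluationFramework,
    rng: np.random.Generator,
    scale_max: int = 4,
    dominant_dimension: str | None = None,
) -> pd.DataFrame:
    """Random integer direct-influence ground truth.

    Off-diagonal cells are drawn uniformly from ``1..scale_max-1`` (keeping
    the panel average away from the clipped scale ends).  When
    ``dominant_dimension`` is given, that dimension's criteria exert maximal
    influence on all other dimensions and receive minimal influence back, so
    it is a planted net source the pipeline should rank first.
    """
    codes = framework.criterion_codes
    n = len(codes)
    truth = rng.integers(1, scale_max, size=(n, n))
    if dominant_dimension is not None:
        if dominant_dimension not in framework.dimension_codes:
            raise ValueError(f"unknown dimension {dominant_dimension!r}")
        planted = [codes.index(c) for c in framework.codes_of(dominant_dimension)]
        others = [i for i in range(n) if i not in planted]
        truth[np.ix_(planted, others)] = scale_max
        truth[np.ix_(others, planted)] = 0
    np.fill_diagonal(truth, 0)
    return pd.DataFrame(truth, index=codes, columns=codes)


def generate_study_instance(
    seed: int = 0,
    framework: EvaluationFramework | None = None,
    dominant_dimension: str | None = None,
    n_users: int = 315,
    n_experts: int = 10,
    performance_sd: float = 1.5,
) -> InstanceBundle:
    """A full study-shaped instance: framework, panel, and two survey groups.

    Criterion mean satisfaction is drawn uniformly from [4, 7] per group —
    the mid-range band the published evaluation sits in — with sd 1.5 on the
    0-10 instrument.
    """
    from .fixtures import load_study_framework

    fw = framework or load_study_framework()
    rng = np.random.default_rng(seed)
    truth = random_influence_truth(fw, rng, dominant_dimension=dominant_dimension)
    codes = fw.criterion_codes
    groups = {}
    for group, n in (("experts", n_experts), ("users", n_users)):
        if n < 1:
            raise ValueError(f"group {group!r} needs at least 1 respondent")
        means = {c: float(m) for c, m in zip(codes, rng.uniform(4.0, 7.0, len(codes)))}
        groups[group] = PerformanceGroupSpec(
            n_respondents=n, mean=means, sd=performance_sd
        )
    spec = GeneratorSpec(
        framework=fw,
        influence_truth=truth,
        groups=groups,
        n_influence_experts=10,
        jitter_p=0.25,
        seed=seed,
    )
    influence = generate_influence_surveys(spec, rng)
    performance = generate_performance_surveys(spec, rng)
    return InstanceBundle(spec=spec, influence=influence, performance=performance)
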