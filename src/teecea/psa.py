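"""Probabilistic sensitivity analysis and cost-effectiveness summaries.

Each simulation draws one realization of every uncertain parameter, runs
both diagnostic strategies deterministically through the decision tree and
the Markov cohort model with that common draw, and records the incremental
cost and QALY of modified TEE over manual palpation.  The draws feed the
ICER (with its dominance-quadrant label), a bivariate-normal confidence
ellipse on the cost-effectiveness plane, and cost-effectiveness
acceptability curves based on net monetary benefit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .decision_tree import (
    StrokePolicy,
    outcome_for_strategy,
    proportional_stroke_policy,
)
from .markov import LifeTable, one_time_costs, run_cohort, strategy_totals
from .params import ParameterSet, Subgroup

__all__ = [
    "StrategyEvaluation",
    "StrategyComparison",
    "Ellipse",
    "CEResult",
    "evaluate_strategy",
    "compare_strategies",
    "run_psa",
    "icer",
    "ceac",
    "confidence_ellipse",
    "default_thresholds",
]

logger = logging.getLogger(__name__)

_MAX_REJECTIONS = 1000


@dataclass(frozen=True)
class StrategyEvaluation:
    """Deterministic model output for one strategy and subgroup."""

    strategy: str
    outcome: object
    cost: float
    life_years: float
    qalys: float


@dataclass(frozen=True)
class StrategyComparison:
    tee: StrategyEvaluation
    mp: StrategyEvaluation

    @property
    def inc_cost(self) -> float:
        return self.tee.cost - self.mp.cost

    @property
    def inc_qaly(self) -> float:
        return self.tee.qalys - self.mp.qalys


def evaluate_strategy(
    subgroup: Subgroup,
    params: ParameterSet,
    lifetable: LifeTable,
    strategy: str,
    arteriopathy_or: float,
    policy: StrokePolicy = proportional_stroke_policy,
) -> StrategyEvaluation:
    """Decision tree + Markov cohort + cost bookkeeping for one strategy."""
    outcome = outcome_for_strategy(subgroup, params, strategy, arteriopathy_or, policy)
    trace = run_cohort(outcome, subgroup, lifetable, params)
    cost, ly, qaly = strategy_totals(trace, one_time_costs(outcome, params, strategy))
    return StrategyEvaluation(
        strategy=strategy, outcome=outcome, cost=cost, life_years=ly, qalys=qaly
    )


def compare_strategies(
    subgroup: Subgroup,
    params: ParameterSet,
    lifetable: LifeTable,
    arteriopathy_or: float,
    policy: StrokePolicy = proportional_stroke_policy,
) -> StrategyComparison:
    return StrategyComparison(
        tee=evaluate_strategy(subgroup, params, lifetable, "tee", arteriopathy_or, policy),
        mp=evaluate_strategy(subgroup, params, lifetable, "mp", arteriopathy_or, policy),
    )


def icer(mean_inc_cost: float, mean_inc_qaly: float) -> tuple[float, str, bool]:
    """Incremental cost-effectiveness ratio with its quadrant label.

    Returns ``(ratio, quadrant, defined)``.  Quadrants of the CE plane:
    NE (more costly, more effective), SE (cost-saving, more effective —
    dominant), NW (more costly, less effective — dominated), SW (cost-saving,
    less effective).  Zero incremental QALYs leave the ratio undefined.
    """
    if mean_inc_qaly > 0:
        quadrant = "NE" if mean_inc_cost >= 0 else "SE"
    elif mean_inc_qaly < 0:
        quadrant = "NW" if mean_inc_cost > 0 else "SW"
    else:
        quadrant = "NW" if mean_inc_cost > 0 else ("SW" if mean_inc_cost < 0 else "NE")
        return float("nan"), quadrant, False
    return mean_inc_cost / mean_inc_qaly, quadrant, True


def ceac(draws: np.ndarray, thresholds: Sequence[float]) -> np.ndarray:
    """Acceptability probability at each willingness-to-pay threshold.

    For threshold ``lam`` the probability is the fraction of draws with
    non-negative net monetary benefit ``lam * dE - dC``.
    """
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != 2 or len(draws) == 0:
        raise ValueError("draws must be a non-empty (n, 2) array of (dC, dE)")
    lam = np.asarray(thresholds, dtype=float)
    nmb = lam[:, None] * draws[:, 1][None, :] - draws[:, 0][None, :]
    return (nmb >= 0).mean(axis=1)


@dataclass(frozen=True)
class Ellipse:
    """Bivariate-normal confidence region on the CE plane.

    ``semi_axes`` are the half-lengths along the principal directions,
    ``angle`` the orientation (radians) of the major axis against the
    incremental-effect axis.  ``degenerate`` flags a collapsed covariance
    (the region is a segment or point).
    """

    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float
    level: float
    degenerate: bool


def confidence_ellipse(draws: np.ndarray, level: float = 0.95) -> Ellipse:
    """Normal-approximation confidence ellipse for (dC, dE) draws."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 2 or draws.shape[1] != 2 or len(draws) < 3:
        raise ValueError("need at least 3 (dC, dE) draws")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    mean = draws.mean(axis=0)
    cov = np.cov(draws, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    scale = stats.chi2.ppf(level, df=2)
    semi = np.sqrt(evals * scale)
    # eigh returns ascending order; report major axis first
    major, minor = semi[1], semi[0]
    vec = evecs[:, 1]
    angle = float(np.arctan2(vec[1], vec[0]))
    degenerate = bool(minor == 0.0)
    return Ellipse(
        center=(float(mean[0]), float(mean[1])),
        semi_axes=(float(major), float(minor)),
        angle=angle,
        level=level,
        degenerate=degenerate,
    )


@dataclass(frozen=True)
class CEResult:
    """PSA output: incremental draws and their cost-effectiveness summaries."""

    draws: np.ndarray  # (n, 2) columns (inc_cost, inc_qaly)
    mean_inc_cost: float
    mean_inc_qaly: float
    icer: float
    icer_quadrant: str
    icer_defined: bool
    ellipse: Ellipse
    thresholds: np.ndarray
    ceac: np.ndarray
    p_cost_saving_health_gain: float
    n_rejected: int

    def ceac_at(self, threshold: float) -> float:
        return float(ceac(self.draws, [threshold])[0])


def default_thresholds(stop: float = 100_000.0, step: float = 1_000.0) -> np.ndarray:
    return np.arange(0.0, stop + step / 2, step)


def run_psa(
    params: ParameterSet,
    subgroup: Subgroup,
    n_sims: int,
    seed: int,
    lifetable: LifeTable,
    arteriopathy_or: float,
    thresholds: Sequence[float] | None = None,
    policy: StrokePolicy = proportional_stroke_policy,
    level: float = 0.95,
) -> CEResult:
    """Monte-Carlo propagation of parameter uncertainty for one subgroup.

    One parameter draw drives both strategies within a simulation (the
    shared quantities — stroke fractions, adaptation effect, costs — are
    strategy-independent).  Draws that produce infeasible probabilities are
    rejected and resampled, with the count logged and reported.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if thresholds is None:
        thresholds = default_thresholds()
    rng = np.random.default_rng(seed)
    draws = np.empty((n_sims, 2))
    rejected = 0
    for i in range(n_sims):
        for _attempt in range(_MAX_REJECTIONS):
            sampled = params.sample(rng)
            try:
                comp = compare_strategies(
                    subgroup, sampled, lifetable, arteriopathy_or, policy
                )
            except ValueError:
                rejected += 1
                continue
            draws[i] = (comp.inc_cost, comp.inc_qaly)
            break
        else:
            raise RuntimeError("too many rejected parameter draws")
    if rejected:
        logger.info("rejected and resampled %d infeasible parameter draws", rejected)

    mean_dc = float(draws[:, 0].mean())
    mean_de = float(draws[:, 1].mean())
    ratio, quadrant, defined = icer(mean_dc, mean_de)
    thr = np.asarray(thresholds, dtype=float)
    return CEResult(
        draws=draws,
        mean_inc_cost=mean_dc,
        mean_inc_qaly=mean_de,
        icer=ratio,
        icer_quadrant=quadrant,
        icer_defined=defined,
        ellipse=confidence_ellipse(draws, level) if n_sims >= 3 else None,
        thresholds=thr,
        ceac=ceac(draws, thr),
        p_cost_saving_health_gain=float(
            np.mean((draws[:, 0] < 0) & (draws[:, 1] > 0))
        ),
        n_rejected=rejected,
    )
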