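"""Markov cohort model: lifetime follow-up after cardiac surgery.

Three health states — post-surgery without complications, post-surgery after
a non-fatal stroke, and dead — evolve in one-year cycles.  The starting
distribution comes from the decision-tree stage.  Annual mortality uses the
excess post-surgical risks for the first years after surgery (the age band
is fixed at surgery: under-61 patients face the elevated risk in years 1-2,
older patients in years 1-5, replacing background mortality) and the age-
and sex-specific life table thereafter.  Survivors accrue one life-year per
cycle, quality-weighted by the state utility, and the post-stroke state
accrues an annual care cost; costs and effects are discounted at separate
annual rates.  Rewards are credited at the end of each cycle, with no
half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .decision_tree import StrategyOutcome
from .params import ParameterSet, Subgroup

__all__ = [
    "LifeTable",
    "CohortTrace",
    "OneTimeCosts",
    "discount_factor",
    "run_cohort",
    "one_time_costs",
    "strategy_totals",
    "excess_band",
    "EXCESS_WINDOW_YEARS",
]

EXCESS_WINDOW_YEARS = {"under61": 2, "61to70": 5, "over70": 5}

_OCC_TOL = 1e-10


def excess_band(age_at_surgery: int) -> str:
    """Excess-mortality age band, fixed at the age when surgery takes place."""
    if age_at_surgery < 61:
        return "under61"
    if age_at_surgery <= 70:
        return "61to70"
    return "over70"


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific annual death probabilities by integer age.

    ``qx`` maps ``'male'``/``'female'`` to arrays over ``ages`` (a contiguous
    integer range ending at a terminal age where the probability is 1).
    """

    ages: np.ndarray
    qx: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        object.__setattr__(self, "ages", ages)
        if len(ages) == 0 or not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise ValueError("ages must be a contiguous integer range")
        clean = {}
        for sex, q in self.qx.items():
            q = np.asarray(q, dtype=float)
            if q.shape != ages.shape:
                raise ValueError(f"life table for {sex!r} does not cover every age")
            if np.any((q < 0) | (q > 1)):
                raise ValueError(f"life table for {sex!r} has probabilities outside [0, 1]")
            if q[-1] != 1.0:
                raise ValueError(f"life table for {sex!r} must end with probability 1")
            clean[sex] = q
        object.__setattr__(self, "qx", clean)

    @property
    def terminal_age(self) -> int:
        return int(self.ages[-1])

    def q(self, sex: str, age: int) -> float:
        """Annual death probability at ``age``; 1 at and beyond the terminal age."""
        if sex not in self.qx:
            raise KeyError(f"no life table for sex {sex!r}")
        if age >= self.terminal_age:
            return 1.0
        if age < self.ages[0]:
            raise ValueError(f"age {age} below life-table range")
        return float(self.qx[sex][age - self.ages[0]])

    def life_expectancy(self, sex: str, age: int) -> float:
        """Expected remaining life-years (end-of-year convention, no discounting)."""
        alive = 1.0
        total = 0.0
        for a in range(age, self.terminal_age + 1):
            alive *= 1.0 - self.q(sex, a)
            total += alive
        return total

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "LifeTable":
        required = {"sex", "age", "qx"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life-table frame needs columns {sorted(required)}")
        ages = None
        qx = {}
        for sex, chunk in frame.groupby("sex"):
            chunk = chunk.sort_values("age")
            a = chunk["age"].to_numpy(dtype=int)
            if ages is None:
                ages = a
            elif not np.array_equal(ages, a):
                raise ValueError("all sexes must cover the same ages")
            qx[str(sex)] = chunk["qx"].to_numpy(dtype=float)
        return cls(ages=ages, qx=qx)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        return cls.from_frame(pd.read_csv(path))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sex": sex, "age": int(a), "qx": float(q)}
            for sex in sorted(self.qx)
            for a, q in zip(self.ages, self.qx[sex])
        ]
        return pd.DataFrame(rows, columns=["sex", "age", "qx"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def discount_factor(rate: float, cycle: int) -> float:
    """Present-value factor ``(1 + rate) ** -cycle``."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    return (1.0 + rate) ** (-cycle)


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy plus accumulated (dis)counted rewards.

    Index 0 is the moment just after surgery (decision-tree outcomes applied,
    no Markov rewards yet); index ``t`` is the end of cycle ``t``.
    """

    cycles: np.ndarray
    occ_no_complication: np.ndarray
    occ_post_stroke: np.ndarray
    occ_dead: np.ndarray
    life_years: float
    qalys: float
    state_costs: float
    life_years_undiscounted: float
    qalys_undiscounted: float
    state_costs_undiscounted: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": self.cycles,
                "no_complication": self.occ_no_complication,
                "post_stroke": self.occ_post_stroke,
                "dead": self.occ_dead,
            }
        )


def run_cohort(
    initial: StrategyOutcome,
    subgroup: Subgroup,
    lifetable: LifeTable,
    params: ParameterSet,
) -> CohortTrace:
    """Propagate the cohort until everyone is dead (or the terminal age).

    Both living states share the same annual mortality; there is no recovery
    from the post-stroke state and no recurrent stroke.  End-of-cycle
    rewards: each survivor of cycle ``t`` adds one (discounted) life-year,
    its utility weight in QALYs, and — in the post-stroke state — the annual
    care cost.
    """
    if params.utility_post_stroke > params.utility_no_complication:
        raise ValueError("post-stroke utility exceeds the no-complication utility")

    well = initial.p_no_complication
    stroke = initial.p_stroke_nonfatal
    dead = initial.p_stroke_fatal + initial.p_death_other

    band = excess_band(subgroup.age_at_surgery)
    window = EXCESS_WINDOW_YEARS[band]
    excess_q = {
        "under61": params.excess_mortality_under61,
        "61to70": params.excess_mortality_61to70,
        "over70": params.excess_mortality_over70,
    }[band]

    occ = [(0, well, stroke, dead)]
    ly = qaly = cost = 0.0
    ly_u = qaly_u = cost_u = 0.0
    u_well = params.utility_no_complication
    u_stroke = params.utility_post_stroke

    t = 0
    while well + stroke > 1e-12:
        t += 1
        age = subgroup.age_at_surgery + t - 1  # age during cycle t
        if t <= window:
            q = excess_q
        else:
            q = lifetable.q(subgroup.sex, age)
        well *= 1.0 - q
        stroke *= 1.0 - q
        dead = 1.0 - well - stroke

        df_e = discount_factor(params.discount_effects, t)
        df_c = discount_factor(params.discount_costs, t)
        alive = well + stroke
        ly += alive * df_e
        ly_u += alive
        qaly += (well * u_well + stroke * u_stroke) * df_e
        qaly_u += well * u_well + stroke * u_stroke
        cost += stroke * params.cost_post_stroke_annual * df_c
        cost_u += stroke * params.cost_post_stroke_annual
        occ.append((t, well, stroke, dead))
        if age + 1 >= lifetable.terminal_age and q == 1.0:
            break

    arr = np.asarray(occ, dtype=float)
    occ_sums = arr[:, 1] + arr[:, 2] + arr[:, 3]
    if np.any(np.abs(occ_sums - 1.0) > _OCC_TOL):
        raise AssertionError("cohort occupancy failed to sum to 1")
    return CohortTrace(
        cycles=arr[:, 0].astype(int),
        occ_no_complication=arr[:, 1],
        occ_post_stroke=arr[:, 2],
        occ_dead=arr[:, 3],
        life_years=ly,
        qalys=qaly,
        state_costs=cost,
        life_years_undiscounted=ly_u,
        qalys_undiscounted=qaly_u,
        state_costs_undiscounted=cost_u,
    )


@dataclass(frozen=True)
class OneTimeCosts:
    """Decision-tree-stage costs, incurred at cycle 0 (undiscounted)."""

    diagnostic: float
    surgery: float
    events: float

    @property
    def total(self) -> float:
        return self.diagnostic + self.surgery + self.events


def one_time_costs(
    outcome: StrategyOutcome, params: ParameterSet, strategy: str
) -> OneTimeCosts:
    """Diagnostic, surgical, and early-event costs for one strategy.

    The device cost applies to every patient in the TEE strategy (manual
    palpation needs no equipment); surgery costs the base amount plus the
    major-adaptation increment weighted by its probability; early fatal
    strokes, other early deaths, and non-fatal strokes incur their event
    costs.  Minor adaptations are cost-free.
    """
    if strategy not in {"tee", "mp"}:
        raise ValueError(f"unknown strategy {strategy!r}")
    diagnostic = params.cost_tee_device if strategy == "tee" else 0.0
    surgery = params.cost_surgery_base + outcome.p_major_adaptation * (
        params.cost_surgery_major_adaptation - params.cost_surgery_base
    )
    events = (
        outcome.p_stroke_fatal * params.cost_fatal_stroke
        + outcome.p_death_other * params.cost_death
        + outcome.p_stroke_nonfatal * params.cost_nonfatal_stroke_acute
    )
    return OneTimeCosts(diagnostic=diagnostic, surgery=surgery, events=events)


def strategy_totals(
    trace: CohortTrace, one_time: OneTimeCosts
) -> tuple[float, float, float]:
    """Expected (cost, life-years, QALYs) per patient for one strategy."""
    return (
        one_time.total + trace.state_costs,
        trace.life_years,
        trace.qalys,
    )
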