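"""Decision-analytic front end: from test accuracy to early outcomes.

Patients are cross-classified by atherosclerosis status and test result.
True positives trigger surgical adaptation — major with a small probability,
otherwise minor; false positives can receive only minor adaptations (a major
adaptation would immediately reveal the absent disease and be aborted) and
carry no cost or risk consequence; false negatives go unadapted.  Adaptation
multiplies the embolic portion of a patient's stroke risk by a relative risk
below one.  The module turns these rules into per-strategy probabilities of
minor/major adaptation, non-fatal stroke, fatal stroke, other early death,
and uncomplicated survival, which seed the Markov cohort model.

The quantitative link from early mortality to baseline stroke risk is not
uniquely determined by the published point estimates, so it is a pluggable
policy.  The default, :func:`proportional_stroke_policy`, scales each
stratum's total stroke risk off its early mortality via the fatal-stroke
share (``T = m * p_death_is_stroke / (1 - p_stroke_nonfatal)``) and applies
the embolic fraction uniformly.  :func:`concentrated_embolic_policy` instead
assigns the whole embolic stroke burden to the atherosclerosis stratum,
reflecting that emboli originate from the atherosclerotic aorta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple

import numpy as np

from .mortality import EarlyMortality, stratify_mortality
from .params import ParameterSet, Subgroup

__all__ = [
    "TestPerformance",
    "Classification",
    "StrategyOutcome",
    "AdaptationProbs",
    "classify",
    "adaptation_probs",
    "stroke_and_death_probs",
    "outcome_for_strategy",
    "proportional_stroke_policy",
    "concentrated_embolic_policy",
    "simulate_classification",
    "MicrosimResult",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class TestPerformance:
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity outside [0, 1]")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError("specificity outside [0, 1]")


@dataclass(frozen=True)
class Classification:
    """Joint probabilities over (atherosclerosis status x test result)."""

    prevalence: float
    p_tp: float
    p_fn: float
    p_fp: float
    p_tn: float

    def __post_init__(self) -> None:
        cells = (self.p_tp, self.p_fn, self.p_fp, self.p_tn)
        if any(c < 0 for c in cells):
            raise ValueError("classification cells must be non-negative")
        if abs(sum(cells) - 1.0) > _SUM_TOL:
            raise ValueError("classification cells must sum to 1")
        if abs(self.p_tp + self.p_fn - self.prevalence) > _SUM_TOL:
            raise ValueError("p_tp + p_fn must equal prevalence")


class AdaptationProbs(NamedTuple):
    p_minor_true: float
    p_major_adapt: float
    p_minor_fp: float


class StratumStrokeRisk(NamedTuple):
    """Per-patient baseline stroke risk split into embolic / non-embolic,
    for the without- and with-atherosclerosis strata."""

    embolic_no: float
    nonembolic_no: float
    embolic_athero: float
    nonembolic_athero: float


StrokePolicy = Callable[[EarlyMortality, float, ParameterSet], StratumStrokeRisk]


@dataclass(frozen=True)
class StrategyOutcome:
    """Early (decision-tree) outcome probabilities for one strategy."""

    p_minor_adaptation_true: float
    p_major_adaptation: float
    p_minor_adaptation_fp: float
    p_stroke_nonfatal: float
    p_stroke_fatal: float
    p_death_other: float
    p_no_complication: float
    floored_death_other: bool = False

    def __post_init__(self) -> None:
        terminal = (
            self.p_stroke_nonfatal,
            self.p_stroke_fatal,
            self.p_death_other,
            self.p_no_complication,
        )
        if any(p < 0 for p in terminal):
            raise ValueError("terminal outcome probabilities must be non-negative")
        if abs(sum(terminal) - 1.0) > 1e-9:
            raise ValueError("terminal outcome probabilities must sum to 1")

    @property
    def p_stroke_total(self) -> float:
        return self.p_stroke_nonfatal + self.p_stroke_fatal


def classify(prevalence: float, perf: TestPerformance) -> Classification:
    """Joint (disease x test result) probabilities for one strategy."""
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence outside [0, 1]")
    return Classification(
        prevalence=prevalence,
        p_tp=prevalence * perf.sensitivity,
        p_fn=prevalence * (1.0 - perf.sensitivity),
        p_fp=(1.0 - prevalence) * (1.0 - perf.specificity),
        p_tn=(1.0 - prevalence) * perf.specificity,
    )


def adaptation_probs(cls: Classification, p_major: float) -> AdaptationProbs:
    """Cohort probabilities of minor/major surgical adaptation.

    Major adaptations occur only in true positives; the remaining detected
    patients get minor adaptations.  False positives also receive minor
    adaptations, reported separately (they carry no cost or risk change).
    """
    if not 0.0 <= p_major <= 1.0:
        raise ValueError("p_major outside [0, 1]")
    return AdaptationProbs(
        p_minor_true=cls.p_tp * (1.0 - p_major),
        p_major_adapt=cls.p_tp * p_major,
        p_minor_fp=cls.p_fp,
    )


def proportional_stroke_policy(
    em: EarlyMortality, prevalence: float, params: ParameterSet
) -> StratumStrokeRisk:
    """Baseline stroke risk proportional to each stratum's early mortality.

    Fatal strokes are a fixed share of early deaths, and fatal strokes are a
    fixed fraction of all strokes, so the per-stratum total stroke risk is
    ``T_i = m_i * p_death_is_stroke / (1 - p_stroke_nonfatal)``; the embolic
    fraction applies uniformly in both strata.
    """
    k = params.p_death_is_stroke / (1.0 - params.p_stroke_nonfatal)
    t_no = em.m_no_athero * k
    t_ath = em.m_athero * k
    pe = params.p_stroke_embolic
    return StratumStrokeRisk(
        embolic_no=pe * t_no,
        nonembolic_no=(1.0 - pe) * t_no,
        embolic_athero=pe * t_ath,
        nonembolic_athero=(1.0 - pe) * t_ath,
    )


def concentrated_embolic_policy(
    em: EarlyMortality, prevalence: float, params: ParameterSet
) -> StratumStrokeRisk:
    """Alternate linkage: all embolic strokes arise in atherosclerosis patients.

    The cohort-average total stroke risk is kept at
    ``T = m_avg * p_death_is_stroke / (1 - p_stroke_nonfatal)``; its
    non-embolic share is spread uniformly while the embolic share is
    concentrated in the atherosclerosis stratum (rate ``p_embolic*T/prev``).
    """
    k = params.p_death_is_stroke / (1.0 - params.p_stroke_nonfatal)
    t_avg = em.m_avg * k
    pe = params.p_stroke_embolic
    emb_ath = pe * t_avg / prevalence if prevalence > 0 else 0.0
    if emb_ath > 1.0:
        raise ValueError("embolic stroke risk exceeds 1 under concentration")
    return StratumStrokeRisk(
        embolic_no=0.0,
        nonembolic_no=(1.0 - pe) * t_avg,
        embolic_athero=emb_ath,
        nonembolic_athero=(1.0 - pe) * t_avg,
    )


def stroke_and_death_probs(
    subgroup: Subgroup,
    em: EarlyMortality,
    cls: Classification,
    params: ParameterSet,
    policy: StrokePolicy = proportional_stroke_policy,
) -> StrategyOutcome:
    """Combine classification, stroke linkage, and adaptation effect.

    Detected atherosclerosis (true positives) has its embolic stroke risk
    multiplied by ``rr_adaptation``; false negatives keep the full risk;
    patients without atherosclerosis are unaffected by (minor) adaptation.
    Fatal and non-fatal strokes split the total by ``p_stroke_nonfatal``;
    other early deaths absorb the remainder of the average early mortality
    (floored at zero, with a flag when flooring bites).
    """
    risk = policy(em, cls.prevalence, params)
    rr = params.rr_adaptation

    risk_adapted_ath = risk.nonembolic_athero + rr * risk.embolic_athero
    risk_unadapted_ath = risk.nonembolic_athero + risk.embolic_athero
    risk_no = risk.nonembolic_no + risk.embolic_no

    total = (
        cls.p_tp * risk_adapted_ath
        + cls.p_fn * risk_unadapted_ath
        + (cls.p_fp + cls.p_tn) * risk_no
    )
    fatal = total * (1.0 - params.p_stroke_nonfatal)
    nonfatal = total * params.p_stroke_nonfatal
    death_other = em.m_avg - fatal
    floored = death_other < 0.0
    if floored:
        death_other = 0.0
    adapt = adaptation_probs(cls, params.p_major_adaptation)
    return StrategyOutcome(
        p_minor_adaptation_true=adapt.p_minor_true,
        p_major_adaptation=adapt.p_major_adapt,
        p_minor_adaptation_fp=adapt.p_minor_fp,
        p_stroke_nonfatal=nonfatal,
        p_stroke_fatal=fatal,
        p_death_other=death_other,
        p_no_complication=1.0 - nonfatal - fatal - death_other,
        floored_death_other=floored,
    )


def outcome_for_strategy(
    subgroup: Subgroup,
    params: ParameterSet,
    strategy: str,
    arteriopathy_or: float,
    policy: StrokePolicy = proportional_stroke_policy,
) -> StrategyOutcome:
    """Full decision-tree evaluation for ``'tee'`` or ``'mp'``."""
    perf = params.test_performance(strategy)
    em = stratify_mortality(
        subgroup.euroscore_avg_mortality, subgroup.prevalence, arteriopathy_or
    )
    cls = classify(subgroup.prevalence, perf)
    return stroke_and_death_probs(subgroup, em, cls, params, policy=policy)


@dataclass(frozen=True)
class MicrosimResult:
    """Counts from an individual-level simulation of the classification stage."""

    n: int
    n_tp: int
    n_fn: int
    n_fp: int
    n_tn: int
    n_major: int
    n_minor_true: int
    n_minor_fp: int

    @property
    def frac_minor_true(self) -> float:
        return self.n_minor_true / self.n

    @property
    def frac_major(self) -> float:
        return self.n_major / self.n


def simulate_classification(
    n: int,
    prevalence: float,
    perf: TestPerformance,
    p_major: float,
    rng: np.random.Generator,
) -> MicrosimResult:
    """First-order microsimulation of testing and adaptation for ``n`` patients.

    Each patient's atherosclerosis status, test result, and (for true
    positives) major-vs-minor adaptation are Bernoulli draws; used to put
    Monte-Carlo error bars on the analytic cohort probabilities.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    disease = rng.random(n) < prevalence
    u_test = rng.random(n)
    positive = np.where(disease, u_test < perf.sensitivity, u_test < 1.0 - perf.specificity)
    tp = disease & positive
    major = tp & (rng.random(n) < p_major)
    return MicrosimResult(
        n=n,
        n_tp=int(tp.sum()),
        n_fn=int((disease & ~positive).sum()),
        n_fp=int((~disease & positive).sum()),
        n_tn=int((~disease & ~positive).sum()),
        n_major=int(major.sum()),
        n_minor_true=int((tp & ~major).sum()),
        n_minor_fp=int((~disease & positive).sum()),
    )
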