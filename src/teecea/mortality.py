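"""Early (within-30-day) surgical mortality.

Three pieces: a logistic risk calculator of the EuroSCORE form for users who
supply raw risk factors, a multiplicative calibration step (predicted risks
are scaled down by a fixed fraction to match contemporary observed
mortality), and the stratification of a subgroup-average early mortality into
with/without-atherosclerosis strata.  Stratification rests on the assumption
that every patient with ascending-aorta atherosclerosis carries the
extra-cardiac arteriopathy risk factor, so the two strata differ by a fixed
odds ratio while their prevalence-weighted mix reproduces the average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import math

from scipy.optimize import brentq

__all__ = [
    "EarlyMortality",
    "euroscore_logistic",
    "calibrate",
    "stratify_mortality",
]

_TOL = 1e-10


@dataclass(frozen=True)
class EarlyMortality:
    """Early mortality split by atherosclerosis status.

    Invariants (both enforced to 1e-10 by :func:`stratify_mortality`):
    the prevalence-weighted mix of the strata equals ``m_avg``, and the odds
    of ``m_athero`` against ``m_no_athero`` equal ``arteriopathy_or``.
    """

    m_avg: float
    m_no_athero: float
    m_athero: float
    arteriopathy_or: float


def euroscore_logistic(
    risk_factor_indicators: Mapping[str, float],
    coefficients: Mapping[str, float],
    intercept: float,
) -> float:
    """Predicted early mortality from a logistic risk equation.

    ``coefficients`` and ``risk_factor_indicators`` must name exactly the
    same factors; the result is the inverse logit of
    ``intercept + sum(coef * indicator)``, strictly inside (0, 1).
    """
    missing = set(coefficients) - set(risk_factor_indicators)
    if missing:
        raise ValueError(f"risk factors missing from indicators: {sorted(missing)}")
    unknown = set(risk_factor_indicators) - set(coefficients)
    if unknown:
        raise ValueError(f"unknown risk factor names: {sorted(unknown)}")
    eta = intercept + sum(
        coefficients[name] * risk_factor_indicators[name] for name in coefficients
    )
    return 1.0 / (1.0 + math.exp(-eta))


def calibrate(predicted: float, reduction: float) -> float:
    """Scale a predicted risk down by ``reduction`` (e.g. 0.71 for a 71% cut)."""
    if not 0.0 < predicted < 1.0:
        raise ValueError(f"predicted risk {predicted!r} outside (0, 1)")
    if not 0.0 <= reduction < 1.0:
        raise ValueError(f"reduction {reduction!r} outside [0, 1)")
    return predicted * (1.0 - reduction)


def _or_transform(p: float, odds_ratio: float) -> float:
    """Apply an odds ratio to a probability."""
    if p >= 1.0:
        return 1.0
    odds = odds_ratio * p / (1.0 - p)
    return odds / (1.0 + odds)


def stratify_mortality(
    m_avg: float, prevalence: float, arteriopathy_or: float
) -> EarlyMortality:
    """Split a cohort-average early mortality into atherosclerosis strata.

    Solves for the without-atherosclerosis mortality ``x`` such that
    ``(1 - prevalence) * x + prevalence * OR(x) == m_avg`` where ``OR(x)``
    applies ``arteriopathy_or`` on the odds scale.  The left side is strictly
    increasing in ``x`` and spans (0, 1), so the root is unique; it is found
    by bracketed root-finding to 1e-12.
    """
    if not 0.0 < m_avg < 1.0:
        raise ValueError(f"m_avg {m_avg!r} outside (0, 1)")
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError(f"prevalence {prevalence!r} outside [0, 1]")
    if arteriopathy_or <= 0.0:
        raise ValueError(f"arteriopathy_or {arteriopathy_or!r} must be > 0")

    if arteriopathy_or == 1.0:
        return EarlyMortality(m_avg, m_avg, m_avg, arteriopathy_or)
    if prevalence == 0.0:
        return EarlyMortality(m_avg, m_avg, _or_transform(m_avg, arteriopathy_or), arteriopathy_or)
    if prevalence == 1.0:
        m_no = _or_transform(m_avg, 1.0 / arteriopathy_or)
        return EarlyMortality(m_avg, m_no, m_avg, arteriopathy_or)

    def f(x: float) -> float:
        return (1.0 - prevalence) * x + prevalence * _or_transform(x, arteriopathy_or) - m_avg

    lo, hi = 1e-300, 1.0 - 1e-15
    if f(lo) > 0.0 or f(hi) < 0.0:
        raise ValueError("no feasible stratification for the given inputs")
    m_no = brentq(f, lo, hi, xtol=1e-14, maxiter=200)
    m_ath = _or_transform(m_no, arteriopathy_or)
    if abs((1.0 - prevalence) * m_no + prevalence * m_ath - m_avg) > _TOL:
        raise ValueError("stratification failed to reproduce the average mortality")
    return EarlyMortality(m_avg, m_no, m_ath, arteriopathy_or)
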