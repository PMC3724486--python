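"""Synthetic life tables and default fixtures.

National statistical-office life tables are licensed data and are not
bundled; instead this module generates life tables from a Gompertz-Makeham
mortality law, the minimal realistic model of adult all-cause mortality: a
constant background hazard plus an exponentially age-increasing component.
The bundled default specs are tuned to the general shape of recent Dutch
mortality (female mortality below male at every age, life expectancy at 65
in the high teens) but are explicitly NOT official statistics — analyses
meant to inform decisions should load a real life table through
:meth:`teecea.markov.LifeTable.from_csv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .markov import LifeTable
from .params import ModelConfig, ParameterSet, Subgroup, default_config_path, load_config

__all__ = [
    "GompertzMakehamSpec",
    "make_lifetable",
    "default_lifetable",
    "default_fixture",
    "DEFAULT_MALE_SPEC",
    "DEFAULT_FEMALE_SPEC",
]


@dataclass(frozen=True)
class GompertzMakehamSpec:
    """Gompertz-Makeham hazard: ``mu(age) = makeham + a * exp(b * age)``.

    The annual death probability is the hazard transform
    ``q(age) = 1 - exp(-mu(age))``, non-decreasing in age for non-negative
    parameters, with ``q = 1`` imposed at ``terminal_age``.
    """

    makeham: float
    gompertz_a: float
    gompertz_b: float
    terminal_age: int = 110

    def __post_init__(self) -> None:
        if self.makeham < 0:
            raise ValueError("makeham component must be >= 0")
        if self.gompertz_a <= 0:
            raise ValueError("gompertz_a must be > 0")
        if self.gompertz_b < 0:
            raise ValueError("gompertz_b must be >= 0")
        if self.terminal_age < 1:
            raise ValueError("terminal_age must be >= 1")

    def q(self, age: float) -> float:
        """Annual death probability at ``age``."""
        if age >= self.terminal_age:
            return 1.0
        hazard = self.makeham + self.gompertz_a * math.exp(self.gompertz_b * age)
        return 1.0 - math.exp(-hazard)


# Fixture constants shaped like recent Dutch period mortality; not official
# statistics (see module docstring).
DEFAULT_MALE_SPEC = GompertzMakehamSpec(
    makeham=5.0e-4, gompertz_a=1.97e-5, gompertz_b=0.098
)
DEFAULT_FEMALE_SPEC = GompertzMakehamSpec(
    makeham=3.0e-4, gompertz_a=1.32e-5, gompertz_b=0.098
)


def make_lifetable(
    spec_male: GompertzMakehamSpec, spec_female: GompertzMakehamSpec
) -> LifeTable:
    """Life table over ages 0..terminal from per-sex Gompertz-Makeham specs."""
    if spec_male.terminal_age != spec_female.terminal_age:
        raise ValueError("both specs must share a terminal age")
    terminal = spec_male.terminal_age
    ages = np.arange(0, terminal + 1)
    qx = {
        "male": np.array([spec_male.q(a) for a in ages]),
        "female": np.array([spec_female.q(a) for a in ages]),
    }
    for sex, q in qx.items():
        if np.any(np.diff(q) < 0):
            raise ValueError(f"generated {sex} mortality is not non-decreasing")
        if np.any((q <= 0) | (q > 1)):
            raise ValueError(f"generated {sex} mortality leaves (0, 1]")
    return LifeTable(ages=ages, qx=qx)


def default_lifetable() -> LifeTable:
    return make_lifetable(DEFAULT_MALE_SPEC, DEFAULT_FEMALE_SPEC)


def default_fixture() -> tuple[ParameterSet, tuple[Subgroup, ...], LifeTable]:
    """The bundled study conditions: default parameters, the 12 subgroups
    (sex x age 55/65/75 x low/high atherosclerosis prevalence), and the
    synthetic life table."""
    config: ModelConfig = load_config(default_config_path())
    return config.parameters, config.subgroups, default_lifetable()
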