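"""Model parameters, their uncertainty distributions, and configuration I/O.

Every quantity the model consumes is carried in a :class:`ParameterSet`:
probabilities governing the stroke pathway, diagnostic test accuracy for the
two strategies, the treatment effect of surgical adaptation, utilities, unit
costs in euros, and discount rates.  Each uncertain quantity is paired with a
:class:`DistributionSpec` used by the probabilistic sensitivity analysis;
quantities without a distribution are treated as fixed.

Configuration files are YAML (or JSON) documents with three blocks:
``parameters`` (keys exactly the :class:`ParameterSet` field names, values
``{value: x, dist: {family: ..., params: [...]}}``), ``euroscore`` (logistic
risk-equation coefficients and the extra-cardiac arteriopathy odds ratio),
and ``subgroups`` (the patient subgroups with their atherosclerosis
prevalence and average predicted early mortality).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import yaml
from scipy import stats

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "Subgroup",
    "EuroscoreConfig",
    "ModelConfig",
    "summarize",
    "sample",
    "load_parameter_set",
    "load_config",
    "default_config_path",
    "alternate_config_path",
    "default_parameter_set",
]

_FAMILIES = {"beta", "lognormal", "uniform", "triangular", "gamma", "fixed"}
_N_PARAMS = {
    "beta": 2,
    "lognormal": 2,
    "uniform": 2,
    "triangular": 3,
    "gamma": 2,
    "fixed": 1,
}


@dataclass(frozen=True)
class DistributionSpec:
    """A sampling distribution for one uncertain model parameter.

    Parameters are family-specific:

    - ``beta``: alpha, beta (both > 0)
    - ``lognormal``: mean and sd on the natural-log scale (sd > 0)
    - ``uniform``: lower, upper (lower < upper)
    - ``triangular``: lower, mode, upper (lower <= mode <= upper)
    - ``gamma``: shape, scale (both > 0)
    - ``fixed``: the value (degenerate distribution)
    """

    family: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}")
        p = tuple(float(x) for x in self.params)
        object.__setattr__(self, "params", p)
        if len(p) != _N_PARAMS[self.family]:
            raise ValueError(
                f"{self.family} expects {_N_PARAMS[self.family]} parameters, got {len(p)}"
            )
        if self.family == "beta" and (p[0] <= 0 or p[1] <= 0):
            raise ValueError("beta requires alpha>0 and beta>0")
        if self.family == "lognormal" and p[1] <= 0:
            raise ValueError("lognormal requires sd>0 on the log scale")
        if self.family == "uniform" and not p[0] < p[1]:
            raise ValueError("uniform requires lower<upper")
        if self.family == "triangular" and not p[0] <= p[1] <= p[2]:
            raise ValueError("triangular requires lower<=mode<=upper")
        if self.family == "gamma" and (p[0] <= 0 or p[1] <= 0):
            raise ValueError("gamma requires shape>0 and scale>0")

    def frozen(self):
        """The scipy frozen distribution (``None`` for the fixed family)."""
        p = self.params
        if self.family == "beta":
            return stats.beta(p[0], p[1])
        if self.family == "lognormal":
            return stats.lognorm(s=p[1], scale=math.exp(p[0]))
        if self.family == "uniform":
            return stats.uniform(loc=p[0], scale=p[1] - p[0])
        if self.family == "triangular":
            lower, mode, upper = p
            width = upper - lower
            if width == 0:
                return None
            return stats.triang(c=(mode - lower) / width, loc=lower, scale=width)
        if self.family == "gamma":
            return stats.gamma(p[0], scale=p[1])
        return None


def summarize(dist: DistributionSpec) -> tuple[float, float, float]:
    """Analytic mean and central 95% interval (2.5% / 97.5% quantiles)."""
    frozen = dist.frozen()
    if frozen is None:
        v = dist.params[0]
        return v, v, v
    return (
        float(frozen.mean()),
        float(frozen.ppf(0.025)),
        float(frozen.ppf(0.975)),
    )


def sample(dist: DistributionSpec, rng: np.random.Generator) -> float:
    """One draw from ``dist`` using the supplied generator.

    The fixed family returns its value without consuming randomness, so a
    fully degenerate parameter set leaves the stream untouched.
    """
    frozen = dist.frozen()
    if frozen is None:
        return float(dist.params[0])
    return float(frozen.rvs(random_state=rng))


# --- parameter set ---------------------------------------------------------

_PROBABILITY_FIELDS = frozenset(
    {
        "p_death_is_stroke",
        "p_stroke_nonfatal",
        "p_stroke_embolic",
        "sens_mp",
        "spec_mp",
        "sens_tee",
        "spec_tee",
        "p_major_adaptation",
        "excess_mortality_under61",
        "excess_mortality_61to70",
        "excess_mortality_over70",
        "utility_post_stroke",
        "utility_no_complication",
        "mortality_calibration_reduction",
    }
)
_NONNEGATIVE_FIELDS = frozenset(
    {
        "cost_death",
        "cost_fatal_stroke",
        "cost_tee_device",
        "cost_surgery_base",
        "cost_surgery_major_adaptation",
        "cost_nonfatal_stroke_acute",
        "cost_post_stroke_annual",
        "discount_costs",
        "discount_effects",
    }
)
_POSITIVE_FIELDS = frozenset({"rr_adaptation"})


@dataclass(frozen=True)
class ParameterSet:
    """All model parameters as point values, plus their PSA distributions.

    ``distributions`` maps field names to :class:`DistributionSpec`; fields
    absent from the map are fixed.  :meth:`sample` returns a new
    :class:`ParameterSet` with each uncertain field replaced by one draw.
    """

    # stroke pathway
    p_death_is_stroke: float
    p_stroke_nonfatal: float
    p_stroke_embolic: float
    # diagnostic accuracy
    sens_mp: float
    spec_mp: float
    sens_tee: float
    spec_tee: float
    # adaptation effect
    rr_adaptation: float
    p_major_adaptation: float
    # excess annual mortality after surgery, by age band at surgery
    excess_mortality_under61: float
    excess_mortality_61to70: float
    excess_mortality_over70: float
    # utilities
    utility_post_stroke: float
    utility_no_complication: float
    # unit costs (euros)
    cost_death: float
    cost_fatal_stroke: float
    cost_tee_device: float
    cost_surgery_base: float
    cost_surgery_major_adaptation: float
    cost_nonfatal_stroke_acute: float
    cost_post_stroke_annual: float
    # discounting
    discount_costs: float
    discount_effects: float
    # early-mortality calibration
    mortality_calibration_reduction: float
    distributions: Mapping[str, DistributionSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in _PROBABILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v!r} outside [0, 1]")
        for name in _NONNEGATIVE_FIELDS:
            v = getattr(self, name)
            if v < 0.0:
                raise ValueError(f"{name}={v!r} must be >= 0")
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if v <= 0.0:
                raise ValueError(f"{name}={v!r} must be > 0")
        for key in self.distributions:
            if key not in _FIELD_NAMES:
                raise ValueError(f"distribution given for unknown parameter {key!r}")

    def sample(self, rng: np.random.Generator) -> "ParameterSet":
        """Draw one realization of every uncertain parameter.

        Fields are visited in declaration order so the mapping from seed to
        draw is stable across runs and platforms.
        """
        updates = {
            name: sample(self.distributions[name], rng)
            for name in _FIELD_NAMES
            if name in self.distributions
        }
        return dataclasses.replace(self, **updates)

    def replace(self, **updates: Any) -> "ParameterSet":
        return dataclasses.replace(self, **updates)

    def test_performance(self, strategy: str):
        """Sensitivity/specificity pair for ``'tee'`` or ``'mp'``."""
        from .decision_tree import TestPerformance

        if strategy == "tee":
            return TestPerformance(self.sens_tee, self.spec_tee)
        if strategy == "mp":
            return TestPerformance(self.sens_mp, self.spec_mp)
        raise ValueError(f"unknown strategy {strategy!r}; expected 'tee' or 'mp'")


_FIELD_NAMES: tuple[str, ...] = tuple(
    f.name for f in dataclasses.fields(ParameterSet) if f.name != "distributions"
)


@dataclass(frozen=True)
class Subgroup:
    """One patient subgroup: sex, age at surgery, atherosclerosis prevalence,
    and the (calibrated) average predicted early mortality for the subgroup."""

    sex: str
    age_at_surgery: int
    prevalence: float
    euroscore_avg_mortality: float

    def __post_init__(self) -> None:
        if self.sex not in {"male", "female"}:
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age_at_surgery < 18:
            raise ValueError("age_at_surgery must be >= 18")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence outside [0, 1]")
        if not 0.0 < self.euroscore_avg_mortality < 1.0:
            raise ValueError("euroscore_avg_mortality outside (0, 1)")

    @property
    def label(self) -> str:
        noun = "men" if self.sex == "male" else "women"
        return f"{noun} {self.age_at_surgery} yr, prevalence {self.prevalence:.0%}"


@dataclass(frozen=True)
class EuroscoreConfig:
    """Logistic risk-equation inputs: intercept, named coefficients, and the
    odds ratio attached to extra-cardiac arteriopathy (the proxy risk factor
    for ascending-aorta atherosclerosis)."""

    intercept: float
    coefficients: Mapping[str, float]
    arteriopathy_or: float

    def __post_init__(self) -> None:
        if self.arteriopathy_or <= 0:
            raise ValueError("arteriopathy_or must be > 0")


@dataclass(frozen=True)
class ModelConfig:
    parameters: ParameterSet
    euroscore: EuroscoreConfig
    subgroups: tuple[Subgroup, ...]


# --- config loading --------------------------------------------------------


def default_config_path() -> Path:
    """Path of the bundled default configuration."""
    return Path(resources.files("teecea").joinpath("data/default_config.yaml"))


def alternate_config_path() -> Path:
    """Bundled alternate preset using the rounded literature figures for the
    fatal-stroke share (15%) and non-fatal fraction (62%)."""
    return Path(resources.files("teecea").joinpath("data/config_literature_rounded.yaml"))


def _read_document(source: str | Path | Mapping[str, Any]) -> Mapping[str, Any]:
    if isinstance(source, Mapping):
        return source
    path = Path(source)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def _parse_entry(name: str, entry: Any) -> tuple[float, DistributionSpec | None]:
    if isinstance(entry, Mapping):
        unknown = set(entry) - {"value", "dist"}
        if unknown:
            raise ValueError(f"parameter {name!r}: unknown keys {sorted(unknown)}")
        if "value" not in entry:
            raise ValueError(f"parameter {name!r}: missing 'value'")
        value = float(entry["value"])
        dist = None
        if "dist" in entry and entry["dist"] is not None:
            d = entry["dist"]
            unknown = set(d) - {"family", "params"}
            if unknown:
                raise ValueError(f"parameter {name!r}: unknown dist keys {sorted(unknown)}")
            dist = DistributionSpec(d["family"], tuple(d.get("params", ())))
        return value, dist
    return float(entry), None


def load_parameter_set(config_source: str | Path | Mapping[str, Any]) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a config document.

    ``config_source`` may be a YAML/JSON file path or an in-memory mapping;
    a document with a ``parameters`` block uses that block, otherwise the
    mapping itself is taken as the parameter block.  Every field must be
    present; unknown keys are rejected; range violations raise a
    :class:`ValueError` naming the offending key.
    """
    doc = _read_document(config_source)
    block = doc.get("parameters", doc) if isinstance(doc, Mapping) else doc
    unknown = set(block) - set(_FIELD_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    missing = set(_FIELD_NAMES) - set(block)
    if missing:
        raise ValueError(f"missing parameter keys: {sorted(missing)}")
    values: dict[str, float] = {}
    dists: dict[str, DistributionSpec] = {}
    for name in _FIELD_NAMES:
        value, dist = _parse_entry(name, block[name])
        values[name] = value
        if dist is not None:
            dists[name] = dist
    return ParameterSet(**values, distributions=dists)


def _parse_subgroups(entries: Sequence[Mapping[str, Any]]) -> tuple[Subgroup, ...]:
    out = []
    for entry in entries:
        unknown = set(entry) - {"sex", "age", "prevalence", "early_mortality"}
        if unknown:
            raise ValueError(f"subgroup entry: unknown keys {sorted(unknown)}")
        out.append(
            Subgroup(
                sex=str(entry["sex"]),
                age_at_surgery=int(entry["age"]),
                prevalence=float(entry["prevalence"]),
                euroscore_avg_mortality=float(entry["early_mortality"]),
            )
        )
    return tuple(out)


def load_config(config_source: str | Path | Mapping[str, Any]) -> ModelConfig:
    """Load a full model configuration (parameters, EuroSCORE block, subgroups)."""
    doc = _read_document(config_source)
    unknown = set(doc) - {"parameters", "euroscore", "subgroups"}
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    if "parameters" not in doc:
        raise ValueError("missing top-level 'parameters' block")
    parameters = load_parameter_set(doc["parameters"])
    es = doc.get("euroscore", {})
    euroscore = EuroscoreConfig(
        intercept=float(es.get("intercept", 0.0)),
        coefficients={str(k): float(v) for k, v in dict(es.get("coefficients", {})).items()},
        arteriopathy_or=float(es.get("arteriopathy_or", 1.0)),
    )
    subgroups = _parse_subgroups(doc.get("subgroups", ()))
    return ModelConfig(parameters=parameters, euroscore=euroscore, subgroups=subgroups)


def default_parameter_set() -> ParameterSet:
    return load_parameter_set(default_config_path())
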