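"""Scenario configuration: the data-generating mechanism of one grid cell.

Defaults reproduce the study's representative setting: a closed cohort
of 80,000 male workers entering at age 20 and followed 60 years; doses
log-normal (GM 0.2623 Gy, GSD 2.223) capped at 1 Gy; smoking prevalence
0.3 at 0 Gy with odds ratio 32 at 1 Gy; cancer hazard ratio 1.3 at 1 Gy
(ERR 0.3) and 1.6 for smoking; standard-normal frailty with coefficient
0; Weibull(6.086609, 75.992411) cancer mortality and the log-quadratic
non-cancer hazard exp(0.001022*(t+0.05311)^2 - 7.221).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

from .hazards import QuadraticLogHazard, WeibullHazard

__all__ = ["DoseModel", "SmokingModel", "RiskModel", "ScenarioConfig"]


@dataclass(frozen=True)
class DoseModel:
    """Log-normal occupational dose distribution with a hard cap.

    ``geometric_mean`` (Gy) and ``geometric_sd`` (dimensionless, >= 1)
    parameterise the log-normal; draws above ``cap`` are clamped to it.
    """

    geometric_mean: float = 0.2623
    geometric_sd: float = 2.223
    cap: float = 1.0

    def __post_init__(self) -> None:
        if not self.geometric_mean > 0:
            raise ValueError("geometric_mean must be positive")
        if not self.geometric_sd >= 1:
            raise ValueError("geometric_sd must be >= 1")
        if not self.cap > 0:
            raise ValueError("cap must be positive")


@dataclass(frozen=True)
class SmokingModel:
    """Logistic-in-dose binary smoking model.

    ``baseline_prob`` is the smoking probability at 0 Gy; ``or_at_1gy``
    is the odds ratio comparing 1 Gy to 0 Gy, so
    ``logit p(d) = logit(p0) + log(or_at_1gy) * d``.
    """

    baseline_prob: float = 0.3
    or_at_1gy: float = 32.0

    def __post_init__(self) -> None:
        if not 0 < self.baseline_prob < 1:
            raise ValueError("baseline_prob must be in (0, 1)")
        if not self.or_at_1gy > 0:
            raise ValueError("or_at_1gy must be positive")

    def probability(self, dose):
        import numpy as np

        logit0 = math.log(self.baseline_prob / (1.0 - self.baseline_prob))
        eta = logit0 + math.log(self.or_at_1gy) * np.asarray(dose, dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass(frozen=True)
class RiskModel:
    """Log-linear multiplicative risk model exp(br*dose + bs*smk + bu*u)."""

    beta_r: float = math.log(1.3)  # log HR per Gy (default ERR 0.3)
    beta_s: float = math.log(1.6)  # log HR for smoking
    beta_u: float = 0.0            # coefficient on standard-normal frailty

    def __post_init__(self) -> None:
        for name in ("beta_r", "beta_s", "beta_u"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    @classmethod
    def from_hazard_ratios(cls, hr_dose: float, hr_smoking: float, beta_u: float = 0.0) -> "RiskModel":
        return cls(beta_r=math.log(hr_dose), beta_s=math.log(hr_smoking), beta_u=beta_u)

    @property
    def err_per_gy(self) -> float:
        """Excess relative risk at 1 Gy: exp(beta_r) - 1."""
        return math.exp(self.beta_r) - 1.0


@dataclass(frozen=True)
class ScenarioConfig:
    """All generator and analysis settings for one simulation scenario."""

    cohort_size: int = 80_000
    follow_up: float = 60.0
    dose_model: DoseModel = field(default_factory=DoseModel)
    smoking_model: SmokingModel = field(default_factory=SmokingModel)
    risk_model: RiskModel = field(default_factory=RiskModel)
    cancer_hazard: WeibullHazard = field(
        default_factory=lambda: WeibullHazard(shape=6.086609, scale=75.992411)
    )
    noncancer_hazard: QuadraticLogHazard = field(
        default_factory=lambda: QuadraticLogHazard(
            curvature=0.001022, shift=0.05311, intercept=-7.221
        )
    )
    n_dose_categories: int = 10
    age_band: float = 1.0
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cohort_size < 2:
            raise ValueError("cohort_size must be >= 2")
        if not self.follow_up > 0:
            raise ValueError("follow_up must be positive")
        if self.n_dose_categories < 2:
            raise ValueError("n_dose_categories must be >= 2")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")

    # -- derived ----------------------------------------------------------

    @property
    def beta_r_true(self) -> float:
        return self.risk_model.beta_r

    @property
    def err_true(self) -> float:
        return self.risk_model.err_per_gy

    # -- replacement / serialization --------------------------------------

    def replace(self, **changes: Any) -> "ScenarioConfig":
        """Return a copy with dotted or flat fields replaced.

        Accepts nested dotted keys such as ``"smoking_model.or_at_1gy"``
        as well as top-level field names.
        """
        top: dict[str, Any] = {}
        for key, value in changes.items():
            if "." in key:
                outer, inner = key.split(".", 1)
                sub = top.get(outer, getattr(self, outer))
                top[outer] = dataclasses.replace(sub, **{inner: value})
            else:
                top[key] = value
        return dataclasses.replace(self, **top)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ScenarioConfig":
        data = dict(data)
        converters = {
            "dose_model": DoseModel,
            "smoking_model": SmokingModel,
            "risk_model": RiskModel,
            "cancer_hazard": WeibullHazard,
            "noncancer_hazard": QuadraticLogHazard,
        }
        for key, typ in converters.items():
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        """Load a scenario from a YAML key-value file (nested mapping)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        grid = data.pop("grid", None)
        cfg = cls.from_dict(data)
        if grid is not None:
            raise ValueError("config contains a 'grid' section; use load_grid()")
        return cfg


def load_grid(path) -> tuple[ScenarioConfig, dict[str, list]]:
    """Load a base scenario plus a sweep grid from one YAML file.

    The optional top-level ``grid`` mapping lists values per (dotted)
    parameter name, e.g. ``grid: {smoking_model.or_at_1gy: [0.1, 1, 32]}``.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    grid = data.pop("grid", {}) or {}
    cfg = ScenarioConfig.from_dict(data)
    return cfg, {str(k): list(v) for k, v in grid.items()}
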