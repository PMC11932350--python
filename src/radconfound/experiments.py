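"""Replication loop, scenario grids and Monte-Carlo performance metrics.

A scenario is summarised per analysis arm (Cox/Poisson × smoking-
adjusted/unadjusted) by three metrics over replications:

* mean relative bias — mean of ``(beta_hat - beta_true) / ERR_true``,
  where ``ERR_true = exp(beta_true) - 1`` is the excess relative risk
  at 1 Gy (the coefficient-scale error divided by the true ERR);
* mean standard error of ``beta_hat``;
* 95% coverage — the fraction of Wald intervals containing ``beta_true``.

The Monte-Carlo standard error of the bias is reported alongside so
runs with fewer replications carry principled tolerances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import generate_cohort
from .config import ScenarioConfig
from .estimators import AnalysisSpec, FitResult, cox_fit, poisson_fit
from .hazards import InversionSampler
from .person_years import build_py_table

__all__ = [
    "ARMS",
    "ArmSummary",
    "ScenarioSummary",
    "relative_bias",
    "coverage",
    "run_scenario",
    "run_grid",
    "extrapolate_or_per_gray",
    "percent_overestimation",
    "write_results_csv",
    "summaries_to_frame",
]

logger = logging.getLogger(__name__)

#: The four analysis arms, keyed (model, analysis): analysis 1 adjusts
#: for smoking, analysis 2 does not.
ARMS: tuple[tuple[str, str], ...] = (
    ("cox", "adjusted"),
    ("cox", "unadjusted"),
    ("poisson", "adjusted"),
    ("poisson", "unadjusted"),
)


def _spec_for(model: str, analysis: str) -> AnalysisSpec:
    covs = ("dose", "smk") if analysis == "adjusted" else ("dose",)
    return AnalysisSpec(model=model, covariates=covs)


def relative_bias(beta_hats: Sequence[float], beta_true: float, err_true: float) -> float:
    """Mean over replications of ``(beta_hat - beta_true) / err_true``."""
    beta_hats = np.asarray(beta_hats, dtype=float)
    if beta_hats.size == 0:
        raise ValueError("beta_hats must be non-empty")
    if err_true == 0:
        raise ValueError("err_true must be non-zero")
    return float(np.mean(beta_hats - beta_true) / err_true)


def coverage(beta_hats: Sequence[float], ses: Sequence[float], beta_true: float,
             z: float = 1.959963984540054) -> float:
    """Fraction of Wald 95% intervals containing ``beta_true``."""
    beta_hats = np.asarray(beta_hats, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if beta_hats.size == 0 or beta_hats.size != ses.size:
        raise ValueError("beta_hats and ses must be equal-length and non-empty")
    if np.any(ses <= 0):
        raise ValueError("all ses must be positive")
    lo = beta_hats - z * ses
    hi = beta_hats + z * ses
    return float(np.mean((lo <= beta_true) & (beta_true <= hi)))


@dataclass(frozen=True)
class ArmSummary:
    """Metrics for one (model, analysis) arm of one scenario."""

    model: str
    analysis: str
    mean_relative_bias: float
    mean_se: float
    coverage95: float
    n_converged: int
    mc_se_of_bias: float


@dataclass(frozen=True)
class ScenarioSummary:
    """All-arm metrics for one scenario, plus the config that produced it."""

    config: ScenarioConfig
    arms: dict = field(default_factory=dict)  # (model, analysis) -> ArmSummary
    n_reps: int = 0

    def arm(self, model: str, analysis: str) -> ArmSummary:
        return self.arms[(model, analysis)]


def _summarize_arm(model: str, analysis: str, fits: list[FitResult],
                   cfg: ScenarioConfig) -> ArmSummary:
    ok = [f for f in fits if f.converged]
    n_dropped = len(fits) - len(ok)
    if n_dropped:
        logger.info("%s/%s: dropped %d non-converged replications", model, analysis, n_dropped)
    if not ok:
        raise RuntimeError(f"all replications failed to converge for arm {model}/{analysis}")
    betas = np.array([f.beta_r_hat for f in ok])
    ses = np.array([f.se for f in ok])
    err = cfg.err_true
    # relative bias is undefined at the null (ERR = 0); coverage still applies
    has_err = err != 0
    return ArmSummary(
        model=model,
        analysis=analysis,
        mean_relative_bias=relative_bias(betas, cfg.beta_r_true, err) if has_err else float("nan"),
        mean_se=float(ses.mean()),
        coverage95=coverage(betas, ses, cfg.beta_r_true),
        n_converged=len(ok),
        mc_se_of_bias=float(betas.std(ddof=1) / math.sqrt(len(ok)) / abs(err))
        if (has_err and len(ok) > 1)
        else float("nan"),
    )


def _fit_one_rep(cfg: ScenarioConfig, rep: int, arms: tuple[tuple[str, str], ...],
                 sampler: InversionSampler) -> dict:
    cohort = generate_cohort(cfg, rep, sampler=sampler)
    out: dict = {}
    pyt = None
    for model, analysis in arms:
        spec = _spec_for(model, analysis)
        if model == "cox":
            out[(model, analysis)] = cox_fit(cohort, spec)
        else:
            if pyt is None:
                pyt = build_py_table(
                    cohort,
                    n_dose_categories=cfg.n_dose_categories,
                    age_band=cfg.age_band,
                    follow_up=cfg.follow_up,
                    dose_max=cfg.dose_model.cap,
                )
            out[(model, analysis)] = poisson_fit(pyt, spec)
    return out


def run_scenario(
    cfg: ScenarioConfig,
    arms: Iterable[tuple[str, str]] = ARMS,
    n_jobs: int = 1,
) -> ScenarioSummary:
    """Run the full replication loop for one scenario.

    Deterministic given ``cfg.seed`` regardless of ``n_jobs``: each
    replication draws from its own child stream of the root seed.
    """
    arms = tuple(arms)
    sampler = InversionSampler(cfg.noncancer_hazard, cfg.follow_up)
    if n_jobs != 1:
        from joblib import Parallel, delayed

        per_rep = Parallel(n_jobs=n_jobs)(
            delayed(_fit_one_rep)(cfg, rep, arms, sampler) for rep in range(cfg.n_reps)
        )
    else:
        per_rep = [_fit_one_rep(cfg, rep, arms, sampler) for rep in range(cfg.n_reps)]
    summaries = {
        key: _summarize_arm(key[0], key[1], [r[key] for r in per_rep], cfg) for key in arms
    }
    return ScenarioSummary(config=cfg, arms=summaries, n_reps=cfg.n_reps)


def run_grid(
    base_cfg: ScenarioConfig,
    grid: Mapping[str, Sequence],
    mode: str = "per_axis",
    arms: Iterable[tuple[str, str]] = ARMS,
    n_jobs: int = 1,
) -> list[ScenarioSummary]:
    """Sweep scenario parameters around a base configuration.

    ``grid`` maps (dotted) ScenarioConfig field names to value lists.
    ``mode='per_axis'`` varies one factor at a time with all others at
    the base values — the layout of the study's results tables;
    ``mode='cartesian'`` crosses all axes.
    """
    for key, values in grid.items():
        if not len(values):
            continue
        try:
            base_cfg.replace(**{key: values[0]})
        except (AttributeError, TypeError) as exc:
            raise KeyError(f"unknown grid key: {key!r}") from exc
    if not grid:
        return [run_scenario(base_cfg, arms=arms, n_jobs=n_jobs)]
    configs: list[ScenarioConfig] = []
    if mode == "per_axis":
        for key, values in grid.items():
            for v in values:
                configs.append(base_cfg.replace(**{key: v}))
    elif mode == "cartesian":
        import itertools

        keys = list(grid)
        for combo in itertools.product(*(grid[k] for k in keys)):
            configs.append(base_cfg.replace(**dict(zip(keys, combo))))
    else:
        raise ValueError("mode must be 'per_axis' or 'cartesian'")
    out = []
    for i, cfg in enumerate(configs):
        logger.info("scenario %d/%d", i + 1, len(configs))
        out.append(run_scenario(cfg, arms=arms, n_jobs=n_jobs))
    return out


def extrapolate_or_per_gray(p_low: float, p_high: float, delta_dose: float) -> float:
    """Odds ratio per Gy implied by smoking proportions at two dose levels.

    Given smoking prevalences ``p_low`` and ``p_high`` in groups whose
    mean doses differ by ``delta_dose`` Gy, the per-Gy odds ratio under
    the logistic-linear model is the observed odds ratio raised to
    ``1/delta_dose``.
    """
    for p in (p_low, p_high):
        if not 0 < p < 1:
            raise ValueError("proportions must lie strictly in (0, 1)")
    if not delta_dose > 0:
        raise ValueError("delta_dose must be positive")
    odds_ratio = (p_high / (1 - p_high)) / (p_low / (1 - p_low))
    return odds_ratio ** (1.0 / delta_dose)


def percent_overestimation(err_unadjusted: float, err_adjusted: float) -> float:
    """Percent overestimation of an ERR estimate relative to an adjusted one."""
    if err_adjusted == 0:
        raise ValueError("err_adjusted must be non-zero")
    return (err_unadjusted / err_adjusted - 1.0) * 100.0


_METRIC_COLS = ["bias", "se", "coverage", "n_converged", "mc_se_bias"]


def summaries_to_frame(summaries: Sequence[ScenarioSummary]) -> pd.DataFrame:
    """Wide results table: one row per scenario, metric columns per arm."""
    if not summaries:
        raise ValueError("summaries must be non-empty")
    rows = []
    for s in summaries:
        cfg = s.config
        row = {
            "cohort_size": cfg.cohort_size,
            "err_per_gy": cfg.err_true,
            "hr_smoking": math.exp(cfg.risk_model.beta_s),
            "beta_u": cfg.risk_model.beta_u,
            "smoking_odds": cfg.smoking_model.or_at_1gy,
            "baseline_smoking": cfg.smoking_model.baseline_prob,
            "dose_gm": cfg.dose_model.geometric_mean,
            "dose_gsd": cfg.dose_model.geometric_sd,
            "n_dose_categories": cfg.n_dose_categories,
            "n_reps": s.n_reps,
            "seed": cfg.seed,
        }
        for (model, analysis), arm in s.arms.items():
            prefix = f"{model}_{'a1' if analysis == 'adjusted' else 'a2'}"
            row[f"{prefix}_bias"] = arm.mean_relative_bias
            row[f"{prefix}_se"] = arm.mean_se
            row[f"{prefix}_coverage"] = arm.coverage95
            row[f"{prefix}_n_converged"] = arm.n_converged
            row[f"{prefix}_mc_se_bias"] = arm.mc_se_of_bias
        rows.append(row)
    return pd.DataFrame(rows)


def write_results_csv(summaries: Sequence[ScenarioSummary], path) -> None:
    """Write the wide results table to CSV (>= 6 significant digits)."""
    summaries_to_frame(summaries).to_csv(path, index=False, float_format="%.8g")
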