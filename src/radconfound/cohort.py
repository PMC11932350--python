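"""Synthetic cohort generation.

One cohort is a cross-section of male workers who received their entire
dose before entry (age 20, t = 0) and are followed for ``follow_up``
years.  Per subject the generator draws a capped log-normal dose, a
logistic-in-dose smoking indicator, a standard-normal frailty, then a
cancer death time (Weibull, hazard scaled by exp(br*dose + bs*smk +
bu*u)) and a non-cancer death time (inversion method).  The observed
time is the minimum of the two death times and the administrative
horizon; only cancer death counts as an event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DoseModel, ScenarioConfig, SmokingModel
from .hazards import InversionSampler, weibull_time

__all__ = ["Cohort", "sample_doses", "assign_smoking", "simulate_outcomes", "generate_cohort"]


@dataclass(frozen=True)
class Cohort:
    """Per-subject simulated follow-up data (parallel numpy arrays)."""

    dose: np.ndarray   # Gy, in [0, cap]
    smk: np.ndarray    # {0, 1}
    u: np.ndarray      # frailty, real
    time: np.ndarray   # years in (0, follow_up]
    event: np.ndarray  # 1 = cancer death, 0 = censored

    def __len__(self) -> int:
        return len(self.dose)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self)),
                "dose": self.dose,
                "smk": self.smk,
                "u": self.u,
                "time": self.time,
                "event": self.event,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def sample_doses(n: int, dm: DoseModel, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` capped log-normal doses (Gy)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    mu = np.log(dm.geometric_mean)
    sigma = np.log(dm.geometric_sd)
    doses = rng.lognormal(mean=mu, sigma=sigma, size=n)
    return np.minimum(doses, dm.cap)


def assign_smoking(doses: np.ndarray, sm: SmokingModel, rng: np.random.Generator) -> np.ndarray:
    """Bernoulli smoking status with logit linear in dose.

    The model is ``logit p(d) = logit(p0) + log(or_at_1gy) * d``, so the
    odds ratio comparing 1 Gy to 0 Gy equals ``or_at_1gy`` exactly.
    """
    p = sm.probability(doses)
    return (rng.random(len(doses)) < p).astype(np.int8)


def simulate_outcomes(
    doses: np.ndarray,
    smk: np.ndarray,
    u: np.ndarray,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    sampler: InversionSampler | None = None,
) -> Cohort:
    """Draw death times and apply the censoring rule.

    Cancer death time uses the Weibull hazard scaled by the subject's
    hazard ratio; non-cancer death time uses the inversion sampler
    (beyond-horizon draws mean no non-cancer death in the window).
    Event = 1 iff the cancer death time is the strict minimum of the two
    death times and the follow-up horizon.
    """
    if not (len(doses) == len(smk) == len(u)):
        raise ValueError("input vectors must have equal length")
    rm = cfg.risk_model
    lam = np.exp(rm.beta_r * doses + rm.beta_s * smk + rm.beta_u * u)
    u_c = rng.random(len(doses))
    t_cancer = weibull_time(cfg.cancer_hazard, lam, _open_unit(u_c))
    if sampler is None:
        sampler = InversionSampler(cfg.noncancer_hazard, cfg.follow_up)
    u_n = rng.random(len(doses))
    t_other = sampler.sample(_open_unit(u_n))
    time = np.minimum(np.minimum(t_cancer, t_other), cfg.follow_up)
    event = ((t_cancer < t_other) & (t_cancer < cfg.follow_up)).astype(np.int8)
    return Cohort(dose=doses, smk=smk, u=u, time=time, event=event)


def generate_cohort(
    cfg: ScenarioConfig,
    rep_index: int = 0,
    sampler: InversionSampler | None = None,
) -> Cohort:
    """Generate the ``rep_index``-th replicate cohort of a scenario.

    Deterministic given ``(cfg.seed, rep_index)``; replicates use
    independent child streams spawned from the root seed, so results do
    not depend on execution order or parallelism.
    """
    if rep_index < 0:
        raise ValueError("rep_index must be non-negative")
    seq = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(rep_index,))
    rng = np.random.default_rng(seq)
    doses = sample_doses(cfg.cohort_size, cfg.dose_model, rng)
    smk = assign_smoking(doses, cfg.smoking_model, rng)
    u = rng.standard_normal(cfg.cohort_size)
    return simulate_outcomes(doses, smk, u, cfg, rng, sampler=sampler)


def _open_unit(u: np.ndarray) -> np.ndarray:
    # default_rng.random() is uniform on [0, 1); nudge exact zeros into
    # the open interval required by the inverse-CDF samplers
    tiny = np.finfo(float).tiny
    return np.where(u <= 0.0, tiny, u)
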